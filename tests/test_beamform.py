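"""DAS/DMAS image formation: delayed sampling, pair sums, scaling laws."""

import numpy as np
import pytest

import mwibeam as mw
from mwibeam.beamform import pairwise_product_sum, sample_delayed
from mwibeam.errors import ConfigurationError
from mwibeam.geometry import DelayTable, ImagingGrid
from mwibeam.preprocess import TimeDomainData


def _td(gamma, dt=1.0):
    return TimeDomainData(gamma=np.asarray(gamma, float), dt=dt, t0=0.0)


def _point_grid(n):
    pts = np.zeros((n, 3))
    pts[:, 0] = np.arange(n) * 0.01
    return ImagingGrid(points=pts, shape=(n, 1), spacing=0.01,
                       extent=((0, (n - 1) * 0.01), (0, 0), (0, 0)))


class TestSampleDelayed:
    def test_zero_delay_is_identity(self):
        td = _td(np.arange(8.0).reshape(8, 1, 1, 1))
        out = sample_delayed(td, (1, 1, 1), 0.0)
        assert np.array_equal(out, np.arange(8.0))

    def test_integer_delay_equals_slicing(self):
        sig = np.arange(8.0)
        td = _td(sig.reshape(8, 1, 1, 1), dt=2.0)
        out = sample_delayed(td, (1, 1, 1), 3 * 2.0)
        assert np.array_equal(out[:5], sig[3:])
        assert np.all(out[5:] == 0)

    def test_half_sample_interpolation(self):
        td = _td(np.array([0.0, 1.0, 0.0]).reshape(3, 1, 1, 1))
        out = sample_delayed(td, (1, 1, 1), 0.5)
        assert out[0] == pytest.approx(0.5) and out[1] == pytest.approx(0.5)

    def test_negative_delay_rejected(self):
        td = _td(np.zeros((4, 1, 1, 1)))
        with pytest.raises(ValueError):
            sample_delayed(td, (1, 1, 1), -1.0)


class TestPairwiseProductSum:
    def test_fast_equals_enumeration(self):
        rng = np.random.default_rng(2)
        x = rng.standard_normal((20, 16))
        fast = pairwise_product_sum(x, "fast")
        slow = pairwise_product_sum(x, "enumerate")
        assert np.allclose(fast, slow, rtol=1e-12)

    def test_three_identical_impulses_give_three_pairs(self):
        x = np.zeros((3, 5))
        x[:, 2] = 1.0
        assert pairwise_product_sum(x, "fast")[2] == pytest.approx(3.0)


class TestImages:
    def _setup(self, n_ch=(2, 2, 2), n_t=32, n_vox=4, seed=0):
        rng = np.random.default_rng(seed)
        gamma = rng.standard_normal((n_t,) + n_ch)
        td = TimeDomainData(gamma=gamma, dt=0.5, t0=0.0)
        grid = _point_grid(n_vox)
        tau = rng.uniform(0, n_t * 0.5 * 0.5, size=(n_vox,) + n_ch)
        return td, DelayTable(tau=tau, background_eps=1.0), grid

    def test_zero_signals_give_zero_maps(self):
        td, delays, grid = self._setup()
        td = TimeDomainData(gamma=np.zeros_like(td.gamma), dt=td.dt)
        assert np.all(mw.das_image(td, delays, grid, gate=None).values == 0)
        assert np.all(mw.dmas_image(td, delays, grid, gate=None).values == 0)

    def test_dmas_matches_pair_enumeration_oracle(self):
        td, delays, grid = self._setup()
        img = mw.dmas_image(td, delays, grid, gate=None)
        tau_flat = delays.tau.reshape(grid.n_points, -1)
        g = td.gamma.reshape(td.n_t, -1)
        for v in range(grid.n_points):
            x = np.stack([
                sample_delayed(
                    TimeDomainData(gamma=g[:, c].reshape(-1, 1, 1, 1), dt=td.dt),
                    (1, 1, 1), tau_flat[v, c])
                for c in range(g.shape[1])
            ])
            expected = pairwise_product_sum(x, "enumerate").sum() * td.dt
            assert img.values[v] == pytest.approx(expected, rel=1e-12)

    def test_quadratic_scale_law(self):
        td, delays, grid = self._setup()
        k = 3.0
        td_k = TimeDomainData(gamma=k * td.gamma, dt=td.dt)
        for fn in (mw.das_image, mw.dmas_image):
            base = fn(td, delays, grid, gate=None).values
            scaled = fn(td_k, delays, grid, gate=None).values
            assert np.allclose(scaled, k ** 2 * base, rtol=1e-12)

    def test_channel_order_invariance(self):
        td, delays, grid = self._setup()
        perm = [1, 0]  # swap the two tx channels, data and delays together
        td_p = TimeDomainData(gamma=td.gamma[:, perm], dt=td.dt)
        delays_p = DelayTable(tau=delays.tau[:, perm], background_eps=1.0)
        for fn in (mw.das_image, mw.dmas_image):
            assert np.allclose(fn(td, delays, grid, gate=None).values,
                               fn(td_p, delays_p, grid, gate=None).values,
                               rtol=1e-12)

    def test_single_channel_dmas_rejected(self):
        rng = np.random.default_rng(0)
        td = TimeDomainData(gamma=rng.standard_normal((16, 1, 1, 1)), dt=1.0)
        grid = _point_grid(2)
        delays = DelayTable(tau=np.zeros((2, 1, 1, 1)), background_eps=1.0)
        with pytest.raises(ConfigurationError):
            mw.dmas_image(td, delays, grid)

    def test_single_channel_das_is_gated_energy(self):
        rng = np.random.default_rng(0)
        gamma = rng.standard_normal((16, 1, 1, 1))
        td = TimeDomainData(gamma=gamma, dt=0.5, t0=0.0)
        grid = _point_grid(1)
        delays = DelayTable(tau=np.zeros((1, 1, 1, 1)), background_eps=1.0)
        img = mw.das_image(td, delays, grid, gate=None)
        assert img.values[0] == pytest.approx((gamma ** 2).sum() * 0.5, rel=1e-12)

    def test_literal_mode_no_rx_pairs_gives_zero(self):
        # the printed index ranges require rx' >= rx + 1: with a single Rx
        # antenna the literal reading has no pairs at all
        rng = np.random.default_rng(3)
        td = TimeDomainData(gamma=rng.standard_normal((16, 2, 1, 2)), dt=1.0)
        grid = _point_grid(2)
        delays = DelayTable(tau=rng.uniform(0, 4, (2, 2, 1, 2)),
                            background_eps=1.0)
        img = mw.dmas_image(td, delays, grid, gate=None, pair_mode="literal")
        assert np.all(img.values == 0)

    def test_literal_equals_unordered_when_only_rx_varies(self):
        rng = np.random.default_rng(4)
        td = TimeDomainData(gamma=rng.standard_normal((16, 1, 4, 1)), dt=1.0)
        grid = _point_grid(3)
        delays = DelayTable(tau=rng.uniform(0, 4, (3, 1, 4, 1)),
                            background_eps=1.0)
        lit = mw.dmas_image(td, delays, grid, gate=None, pair_mode="literal")
        uno = mw.dmas_image(td, delays, grid, gate=None, pair_mode="unordered")
        assert np.allclose(lit.values, uno.values, rtol=1e-12)

    def test_single_noiseless_scatterer_recovered(self, scaled_geom, freqs101,
                                                  grid2mm, delays2mm):
        ph = mw.make_phantom("B", with_interior=False)
        truth = np.array(ph.scatterers[0][0])
        td = mw.preprocess_dataset(
            mw.simulate_scatter_dataset(ph, scaled_geom, freqs101))
        img = mw.dmas_image(td, delays2mm, grid2mm)
        peak = grid2mm.points[np.argmax(img.values)]
        assert np.linalg.norm(peak - truth) <= 0.010
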