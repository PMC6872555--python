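"""Array geometry, imaging grids and delay tables."""

import numpy as np
import pytest

import mwibeam as mw
from mwibeam.errors import ConfigurationError
from mwibeam.geometry import ImagingGrid


class TestArrayConstruction:
    def test_interleaved_16_antenna_ring(self):
        geom = mw.build_cylindrical_array(8, 8, 0.1, 50, 7.2)
        assert geom.n_tx + geom.n_rx == 16
        assert geom.n_phi == 50 and geom.n_odd == 25
        # Rx offset by half the Tx spacing
        assert geom.rx_base_angles[0] - geom.tx_base_angles[0] == pytest.approx(22.5)
        assert np.allclose(np.diff(geom.tx_base_angles), 45.0)

    def test_minimal_two_position_geometry(self):
        geom = mw.build_cylindrical_array(1, 1, 0.1, 2, 180.0)
        assert geom.tx_base_angles[0] == 0.0
        assert geom.rx_base_angles[0] == pytest.approx(180.0)

    @pytest.mark.parametrize("kwargs", [
        dict(n_tx=8, n_rx=8, radius=0.1, n_phi=49, phi_step=7.2),   # odd n_phi
        dict(n_tx=8, n_rx=8, radius=0.1, n_phi=50, phi_step=7.0),   # no closure
        dict(n_tx=8, n_rx=8, radius=-0.1, n_phi=50, phi_step=7.2),  # bad radius
    ])
    def test_invalid_configurations_rejected(self, kwargs):
        with pytest.raises(ConfigurationError):
            mw.build_cylindrical_array(**kwargs)


class TestAntennaPositions:
    def test_rotation_index_one_is_one_step_past_base(self):
        geom = mw.build_cylindrical_array(8, 8, 0.1, 50, 7.2)
        tx, _ = mw.antenna_positions_at_rotation(geom, 1)
        expected = 0.1 * np.array([np.cos(np.deg2rad(7.2)), np.sin(np.deg2rad(7.2)), 0.0])
        assert np.allclose(tx[0], expected, atol=1e-15)

    def test_full_cycle_periodicity(self):
        geom = mw.build_cylindrical_array(8, 8, 0.1, 50, 7.2)
        a = mw.antenna_positions_at_rotation(geom, 1)
        b = mw.antenna_positions_at_rotation(geom, geom.n_phi + 1)
        assert np.allclose(a[0], b[0], atol=1e-12) and np.allclose(a[1], b[1], atol=1e-12)

    def test_positions_on_cylinder(self):
        geom = mw.build_cylindrical_array(8, 8, 0.1, 50, 7.2, z_plane=0.05)
        for phi in (1, 17, 50):
            tx, rx = mw.antenna_positions_at_rotation(geom, phi)
            for pts in (tx, rx):
                assert np.allclose(pts[:, 0] ** 2 + pts[:, 1] ** 2, 0.1 ** 2,
                                   rtol=1e-12)
                assert np.all(pts[:, 2] == 0.05)

    def test_index_below_one_rejected(self):
        geom = mw.build_cylindrical_array(8, 8, 0.1, 50, 7.2)
        with pytest.raises(IndexError):
            mw.antenna_positions_at_rotation(geom, 0)


class TestImagingGrid:
    def test_square_slice_point_count(self):
        grid = mw.build_imaging_grid(0.1, 0.01)
        assert grid.n_points == 121 and grid.shape == (11, 11)

    def test_spacing_larger_than_extent_gives_single_point(self):
        grid = mw.build_imaging_grid(0.01, 0.05)
        assert grid.n_points == 1

    def test_volume_with_three_levels_triples_count(self):
        flat = mw.build_imaging_grid(0.1, 0.01, mode="slice2d")
        vol = mw.build_imaging_grid(0.1, 0.01, mode="volume3d", z_extent=0.02)
        assert vol.n_points == 3 * flat.n_points

    def test_extent_outside_array_rejected(self):
        with pytest.raises(ConfigurationError):
            mw.build_imaging_grid(0.2, 0.01, array_radius=0.1)

    def test_points_row_major_and_inside_cylinder(self):
        grid = mw.build_imaging_grid(0.08, 0.02, array_radius=0.1)
        assert np.all(np.hypot(grid.points[:, 0], grid.points[:, 1]) <= 0.1)
        arr = grid.points[:, 1].reshape(grid.shape)
        assert np.all(np.diff(arr, axis=1) > 0)  # y varies fastest


class TestDistancesAndDelays:
    def test_center_point_distance_is_radius_at_every_rotation(self, scaled_geom):
        grid = mw.build_imaging_grid(0.001, 0.01)  # single point at the origin
        dist = mw.compute_distance_tables(grid, scaled_geom)
        assert np.allclose(dist.tx_to_point, 0.1, rtol=1e-12)
        assert np.allclose(dist.point_to_rx, 0.1, rtol=1e-12)

    def test_point_coinciding_with_antenna_gives_zero(self, scaled_geom):
        tx, _ = mw.antenna_positions_at_rotation(scaled_geom, 1)
        grid = ImagingGrid(points=tx[:1], shape=(1, 1), spacing=0.001,
                           extent=((0, 0), (0, 0), (0, 0)))
        dist = mw.compute_distance_tables(grid, scaled_geom)
        assert dist.tx_to_point[0, 0, 0] == 0.0

    def test_distances_match_bruteforce(self, scaled_geom):
        rng = np.random.default_rng(11)
        pts = rng.uniform(-0.03, 0.03, size=(5, 3))
        pts[:, 2] = 0.0
        grid = ImagingGrid(points=pts, shape=(5, 1), spacing=0.001,
                           extent=((0, 0), (0, 0), (0, 0)))
        dist = mw.compute_distance_tables(grid, scaled_geom)
        for l, phi in enumerate(scaled_geom.odd_phi_indices):
            tx, rx = mw.antenna_positions_at_rotation(scaled_geom, int(phi))
            for i in range(5):
                for a in range(scaled_geom.n_tx):
                    expected = np.sqrt(((pts[i] - tx[a]) ** 2).sum())
                    assert dist.tx_to_point[i, a, l] == pytest.approx(
                        expected, rel=1e-15)

    def test_delay_closed_form_and_scaling(self):
        # tx at (0.1,0,0), rx at (-0.1,0,0), point at origin: path 0.2 m
        geom = mw.build_cylindrical_array(1, 1, 0.1, 2, 180.0)
        # rotate back so tx sits at 0 deg: rotation 1 puts base+180... use
        # base angles directly via rotation 2 (=full turn)
        grid = mw.build_imaging_grid(0.001, 0.01)
        dist = mw.compute_distance_tables(grid, geom)
        tau1 = mw.compute_delay_table(dist, eps_b=1.0)
        assert tau1.tau[0, 0, 0, 0] == pytest.approx(0.2 / mw.C_VACUUM, rel=1e-12)
        assert tau1.tau[0, 0, 0, 0] == pytest.approx(6.6713e-10, rel=1e-4)
        tau4 = mw.compute_delay_table(dist, eps_b=4.0)
        assert np.allclose(tau4.tau, 2.0 * tau1.tau, rtol=1e-15)

    def test_background_eps_below_one_rejected(self, grid2mm, scaled_geom):
        dist = mw.compute_distance_tables(
            mw.build_imaging_grid(0.01, 0.01), scaled_geom)
        with pytest.raises(ValueError):
            mw.compute_delay_table(dist, eps_b=0.5)

    def test_delay_table_matches_scalar_loop(self, scaled_geom):
        rng = np.random.default_rng(5)
        pts = rng.uniform(-0.03, 0.03, size=(20, 3))
        pts[:, 2] = 0.0
        grid = ImagingGrid(points=pts, shape=(20, 1), spacing=0.001,
                           extent=((0, 0), (0, 0), (0, 0)))
        dist = mw.compute_distance_tables(grid, scaled_geom)
        table = mw.compute_delay_table(dist, eps_b=2.5)
        for l, phi in enumerate(scaled_geom.odd_phi_indices):
            tx, rx = mw.antenna_positions_at_rotation(scaled_geom, int(phi))
            for i in (0, 7, 19):
                for a in range(scaled_geom.n_tx):
                    for b in range(scaled_geom.n_rx):
                        d = (np.linalg.norm(pts[i] - tx[a])
                             + np.linalg.norm(pts[i] - rx[b]))
                        expected = np.sqrt(2.5) * d / mw.C_VACUUM
                        assert table.tau[i, a, b, l] == pytest.approx(
                            expected, rel=1e-15)

    def test_delay_symmetric_under_txrx_swap(self):
        g1 = mw.build_cylindrical_array(2, 2, 0.1, 4, 90.0)
        g2 = mw.ArrayGeometry(n_tx=2, n_rx=2, radius=0.1, z_plane=0.0,
                              n_phi=4, phi_step=90.0,
                              tx_base_angles=g1.rx_base_angles,
                              rx_base_angles=g1.tx_base_angles)
        grid = mw.build_imaging_grid(0.04, 0.01)
        t1 = mw.compute_delay_table(mw.compute_distance_tables(grid, g1)).tau
        t2 = mw.compute_delay_table(mw.compute_distance_tables(grid, g2)).tau
        assert np.allclose(t1, np.swapaxes(t2, 1, 2), rtol=1e-15)

    def test_center_voxel_delay_rotation_invariant(self, scaled_geom):
        grid = mw.build_imaging_grid(0.001, 0.01)
        tau = mw.compute_delay_table(
            mw.compute_distance_tables(grid, scaled_geom)).tau
        assert np.allclose(tau, tau[..., :1], rtol=1e-12)
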