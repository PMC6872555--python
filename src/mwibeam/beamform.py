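"""Confocal image formation: delay-and-sum (DAS) and delay-multiply-and-sum (DMAS).

For every image point the per-channel signals are aligned by the point's
two-way propagation delay — ``x_c(t) = Gamma_c(t + tau(i, c))`` — so that a
scatterer actually located at that point produces wavelets coincident at
t = 0 in every channel.  DAS scores the point by the integrated square of
the coherent sum; DMAS by the integrated sum of pairwise products of
distinct channels, which rewards inter-channel coherence and suppresses
incoherent clutter:

    Y_DAS(i)  = int ( sum_c x_c(t) )^2 dt
    Y_DMAS(i) = int sum_{c < c'} x_c(t) x_c'(t) dt
              = int ( (sum_c x_c)^2 - sum_c x_c^2 ) / 2 dt

The identity on the second line is the fast form used in production; the
explicit pair enumeration is retained as an independent oracle
(:func:`pairwise_product_sum` with ``method="enumerate"``).

By default the score is evaluated at the single time sample nearest the
aligned arrival (``gate="auto"``) — the classic confocal evaluation.  That
choice is what makes the image sensitive to a *common* per-voxel delay
error: integrated over the whole record (``gate=None``), every pairwise
product is a cross-correlation at a fixed channel-pair lag and is invariant
under a delay shift applied equally to all channels — precisely the shift
the iterative delay correction applies; and any window of a carrier period
or wider averages the carrier phase away.  Scored at the arrival itself, a
common delay error dtau costs a factor cos^2(2 pi f_c dtau), which the
correction visibly recovers.  An explicit ``(t_lo, t_hi)`` window is also
accepted.

Products of signed signals are summed as-is; the raw (possibly negative)
map is preserved for metrics, and clamping happens only at display time.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np

from .errors import ConfigurationError, ShapeError
from .geometry import DelayTable, ImagingGrid
from .preprocess import TimeDomainData

GateSpec = tuple[float, float] | None | Literal["auto"]


@dataclass(frozen=True)
class ScatteringIntensityMap:
    """Per-voxel scattering intensity (the reconstructed image)."""

    values: np.ndarray
    grid: ImagingGrid
    algorithm: str
    n_iter: int = 0

    def __post_init__(self) -> None:
        if self.values.shape != (self.grid.n_points,):
            raise ShapeError("map length must equal the grid point count")
        if not np.all(np.isfinite(self.values)):
            raise ShapeError("map contains non-finite values")

    def as_array(self) -> np.ndarray:
        """Values reshaped to the grid shape (row-major)."""
        return self.values.reshape(self.grid.shape)


def sample_delayed(
    td: TimeDomainData, channel: tuple[int, int, int], tau: float
) -> np.ndarray:
    """One channel's signal aligned by ``tau``: returns ``Gamma(t_k + tau)``.

    ``channel`` is 1-based ``(tx, rx, odd_frame)`` where ``odd_frame`` is the
    ordinal of the odd rotation (1 for phi = 1, 2 for phi = 3, ...).  Values
    are linearly interpolated at fractional-sample offsets; samples falling
    outside the record are zero.  ``tau = 0`` is the identity; an integer
    multiple of dt reduces to index slicing.
    """
    if tau < 0:
        raise ValueError(f"tau must be >= 0, got {tau}")
    tx, rx, frame = channel
    sig = td.gamma[:, tx - 1, rx - 1, frame - 1]
    pos = np.arange(td.n_t) + tau / td.dt
    return _gather(sig, pos)


def _gather(signal: np.ndarray, pos: np.ndarray) -> np.ndarray:
    """Linear interpolation of ``signal`` at fractional indices ``pos`` (0 outside)."""
    n = signal.shape[0]
    i0 = np.floor(pos).astype(np.int64)
    frac = pos - i0
    i1 = i0 + 1
    v0 = np.where((i0 >= 0) & (i0 < n), signal[np.clip(i0, 0, n - 1)], 0.0)
    v1 = np.where((i1 >= 0) & (i1 < n), signal[np.clip(i1, 0, n - 1)], 0.0)
    return v0 * (1.0 - frac) + v1 * frac


def pairwise_product_sum(x: np.ndarray, method: str = "fast") -> np.ndarray:
    """Sum of products over unordered distinct channel pairs, per time sample.

    ``x`` has shape (n_channels, n_t).  ``method="fast"`` uses the
    ((sum)^2 - sum of squares)/2 identity; ``method="enumerate"`` loops over
    every pair explicitly and serves as the independent oracle.
    """
    x = np.asarray(x, float)
    if x.ndim != 2:
        raise ShapeError("expected (n_channels, n_t)")
    if method == "fast":
        s1 = x.sum(axis=0)
        s2 = (x * x).sum(axis=0)
        return 0.5 * (s1 * s1 - s2)
    if method == "enumerate":
        n_ch = x.shape[0]
        out = np.zeros(x.shape[1])
        for a in range(n_ch):
            for b in range(a + 1, n_ch):
                out += x[a] * x[b]
        return out
    raise ConfigurationError(f"unknown method {method!r}")


def _gate_samples(td: TimeDomainData, gate: GateSpec) -> np.ndarray:
    """Indices of the time samples inside the coherence gate.

    ``"auto"`` selects the single sample nearest the aligned arrival (t = 0):
    the classic confocal evaluation.  Wider windows must stay well below half
    a carrier period to remain phase-sensitive — sample sums of cos^2 over a
    period-scale window are constant (or even inverted) in the common phase
    offset, which would blind the image to exactly the delay error the
    iterative correction removes.
    """
    t = td.times
    if gate == "auto":
        return np.array([int(np.argmin(np.abs(t)))])
    if gate is None:
        return np.arange(td.n_t)
    lo, hi = gate
    if hi <= lo:
        raise ConfigurationError(f"empty gate ({lo}, {hi})")
    idx = np.nonzero((t >= lo) & (t <= hi))[0]
    if idx.size == 0:
        raise ConfigurationError("gate contains no time samples")
    return idx


def _check_consistency(td: TimeDomainData, delays: DelayTable, grid: ImagingGrid) -> None:
    if delays.tau.shape[1:] != td.gamma.shape[1:]:
        raise ShapeError(
            f"delay table channels {delays.tau.shape[1:]} != data channels "
            f"{td.gamma.shape[1:]}"
        )
    if delays.tau.shape[0] != grid.n_points:
        raise ShapeError("delay table voxel count != grid point count")


def _accumulate(
    td: TimeDomainData, delays: DelayTable, grid: ImagingGrid, gate: GateSpec
) -> tuple[np.ndarray, np.ndarray]:
    """Per-voxel sum and sum-of-squares of aligned channels over the gate.

    Returns ``(S1, S2)`` of shape (n_voxels, n_gate_samples); channels are the
    flattened (tx, rx, odd_frame) axes in C order, matching the delay table.
    """
    k_idx = _gate_samples(td, gate)
    n_t = td.n_t
    g = td.gamma.reshape(n_t, -1)                    # (n_t, n_ch)
    tau_flat = delays.tau.reshape(grid.n_points, -1)  # (n_vox, n_ch)
    n_vox, n_ch = tau_flat.shape
    s1 = np.zeros((n_vox, k_idx.size))
    s2 = np.zeros((n_vox, k_idx.size))
    chunk = max(1, int(4_000_000 // max(k_idx.size, 1)))
    for lo in range(0, n_vox, chunk):
        hi = min(lo + chunk, n_vox)
        for c in range(n_ch):
            pos = tau_flat[lo:hi, c, None] / td.dt + k_idx[None, :]
            x = _gather(g[:, c], pos)
            s1[lo:hi] += x
            s2[lo:hi] += x * x
    return s1, s2


def das_image(
    td: TimeDomainData,
    delays: DelayTable,
    grid: ImagingGrid,
    gate: GateSpec = "auto",
) -> ScatteringIntensityMap:
    """Delay-and-sum image: integrated square of the coherent channel sum."""
    _check_consistency(td, delays, grid)
    s1, _ = _accumulate(td, delays, grid, gate)
    values = (s1 * s1).sum(axis=1) * td.dt
    return ScatteringIntensityMap(values=values, grid=grid, algorithm="das")


def dmas_image(
    td: TimeDomainData,
    delays: DelayTable,
    grid: ImagingGrid,
    gate: GateSpec = "auto",
    pair_mode: Literal["unordered", "literal"] = "unordered",
) -> ScatteringIntensityMap:
    """Delay-multiply-and-sum image over distinct channel pairs.

    ``pair_mode="unordered"`` (default) sums every unordered distinct pair of
    the flattened (tx, rx, odd rotation) channel set — the standard DMAS
    construction.  ``pair_mode="literal"`` reproduces the nested index ranges
    (phi' >= phi, tx' >= tx, rx' >= rx + 1) as printed in some formulations;
    it skips cross terms and is retained for comparison only (loop
    implementation, small inputs).
    """
    _check_consistency(td, delays, grid)
    n_ch = int(np.prod(td.gamma.shape[1:]))
    if n_ch < 2:
        raise ConfigurationError("DMAS needs at least two channels (no pairs otherwise)")
    if pair_mode == "unordered":
        s1, s2 = _accumulate(td, delays, grid, gate)
        values = (0.5 * (s1 * s1 - s2)).sum(axis=1) * td.dt
        return ScatteringIntensityMap(values=values, grid=grid, algorithm="dmas")
    if pair_mode != "literal":
        raise ConfigurationError(f"unknown pair_mode {pair_mode!r}")

    k_idx = _gate_samples(td, gate)
    _, n_tx, n_rx, n_odd = td.gamma.shape
    values = np.zeros(grid.n_points)
    for i in range(grid.n_points):
        aligned = np.empty((n_tx, n_rx, n_odd, k_idx.size))
        for a in range(n_tx):
            for b in range(n_rx):
                for p in range(n_odd):
                    pos = delays.tau[i, a, b, p] / td.dt + k_idx
                    aligned[a, b, p] = _gather(td.gamma[:, a, b, p], pos)
        acc = 0.0
        for p in range(n_odd):
            for a in range(n_tx):
                for b in range(n_rx):
                    for p2 in range(p, n_odd):
                        for a2 in range(a, n_tx):
                            for b2 in range(b + 1, n_rx):
                                acc += float(
                                    aligned[a, b, p] @ aligned[a2, b2, p2]
                                )
        values[i] = acc * td.dt
    return ScatteringIntensityMap(values=values, grid=grid, algorithm="dmas-literal")
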