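"""Skin-artifact removal and frequency-to-time conversion.

The raw cube S(f, tx, rx, phi) is split by rotation parity: the odd frames
(phi = 1, 3, ..., N_phi - 1) are the original illumination, the even frames
the offset illumination.  Their elementwise difference cancels everything
that is rotation-invariant — dominated by the air-skin interface reflection —
while localized scatterer responses, which move with the rotation, persist.

The differenced spectra are then converted to time-domain signals
Gamma(t, tx, rx, phi_odd) by a band-limited inverse Fourier synthesis: the
acquisition band is kept at its true position on the frequency axis so that
signal delays map to true round-trip times, which is what the delay tables
assume.  The synthesis is evaluated on a time grid with

    dt = 1 / (pad_factor * n_freq * df),    record length T = 1 / df,

optionally windowed (Hann by default: sidelobe suppression materially
affects DMAS clutter).  A small acausal margin (one eighth of the record)
is included ahead of t = 0 so that wavelets whose corrected arrival falls at
or slightly before zero keep their left tail inside the record.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np

from .errors import FormatError, ShapeError
from .simulate import ScatterDataset

_FREQ_UNIFORM_RTOL = 1e-6


@dataclass(frozen=True)
class TimeDomainData:
    """Real signals gamma[t, tx, rx, phi_odd] on a uniform time grid.

    ``t0`` is the time of the first sample (may be negative: acausal margin);
    ``band`` is the acquisition band (f_lo, f_hi) in Hz, carried along so that
    beamformers can derive a default coherence gate from the carrier period.
    """

    gamma: np.ndarray      # (n_t, n_tx, n_rx, n_odd) float
    dt: float
    t0: float = 0.0
    band: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ShapeError("dt must be > 0")
        if not np.all(np.isfinite(self.gamma)):
            raise ShapeError("time-domain data contains non-finite values")

    @property
    def n_t(self) -> int:
        return self.gamma.shape[0]

    @property
    def times(self) -> np.ndarray:
        return self.t0 + self.dt * np.arange(self.n_t)


def split_even_odd(ds: ScatterDataset) -> tuple[np.ndarray, np.ndarray]:
    """Split the cube by rotation parity.

    Returns ``(s_odd, s_even)`` holding phi = 1, 3, ..., N_phi - 1 and
    phi = 2, 4, ..., N_phi respectively, each with N_phi / 2 frames.
    """
    n_phi = ds.s.shape[3]
    if n_phi % 2 != 0:
        raise ShapeError(f"n_phi must be even for the odd/even split, got {n_phi}")
    return ds.s[:, :, :, 0::2].copy(), ds.s[:, :, :, 1::2].copy()


def rotation_subtract(s_odd: np.ndarray, s_even: np.ndarray) -> np.ndarray:
    """Elementwise difference of paired rotation frames.

    Frame k pairs phi_odd = 2k - 1 with phi_even = 2k; anything identical
    across rotations (the skin term) cancels exactly.  Antisymmetric under
    swapping the arguments.
    """
    if s_odd.shape != s_even.shape:
        raise ShapeError(
            f"odd/even cubes must match, got {s_odd.shape} vs {s_even.shape}"
        )
    return s_odd - s_even


def _check_uniform(freqs: np.ndarray) -> float:
    df = np.diff(freqs)
    if freqs.size < 2:
        raise FormatError("need at least two frequency points")
    if np.any(df <= 0) or np.max(np.abs(df - df[0])) > _FREQ_UNIFORM_RTOL * df[0]:
        raise FormatError("frequency grid must be uniform and ascending")
    return float(df[0])


def _window(n: int, kind: str) -> np.ndarray:
    if kind == "none":
        return np.ones(n)
    if kind == "hann":
        return np.hanning(n)
    if kind == "hamming":
        return np.hamming(n)
    raise FormatError(f"unknown window {kind!r}; choose none, hann or hamming")


def band_synthesis(
    s: np.ndarray,
    freqs: np.ndarray,
    pad_factor: int = 4,
    window: Literal["none", "hann", "hamming"] = "none",
    t0: float | None = None,
) -> tuple[np.ndarray, float, float]:
    """Band-limited inverse Fourier synthesis (complex analytic output).

    ``y(t_k) = (1/n_f) sum_n w_n S(f_n) exp(+2j pi f_n t_k)`` evaluated on
    ``n_t = pad_factor * n_f`` samples with ``dt = 1 / (pad_factor * n_f * df)``.
    With ``pad_factor = 1`` and no window the discrete Parseval identity
    ``n_f * sum_k |y_k|^2 == sum_n |S_n|^2`` holds exactly regardless of the
    band's center frequency.  Returns ``(y, dt, t0)`` with frequency on the
    first axis of ``s`` replaced by time.
    """
    freqs = np.asarray(freqs, float)
    df = _check_uniform(freqs)
    if pad_factor < 1:
        raise FormatError("pad_factor must be >= 1")
    n_f = freqs.size
    n_t = pad_factor * n_f
    dt = 1.0 / (pad_factor * n_f * df)
    if t0 is None:
        t0 = -(n_t // 8) * dt
    t = t0 + dt * np.arange(n_t)
    w = _window(n_f, window)
    basis = np.exp(2j * np.pi * t[:, None] * freqs[None, :]) / n_f   # (n_t, n_f)
    flat = (w[:, None] * s.reshape(n_f, -1)) if s.ndim > 1 else (w * s)[:, None]
    y = basis @ flat.reshape(n_f, -1)
    return y.reshape((n_t,) + s.shape[1:]), dt, float(t0)


def to_time_domain(
    s: np.ndarray,
    freqs: np.ndarray,
    window: Literal["none", "hann", "hamming"] = "hann",
    pad_factor: int = 4,
    t0: float | None = None,
) -> TimeDomainData:
    """Convert a (skin-removed) complex cube to real time-domain signals.

    The real part of the analytic synthesis is retained as Gamma, because the
    beamformer multiplies signed signals; envelopes are for display only.
    """
    y, dt, t0_out = band_synthesis(s, freqs, pad_factor=pad_factor,
                                   window=window, t0=t0)
    return TimeDomainData(gamma=np.ascontiguousarray(y.real), dt=dt,
                          t0=t0_out, band=(float(freqs[0]), float(freqs[-1])))


def preprocess_dataset(
    ds: ScatterDataset,
    window: Literal["none", "hann", "hamming"] = "hann",
    pad_factor: int = 4,
) -> TimeDomainData:
    """Full preprocessing: odd/even split, rotation subtraction, time conversion."""
    s_odd, s_even = split_even_odd(ds)
    return to_time_domain(rotation_subtract(s_odd, s_even), ds.freqs,
                          window=window, pad_factor=pad_factor)
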