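"""Synthetic multistatic scattering-data generator.

Replaces the antenna-array/VNA acquisition with a Born-type point-scatterer
forward model so the full reconstruction chain can be exercised at desk
scale.  For each frequency f, transmit antenna tx, receive antenna rx and
rotation position phi, the complex sample is

    S(f, tx, rx, phi) = sum_s  a_s / (d_tx * d_rx) * exp(-j 2 pi f tau_s)
                        + skin(f, tx, rx)  +  noise

where ``d_tx``/``d_rx`` are the antenna-to-scatterer distances at that
rotation, ``tau_s`` the two-way electrical delay, and amplitudes spread as
1/r per leg (3D Green-function magnitude).  Three features of the measured
data matter to the reconstruction chain and are emulated explicitly:

* **Skin reflection** — a rotation-invariant additive term per (f, tx, rx),
  orders of magnitude stronger than the tumor response, whose path length is
  taken via the skin-ring point between each Tx/Rx pair.  Rotation
  subtraction cancels it exactly, which is the premise of that step.
* **Interior retardation** — breast tissue slows propagation relative to
  the air background assumed by the delay tables.  Each scatterer response
  is delayed by the extra electrical path ``(sqrt(eps_int) - sqrt(eps_b)) *
  L_chord`` accumulated along the ray chords inside a retarding disk.  This
  is the delay error the iteratively corrected beamformer exists to fix;
  with ``interior=None`` the model reduces to pure background-medium delays.
* **Noise** — i.i.d. circularly-symmetric complex Gaussian per sample, one
  seeded stream.

Tissue dielectric dispersion (complex permittivity eps_r + i sigma/(omega
eps0)) is available as an optional per-frequency modulation of the scatterer
reflectivity and is off by default.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .errors import ConfigurationError
from .geometry import ArrayGeometry, C_VACUUM, antenna_positions_at_rotation

#: vacuum permittivity, F/m (CODATA)
EPS0 = 8.8541878128e-12


@dataclass(frozen=True)
class DielectricSpec:
    """Lossy dielectric: relative permittivity eps_r and conductivity sigma (S/m)."""

    eps_r: float
    sigma: float = 0.0

    def __post_init__(self) -> None:
        if self.eps_r < 1.0:
            raise ConfigurationError(f"eps_r must be >= 1, got {self.eps_r}")
        if self.sigma < 0.0:
            raise ConfigurationError(f"sigma must be >= 0, got {self.sigma}")


def complex_permittivity(spec: DielectricSpec, freq: float) -> complex:
    """Complex relative permittivity eps_r + i sigma / (omega eps0) at ``freq`` Hz.

    The loss term scales as 1/omega: halving the frequency doubles the
    imaginary part.  Raises for non-positive frequency.
    """
    freq = float(freq)
    if freq <= 0:
        raise ValueError(f"frequency must be > 0, got {freq}")
    omega = 2.0 * np.pi * freq
    return complex(spec.eps_r, spec.sigma / (omega * EPS0))


@dataclass(frozen=True)
class PhantomModel:
    """Abstract phantom: background medium, skin ring, point scatterers, noise.

    ``scatterers`` is a list of ``(position_m, reflectivity)`` pairs.  ``skin``
    is ``(ring_radius_m, reflectivity)`` or ``None``.  ``interior`` is
    ``(eps_r, disk_radius_m)`` or ``None`` and models tissue retardation (see
    module docstring).  ``noise_sigma`` is the standard deviation of the
    complex noise per sample (real and imaginary parts each get
    ``noise_sigma / sqrt(2)``).
    """

    background_eps: float = 1.0
    scatterers: tuple[tuple[tuple[float, float, float], float], ...] = ()
    skin: tuple[float, float] | None = None
    interior: tuple[float, float] | None = None
    noise_sigma: float = 0.0
    seed: int = 0
    dispersion: DielectricSpec | None = None
    name: str = "custom"

    def __post_init__(self) -> None:
        if self.background_eps < 1.0:
            raise ConfigurationError("background_eps must be >= 1")
        if self.noise_sigma < 0.0:
            raise ConfigurationError("noise_sigma must be >= 0")
        for pos, refl in self.scatterers:
            if not np.all(np.isfinite(pos)) or not np.isfinite(refl):
                raise ConfigurationError("scatterer positions/reflectivities must be finite")


# Preset scatterer layouts: 0 / 1 / 2 tumors inside a 50 mm skin ring, at
# mid-radius offsets.  Rotation subtraction inherently leaves a sign-flipped
# replica of each scatterer at its position rotated by one rotation step, so
# a tumor's offset radius bounds how far that replica can land from it
# (2 r sin(step/2)); mid-radius placement keeps the replica inside the main
# response blob even for coarse desk-scale rotation grids.  The two-tumor
# layout is point-symmetric about the axis, so both tumors see identical
# imaging conditions under the array's rotational symmetry.
_PRESETS: dict[str, tuple[tuple[tuple[float, float, float], float], ...]] = {
    "A": (),
    "B": (((0.0085, 0.0085, 0.0), 1.0),),
    "C": (((0.0085, 0.0085, 0.0), 1.0), ((-0.0085, -0.0085, 0.0), 1.0)),
}

_SKIN_RADIUS = 0.050          # m
_SKIN_REFLECTIVITY = 100.0    # skin-to-tumor amplitude ratio 100:1
_INTERIOR_EPS = 1.2           # effective retarding permittivity inside the skin ring


def make_phantom(
    preset: str,
    seed: int = 0,
    noise_sigma: float = 0.0,
    array_radius: float = 0.1,
    with_interior: bool = True,
) -> PhantomModel:
    """Deterministic preset phantoms.

    ``"A"`` is skin only, ``"B"`` adds one tumor, ``"C"`` two tumors.  All
    scatterers must lie inside the array cylinder.  ``with_interior=False``
    removes the retarding interior disk, reducing the forward model to pure
    background-medium delays.
    """
    key = preset.upper()
    if key not in _PRESETS:
        raise ConfigurationError(f"unknown phantom preset {preset!r}; choose A, B or C")
    scatterers = _PRESETS[key]
    for pos, _ in scatterers:
        if np.hypot(pos[0], pos[1]) >= array_radius:
            raise ConfigurationError(
                f"scatterer at {pos} lies outside the array radius {array_radius} m"
            )
    return PhantomModel(
        background_eps=1.0,
        scatterers=scatterers,
        skin=(_SKIN_RADIUS, _SKIN_REFLECTIVITY),
        interior=(_INTERIOR_EPS, _SKIN_RADIUS) if with_interior else None,
        noise_sigma=float(noise_sigma),
        seed=int(seed),
        name=f"preset-{key}",
    )


@dataclass(frozen=True)
class ScatterDataset:
    """Complex S-parameter cube S(f, tx, rx, phi) with axis metadata."""

    s: np.ndarray           # complex, (n_freq, n_tx, n_rx, n_phi)
    freqs: np.ndarray       # Hz, strictly increasing
    geometry: ArrayGeometry
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        f = np.asarray(self.freqs, float)
        if f.ndim != 1 or f.size == 0 or np.any(np.diff(f) <= 0):
            raise ConfigurationError("freqs must be non-empty and strictly increasing")
        expected = (f.size, self.geometry.n_tx, self.geometry.n_rx, self.geometry.n_phi)
        if self.s.shape != expected:
            raise ConfigurationError(
                f"data cube shape {self.s.shape} != expected {expected}"
            )
        if not np.all(np.isfinite(self.s.view(float))):
            raise ConfigurationError("data cube contains non-finite values")

    @property
    def n_freq(self) -> int:
        return self.freqs.size


def default_frequency_grid(n: int = 201, f_start: float = 2.7e9, f_stop: float = 8.0e9) -> np.ndarray:
    """Evenly spaced acquisition band; defaults mirror 201 points over 2.7-8.0 GHz."""
    return np.linspace(f_start, f_stop, n)


def _chord_inside_disk(p_out: np.ndarray, p_in: np.ndarray, radius: float) -> float:
    """Length of the segment p_out -> p_in that lies inside the xy-disk of ``radius``.

    ``p_in`` is assumed inside the disk; ``p_out`` outside (antenna position).
    Only the xy projection matters (the rig is planar).
    """
    a = np.asarray(p_out[:2], float)
    b = np.asarray(p_in[:2], float)
    d = b - a
    # solve |a + t d|^2 = radius^2 for t in [0, 1]
    aa = float(d @ d)
    if aa == 0.0:
        return 0.0
    bb = 2.0 * float(a @ d)
    cc = float(a @ a) - radius * radius
    disc = bb * bb - 4.0 * aa * cc
    if disc <= 0.0:
        return 0.0
    t_entry = (-bb - np.sqrt(disc)) / (2.0 * aa)
    t_entry = min(max(t_entry, 0.0), 1.0)
    return float((1.0 - t_entry) * np.sqrt(aa))


def _skin_ring_point(tx: np.ndarray, rx: np.ndarray, radius: float, z: float) -> np.ndarray:
    """Specular point on the skin ring between a Tx/Rx pair: the ring point in
    the angular-midpoint direction of the two antennas."""
    u = tx[:2] / np.linalg.norm(tx[:2]) + rx[:2] / np.linalg.norm(rx[:2])
    n = np.linalg.norm(u)
    if n < 1e-12:  # antennas diametrically opposite: pick a perpendicular
        u = np.array([-tx[1], tx[0]]) / np.linalg.norm(tx[:2])
        n = 1.0
    q = radius * u / n
    return np.array([q[0], q[1], z])


def simulate_scatter_dataset(
    phantom: PhantomModel,
    geom: ArrayGeometry,
    freqs: np.ndarray | Sequence[float] | None = None,
) -> ScatterDataset:
    """Simulate the full S(f, tx, rx, phi) cube for a phantom.

    Deterministic given (phantom, geometry, freqs, phantom.seed); linear in
    the scatterer reflectivities with the noise off.
    """
    f = np.asarray(default_frequency_grid() if freqs is None else freqs, float)
    if f.ndim != 1 or f.size == 0 or np.any(np.diff(f) <= 0):
        raise ConfigurationError("freqs must be non-empty and strictly increasing")
    sqrt_eb = np.sqrt(phantom.background_eps)
    s = np.zeros((f.size, geom.n_tx, geom.n_rx, geom.n_phi), dtype=complex)

    disp_scale = None
    if phantom.dispersion is not None:
        # per-frequency reflectivity modulation: dielectric contrast against the
        # background, normalized at the band center
        eps_f = np.array([complex_permittivity(phantom.dispersion, fi) for fi in f])
        contrast = np.abs(eps_f - phantom.background_eps)
        ref = np.abs(
            complex_permittivity(phantom.dispersion, float(f[f.size // 2]))
            - phantom.background_eps
        )
        disp_scale = contrast / ref if ref > 0 else np.ones_like(contrast)

    for j in range(geom.n_phi):
        phi = j + 1
        tx_pos, rx_pos = antenna_positions_at_rotation(geom, phi)
        for pos, refl in phantom.scatterers:
            p = np.asarray(pos, float)
            d_tx = np.linalg.norm(tx_pos - p, axis=1)      # (n_tx,)
            d_rx = np.linalg.norm(rx_pos - p, axis=1)      # (n_rx,)
            if np.any(d_tx == 0) or np.any(d_rx == 0):
                raise ConfigurationError("scatterer coincides with an antenna position")
            path = sqrt_eb * (d_tx[:, None] + d_rx[None, :])
            if phantom.interior is not None:
                eps_i, r_i = phantom.interior
                extra = np.sqrt(eps_i) - sqrt_eb
                l_tx = np.array([_chord_inside_disk(t, p, r_i) for t in tx_pos])
                l_rx = np.array([_chord_inside_disk(r, p, r_i) for r in rx_pos])
                path = path + extra * (l_tx[:, None] + l_rx[None, :])
            tau = path / C_VACUUM                           # (n_tx, n_rx)
            amp = refl / (d_tx[:, None] * d_rx[None, :])
            term = amp[None, :, :] * np.exp(
                -2j * np.pi * f[:, None, None] * tau[None, :, :]
            )
            if disp_scale is not None:
                term = term * disp_scale[:, None, None]
            s[:, :, :, j] += term

    if phantom.skin is not None:
        r_skin, refl_skin = phantom.skin
        tx_pos, rx_pos = antenna_positions_at_rotation(geom, 1)
        skin_term = np.zeros((f.size, geom.n_tx, geom.n_rx), dtype=complex)
        for a in range(geom.n_tx):
            for b in range(geom.n_rx):
                q = _skin_ring_point(tx_pos[a], rx_pos[b], r_skin, geom.z_plane)
                p1 = np.linalg.norm(tx_pos[a] - q)
                p2 = np.linalg.norm(q - rx_pos[b])
                tau = sqrt_eb * (p1 + p2) / C_VACUUM
                skin_term[:, a, b] = (refl_skin / (p1 * p2)) * np.exp(
                    -2j * np.pi * f * tau
                )
        # identical across phi by construction: rotation subtraction cancels it
        s += skin_term[:, :, :, None]

    if phantom.noise_sigma > 0:
        rng = np.random.default_rng(phantom.seed)
        scale = phantom.noise_sigma / np.sqrt(2.0)
        s = s + scale * (
            rng.standard_normal(s.shape) + 1j * rng.standard_normal(s.shape)
        )

    meta = {"seed": phantom.seed, "phantom": phantom.name,
            "noise_sigma": phantom.noise_sigma}
    return ScatterDataset(s=s, freqs=f, geometry=geom, meta=meta)


def scatterer_signal_rms(phantom: PhantomModel, geom: ArrayGeometry,
                         freqs: np.ndarray | None = None) -> float:
    """RMS amplitude of the noiseless scatterer-only response (skin excluded).

    Used to set noise levels relative to the tumor signal: a phantom with
    ``noise_sigma = 0.1 * scatterer_signal_rms(...)`` has roughly 20 dB
    per-sample SNR on the tumor response, which is what this package treats
    as a moderate, realistic acquisition noise level.
    """
    bare = replace(phantom, skin=None, noise_sigma=0.0)
    ds = simulate_scatter_dataset(bare, geom, freqs)
    return float(np.sqrt(np.mean(np.abs(ds.s) ** 2)))
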