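"""Cylindrical antenna array geometry, imaging grids and propagation-delay tables.

The acquisition hardware this package models is a ring of interleaved
transmit/receive antennas mounted on a turntable that steps through a full
rotation around the object.  Everything downstream of the raw data cube —
rotation subtraction, beamforming, iterative delay correction — only needs
the geometry through two derived products:

* Euclidean distances from every imaging-grid point to every antenna at
  every *odd* rotation position (the frames that survive rotation
  subtraction), and
* the two-way propagation delay
  ``tau(i, tx, rx, phi_odd) = sqrt(eps_b) * (P_tx->i + P_i->rx) / c``
  through a homogeneous background medium of relative permittivity eps_b.

Conventions (used consistently by the simulator and the reconstructor):

* right-handed Cartesian coordinates in meters, cylinder axis = z;
* counter-clockwise positive rotation; rotation index ``k`` places the
  antennas ``k * phi_step`` degrees past their base angles, so index 1 is
  one step past the base orientation;
* antenna and rotation indices are 1-based at the API surface, mirroring
  the tx = 1..8, phi = 1..N_phi bookkeeping of multistatic radar rigs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np

from .errors import ConfigurationError

#: speed of light in vacuum, m/s
C_VACUUM = 299_792_458.0

_ANGLE_CLOSURE_TOL_DEG = 1e-6


@dataclass(frozen=True)
class ArrayGeometry:
    """Cylindrical interleaved Tx/Rx array on a rotating platform.

    ``tx_base_angles`` / ``rx_base_angles`` are the angular positions (degrees)
    of the antennas at rotation index 0 (the unrotated base orientation).
    """

    n_tx: int
    n_rx: int
    radius: float
    z_plane: float
    n_phi: int
    phi_step: float
    tx_base_angles: np.ndarray
    rx_base_angles: np.ndarray

    def __post_init__(self) -> None:
        if self.n_tx < 1 or self.n_rx < 1:
            raise ConfigurationError("need at least one Tx and one Rx antenna")
        if self.radius <= 0:
            raise ConfigurationError(f"array radius must be > 0, got {self.radius}")
        if self.n_phi < 2 or self.n_phi % 2 != 0:
            raise ConfigurationError(
                f"n_phi must be even and >= 2 for the odd/even rotation split, got {self.n_phi}"
            )
        if self.phi_step <= 0:
            raise ConfigurationError(f"phi_step must be > 0, got {self.phi_step}")
        if abs(self.n_phi * self.phi_step - 360.0) > _ANGLE_CLOSURE_TOL_DEG:
            raise ConfigurationError(
                f"rotation positions must close a full turn: "
                f"n_phi * phi_step = {self.n_phi * self.phi_step!r} != 360"
            )
        all_angles = np.concatenate(
            [np.asarray(self.tx_base_angles, float) % 360.0,
             np.asarray(self.rx_base_angles, float) % 360.0]
        )
        if len(np.unique(np.round(all_angles, 9))) != all_angles.size:
            raise ConfigurationError("tx/rx base angles must be pairwise distinct")

    @property
    def n_odd(self) -> int:
        """Number of odd rotation positions (phi = 1, 3, ..., n_phi - 1)."""
        return self.n_phi // 2

    @property
    def odd_phi_indices(self) -> np.ndarray:
        """The 1-based rotation indices retained after the odd/even split."""
        return np.arange(1, self.n_phi, 2)


def build_cylindrical_array(
    n_tx: int,
    n_rx: int,
    radius: float,
    n_phi: int,
    phi_step: float,
    z_plane: float = 0.0,
) -> ArrayGeometry:
    """Build an interleaved cylindrical array.

    Tx antennas sit at ``k * 360 / n_tx`` degrees (k = 0..n_tx-1); Rx antennas
    are offset by half the Tx spacing, giving uniform bistatic angle coverage.
    For the 8 + 8 configuration this puts Tx at 0, 45, ... and Rx at
    22.5, 67.5, ... degrees.
    """
    if n_tx < 1 or n_rx < 1:
        raise ConfigurationError("need at least one Tx and one Rx antenna")
    tx_angles = np.arange(n_tx) * (360.0 / n_tx)
    rx_angles = np.arange(n_rx) * (360.0 / n_rx) + 180.0 / n_tx
    return ArrayGeometry(
        n_tx=n_tx,
        n_rx=n_rx,
        radius=float(radius),
        z_plane=float(z_plane),
        n_phi=int(n_phi),
        phi_step=float(phi_step),
        tx_base_angles=tx_angles,
        rx_base_angles=rx_angles,
    )


def _positions(geom: ArrayGeometry, base_angles: np.ndarray, rotation_deg: float) -> np.ndarray:
    ang = np.deg2rad((np.asarray(base_angles, float) + rotation_deg) % 360.0)
    return np.column_stack(
        [geom.radius * np.cos(ang),
         geom.radius * np.sin(ang),
         np.full(ang.shape, geom.z_plane)]
    )


def antenna_positions_at_rotation(
    geom: ArrayGeometry, phi_index: int
) -> tuple[np.ndarray, np.ndarray]:
    """Tx and Rx antenna positions (meters) at 1-based rotation index ``phi_index``.

    Rotation index k places the array ``k * phi_step`` degrees past the base
    angles.  Indices above ``n_phi`` wrap periodically (the positions repeat
    after a full turn); indices below 1 raise ``IndexError``.
    """
    if phi_index < 1:
        raise IndexError(f"phi_index must be >= 1, got {phi_index}")
    rotation = (phi_index % geom.n_phi) * geom.phi_step
    return (
        _positions(geom, geom.tx_base_angles, rotation),
        _positions(geom, geom.rx_base_angles, rotation),
    )


@dataclass(frozen=True)
class ImagingGrid:
    """Ordered (row-major) set of 3D image points with uniform spacing."""

    points: np.ndarray          # (n_points, 3) meters
    shape: tuple[int, ...]      # (nx, ny) or (nx, ny, nz)
    spacing: float              # meters, identical along every axis
    extent: tuple[tuple[float, float], ...]  # per-axis (lo, hi) bounding box
    mode: str = "slice2d"

    def __post_init__(self) -> None:
        if self.spacing <= 0:
            raise ConfigurationError("grid spacing must be > 0")
        if self.points.shape != (int(np.prod(self.shape)), 3):
            raise ConfigurationError("grid point count inconsistent with shape")

    @property
    def n_points(self) -> int:
        return self.points.shape[0]


def _axis(center: float, half: float, spacing: float) -> np.ndarray:
    n_half = int(np.floor(half / spacing + 1e-12))
    return center + spacing * np.arange(-n_half, n_half + 1)


def build_imaging_grid(
    extent: float | Sequence[float],
    spacing: float,
    mode: Literal["slice2d", "volume3d"] = "slice2d",
    z_plane: float = 0.0,
    z_extent: float | None = None,
    array_radius: float | None = None,
) -> ImagingGrid:
    """Build a centered, row-major imaging grid.

    ``extent`` is the side length (meters) of the reconstruction box, either a
    scalar (square footprint) or ``(x_extent, y_extent)``.  ``slice2d`` places
    all points at ``z = z_plane``; ``volume3d`` stacks z levels spaced like the
    transverse axes over ``z_extent`` (default: same as the x extent) around
    ``z_plane``.  When ``array_radius`` is given the footprint is validated to
    lie inside the antenna cylinder.
    """
    if spacing <= 0:
        raise ConfigurationError("spacing must be > 0")
    if np.isscalar(extent):
        ex = ey = float(extent)  # type: ignore[arg-type]
    else:
        ex, ey = (float(v) for v in extent)  # type: ignore[misc]
    if ex <= 0 or ey <= 0:
        raise ConfigurationError("extent must be positive")
    if array_radius is not None and np.hypot(ex / 2, ey / 2) > array_radius:
        raise ConfigurationError(
            f"grid extent ({ex} x {ey} m) reaches outside the array cylinder "
            f"(radius {array_radius} m)"
        )
    xs = _axis(0.0, ex / 2, spacing)
    ys = _axis(0.0, ey / 2, spacing)
    if mode == "slice2d":
        zs = np.array([z_plane])
    elif mode == "volume3d":
        ez = float(z_extent) if z_extent is not None else ex
        zs = _axis(z_plane, ez / 2, spacing)
    else:
        raise ConfigurationError(f"unknown grid mode {mode!r}")
    gx, gy, gz = np.meshgrid(xs, ys, zs, indexing="ij")
    points = np.column_stack([gx.ravel(), gy.ravel(), gz.ravel()])
    shape: tuple[int, ...]
    if mode == "slice2d":
        shape = (xs.size, ys.size)
    else:
        shape = (xs.size, ys.size, zs.size)
    extent_box = (
        (float(xs[0]), float(xs[-1])),
        (float(ys[0]), float(ys[-1])),
        (float(zs[0]), float(zs[-1])),
    )
    return ImagingGrid(points=points, shape=shape, spacing=float(spacing),
                       extent=extent_box, mode=mode)


@dataclass(frozen=True)
class DistanceTables:
    """Euclidean distances point<->antenna for every odd rotation position.

    ``tx_to_point[i, tx, l]`` and ``point_to_rx[i, rx, l]`` in meters, where
    ``l`` runs over the odd rotation indices 1, 3, ..., n_phi - 1 in order.
    """

    tx_to_point: np.ndarray
    point_to_rx: np.ndarray
    odd_phi_indices: np.ndarray


def compute_distance_tables(grid: ImagingGrid, geom: ArrayGeometry) -> DistanceTables:
    """Distances from every grid point to every Tx/Rx antenna at every odd rotation."""
    pts = grid.points
    odd = geom.odd_phi_indices
    d_tx = np.empty((grid.n_points, geom.n_tx, geom.n_odd))
    d_rx = np.empty((grid.n_points, geom.n_rx, geom.n_odd))
    for l, phi in enumerate(odd):
        tx_pos, rx_pos = antenna_positions_at_rotation(geom, int(phi))
        d_tx[:, :, l] = np.linalg.norm(pts[:, None, :] - tx_pos[None, :, :], axis=2)
        d_rx[:, :, l] = np.linalg.norm(pts[:, None, :] - rx_pos[None, :, :], axis=2)
    return DistanceTables(tx_to_point=d_tx, point_to_rx=d_rx, odd_phi_indices=odd)


@dataclass(frozen=True)
class DelayTable:
    """Two-way propagation delays tau[i, tx, rx, l] in seconds (l = odd rotations)."""

    tau: np.ndarray
    background_eps: float
    c: float = C_VACUUM


def compute_delay_table(dist: DistanceTables, eps_b: float = 1.0) -> DelayTable:
    """Two-way delay through a homogeneous background of relative permittivity eps_b.

    ``tau(i, tx, rx, l) = sqrt(eps_b) * (P_tx->i + P_i->rx) / c``; eps_b = 1 is
    air.  Raises for eps_b < 1 (faster-than-vacuum background).
    """
    if eps_b < 1.0:
        raise ValueError(f"background permittivity must be >= 1, got {eps_b}")
    tau = (
        np.sqrt(eps_b)
        * (dist.tx_to_point[:, :, None, :] + dist.point_to_rx[:, None, :, :])
        / C_VACUUM
    )
    return DelayTable(tau=tau, background_eps=float(eps_b))
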