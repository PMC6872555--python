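"""Image-quality metrics: signal-to-mean ratio (SMR) and localization error.

SMR is the ratio of the tumor-region energy to the mean energy over the
whole image, in dB.  Two variants are in circulation — the maximum over the
tumor region ("peak") and the mean over the tumor region ("region_mean") —
so both are provided.  "Energy" here is the per-voxel intensity value
clamped at zero: the DMAS map is already a quadratic (pairwise-product)
quantity, so it is not squared again by default (``squared=True`` applies
the squared convention).  The dB convention is 10 log10 of the energy ratio.

Localization error compares the strongest well-separated local maxima of a
map against known ground-truth scatterer positions via greedy nearest
matching; a truth without a detection is reported as a missed detection
(NaN), never as an exception.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .beamform import ScatteringIntensityMap
from .errors import ShapeError


@dataclass(frozen=True)
class SMRReport:
    smr_db: float
    tumor_energy: float
    mean_energy: float
    mode: str
    mask_size: int


def tumor_mask_spheres(grid, positions, radius: float = 0.005) -> np.ndarray:
    """Boolean voxel mask: union of spheres of ``radius`` around ``positions``."""
    mask = np.zeros(grid.n_points, dtype=bool)
    for pos in np.atleast_2d(np.asarray(positions, float)):
        mask |= np.linalg.norm(grid.points - pos[None, :], axis=1) <= radius
    return mask


def smr(map_: ScatteringIntensityMap, tumor_mask: np.ndarray,
        mode: str = "peak", squared: bool = False) -> SMRReport:
    """Signal-to-mean ratio of a reconstructed map, in dB.

    ``mode="peak"``: max intensity over the tumor mask over the whole-image
    mean.  ``mode="region_mean"``: mean over the mask over the whole-image
    mean.  Negative intensities are clamped at zero before the ratio.
    """
    mask = np.asarray(tumor_mask, bool)
    if mask.shape != map_.values.shape:
        raise ShapeError("tumor mask must match the map")
    if not mask.any():
        raise ValueError("tumor mask is empty")
    v = np.clip(map_.values, 0.0, None)
    if squared:
        v = v * v
    mean_energy = float(v.mean())
    if mean_energy == 0.0:
        raise ValueError("map is identically zero; SMR undefined")
    if mode == "peak":
        tumor_energy = float(v[mask].max())
    elif mode == "region_mean":
        tumor_energy = float(v[mask].mean())
    else:
        raise ValueError(f"unknown SMR mode {mode!r}")
    ratio = tumor_energy / mean_energy
    smr_db = 10.0 * np.log10(ratio) if ratio > 0 else -np.inf
    return SMRReport(smr_db=float(smr_db), tumor_energy=tumor_energy,
                     mean_energy=mean_energy, mode=mode,
                     mask_size=int(mask.sum()))


@dataclass(frozen=True)
class LocalizationResult:
    """Per-truth localization errors (meters; NaN = missed) and detections."""

    errors: np.ndarray            # (n_truth,)
    detected_positions: np.ndarray  # (n_detections, 3)
    n_detections: int

    @property
    def n_missed(self) -> int:
        return int(np.sum(np.isnan(self.errors)))


def find_peaks(map_: ScatteringIntensityMap, n_peaks: int,
               min_separation: float | None = None) -> np.ndarray:
    """Positions of the ``n_peaks`` strongest well-separated local maxima.

    A voxel is a candidate if it attains the maximum of its neighborhood of
    radius ``min_separation`` (default 2 grid spacings — suppresses
    double-counting of the halo around a true response).  Candidates are
    taken strongest-first, discarding any within ``min_separation`` of an
    already accepted peak.
    """
    sep = 2.0 * map_.grid.spacing if min_separation is None else float(min_separation)
    arr = np.clip(map_.as_array(), 0.0, None)
    size = 2 * max(1, int(round(sep / map_.grid.spacing))) + 1
    local_max = (arr == ndimage.maximum_filter(arr, size=size, mode="nearest"))
    local_max &= arr > 0
    cand = np.flatnonzero(local_max.ravel())
    cand = cand[np.argsort(arr.ravel()[cand])[::-1]]
    chosen: list[int] = []
    pts = map_.grid.points
    for idx in cand:
        if len(chosen) >= n_peaks:
            break
        if all(np.linalg.norm(pts[idx] - pts[j]) >= sep for j in chosen):
            chosen.append(int(idx))
    return pts[chosen] if chosen else np.empty((0, 3))


def localization_error(map_: ScatteringIntensityMap, true_positions,
                       min_separation: float | None = None) -> LocalizationResult:
    """Greedy nearest matching of detected peaks to ground-truth positions."""
    truths = np.atleast_2d(np.asarray(true_positions, float))
    detections = find_peaks(map_, n_peaks=truths.shape[0],
                            min_separation=min_separation)
    errors = np.full(truths.shape[0], np.nan)
    if detections.shape[0]:
        dist = np.linalg.norm(truths[:, None, :] - detections[None, :, :], axis=2)
        remaining = set(range(detections.shape[0]))
        # greedy: repeatedly take the globally closest (truth, detection) pair
        order = np.dstack(np.unravel_index(np.argsort(dist, axis=None), dist.shape))[0]
        assigned_truths: set[int] = set()
        for ti, di in order:
            if ti in assigned_truths or di not in remaining:
                continue
            errors[ti] = dist[ti, di]
            assigned_truths.add(int(ti))
            remaining.discard(int(di))
    return LocalizationResult(errors=errors, detected_positions=detections,
                              n_detections=int(detections.shape[0]))
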