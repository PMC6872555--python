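"""Dataset and image persistence, and run configuration.

Native containers are versioned columnar text so that fixtures remain
inspectable: header lines are prefixed ``#`` as ``key=value`` pairs, data
rows follow in CSV form at full decimal precision (``%.17g`` round-trips
IEEE-754 doubles bit-exactly).  Paths ending in ``.h5``/``.hdf5`` select an
equivalent HDF5 container for speed; the text form is the reference.

Dataset rows are ``freq_hz, tx, rx, phi, re, im`` with 1-based antenna and
rotation indices.  Reading validates completeness (every (f, tx, rx, phi)
combination exactly once) and header consistency (the rotation positions
must close a full turn), and reports the first gap it finds.

Images store the grid header (shape, spacing, extent, mode) plus row-major
voxel values; an 8-bit ASCII-PGM grayscale export (peak-normalized, negative
values clamped) is provided for quick visual inspection.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .beamform import ScatteringIntensityMap
from .errors import FormatError
from .geometry import ArrayGeometry, ImagingGrid
from .simulate import ScatterDataset

_DATASET_MAGIC = "mwibeam-dataset v1"
_IMAGE_MAGIC = "mwibeam-image v1"
_FLOAT_FMT = "%.17g"


def _header_lines(magic: str, fields: dict) -> list[str]:
    lines = [f"# {magic}"]
    for key, value in fields.items():
        if isinstance(value, float):
            value = _FLOAT_FMT % value
        lines.append(f"# {key}={value}")
    return lines


def _parse_header(path: Path, magic: str) -> dict[str, str]:
    fields: dict[str, str] = {}
    with open(path) as fh:
        first = fh.readline().strip()
        if first != f"# {magic}":
            raise FormatError(f"{path}: expected header '# {magic}', got {first!r}")
        for line in fh:
            if not line.startswith("#"):
                break
            body = line[1:].strip()
            if "=" in body:
                key, _, value = body.partition("=")
                fields[key.strip()] = value.strip()
    return fields


# ---------------------------------------------------------------------------
# datasets
# ---------------------------------------------------------------------------

def write_dataset(ds: ScatterDataset, path: str | Path) -> None:
    """Persist a scattering cube (text DatasetFileV1, or HDF5 for .h5/.hdf5)."""
    path = Path(path)
    if path.suffix in (".h5", ".hdf5"):
        _write_dataset_h5(ds, path)
        return
    g = ds.geometry
    header = _header_lines(_DATASET_MAGIC, {
        "n_tx": g.n_tx, "n_rx": g.n_rx, "radius_m": g.radius,
        "z_plane_m": g.z_plane, "n_phi": g.n_phi, "phi_step_deg": g.phi_step,
        "n_freq": ds.n_freq,
        "seed": ds.meta.get("seed", ""), "phantom": ds.meta.get("phantom", ""),
    })
    n_f, n_tx, n_rx, n_phi = ds.s.shape
    f_col = np.repeat(ds.freqs, n_tx * n_rx * n_phi)
    tx_col = np.tile(np.repeat(np.arange(1, n_tx + 1), n_rx * n_phi), n_f)
    rx_col = np.tile(np.repeat(np.arange(1, n_rx + 1), n_phi), n_f * n_tx)
    phi_col = np.tile(np.arange(1, n_phi + 1), n_f * n_tx * n_rx)
    flat = ds.s.ravel()
    with open(path, "w") as fh:
        fh.write("\n".join(header) + "\n")
        fh.write("freq_hz,tx,rx,phi,re,im\n")
        np.savetxt(fh, np.column_stack([f_col, tx_col, rx_col, phi_col,
                                        flat.real, flat.imag]),
                   fmt=[_FLOAT_FMT, "%d", "%d", "%d", _FLOAT_FMT, _FLOAT_FMT],
                   delimiter=",")


def read_dataset(path: str | Path, geometry: ArrayGeometry | None = None) -> ScatterDataset:
    """Read a dataset written by :func:`write_dataset`; lossless round trip.

    If ``geometry`` is omitted it is rebuilt from the header with the default
    interleaved-array convention.
    """
    path = Path(path)
    if path.suffix in (".h5", ".hdf5"):
        return _read_dataset_h5(path, geometry)
    fields = _parse_header(path, _DATASET_MAGIC)
    try:
        n_tx, n_rx = int(fields["n_tx"]), int(fields["n_rx"])
        n_phi, n_freq = int(fields["n_phi"]), int(fields["n_freq"])
        phi_step = float(fields["phi_step_deg"])
        radius = float(fields["radius_m"])
        z_plane = float(fields["z_plane_m"])
    except (KeyError, ValueError) as exc:
        raise FormatError(f"{path}: missing or malformed header field: {exc}") from exc
    if abs(n_phi * phi_step - 360.0) > 1e-6:
        raise FormatError(
            f"{path}: header inconsistency: n_phi={n_phi} x phi_step={phi_step} "
            "does not close a full rotation"
        )
    if geometry is None:
        from .geometry import build_cylindrical_array
        geometry = build_cylindrical_array(n_tx, n_rx, radius, n_phi, phi_step, z_plane)

    table = pd.read_csv(path, comment="#", float_precision="round_trip")
    expected_cols = ["freq_hz", "tx", "rx", "phi", "re", "im"]
    if list(table.columns) != expected_cols:
        raise FormatError(f"{path}: expected columns {expected_cols}, got {list(table.columns)}")
    freqs = np.sort(table["freq_hz"].unique())
    if freqs.size != n_freq:
        raise FormatError(
            f"{path}: header says n_freq={n_freq} but rows cover {freqs.size} frequencies"
        )
    n_rows_expected = n_freq * n_tx * n_rx * n_phi
    s = np.full((n_freq, n_tx, n_rx, n_phi), np.nan + 0j, dtype=complex)
    f_idx = np.searchsorted(freqs, table["freq_hz"].to_numpy())
    tx = table["tx"].to_numpy(int) - 1
    rx = table["rx"].to_numpy(int) - 1
    phi = table["phi"].to_numpy(int) - 1
    for name, idx, n in (("tx", tx, n_tx), ("rx", rx, n_rx), ("phi", phi, n_phi)):
        if idx.min() < 0 or idx.max() >= n:
            raise FormatError(f"{path}: {name} index out of range 1..{n}")
    if len(table) != n_rows_expected:
        _report_gap(path, s, f_idx, tx, rx, phi, freqs, len(table), n_rows_expected)
    s[f_idx, tx, rx, phi] = table["re"].to_numpy() + 1j * table["im"].to_numpy()
    if np.any(np.isnan(s.real)):
        _report_gap(path, s, f_idx, tx, rx, phi, freqs, len(table), n_rows_expected,
                    filled=True)
    meta = {"seed": fields.get("seed", ""), "phantom": fields.get("phantom", "")}
    return ScatterDataset(s=s, freqs=freqs, geometry=geometry, meta=meta)


def _report_gap(path, s, f_idx, tx, rx, phi, freqs, n_rows, n_expected,
                filled: bool = False) -> None:
    probe = np.zeros(s.shape, dtype=np.int64)
    np.add.at(probe, (f_idx, tx, rx, phi), 1)
    if np.any(probe > 1):
        fi, a, b, p = (int(v[0]) for v in np.nonzero(probe > 1))
        raise FormatError(
            f"{path}: duplicate row for (freq={freqs[fi]:g} Hz, tx={a+1}, "
            f"rx={b+1}, phi={p+1})"
        )
    missing = np.nonzero(probe == 0)
    if missing[0].size:
        fi, a, b, p = (int(v[0]) for v in missing)
        raise FormatError(
            f"{path}: missing row for (freq={freqs[fi]:g} Hz, tx={a+1}, "
            f"rx={b+1}, phi={p+1}); {n_rows} rows found, {n_expected} expected"
        )


def _write_dataset_h5(ds: ScatterDataset, path: Path) -> None:
    import h5py

    g = ds.geometry
    with h5py.File(path, "w") as fh:
        fh.attrs["magic"] = _DATASET_MAGIC
        fh.create_dataset("s", data=ds.s)
        fh.create_dataset("freqs", data=ds.freqs)
        for key, value in (("n_tx", g.n_tx), ("n_rx", g.n_rx),
                           ("radius_m", g.radius), ("z_plane_m", g.z_plane),
                           ("n_phi", g.n_phi), ("phi_step_deg", g.phi_step),
                           ("seed", str(ds.meta.get("seed", ""))),
                           ("phantom", str(ds.meta.get("phantom", "")))):
            fh.attrs[key] = value


def _read_dataset_h5(path: Path, geometry: ArrayGeometry | None) -> ScatterDataset:
    import h5py

    with h5py.File(path, "r") as fh:
        if fh.attrs.get("magic") != _DATASET_MAGIC:
            raise FormatError(f"{path}: not a {_DATASET_MAGIC} container")
        s = fh["s"][()]
        freqs = fh["freqs"][()]
        if geometry is None:
            from .geometry import build_cylindrical_array
            geometry = build_cylindrical_array(
                int(fh.attrs["n_tx"]), int(fh.attrs["n_rx"]),
                float(fh.attrs["radius_m"]), int(fh.attrs["n_phi"]),
                float(fh.attrs["phi_step_deg"]), float(fh.attrs["z_plane_m"]),
            )
        meta = {"seed": fh.attrs.get("seed", ""), "phantom": fh.attrs.get("phantom", "")}
    return ScatterDataset(s=s, freqs=freqs, geometry=geometry, meta=meta)


# ---------------------------------------------------------------------------
# images
# ---------------------------------------------------------------------------

def write_image(map_: ScatteringIntensityMap, path: str | Path) -> None:
    """Persist an intensity map (text ImageFileV1); lossless round trip."""
    path = Path(path)
    grid = map_.grid
    extent_flat = ",".join(_FLOAT_FMT % v for pair in grid.extent for v in pair)
    header = _header_lines(_IMAGE_MAGIC, {
        "shape": ",".join(str(n) for n in grid.shape),
        "spacing_m": grid.spacing,
        "mode": grid.mode,
        "extent": extent_flat,
        "algorithm": map_.algorithm,
        "n_iter": map_.n_iter,
    })
    with open(path, "w") as fh:
        fh.write("\n".join(header) + "\n")
        np.savetxt(fh, map_.values, fmt=_FLOAT_FMT)


def read_image(path: str | Path) -> ScatteringIntensityMap:
    """Read an ImageFileV1 written by :func:`write_image`."""
    path = Path(path)
    fields = _parse_header(path, _IMAGE_MAGIC)
    try:
        shape = tuple(int(v) for v in fields["shape"].split(","))
        spacing = float(fields["spacing_m"])
        mode = fields["mode"]
        ext = [float(v) for v in fields["extent"].split(",")]
        algorithm = fields["algorithm"]
        n_iter = int(fields["n_iter"])
    except (KeyError, ValueError) as exc:
        raise FormatError(f"{path}: missing or malformed header field: {exc}") from exc
    values = np.loadtxt(path, comments="#")
    values = np.atleast_1d(values)
    if values.size != int(np.prod(shape)):
        raise FormatError(
            f"{path}: {values.size} voxel values for declared shape {shape}"
        )
    extent = tuple((ext[2 * k], ext[2 * k + 1]) for k in range(3))
    axes = [np.array([lo]) if n == 1 else lo + spacing * np.arange(n)
            for (lo, _), n in zip(extent, shape + (1,) * (3 - len(shape)))]
    gx, gy, gz = np.meshgrid(*axes, indexing="ij")
    grid = ImagingGrid(points=np.column_stack([gx.ravel(), gy.ravel(), gz.ravel()]),
                       shape=shape, spacing=spacing, extent=extent, mode=mode)
    return ScatteringIntensityMap(values=values, grid=grid, algorithm=algorithm,
                                  n_iter=n_iter)


def write_pgm(map_: ScatteringIntensityMap, path: str | Path) -> None:
    """8-bit ASCII-PGM grayscale export, peak-normalized, negatives clamped.

    Raster row r / column c correspond to grid x-index r / y-index c of the
    z slice containing the global maximum, so the brightest pixel sits at the
    map's argmax indices.
    """
    arr = np.clip(map_.as_array(), 0.0, None)
    if arr.ndim == 3:
        arr = arr[:, :, int(np.argmax(arr.max(axis=(0, 1))))]
    peak = arr.max()
    pix = np.zeros(arr.shape, dtype=int) if peak == 0 else np.rint(
        255.0 * arr / peak).astype(int)
    with open(path, "w") as fh:
        fh.write(f"P2\n{pix.shape[1]} {pix.shape[0]}\n255\n")
        for row in pix:
            fh.write(" ".join(str(v) for v in row) + "\n")


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

DEFAULT_CONFIG: dict = {
    "seed": 0,
    "geometry": {"n_tx": 8, "n_rx": 8, "radius_m": 0.1, "n_phi": 50,
                 "phi_step_deg": 7.2, "z_plane_m": 0.0},
    "grid": {"extent_m": 0.08, "spacing_m": 0.002, "mode": "slice2d"},
    "frequencies": {"start_hz": 2.7e9, "stop_hz": 8.0e9, "n": 201},
    "phantom": {"preset": "B", "noise_sigma": 0.0, "with_interior": True},
    "preprocess": {"window": "hann", "pad_factor": 4},
    "beamform": {"pair_mode": "unordered", "gate": "auto"},
    "correction": {"threshold": 1e-5, "max_iter": 7, "path_scale_m": 0.01},
    "metrics": {"tumor_radius_m": 0.005},
    "algorithms": ["das", "dmas", "icdmas"],
}


def _merge(base: dict, override: dict) -> dict:
    out = dict(base)
    for key, value in override.items():
        if isinstance(value, dict) and isinstance(out.get(key), dict):
            out[key] = _merge(out[key], value)
        else:
            out[key] = value
    return out


def load_config(path: str | Path | None = None, overrides: dict | None = None) -> dict:
    """Defaults, overlaid with a YAML file and then explicit overrides."""
    import yaml

    cfg = DEFAULT_CONFIG
    if path is not None:
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
        if not isinstance(user, dict):
            raise FormatError(f"{path}: config must be a mapping")
        cfg = _merge(cfg, user)
    if overrides:
        cfg = _merge(cfg, overrides)
    return cfg


def config_hash(cfg: dict) -> str:
    """Stable sha256 of the canonical JSON form of a config."""
    import hashlib

    return hashlib.sha256(
        json.dumps(cfg, sort_keys=True, separators=(",", ":")).encode()
    ).hexdigest()
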