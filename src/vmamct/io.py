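"""Readers/writers and run configuration.

Sinograms travel either as a lossless compressed array archive (.npz) or
as a float32 TIFF with a JSON metadata sidecar (angle grid, detector
pitch, COR).  Phantoms are two-page TIFFs (float32 MAC map, uint16 section
labels) with a CSV marker table.  Run configs are flat, versioned
key/value YAML files checked against a schema — unknown keys are errors so
a typo in a motion rate cannot pass silently.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from .elastic_rigid import ScaleSeries
from .phantom import AngleGrid, Marker, Phantom
from .projector import Sinogram
from .trajectory import MarkerTrajectory, TrajectoryFit

__all__ = [
    "load_config",
    "read_phantom",
    "read_sinogram",
    "save_config",
    "write_phantom",
    "write_run_log",
    "write_sinogram",
]

log = logging.getLogger("vmamct")

CONFIG_VERSION = 1

# key -> (type, default); None default means required
CONFIG_SCHEMA = {
    "version": (int, CONFIG_VERSION),
    "preset": (str, "two-section"),
    "grid_side": (int, 255),
    "n_angles": (int, 1200),
    "angle_step_deg": (float, 0.15),
    "section_mac": (float, 1.0),
    "marker_mac": (float, 3.0),
    "marker_radius_px": (float, 4.0),
    "rate_regular": (float, 0.00054),
    "rate_elliptic_major": (float, 0.00054),
    "rate_elliptic_minor": (float, 0.00036),
    "elliptic_axis_deg": (float, 90.0),
    "jitter_px": (float, 0.0),
    "seed": (int, 0),
    "filter": (str, "ramp"),
}


def _sidecar(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def _grid_to_meta(grid: AngleGrid) -> dict:
    step = grid.step
    if step is not None:
        return {"angle_start": float(grid.angles[0]), "angle_step": step, "n_angles": len(grid)}
    return {"angles": [float(a) for a in grid.angles]}


def _grid_from_meta(meta: dict) -> AngleGrid:
    if "angles" in meta:
        return AngleGrid(np.asarray(meta["angles"], dtype=float))
    return AngleGrid.uniform(meta["n_angles"], meta["angle_step"], meta.get("angle_start", 0.0))


def write_sinogram(sino: Sinogram, path) -> Path:
    """Write .npz (lossless) or .tif/.tiff (float32 + JSON sidecar)."""
    path = Path(path)
    meta = {
        "detector_pitch": sino.detector_pitch,
        "cor_col": sino.cor_col,
        **_grid_to_meta(sino.angle_grid),
    }
    if path.suffix == ".npz":
        np.savez_compressed(
            path,
            data=sino.data,
            angles=sino.angle_grid.angles,
            detector_pitch=sino.detector_pitch,
            cor_col=np.nan if sino.cor_col is None else sino.cor_col,
        )
    elif path.suffix in (".tif", ".tiff"):
        tifffile.imwrite(path, sino.data.astype(np.float32))
        _sidecar(path).write_text(json.dumps(meta, indent=1))
    else:
        raise ValueError(f"unsupported sinogram format {path.suffix!r}")
    return path


def read_sinogram(path) -> Sinogram:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"sinogram file not found: {path}")
    if path.suffix == ".npz":
        with np.load(path) as z:
            cor = float(z["cor_col"])
            return Sinogram(
                z["data"],
                AngleGrid(z["angles"]),
                float(z["detector_pitch"]),
                None if np.isnan(cor) else cor,
            )
    if path.suffix in (".tif", ".tiff"):
        data = np.asarray(tifffile.imread(path), dtype=float)
        side = _sidecar(path)
        if side.exists():
            meta = json.loads(side.read_text())
            return Sinogram(
                data, _grid_from_meta(meta), meta.get("detector_pitch", 1.0), meta.get("cor_col")
            )
        log.warning(
            "no metadata sidecar %s; assuming a uniform [0, 180) angle grid, "
            "pitch 1 px and unknown COR",
            side.name,
        )
        return Sinogram(data, AngleGrid.uniform(data.shape[0], 180.0 / data.shape[0]))
    raise ValueError(f"unsupported sinogram format {path.suffix!r}")


def write_phantom(phantom: Phantom, path) -> Path:
    """Two-page TIFF (float32 MAC map, uint16 labels) + marker CSV."""
    path = Path(path)
    tifffile.imwrite(
        path,
        [phantom.image.astype(np.float32), phantom.section_labels.astype(np.uint16)],
    )
    rows = [
        {"section": m.section, "row": m.row, "col": m.col, "radius": m.radius, "mac": m.mac}
        for m in phantom.markers
    ]
    pd.DataFrame(rows, columns=["section", "row", "col", "radius", "mac"]).to_csv(
        path.with_suffix(".markers.csv"), index=False
    )
    return path


def read_phantom(path) -> Phantom:
    path = Path(path)
    pages = tifffile.imread(path)
    image, labels = np.asarray(pages[0], float), np.asarray(pages[1], np.int32)
    markers = []
    mpath = path.with_suffix(".markers.csv")
    if mpath.exists():
        for _, r in pd.read_csv(mpath).iterrows():
            markers.append(Marker(r["row"], r["col"], r["radius"], r["mac"], int(r["section"])))
    return Phantom(image, labels, markers)


def trajectory_to_csv(traj: MarkerTrajectory, grid: AngleGrid, path) -> Path:
    path = Path(path)
    pd.DataFrame(
        {"angle_deg": grid.angles, "u_px": traj.u, "valid": traj.valid.astype(int)}
    ).to_csv(path, index=False)
    return path


def fit_to_csv(fit: TrajectoryFit, path) -> Path:
    path = Path(path)
    pd.DataFrame(
        [{"c": fit.c, "r": fit.r, "phi_deg": fit.phi_deg, "rms": fit.rms_residual}]
    ).to_csv(path, index=False)
    return path


def scales_to_csv(scales: ScaleSeries, grid: AngleGrid, path) -> Path:
    path = Path(path)
    pd.DataFrame(
        {
            "angle_deg": grid.angles,
            "a": scales.a,
            "b": scales.b,
            "valid": scales.valid.astype(int),
        }
    ).to_csv(path, index=False)
    return path


def load_config(path) -> dict:
    """Flat key/value YAML with schema check; unknown keys are errors."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"config file not found: {path}")
    raw = yaml.safe_load(path.read_text()) or {}
    if not isinstance(raw, dict):
        raise ValueError("config must be a flat key/value mapping")
    unknown = set(raw) - set(CONFIG_SCHEMA)
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    cfg = {}
    for key, (typ, default) in CONFIG_SCHEMA.items():
        val = raw.get(key, default)
        if val is None:
            raise ValueError(f"missing required config key {key!r}")
        try:
            cfg[key] = typ(val)
        except (TypeError, ValueError):
            raise ValueError(f"config key {key!r} must be {typ.__name__}, got {val!r}")
    if cfg["version"] != CONFIG_VERSION:
        raise ValueError(f"unsupported config version {cfg['version']}")
    return cfg


def save_config(cfg: dict, path) -> Path:
    path = Path(path)
    path.write_text(yaml.safe_dump(cfg, sort_keys=True))
    return path


def config_hash(cfg: dict) -> str:
    return hashlib.sha256(json.dumps(cfg, sort_keys=True).encode()).hexdigest()[:16]


def write_run_log(path, cfg: dict, entries: dict) -> Path:
    """Plain-text reproducibility log: config hash, seed, per-step records."""
    path = Path(path)
    lines = [f"config_hash: {config_hash(cfg)}", f"seed: {cfg.get('seed')}"]
    for k, v in entries.items():
        lines.append(f"{k}: {v}")
    path.write_text("\n".join(lines) + "\n")
    return path
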