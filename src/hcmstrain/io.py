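"""File formats: NIfTI image series, JSON contours/ground truth, CSV tables,
YAML configuration.

Every table and JSON document written by the pipeline carries a provenance
mapping (package version, master seed, config hash) so a run can be
reproduced from its outputs alone.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from . import __version__
from .phantom import TaggedSeries

__all__ = [
    "save_tagged_series",
    "load_tagged_series",
    "save_contours",
    "load_contours",
    "write_table",
    "read_table",
    "write_json",
    "read_json",
    "load_config",
    "save_config",
    "config_hash",
]


def config_hash(config: dict) -> str:
    """Stable short hash of a configuration mapping."""
    canon = json.dumps(config, sort_keys=True, default=str)
    return hashlib.sha256(canon.encode()).hexdigest()[:16]


def _provenance(seed=None, cfg_hash=None) -> dict:
    prov = {"package": f"hcmstrain {__version__}"}
    if seed is not None:
        prov["seed"] = int(seed)
    if cfg_hash is not None:
        prov["config_hash"] = cfg_hash
    return prov


# ---------------------------------------------------------------------------
# images


def save_tagged_series(series: TaggedSeries, path: str | Path,
                       seed=None, cfg_hash=None) -> None:
    """Write a tagged series as 2D+time NIfTI plus a JSON sidecar holding
    the acquisition metadata the header cannot carry."""
    path = Path(path)
    dy, dx = series.pixel_spacing_mm
    dt = float(np.median(np.diff(series.frame_times_ms)))
    data = np.transpose(series.frames, (2, 1, 0))[:, :, None, :]  # x,y,z,t
    affine = np.diag([dx, dy, 1.0, 1.0])
    img = nib.Nifti1Image(data.astype(np.float32), affine)
    img.header.set_zooms((dx, dy, 1.0, dt / 1000.0))
    img.header.set_xyzt_units("mm", "sec")
    nib.save(img, str(path))
    sidecar = {
        "frame_times_ms": series.frame_times_ms.tolist(),
        "pixel_spacing_mm": [dy, dx],
        "tag_spacing_mm": series.tag_spacing_mm,
        "slice_label": series.slice_label,
        "anchor_angle_rad": series.anchor_angle,
        "noise_sigma": series.noise_sigma,
        "center_mm": list(series.center_mm),
        "endo_radius_mm": series.endo_radius_mm,
        "epi_radius_mm": series.epi_radius_mm,
        "provenance": _provenance(seed, cfg_hash),
    }
    Path(str(path) + ".json").write_text(json.dumps(sidecar, indent=1))


def load_tagged_series(path: str | Path) -> TaggedSeries:
    img = nib.load(str(path))
    meta = json.loads(Path(str(path) + ".json").read_text())
    frames = np.transpose(np.asarray(img.dataobj)[:, :, 0, :], (2, 1, 0))
    return TaggedSeries(
        frames=frames.astype(np.float32),
        pixel_spacing_mm=tuple(meta["pixel_spacing_mm"]),
        frame_times_ms=np.asarray(meta["frame_times_ms"], dtype=float),
        tag_spacing_mm=meta["tag_spacing_mm"],
        slice_label=meta["slice_label"],
        anchor_angle=meta["anchor_angle_rad"],
        noise_sigma=meta["noise_sigma"],
        center_mm=tuple(meta["center_mm"]),
        endo_radius_mm=meta["endo_radius_mm"],
        epi_radius_mm=meta["epi_radius_mm"],
    )


# ---------------------------------------------------------------------------
# contours


def save_contours(contours: dict, path: str | Path,
                  seed=None, cfg_hash=None) -> None:
    """Contour sets as JSON: ``"slice/phase/structure" -> [[x, y], ...]``
    in mm (plain ``"structure"`` keys are allowed for single-slice sets)."""
    doc = {"provenance": _provenance(seed, cfg_hash), "contours": {}}
    for key, pts in contours.items():
        name = "/".join(str(k) for k in key) if isinstance(key, tuple) else str(key)
        doc["contours"][name] = np.asarray(pts, dtype=float).round(4).tolist()
    Path(path).write_text(json.dumps(doc))


def load_contours(path: str | Path) -> dict:
    doc = json.loads(Path(path).read_text())
    out = {}
    for name, pts in doc["contours"].items():
        parts = name.split("/")
        key = (int(parts[0]), int(parts[1]), parts[2]) if len(parts) == 3 else name
        out[key] = np.asarray(pts, dtype=float)
    return out


# ---------------------------------------------------------------------------
# tables / json / config


def write_table(df: pd.DataFrame, path: str | Path,
                seed=None, cfg_hash=None) -> None:
    """CSV with a commented provenance header line."""
    path = Path(path)
    prov = _provenance(seed, cfg_hash)
    header = "# " + " ".join(f"{k}={v}" for k, v in prov.items())
    with open(path, "w") as fh:
        fh.write(header + "\n")
        df.to_csv(fh, index=False)


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")


def write_json(obj, path: str | Path, seed=None, cfg_hash=None) -> None:
    doc = {"provenance": _provenance(seed, cfg_hash), "data": obj}

    def default(o):
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.integer, np.floating, np.bool_)):
            return o.item()
        raise TypeError(f"not JSON serializable: {type(o)}")

    Path(path).write_text(json.dumps(doc, indent=1, default=default))


def read_json(path: str | Path):
    return json.loads(Path(path).read_text())["data"]


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError("configuration must be a YAML mapping")
    return cfg


def save_config(cfg: dict, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=False)
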