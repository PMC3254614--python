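"""Readers/writers for volumes, masks, echo series, configs and results.

NIfTI-1 is the canonical volume format (echo times travel in a JSON sidecar
because the NIfTI header has no TE field); multi-page TIFF is accepted for
microscopy-style fixtures. Results are plain CSV/JSON so any downstream
tooling can consume them unchanged.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import tifffile
import yaml

from .blackpixel import LesionReport, NSIHistogram
from .containers import EchoSeries
from .errors import ValidationError

__version__ = "0.1.0"

_NIFTI_SUFFIXES = (".nii", ".nii.gz")
_TIFF_SUFFIXES = (".tif", ".tiff")


def _suffix(path: Path) -> str:
    name = path.name.lower()
    if name.endswith(".nii.gz"):
        return ".nii.gz"
    return path.suffix.lower()


def read_volume(path) -> tuple:
    """Load one magnitude volume. Returns ``(array, meta)``.

    ``meta`` holds ``voxel_size_mm`` when the format records it. NaN or
    negative intensities fail validation — magnitude MR data are non-negative.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such volume: {path}")
    sfx = _suffix(path)
    if sfx in _NIFTI_SUFFIXES:
        img = nib.load(str(path))
        data = np.asarray(img.get_fdata(), dtype=float)
        voxel = tuple(float(z) for z in img.header.get_zooms()[: data.ndim])
        meta = {"voxel_size_mm": voxel, "format": "nifti"}
    elif sfx in _TIFF_SUFFIXES:
        data = np.asarray(tifffile.imread(str(path)), dtype=float)
        meta = {"voxel_size_mm": (1.0,) * data.ndim, "format": "tiff"}
    else:
        raise ValidationError(f"unsupported volume format: {path.name}")
    if np.any(~np.isfinite(data)):
        raise ValidationError(f"{path.name}: volume contains NaN/inf voxels")
    if np.any(data < 0):
        raise ValidationError(f"{path.name}: magnitude volume has negative voxels")
    return data, meta


def write_volume(path, array, voxel_size_mm=None) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    arr = np.asarray(array, dtype=float)
    sfx = _suffix(path)
    if sfx in _NIFTI_SUFFIXES:
        affine = np.eye(4)
        if voxel_size_mm is not None:
            for i, z in enumerate(voxel_size_mm[: min(3, arr.ndim)]):
                affine[i, i] = z
        img = nib.Nifti1Image(arr, affine)
        if voxel_size_mm is not None:
            img.header.set_zooms(tuple(voxel_size_mm[: arr.ndim]))
        nib.save(img, str(path))
    elif sfx in _TIFF_SUFFIXES:
        tifffile.imwrite(str(path), arr.astype(np.float32), photometric="minisblack")
    else:
        raise ValidationError(f"unsupported volume format: {path.name}")
    return path


def read_mask(path) -> np.ndarray:
    """Load a binary mask volume; any value outside {0, 1} fails validation."""
    path = Path(path)
    sfx = _suffix(path)
    if sfx in _NIFTI_SUFFIXES:
        data = np.asarray(nib.load(str(path)).get_fdata())
    elif sfx in _TIFF_SUFFIXES:
        data = np.asarray(tifffile.imread(str(path)))
    else:
        raise ValidationError(f"unsupported mask format: {path.name}")
    if np.any(~np.isfinite(data)):
        raise ValidationError(f"{path.name}: mask contains NaN/inf")
    vals = np.unique(data)
    if not np.all(np.isin(vals, (0, 1))):
        raise ValidationError(
            f"{path.name}: mask must be binary, found values {vals[:6]}"
        )
    return data.astype(bool)


def write_mask(path, mask, voxel_size_mm=None) -> Path:
    return write_volume(path, np.asarray(mask).astype(np.uint8), voxel_size_mm)


def write_echo_series(out_dir, series: EchoSeries, prefix: str = "echo") -> dict:
    """One NIfTI per echo plus a JSON sidecar with the echo times (ms)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for i in range(series.n_echoes):
        p = out_dir / f"{prefix}_{i:02d}.nii"
        write_volume(p, series.data[i], series.voxel_size_mm)
        paths.append(p.name)
    sidecar = {
        "echo_times_ms": series.echo_times.tolist(),
        "volumes": paths,
        "voxel_size_mm": list(series.voxel_size_mm),
        "meta": {k: v for k, v in series.meta.items() if _jsonable(v)},
    }
    sidecar_path = out_dir / f"{prefix}.json"
    sidecar_path.write_text(json.dumps(sidecar, indent=2))
    return {"sidecar": sidecar_path, "volumes": [out_dir / p for p in paths]}


def read_echo_series(volume_paths=None, echo_times=None, sidecar=None) -> EchoSeries:
    """Assemble an EchoSeries from explicit volumes + TEs or from a sidecar."""
    if sidecar is not None:
        sidecar = Path(sidecar)
        info = json.loads(sidecar.read_text())
        volume_paths = [sidecar.parent / p for p in info["volumes"]]
        echo_times = info["echo_times_ms"]
    if volume_paths is None or echo_times is None:
        raise ValidationError("need volume paths and echo times (or a sidecar)")
    vols, meta = [], {}
    for p in volume_paths:
        data, m = read_volume(p)
        vols.append(data)
        meta = m
    data = np.stack(vols)
    return EchoSeries(
        data=data,
        echo_times=np.asarray(echo_times, dtype=float),
        voxel_size_mm=tuple(meta.get("voxel_size_mm", (1.0,) * (data.ndim - 1))),
    )


def _jsonable(v) -> bool:
    try:
        json.dumps(v)
        return True
    except TypeError:
        return False


def load_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValidationError(f"{path}: config must be a YAML mapping")
    return cfg


def write_provenance(out_dir, config: dict, seed: int) -> Path:
    """Record config + seed + software version next to the results."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    record = {"software": "fionmri", "version": __version__, "seed": seed,
              "config": config}
    path = out_dir / "provenance.json"
    path.write_text(json.dumps(record, indent=2, default=str))
    return path


def histogram_to_frame(hist: NSIHistogram) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "bin_start": hist.bin_edges[:-1],
            "bin_end": hist.bin_edges[1:],
            "frequency_pct": hist.frequencies,
        }
    )


def report_to_dict(report: LesionReport) -> dict:
    d = {
        "muscle_ref_pre": report.muscle_ref_pre,
        "muscle_ref_post": report.muscle_ref_post,
        "threshold_nsi": report.threshold_nsi,
        "result": dataclasses.asdict(report.result),
        "call": dataclasses.asdict(report.call) if report.call else None,
    }
    return d
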