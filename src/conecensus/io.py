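"""File formats: 16-bit TIFF images, ground-truth CSVs, JSON sidecars."""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .synthetic import SATURATION, FlatMountSpec, GroundTruth, RatioGroundTruth

__all__ = [
    "to_uint16",
    "read_image",
    "read_ratio_pair",
    "write_flatmount",
    "write_ratio_pair",
    "spec_to_dict",
    "spec_from_dict",
]


def to_uint16(image: np.ndarray) -> np.ndarray:
    """Quantize a float image to uint16, clipping at saturation."""
    return np.clip(np.round(image), 0, SATURATION).astype(np.uint16)


def read_image(path) -> np.ndarray:
    """Read a single-page grayscale TIFF as float64."""
    arr = tifffile.imread(path)
    if arr.ndim == 3:  # multi-page: first page
        arr = arr[0]
    return arr.astype(np.float64)


def read_ratio_pair(path) -> tuple[np.ndarray, np.ndarray]:
    """Read a two-page TIFF as (numerator, denominator) float64 channels."""
    arr = tifffile.imread(path)
    if arr.ndim != 3 or arr.shape[0] != 2:
        raise ValueError(f"{path}: expected a 2-page TIFF, got shape {arr.shape}")
    return arr[0].astype(np.float64), arr[1].astype(np.float64)


def spec_to_dict(spec: FlatMountSpec) -> dict:
    d = dataclasses.asdict(spec)
    d["image_size"] = list(d["image_size"])
    return d


def spec_from_dict(d: dict) -> FlatMountSpec:
    d = dict(d)
    d["image_size"] = tuple(d["image_size"])
    if d.get("retina_center") is not None:
        d["retina_center"] = tuple(d["retina_center"])
    d["crater_radius_range"] = tuple(d["crater_radius_range"])
    return FlatMountSpec(**d)


def _truth_frame(truth: GroundTruth) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "x": truth.centers[:, 0],
            "y": truth.centers[:, 1],
            "labeled": truth.labeled,
            "amplitude": truth.amplitudes,
        }
    )


def write_flatmount(outdir, stem: str, image: np.ndarray, truth: GroundTruth, spec: FlatMountSpec) -> dict:
    """Write image TIFF + ground-truth CSV + JSON sidecar; return the paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    img_path = outdir / f"{stem}.tif"
    truth_path = outdir / f"{stem}_truth.csv"
    side_path = outdir / f"{stem}_spec.json"
    tifffile.imwrite(img_path, to_uint16(image))
    _truth_frame(truth).to_csv(truth_path, index=False)
    sidecar = {
        "spec": spec_to_dict(spec),
        "seed": spec.seed,
        "counts": truth.counts,
        "crater_disks": [[list(c), r] for c, r in truth.crater_disks],
    }
    side_path.write_text(json.dumps(sidecar, indent=2, sort_keys=True))
    return {"image": str(img_path), "truth": str(truth_path), "sidecar": str(side_path)}


def write_ratio_pair(
    outdir, stem: str, num: np.ndarray, den: np.ndarray, truth: RatioGroundTruth, spec: FlatMountSpec
) -> dict:
    """Write a 2-page TIFF (numerator first) + JSON sidecar."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    img_path = outdir / f"{stem}.tif"
    side_path = outdir / f"{stem}_spec.json"
    tifffile.imwrite(img_path, np.stack([to_uint16(num), to_uint16(den)]))
    sidecar = {"spec": spec_to_dict(spec), "seed": spec.seed, "true_ratio": truth.true_ratio}
    side_path.write_text(json.dumps(sidecar, indent=2, sort_keys=True))
    return {"image": str(img_path), "sidecar": str(side_path)}
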