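"""End-to-end orchestration: simulate -> count -> ratio -> stats.

A run is described by a :class:`RunConfig` (typically loaded from a YAML
file), is deterministic given its seed, and leaves behind per-image
CSVs, a comparisons CSV, and a JSON run report echoing every parameter
so the run can be reproduced from the report alone.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import zlib

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .detection import CalibrationGrid, CellCensus, DetectionParams, calibrate_params, count_in_half_radius, detect_cones
from .geometry import fit_retina_outline, manual_geometry
from .io import read_image, read_ratio_pair, write_flatmount, write_ratio_pair
from .ratiometric import compute_ratio, normalize_to_control
from .stats import anova_dunnett, unpaired_t_test
from .synthetic import FlatMountSpec, generate_flatmount, generate_ratio_pair, preset

log = logging.getLogger("conecensus")

__all__ = ["RunConfig", "SimulatedGroup", "run_pipeline", "read_manifest", "derive_seed"]

_BASE_MANIFEST_COLUMNS = ("image_path", "group", "retina_id")
_GEOMETRY_COLUMNS = ("center_x", "center_y", "radius")
_RATIO_COLUMNS = ("sensor", "condition", "image_id")


def derive_seed(master_seed: int, *key) -> int:
    """Deterministic child seed below 2**31 from a master seed and a key.

    Uses crc32 on the key parts (not ``hash``, which is salted per
    process) so the same config + seed gives byte-identical outputs.
    """
    parts = [zlib.crc32(repr(k).encode()) for k in key]
    ss = np.random.SeedSequence([int(master_seed)] + parts)
    return int(ss.generate_state(1)[0] % (2**31))


@dataclass(frozen=True)
class SimulatedGroup:
    """One experimental arm of a simulated study."""

    name: str
    n_retinas: int = 6
    preset: str = "rd1_P20"
    image_size: int = 512
    density_multiplier: float = 1.0
    true_ratio: float = 1.0  # ratio-pair experiments only
    condition: str = "default"
    spec_overrides: dict = field(default_factory=dict)


@dataclass(frozen=True)
class RunConfig:
    """Everything needed to reproduce a pipeline run."""

    mode: str
    output_dir: str
    seed: int = 0
    manifest_path: str | None = None
    detection: DetectionParams | None = None
    calibration: CalibrationGrid | None = None
    calibration_column: str = "reference_count"
    control_group: str = "control"
    experiment_kind: str = "flatmount"  # or "ratio_pair"
    sensor: str = "PercevalHR"
    groups: tuple[SimulatedGroup, ...] = ()
    stats_value_column: str | None = None

    def __post_init__(self) -> None:
        if self.mode not in ("simulate", "count", "ratio", "stats", "full"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.mode in ("count", "ratio", "stats") and self.manifest_path is None:
            raise ValueError(f"mode {self.mode!r} requires manifest_path")

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "detection" in d and d["detection"] is not None and not isinstance(d["detection"], DetectionParams):
            det = dict(d["detection"])
            if "variance_bounds" in det and det["variance_bounds"] is not None:
                det["variance_bounds"] = tuple(det["variance_bounds"])
            d["detection"] = DetectionParams(**det)
        if "calibration" in d and d["calibration"] is not None and not isinstance(d["calibration"], CalibrationGrid):
            cal = dict(d["calibration"])
            if cal.get("variance_bounds_options"):
                cal["variance_bounds_options"] = tuple(tuple(v) for v in cal["variance_bounds_options"])
            d["calibration"] = CalibrationGrid(**cal)
        if "groups" in d:
            d["groups"] = tuple(
                g if isinstance(g, SimulatedGroup) else SimulatedGroup(**g) for g in d["groups"]
            )
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d


def read_manifest(path, kind: str = "flatmount") -> list[dict]:
    """Read and validate a sample manifest CSV.

    Required columns: image_path, group, retina_id (plus sensor,
    condition, image_id for ratio manifests). Geometry columns
    (center_x, center_y, radius) are optional; when present and
    non-missing they override automatic outline fitting. Relative image
    paths are resolved against the manifest's directory, so a run
    directory is relocatable.

    Raises
    ------
    ValueError
        Naming every missing required column.
    """
    df = pd.read_csv(path)
    required = list(_BASE_MANIFEST_COLUMNS)
    if kind == "ratio":
        required += list(_RATIO_COLUMNS)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"manifest {path} is missing required columns: {missing}")
    records = df.to_dict(orient="records")
    base = Path(path).parent
    for rec in records:
        has_geom = all(c in df.columns and pd.notna(rec.get(c)) for c in _GEOMETRY_COLUMNS)
        rec["_has_geometry"] = has_geom
        p = Path(str(rec["image_path"]))
        rec["_resolved_path"] = str(p if p.is_absolute() else base / p)
    return records


# ---------------------------------------------------------------------------
# stages


def _stage_simulate(config: RunConfig, outdir: Path) -> dict:
    rows = []
    info: dict = {"images": []}
    for group in config.groups:
        base = preset(group.preset, image_size=group.image_size)
        n_cones = int(round(base.n_cones_total * group.density_multiplier))
        for i in range(group.n_retinas):
            seed = derive_seed(config.seed, group.name, i)
            changes = {"n_cones_total": n_cones, "seed": seed, **group.spec_overrides}
            spec = dataclasses.replace(base, **changes)
            stem = f"{group.name}_retina{i:02d}"
            t0 = time.perf_counter()
            if config.experiment_kind == "ratio_pair":
                num, den, truth = generate_ratio_pair(spec, group.true_ratio, config.sensor)
                paths = write_ratio_pair(outdir, stem, num, den, truth, spec)
                rows.append(
                    dict(
                        image_path=Path(paths["image"]).name, group=group.name,
                        retina_id=stem, image_id=stem, sensor=config.sensor,
                        condition=group.condition,
                    )
                )
            else:
                image, truth = generate_flatmount(spec)
                paths = write_flatmount(outdir, stem, image, truth, spec)
                cx, cy = spec.center
                rows.append(
                    dict(
                        image_path=Path(paths["image"]).name, group=group.name,
                        retina_id=stem, center_x=cx, center_y=cy,
                        radius=spec.retina_radius,
                        truth_path=Path(paths["truth"]).name,
                        truth_labeled_half_radius=truth.n_labeled_half_radius,
                    )
                )
            log.info("simulated %s in %.2fs", stem, time.perf_counter() - t0)
            info["images"].append(stem)
    manifest = outdir / "manifest.csv"
    pd.DataFrame(rows).to_csv(manifest, index=False)
    info["manifest"] = str(manifest)
    return info


def _detection_params(config: RunConfig, records: list[dict]) -> DetectionParams:
    if config.detection is not None:
        return config.detection
    if config.calibration is not None:
        col = config.calibration_column
        cal_set = []
        for rec in records:
            if col in rec and pd.notna(rec[col]):
                cal_set.append((read_image(rec["_resolved_path"]), int(rec[col])))
        if not cal_set:
            raise ValueError(
                f"calibration grid given but no rows carry a {col!r} reference count"
            )
        params = calibrate_params(cal_set, config.calibration)
        log.info("calibrated detection params: %s", params)
        return params
    return DetectionParams()


def _stage_count(config: RunConfig, outdir: Path, manifest_path) -> dict:
    records = read_manifest(manifest_path, kind="flatmount")
    params = _detection_params(config, records)
    summary = []
    for rec in records:
        t0 = time.perf_counter()
        image = read_image(rec["_resolved_path"])
        if rec["_has_geometry"]:
            geom = manual_geometry((rec["center_x"], rec["center_y"]), rec["radius"])
        else:
            geom = fit_retina_outline(image)
        census = detect_cones(image, params)
        n_half = count_in_half_radius(census, geom)
        spot_path = outdir / f"{rec['retina_id']}_spots.csv"
        census.to_dataframe().to_csv(spot_path, index=False)
        summary.append(
            dict(
                retina_id=rec["retina_id"], group=rec["group"], image_path=rec["image_path"],
                n_total=census.n_total, n_half_radius=n_half,
                geometry_source=geom.source, center_x=geom.center[0],
                center_y=geom.center[1], radius=geom.radius,
            )
        )
        log.info(
            "counted %s: %d spots, %d in half-radius (%.2fs)",
            rec["retina_id"], census.n_total, n_half, time.perf_counter() - t0,
        )
    out = outdir / "counts_summary.csv"
    pd.DataFrame(summary).to_csv(out, index=False)
    return {
        "summary": str(out),
        "params": dataclasses.asdict(params),
        "n_images": len(summary),
    }


def _stage_ratio(config: RunConfig, outdir: Path, manifest_path) -> dict:
    records = read_manifest(manifest_path, kind="ratio")
    measurements = []
    for rec in records:
        num, den = read_ratio_pair(rec["_resolved_path"])
        m = compute_ratio(
            num, den, None, rec["sensor"],
            retina_id=str(rec["retina_id"]), image_id=str(rec["image_id"]),
            condition=str(rec["condition"]), group=str(rec["group"]),
        )
        measurements.append(m)
    measurements = normalize_to_control(measurements, config.control_group)
    df = pd.DataFrame([dataclasses.asdict(m) for m in measurements])
    out = outdir / "ratios.csv"
    df.to_csv(out, index=False)
    return {"ratios": str(out), "n_images": len(measurements)}


def _stage_stats(config: RunConfig, outdir: Path, table_path, value_column: str) -> dict:
    df = pd.read_csv(table_path)
    if "group" not in df.columns or value_column not in df.columns:
        raise ValueError(f"stats input must carry 'group' and {value_column!r} columns")
    names = sorted(df["group"].unique())
    if config.control_group not in names:
        raise ValueError(
            f"control group {config.control_group!r} absent from {table_path} (groups: {names})"
        )
    ordered = [config.control_group] + [g for g in names if g != config.control_group]
    samples = [df.loc[df["group"] == g, value_column].to_numpy(dtype=float) for g in ordered]
    if len(ordered) == 2:
        res = unpaired_t_test(samples[1], samples[0], labels=(ordered[1], ordered[0]))
    else:
        res = anova_dunnett(samples, control_index=0, labels=ordered, seed=config.seed)
    rows = []
    for (ga, gb), p, star in zip(res.comparisons, res.p_values, res.stars):
        ia, ib = res.groups.index(ga), res.groups.index(gb)
        rows.append(
            dict(
                group=ga, control=gb, n_group=res.n_per_group[ia], n_control=res.n_per_group[ib],
                mean_group=res.means[ia], mean_control=res.means[ib],
                dispersion_group=res.dispersions[ia], dispersion_control=res.dispersions[ib],
                dispersion_mode=res.dispersion_mode, test=res.test,
                statistic=res.statistic, p_value=p, stars=star,
            )
        )
    out = outdir / "comparisons.csv"
    pd.DataFrame(rows).to_csv(out, index=False)
    return {"comparisons": str(out), "test": res.test, "p_values": list(res.p_values)}


def run_pipeline(config: RunConfig) -> dict:
    """Run the configured stages; return (and write) the JSON run report."""
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict = {
        "package_version": __version__,
        "numpy_version": np.__version__,
        "seed": config.seed,
        "mode": config.mode,
        "config": config.to_dict(),
        "stages": {},
    }
    manifest = config.manifest_path
    if config.mode in ("simulate", "full"):
        info = _stage_simulate(config, outdir)
        report["stages"]["simulate"] = info
        manifest = info["manifest"]
    if config.mode in ("count", "full") and config.experiment_kind == "flatmount":
        info = _stage_count(config, outdir, manifest)
        report["stages"]["count"] = info
        stats_input, value_col = info["summary"], "n_half_radius"
    if config.mode in ("ratio", "full") and config.experiment_kind == "ratio_pair":
        info = _stage_ratio(config, outdir, manifest)
        report["stages"]["ratio"] = info
        stats_input, value_col = info["ratios"], "normalized_ratio"
    if config.mode == "stats":
        stats_input = manifest
        value_col = config.stats_value_column or "n_half_radius"
    if config.mode in ("stats", "full"):
        report["stages"]["stats"] = _stage_stats(config, outdir, stats_input, value_col)
    (outdir / "run_report.json").write_text(json.dumps(report, indent=2, sort_keys=True))
    return report
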