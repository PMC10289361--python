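"""File formats, run configuration and the end-to-end pipeline.

Volumes are NIfTI (.nii.gz) with voxel spacing in the header, annotations a
JSON array of ``{stone_id, center_mm, radius_mm}``, and all tabular data
plain CSV.  Every output CSV carries the configuration hash and master seed
as columns so results are traceable to their run.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from . import agreement as agreement_mod
from .core import Annotation, CTVolume, Method, MethodParams
from .errors import ConfigurationError, FormatError, LithosegError, SchemaError
from .optimize import CostWeights, MeasurementCache, SearchConfig, cross_validate
from .phantom import GroundTruth, PhantomConfig, PhantomDataset, RaterRecord, make_phantom
from .segmentation import ROUGH_THRESHOLD_HU, segment

log = logging.getLogger("lithoseg")

METHODS = [Method.ABS, Method.ABS_PV, Method.MED, Method.MED_PV]


# --------------------------------------------------------------------------
# volumes
# --------------------------------------------------------------------------
def write_volume(volume: CTVolume, path) -> None:
    affine = np.diag([*volume.spacing_mm, 1.0])
    affine[:3, 3] = volume.origin_mm
    img = nib.Nifti1Image(np.asarray(volume.values, dtype=np.float32), affine)
    img.header.set_zooms(tuple(volume.spacing_mm))
    nib.save(img, str(path))


def read_volume(path) -> CTVolume:
    path = Path(path)
    if not path.exists():
        raise LithosegError(f"no such volume file: {path}")
    try:
        img = nib.load(str(path))
        data = np.asanyarray(img.dataobj)
    except Exception as exc:  # corrupt file
        raise LithosegError(f"cannot read NIfTI volume {path}: {exc}") from exc
    if data.ndim != 3:
        raise FormatError(f"{path}: expected a 3D volume, got {data.ndim}D")
    spacing = np.asarray(img.header.get_zooms()[:3], dtype=float)
    origin = np.asarray(img.affine[:3, 3], dtype=float)
    return CTVolume(np.asarray(data, dtype=np.float32), spacing, origin)


def write_mask(mask_values: np.ndarray, spacing_mm, path, origin_mm=None) -> None:
    vol = CTVolume(np.asarray(mask_values, dtype=np.uint8), spacing_mm, origin_mm)
    write_volume(vol, path)


# --------------------------------------------------------------------------
# annotations and reference tables
# --------------------------------------------------------------------------
def write_annotations(annotations: list[Annotation], path) -> None:
    payload = [
        {"stone_id": a.stone_id, "center_mm": list(a.center_mm), "radius_mm": a.radius_mm}
        for a in annotations
    ]
    Path(path).write_text(json.dumps(payload, indent=1))


def read_annotations(path) -> list[Annotation]:
    try:
        payload = json.loads(Path(path).read_text())
    except (OSError, json.JSONDecodeError) as exc:
        raise SchemaError(f"cannot read annotations {path}: {exc}") from exc
    anns, seen = [], set()
    for rec in payload:
        try:
            ann = Annotation(rec["stone_id"], tuple(map(float, rec["center_mm"])), float(rec["radius_mm"]))
        except (KeyError, TypeError, ValueError) as exc:
            raise SchemaError(f"malformed annotation record {rec!r}") from exc
        if ann.stone_id in seen:
            raise SchemaError(f"duplicate stone_id {ann.stone_id!r}")
        seen.add(ann.stone_id)
        anns.append(ann)
    return anns


def write_ground_truth(truths: list[GroundTruth], path) -> None:
    pd.DataFrame(
        [{"stone_id": t.stone_id, "volume_ml": t.volume_ml, "diameter_mm": t.diameter_mm} for t in truths]
    ).to_csv(path, index=False, float_format="%.17g")


def write_raters(raters: list[RaterRecord], path) -> None:
    rows = []
    for r in raters:
        row = {"stone_id": r.stone_id}
        for i in range(3):
            row[f"volume_ml_rater{i + 1}"] = r.volumes_ml[i]
            row[f"diameter_mm_rater{i + 1}"] = r.diameters_mm[i]
        row["reference_volume_ml"] = r.reference_volume_ml
        row["reference_diameter_mm"] = r.reference_diameter_mm
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False, float_format="%.17g")


def read_references(path) -> list[RaterRecord]:
    """Read the rater CSV, recomputing and checking the stored means."""
    try:
        df = pd.read_csv(path, float_precision="round_trip")
    except Exception as exc:
        raise SchemaError(f"cannot read references {path}: {exc}") from exc
    needed = {"stone_id", "reference_volume_ml", "reference_diameter_mm"} | {
        f"{q}_rater{i}" for q in ("volume_ml", "diameter_mm") for i in (1, 2, 3)
    }
    missing = needed - set(df.columns)
    if missing:
        raise SchemaError(f"references missing columns: {sorted(missing)}")
    if df["stone_id"].duplicated().any():
        dup = df.loc[df["stone_id"].duplicated(), "stone_id"].iloc[0]
        raise SchemaError(f"duplicate stone_id {dup!r}")
    out = []
    for _, row in df.iterrows():
        vols = tuple(float(row[f"volume_ml_rater{i}"]) for i in (1, 2, 3))
        diams = tuple(float(row[f"diameter_mm_rater{i}"]) for i in (1, 2, 3))
        if min(vols) <= 0 or min(diams) <= 0:
            raise SchemaError(f"non-positive measurement for stone {row['stone_id']!r}")
        for stored, recomputed, name in (
            (float(row["reference_volume_ml"]), float(np.mean(vols)), "volume"),
            (float(row["reference_diameter_mm"]), float(np.mean(diams)), "diameter"),
        ):
            if abs(stored - recomputed) > 1e-6 * max(1.0, abs(recomputed)):
                raise SchemaError(
                    f"stone {row['stone_id']!r}: stored reference {name} differs from rater mean"
                )
        out.append(RaterRecord(str(row["stone_id"]), vols, diams, float(np.mean(vols)), float(np.mean(diams))))
    return out


def write_measurements(measurements, path, config_hash: str = "", seed: int | None = None) -> None:
    rows = []
    for m in measurements:
        p = m.params
        rows.append(
            {
                "stone_id": m.stone_id,
                "method": p.method.value if p else "",
                "p1": p.p1 if p else np.nan,
                "p2": (p.p2 if p and p.p2 is not None else np.nan),
                "voxel_count": m.voxel_count,
                "surface_voxel_count": m.surface_voxel_count,
                "volume_ml": m.volume_ml,
                "diameter_mm": m.diameter_mm,
            }
        )
    df = pd.DataFrame(rows)
    df["config_hash"], df["seed"] = config_hash, seed
    df.to_csv(path, index=False)


# --------------------------------------------------------------------------
# run configuration
# --------------------------------------------------------------------------
@dataclass(frozen=True)
class RunConfig:
    """Declarative configuration of a full simulate-optimize-evaluate run."""

    n_stones: int = 101
    seed: int = 0
    phantom: PhantomConfig = field(default_factory=PhantomConfig)
    rough_threshold_hu: float = ROUGH_THRESHOLD_HU
    weights: CostWeights = field(default_factory=CostWeights)
    search: SearchConfig = field(default_factory=SearchConfig)
    n_reps: int = 1000
    train_size: int = 80
    val_size: int = 21
    pv_affects_diameter: bool = False
    icc_variant: str = "A1"

    def __post_init__(self) -> None:
        if self.train_size + self.val_size != self.n_stones:
            raise ConfigurationError(
                f"train_size + val_size ({self.train_size}+{self.val_size}) "
                f"must equal n_stones ({self.n_stones})"
            )
        if self.n_reps < 1:
            raise ConfigurationError("n_reps must be >= 1")
        if self.rough_threshold_hu <= 0:
            raise ConfigurationError("rough_threshold_hu must be > 0")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["phantom"] = dataclasses.asdict(
            dataclasses.replace(self.phantom, seed=self.seed)
        )
        return d

    @property
    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True, default=float)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        kwargs = dict(raw)
        if "phantom" in kwargs:
            kwargs["phantom"] = PhantomConfig(**kwargs["phantom"])
        if "weights" in kwargs:
            kwargs["weights"] = CostWeights(**kwargs["weights"])
        if "search" in kwargs:
            kwargs["search"] = SearchConfig(
                **{k: tuple(v) if isinstance(v, list) else v for k, v in kwargs["search"].items()}
            )
        try:
            return cls(**kwargs)
        except TypeError as exc:
            raise ConfigurationError(f"bad config file {path}: {exc}") from exc


# --------------------------------------------------------------------------
# pipeline
# --------------------------------------------------------------------------
def simulate_to_dir(config: RunConfig, outdir) -> PhantomDataset:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    phantom_cfg = dataclasses.replace(config.phantom, seed=config.seed)
    dataset = make_phantom(config.n_stones, phantom_cfg)
    write_volume(dataset.volume, outdir / "volume.nii.gz")
    write_annotations(dataset.annotations, outdir / "annotations.json")
    write_ground_truth(dataset.truths, outdir / "ground_truth.csv")
    write_raters(dataset.raters, outdir / "raters.csv")
    return dataset


def run_pipeline(config: RunConfig, outdir) -> dict:
    """simulate -> segment x4 -> optimize x4 -> evaluate; artifacts on disk.

    Returns a manifest dict (also written as run_manifest.json) with the
    config hash, per-stage timings and headline results.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    chash = config.config_hash
    manifest: dict = {"config_hash": chash, "seed": config.seed, "timings_s": {}}

    t0 = time.perf_counter()
    log.info("simulating %d-stone phantom (seed %d)", config.n_stones, config.seed)
    dataset = simulate_to_dir(config, outdir)
    manifest["timings_s"]["simulate"] = round(time.perf_counter() - t0, 2)

    t0 = time.perf_counter()
    cache = MeasurementCache(dataset.volume, dataset.annotations, config.rough_threshold_hu)
    reports = {}
    rows = []
    for method in METHODS:
        log.info("cross-validating method %s (%d reps)", method.value, config.n_reps)
        rep = cross_validate(
            method,
            cache,
            dataset.raters,
            n_reps=config.n_reps,
            train_size=config.train_size,
            val_size=config.val_size,
            seed=config.seed,
            weights=config.weights,
            search=config.search,
        )
        reports[method] = rep
        rows.append(
            {
                "method": method.value,
                "n_repetitions": rep.n_repetitions,
                "p1_mean": rep.p1_mean,
                "p1_std": rep.p1_std,
                "p2_mean": rep.p2_mean,
                "p2_std": rep.p2_std,
                "icc_volume_mean": rep.icc_volume_mean,
                "icc_volume_std": rep.icc_volume_std,
                "meandiff_volume_mean": rep.meandiff_volume_mean,
                "std_volume_mean": rep.std_volume_mean,
                "icc_diameter_mean": rep.icc_diameter_mean,
                "icc_diameter_std": rep.icc_diameter_std,
                "meandiff_diameter_mean": rep.meandiff_diameter_mean,
                "std_diameter_mean": rep.std_diameter_mean,
            }
        )
    df = pd.DataFrame(rows)
    df["config_hash"], df["seed"] = chash, config.seed
    df.to_csv(outdir / "optimization.csv", index=False)
    manifest["timings_s"]["optimize"] = round(time.perf_counter() - t0, 2)

    t0 = time.perf_counter()
    estimates_by_method = {}
    for method in METHODS:
        params = reports[method].mean_params
        est = cache.estimates(params, pv_affects_diameter=config.pv_affects_diameter)
        empties = [e.stone_id for e in est if e.voxel_count == 0]
        for sid in empties:
            log.warning("method %s: empty segmentation for stone %s", method.value, sid)
        estimates_by_method[method.value] = est
        write_measurements(est, outdir / f"measurements_{method.value}.csv", chash, config.seed)
    ag_reports, comparisons = agreement_mod.evaluate_all_methods(
        estimates_by_method, dataset.raters
    )
    ag_rows = [
        {
            "method": label,
            "quantity": qty,
            "n": r.n,
            "icc": r.icc,
            "pearson_r": r.pearson_r,
            "mean_diff": r.mean_diff,
            "std_diff": r.std_diff,
            "loa_low": r.loa_low,
            "loa_high": r.loa_high,
        }
        for (label, qty), r in ag_reports.items()
    ]
    ag = pd.DataFrame(ag_rows)
    ag["config_hash"], ag["seed"] = chash, config.seed
    ag.to_csv(outdir / "agreement.csv", index=False)
    ba = pd.DataFrame(
        [
            {"quantity": qty, "k": c.k, "statistic": c.statistic, "dof": c.dof, "p_value": c.p_value}
            for qty, c in comparisons.items()
        ]
    )
    ba["config_hash"], ba["seed"] = chash, config.seed
    ba.to_csv(outdir / "bartlett.csv", index=False)
    manifest["timings_s"]["evaluate"] = round(time.perf_counter() - t0, 2)

    manifest["bartlett_p"] = {qty: c.p_value for qty, c in comparisons.items()}
    manifest["mean_params"] = {
        m.value: {"p1": reports[m].p1_mean, "p2": reports[m].p2_mean} for m in METHODS
    }
    (outdir / "run_manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest


def segment_to_dir(
    volume: CTVolume,
    annotations: list[Annotation],
    params: MethodParams,
    outdir,
    rough_threshold_hu: float = ROUGH_THRESHOLD_HU,
) -> list:
    """Segment every annotated stone, writing one mask NIfTI per stone."""
    from .morphometry import measure

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    measurements = []
    for ann in annotations:
        mask = segment(volume, ann, params, rough_threshold_hu)
        write_mask(mask.values, volume.spacing_mm, outdir / f"mask_{ann.stone_id}.nii.gz", volume.origin_mm)
        measurements.append(measure(mask, params, volume.spacing_mm))
    return measurements
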