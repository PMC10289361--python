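"""Weighted-L1 parameter optimization and repeated random-split validation.

The cost of a parameter setting over a set of stones is

    sum_stones  w_V * |Ve - Vr|  +  w_D * |De - Dr|

with default weights (4 per mL, 1 per mm); Vr, Dr are the rater-mean
reference values and Ve, De the segmentation-derived estimates.

Optimization is an exhaustive coarse grid (2 HU steps for absolute
thresholds, 0.005 for median fractions, 0.01 for the surface factor)
followed by a deterministic fine-grid refinement (an eighth of a coarse
step, within one coarse step of the coarse argmin).  Ties on flat cost
regions resolve to the smallest P1, then the smallest P2.  Parameter
settings that leave a stone unsegmented incur a large finite penalty
rather than an error.

The validation protocol repeatedly splits the stone set at random into a
training set (optimize P1/P2) and a validation set (evaluate ICC, mean and
SD of reference - estimate), and reports the mean and SD of parameters and
metrics over repetitions.  Per-repetition RNG streams are derived from the
master seed by repetition index, so runs are reproducible and individual
repetitions can be recomputed in isolation.

Segmentation results are cached per (stone, threshold) in a
:class:`MeasurementCache`, which makes a 1000-repetition protocol
tractable; caching is semantically invisible (tested against the uncached
path).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import Annotation, CTVolume, Method, MethodParams
from .errors import (
    AlignmentError,
    ConfigurationError,
    EmptySegmentationError,
    OptimizationInfeasibleError,
)
from .morphometry import StoneMeasurement, _max_pair
from .segmentation import (
    ROUGH_THRESHOLD_HU,
    _fill_holes,
    _roi_mask_box,
    _select_component,
    surface_voxels,
)
from . import agreement

EMPTY_PENALTY = 1e6


@dataclass(frozen=True)
class CostWeights:
    """L1 weights: volume error in mL weighted 4x against diameter error in mm."""

    volume_weight: float = 4.0
    diameter_weight: float = 1.0

    def __post_init__(self) -> None:
        if self.volume_weight <= 0 or self.diameter_weight <= 0:
            raise ConfigurationError("cost weights must be > 0")


@dataclass(frozen=True)
class SearchConfig:
    """Grid bounds and steps for the parameter search."""

    abs_p1_bounds: tuple[float, float] = (50.0, 1000.0)
    abs_p1_step: float = 2.0
    med_p1_bounds: tuple[float, float] = (0.005, 1.0)
    med_p1_step: float = 0.005
    p2_bounds: tuple[float, float] = (0.0, 0.9)
    p2_step: float = 0.01
    refine_factor: int = 8  # fine step = coarse step / refine_factor

    def p1_grid(self, method: Method) -> np.ndarray:
        lo, hi = self.abs_p1_bounds if not method.adaptive else self.med_p1_bounds
        step = self.abs_p1_step if not method.adaptive else self.med_p1_step
        n = int(round((hi - lo) / step))
        return lo + step * np.arange(n + 1)

    def p2_grid(self) -> np.ndarray:
        lo, hi = self.p2_bounds
        n = int(round((hi - lo) / self.p2_step))
        return lo + self.p2_step * np.arange(n + 1)


def cost(
    estimates: list[StoneMeasurement],
    references,
    weights: CostWeights = CostWeights(),
) -> float:
    """Weighted-L1 cost of a set of estimates against rater references.

    ``references`` is a list of objects with ``stone_id``,
    ``reference_volume_ml`` and ``reference_diameter_mm`` (RaterRecord or
    equivalent).  Stones must match one-to-one by id.
    """
    if not estimates:
        raise AlignmentError("no estimates")
    ref = {r.stone_id: (r.reference_volume_ml, r.reference_diameter_mm) for r in references}
    est_ids = [e.stone_id for e in estimates]
    if sorted(est_ids) != sorted(ref):
        raise AlignmentError("estimate and reference stone ids do not match")
    total = 0.0
    for e in estimates:
        vr, dr = ref[e.stone_id]
        total += weights.volume_weight * abs(e.volume_ml - vr)
        total += weights.diameter_weight * abs(e.diameter_mm - dr)
    return total


class MeasurementCache:
    """Per-stone crops plus memoized (voxel count, surface count, diameter)
    as a function of the working HU threshold.

    The segmentation applied here is byte-for-byte the public pipeline
    (ROI restriction, inclusive threshold, 26-connected component at the
    centre, fill-hole); only the grid cropping and memoization differ, and
    tests assert the cached path equals :func:`lithoseg.segmentation.segment`
    plus :func:`lithoseg.morphometry.measure`.
    """

    def __init__(
        self,
        volume: CTVolume,
        annotations: list[Annotation],
        rough_threshold_hu: float = ROUGH_THRESHOLD_HU,
    ) -> None:
        self.spacing = np.asarray(volume.spacing_mm, dtype=float)
        self.voxel_mm3 = float(np.prod(self.spacing))
        self.stone_ids = [a.stone_id for a in annotations]
        self._stones: dict[str, dict] = {}
        self._memo: dict[tuple[str, float], tuple[float, float, float] | None] = {}
        self._tables: dict = {}
        self._id_index = {a.stone_id: i for i, a in enumerate(annotations)}
        for ann in annotations:
            box, roi, center_vox = _roi_mask_box(volume, ann)
            hu = np.ascontiguousarray(volume.values[box])
            entry = {"hu": hu, "roi": roi, "center": center_vox}
            self._stones[ann.stone_id] = entry
        self._rough_threshold = rough_threshold_hu
        self._medians: dict[str, float] = {}

    def rough_median(self, stone_id: str) -> float:
        """Median HU over the rough (20 HU) segmentation of a stone."""
        if stone_id not in self._medians:
            entry = self._stones[stone_id]
            comp = _select_component(
                entry["roi"] & (entry["hu"] >= self._rough_threshold),
                entry["center"],
                self.spacing,
            )
            self._medians[stone_id] = float(np.median(entry["hu"][comp]))
        return self._medians[stone_id]

    def threshold_for(self, stone_id: str, method: Method, p1: float) -> float:
        return float(p1) if not method.adaptive else float(p1) * self.rough_median(stone_id)

    def measure_at(self, stone_id: str, threshold_hu: float):
        """(voxel count, surface count, diameter mm) at a threshold, or None
        when nothing survives."""
        key = (stone_id, round(float(threshold_hu), 6))
        if key in self._memo:
            return self._memo[key]
        entry = self._stones[stone_id]
        cand = entry["roi"] & (entry["hu"] >= threshold_hu)
        if not cand.any():
            self._memo[key] = None
            return None
        try:
            comp = _select_component(cand, entry["center"], self.spacing)
        except EmptySegmentationError:
            self._memo[key] = None
            return None
        comp = _fill_holes(comp)
        surf, n_surf = surface_voxels(comp)
        n = int(comp.sum())
        d2, disp = _max_pair(np.argwhere(surf), self.spacing)
        edge = (
            float(self.spacing.max())
            if np.allclose(disp, 0)
            else float(self.spacing[int(np.argmax(np.abs(disp)))])
        )
        result = (float(n), float(n_surf), float(np.sqrt(d2)) + edge)
        self._memo[key] = result
        return result

    def table(self, method: Method, p1_values: np.ndarray, stone_ids=None):
        """Arrays (N, NS, D) of shape (len(p1_values), n_stones); NaN where empty.

        Full-population tables are memoized per (method, grid); a stone
        subset slices columns out of the cached arrays.
        """
        key = (method, np.asarray(p1_values, dtype=float).tobytes())
        if key not in self._tables:
            N = np.full((len(p1_values), len(self.stone_ids)), np.nan)
            NS = np.full_like(N, np.nan)
            D = np.full_like(N, np.nan)
            for j, sid in enumerate(self.stone_ids):
                for i, p1 in enumerate(p1_values):
                    res = self.measure_at(sid, self.threshold_for(sid, method, p1))
                    if res is not None:
                        N[i, j], NS[i, j], D[i, j] = res
            self._tables[key] = (N, NS, D)
        N, NS, D = self._tables[key]
        if stone_ids is None:
            return N, NS, D
        cols = [self._id_index[sid] for sid in stone_ids]
        return N[:, cols], NS[:, cols], D[:, cols]

    def estimates(
        self, params: MethodParams, stone_ids=None, pv_affects_diameter: bool = False
    ) -> list[StoneMeasurement]:
        """StoneMeasurements for all (or selected) stones at fixed parameters.

        Stones left unsegmented yield volume 0 / diameter 0 (the method
        failed for that stone) rather than an error.
        """
        ids = list(stone_ids) if stone_ids is not None else self.stone_ids
        out = []
        for sid in ids:
            res = self.measure_at(sid, self.threshold_for(sid, params.method, params.p1))
            if res is None:
                out.append(StoneMeasurement(sid, 0.0, 0.0, 0, 0, params))
                continue
            n, ns, d = res
            vol = (n - params.pv_factor * ns) * self.voxel_mm3 / 1000.0
            if pv_affects_diameter and params.pv_factor > 0:
                d = max(d - params.pv_factor * float(self.spacing.max()), 0.0)
            out.append(StoneMeasurement(sid, vol, d, int(n), int(ns), params))
        return out


def _grid_cost(
    N: np.ndarray,
    NS: np.ndarray,
    D: np.ndarray,
    p2: np.ndarray | None,
    vr: np.ndarray,
    dr: np.ndarray,
    weights: CostWeights,
    voxel_mm3: float,
) -> np.ndarray:
    """Cost over the parameter grid; shape (n_p1,) or (n_p1, n_p2)."""
    empty = np.isnan(N)
    if p2 is None:
        V = N * voxel_mm3 / 1000.0
        per = weights.volume_weight * np.abs(V - vr) + weights.diameter_weight * np.abs(D - dr)
        per = np.where(empty, EMPTY_PENALTY, per)
        return per.sum(axis=-1)
    V = (N[:, None, :] - p2[None, :, None] * NS[:, None, :]) * voxel_mm3 / 1000.0
    per = weights.volume_weight * np.abs(V - vr) + weights.diameter_weight * np.abs(
        D[:, None, :] - dr
    )
    per = np.where(empty[:, None, :], EMPTY_PENALTY, per)
    return per.sum(axis=-1)


def _argmin_first(costs: np.ndarray) -> tuple[int, ...]:
    """First (lexicographically smallest) index of the minimum: the tie rule
    'smallest P1, then smallest P2' for ascending grids in C order."""
    return np.unravel_index(int(np.argmin(costs)), costs.shape)


def optimize_params(
    method: Method | str,
    cache: MeasurementCache,
    references,
    weights: CostWeights = CostWeights(),
    search: SearchConfig = SearchConfig(),
    stone_ids=None,
) -> MethodParams:
    """Grid-plus-refinement minimization of the cost over the given stones."""
    method = Method(method)
    ids = list(stone_ids) if stone_ids is not None else cache.stone_ids
    if len(ids) < 2:
        raise ConfigurationError("optimization needs at least 2 stones")
    ref = {r.stone_id: (r.reference_volume_ml, r.reference_diameter_mm) for r in references}
    missing = [i for i in ids if i not in ref]
    if missing:
        raise AlignmentError(f"no reference for stones {missing[:3]}")
    vr = np.array([ref[i][0] for i in ids])
    dr = np.array([ref[i][1] for i in ids])
    p2 = search.p2_grid() if method.uses_pv else None

    def best_on(p1_values: np.ndarray) -> tuple[float, float | None, float]:
        N, NS, D = cache.table(method, p1_values, ids)
        costs = _grid_cost(N, NS, D, p2, vr, dr, weights, cache.voxel_mm3)
        idx = _argmin_first(costs)
        best_p1 = float(p1_values[idx[0]])
        best_p2 = float(p2[idx[1]]) if method.uses_pv else None
        return best_p1, best_p2, float(costs[idx])

    coarse = search.p1_grid(method)
    p1_c, p2_c, cost_c = best_on(coarse)
    if cost_c >= EMPTY_PENALTY * len(ids):
        raise OptimizationInfeasibleError("every stone empty at every candidate threshold")

    step = search.abs_p1_step if not method.adaptive else search.med_p1_step
    fine_step = step / search.refine_factor
    lo = max(p1_c - step, float(coarse[0]))
    hi = min(p1_c + step, float(coarse[-1]))
    fine = np.unique(np.concatenate([np.arange(lo, hi + fine_step / 2, fine_step), [p1_c]]))
    p1_f, p2_f, cost_f = best_on(np.sort(fine))
    if cost_f < cost_c or (cost_f == cost_c and p1_f < p1_c):
        p1_c, p2_c = p1_f, p2_f
    return MethodParams(method, p1_c, p2_c)


@dataclass
class SplitResult:
    """One train/validation repetition."""

    repetition: int
    train_ids: list[str]
    val_ids: list[str]
    optimal_params: MethodParams
    val_icc_volume: float
    val_icc_diameter: float
    val_meandiff_volume_ml: float
    val_std_volume_ml: float
    val_meandiff_diameter_mm: float
    val_std_diameter_mm: float


@dataclass
class OptimizationReport:
    """Aggregate over repetitions: mean and SD of parameters and validation metrics."""

    method: Method
    n_repetitions: int
    p1_mean: float
    p1_std: float
    p2_mean: float | None
    p2_std: float | None
    icc_volume_mean: float
    icc_volume_std: float
    icc_diameter_mean: float
    icc_diameter_std: float
    meandiff_volume_mean: float
    meandiff_volume_std: float
    std_volume_mean: float
    std_volume_std: float
    meandiff_diameter_mean: float
    meandiff_diameter_std: float
    std_diameter_mean: float
    std_diameter_std: float
    splits: list[SplitResult] = field(default_factory=list, repr=False)

    @property
    def mean_params(self) -> MethodParams:
        return MethodParams(self.method, self.p1_mean, self.p2_mean)


def cross_validate(
    method: Method | str,
    cache: MeasurementCache,
    references,
    n_reps: int = 1000,
    train_size: int = 80,
    val_size: int = 21,
    seed: int = 0,
    weights: CostWeights = CostWeights(),
    search: SearchConfig = SearchConfig(),
) -> OptimizationReport:
    """Repeated random-split optimization and validation.

    Per repetition: split stones into train/validation, optimize P1 (and P2)
    on the training set, then evaluate ICC, mean and SD of
    (reference - estimate) for volume and diameter on the validation set.
    """
    method = Method(method)
    ids = np.array(cache.stone_ids)
    if train_size + val_size != len(ids):
        raise ConfigurationError(
            f"train_size + val_size must equal the stone count ({len(ids)})"
        )
    if n_reps < 1:
        raise ConfigurationError("n_reps must be >= 1")
    ref = {r.stone_id: (r.reference_volume_ml, r.reference_diameter_mm) for r in references}

    splits: list[SplitResult] = []
    for rep in range(n_reps):
        rng = np.random.default_rng(np.random.SeedSequence([int(seed), rep]))
        perm = rng.permutation(len(ids))
        train = list(ids[perm[:train_size]])
        val = list(ids[perm[train_size:]])
        params = optimize_params(method, cache, references, weights, search, stone_ids=train)
        est = cache.estimates(params, stone_ids=val)
        ev = np.array([e.volume_ml for e in est])
        ed = np.array([e.diameter_mm for e in est])
        vr = np.array([ref[i][0] for i in val])
        dr = np.array([ref[i][1] for i in val])
        dv = vr - ev
        dd = dr - ed
        splits.append(
            SplitResult(
                repetition=rep,
                train_ids=train,
                val_ids=val,
                optimal_params=params,
                val_icc_volume=agreement.icc(ev, vr),
                val_icc_diameter=agreement.icc(ed, dr),
                val_meandiff_volume_ml=float(dv.mean()),
                val_std_volume_ml=float(dv.std(ddof=1)),
                val_meandiff_diameter_mm=float(dd.mean()),
                val_std_diameter_mm=float(dd.std(ddof=1)),
            )
        )

    def agg(values):
        arr = np.asarray(values, dtype=float)
        return float(arr.mean()), float(arr.std(ddof=1)) if len(arr) > 1 else 0.0

    p1m, p1s = agg([s.optimal_params.p1 for s in splits])
    if method.uses_pv:
        p2m, p2s = agg([s.optimal_params.p2 for s in splits])
    else:
        p2m = p2s = None
    fields = {
        "icc_volume": [s.val_icc_volume for s in splits],
        "icc_diameter": [s.val_icc_diameter for s in splits],
        "meandiff_volume": [s.val_meandiff_volume_ml for s in splits],
        "std_volume": [s.val_std_volume_ml for s in splits],
        "meandiff_diameter": [s.val_meandiff_diameter_mm for s in splits],
        "std_diameter": [s.val_std_diameter_mm for s in splits],
    }
    aggs = {k: agg(v) for k, v in fields.items()}
    return OptimizationReport(
        method=method,
        n_repetitions=n_reps,
        p1_mean=p1m,
        p1_std=p1s,
        p2_mean=p2m,
        p2_std=p2s,
        icc_volume_mean=aggs["icc_volume"][0],
        icc_volume_std=aggs["icc_volume"][1],
        icc_diameter_mean=aggs["icc_diameter"][0],
        icc_diameter_std=aggs["icc_diameter"][1],
        meandiff_volume_mean=aggs["meandiff_volume"][0],
        meandiff_volume_std=aggs["meandiff_volume"][1],
        std_volume_mean=aggs["std_volume"][0],
        std_volume_std=aggs["std_volume"][1],
        meandiff_diameter_mean=aggs["meandiff_diameter"][0],
        meandiff_diameter_std=aggs["meandiff_diameter"][1],
        std_diameter_mean=aggs["std_diameter"][0],
        std_diameter_std=aggs["std_diameter"][1],
        splits=splits,
    )
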