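"""Synthetic CT phantom: stones with analytic ground truth in a water bath.

The simulator stands in for a physical phantom study: dense stones
(hundreds to >1000 HU) immersed in water (0 HU), imaged at 0.7 mm isotropic
resolution.  Two imaging effects are modelled:

* **surface partial volume** — a boundary voxel's HU is the occupancy-
  weighted mixture of stone and background, obtained by supersampled
  sub-voxel point sampling;
* **scanner blur** — an isotropic Gaussian point-spread surrogate.

Additive Gaussian HU noise emulates a low-dose acquisition.  Three noisy
"raters" per stone emulate independent caliper / water-displacement
reference measurements; their mean is the reference standard.

All randomness flows through a single master seed
(:class:`numpy.random.SeedSequence` children per consumer), so identical
seeds give identical phantoms.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.ndimage import gaussian_filter
from scipy.spatial import ConvexHull, QhullError
from scipy.spatial.distance import pdist

from .core import Annotation, CTVolume
from .errors import InvalidSpecError, OutOfBoundsError, PlacementError

SHAPE_FAMILIES = ("sphere", "ellipsoid", "perturbed_ellipsoid")

# normalized quadratic direction harmonics used for the radial perturbation;
# each is bounded by 1 in magnitude on the unit sphere
def _harmonics(u: np.ndarray) -> np.ndarray:
    ux, uy, uz = u[..., 0], u[..., 1], u[..., 2]
    return np.stack(
        [2 * ux * uy, 2 * uy * uz, 2 * uz * ux, ux * ux - uy * uy, (3 * uz * uz - 1) / 2],
        axis=-1,
    )

_HARMONIC_GRAD_BOUND = 3.0  # sup of |surface gradient| over the 5 harmonics


@dataclass(frozen=True)
class StoneSpec:
    """Geometry and density of one synthetic stone.

    ``shape_params`` holds the semi-axes in mm under key ``semi_axes`` (a
    single radius for spheres is stored as three equal semi-axes) and, for
    the perturbed family, ``amplitude`` (relative radial perturbation) and
    ``coeffs`` (5 harmonic coefficients with |coeffs| summing to 1).
    """

    stone_id: str
    shape_family: str
    shape_params: dict
    density_hu: float
    center_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        if self.shape_family not in SHAPE_FAMILIES:
            raise InvalidSpecError(f"unknown shape_family {self.shape_family!r}")
        axes = np.asarray(self.shape_params["semi_axes"], dtype=float)
        if axes.shape != (3,) or np.any(axes <= 0):
            raise InvalidSpecError("semi_axes must be 3 positive lengths")
        amp = self._amp_total()
        if 2 * axes.min() * (1 - amp) < 4.0 - 1e-9:
            raise InvalidSpecError(
                f"stone {self.stone_id}: minimum diameter below the 4 mm inclusion rule"
            )
        if not self.density_hu > 100:
            raise InvalidSpecError("density_hu must exceed 100 HU")

    def _amp_total(self) -> float:
        if self.shape_family != "perturbed_ellipsoid":
            return 0.0
        amp = float(self.shape_params.get("amplitude", 0.0))
        coeffs = np.asarray(self.shape_params.get("coeffs", np.zeros(5)), dtype=float)
        return amp * float(np.abs(coeffs).sum())


@dataclass(frozen=True)
class GroundTruth:
    """Analytic truth for one stone: volume in mL, maximum (Feret) diameter in mm."""

    stone_id: str
    volume_ml: float
    diameter_mm: float

    def __post_init__(self) -> None:
        if not self.volume_ml > 0:
            raise InvalidSpecError("volume_ml must be > 0")
        # diameter^3 >= 6 V / pi, equality iff sphere
        lower = (6000.0 * self.volume_ml / math.pi) ** (1 / 3)
        if self.diameter_mm < lower - 1e-6:
            raise InvalidSpecError("diameter inconsistent with volume (below sphere bound)")


@dataclass(frozen=True)
class RaterRecord:
    """Three simulated reference measurements per stone; the mean is the reference."""

    stone_id: str
    volumes_ml: tuple[float, float, float]
    diameters_mm: tuple[float, float, float]
    reference_volume_ml: float
    reference_diameter_mm: float

    def __post_init__(self) -> None:
        if min(self.volumes_ml) <= 0 or min(self.diameters_mm) <= 0:
            raise InvalidSpecError("rater measurements must be positive")
        if not math.isclose(self.reference_volume_ml, float(np.mean(self.volumes_ml)), rel_tol=1e-9):
            raise InvalidSpecError("reference_volume_ml must equal the rater mean")
        if not math.isclose(self.reference_diameter_mm, float(np.mean(self.diameters_mm)), rel_tol=1e-9):
            raise InvalidSpecError("reference_diameter_mm must equal the rater mean")


@dataclass(frozen=True)
class PhantomConfig:
    """Imaging and simulation parameters.

    Defaults reproduce the study conditions: 0.7 mm isotropic voxels, water
    background, 0.5 mm Gaussian PSF surrogate, 10 HU noise (low-dose
    order of magnitude), supersample 8 for partial-volume rasterization,
    3% rater coefficient of variation, stone densities uniform in
    300–1500 HU and maximum diameters log-uniform in 5–30 mm (a population
    whose between-stone spread mirrors a mixed clinical collection
    including large animal stones).
    """

    spacing_mm: tuple[float, float, float] = (0.7, 0.7, 0.7)
    background_hu: float = 0.0
    psf_sigma_mm: float = 0.5
    noise_sd_hu: float = 10.0
    supersample: int = 8
    rater_noise_cv: float = 0.03
    seed: int = 0
    density_range_hu: tuple[float, float] = (300.0, 1500.0)
    diameter_range_mm: tuple[float, float] = (5.0, 30.0)
    annotation_margin_mm: float = 2.0
    clearance_mm: float = 5.0

    def __post_init__(self) -> None:
        if np.any(np.asarray(self.spacing_mm) <= 0):
            raise InvalidSpecError("spacing must be positive")
        if self.supersample < 1:
            raise InvalidSpecError("supersample must be >= 1")
        if self.noise_sd_hu < 0 or self.rater_noise_cv < 0 or self.psf_sigma_mm < 0:
            raise InvalidSpecError("noise scales must be >= 0")


class StoneShape:
    """Star-convex implicit shape: an ellipsoid with an optional low-order
    harmonic radial perturbation.

    A point x is inside iff |E (x - c)| <= s(u), where E = diag(1/a, 1/b, 1/c),
    u = (x - c)/|x - c| and s(u) = 1 + amplitude * coeffs . harmonics(u).
    """

    def __init__(
        self,
        center_mm: np.ndarray,
        semi_axes_mm: np.ndarray,
        amplitude: float = 0.0,
        coeffs: np.ndarray | None = None,
    ) -> None:
        self.center = np.asarray(center_mm, dtype=float)
        self.axes = np.asarray(semi_axes_mm, dtype=float)
        self.amplitude = float(amplitude)
        self.coeffs = np.zeros(5) if coeffs is None else np.asarray(coeffs, dtype=float)
        self.amp_total = self.amplitude * float(np.abs(self.coeffs).sum())
        if self.amp_total >= 0.5:
            raise InvalidSpecError("perturbation amplitude too large for star-convexity")

    # -- geometry ---------------------------------------------------------
    def _scale(self, u: np.ndarray) -> np.ndarray:
        if self.amp_total == 0:
            return np.ones(u.shape[:-1])
        return 1.0 + self.amplitude * (_harmonics(u) @ self.coeffs)

    def radius(self, u: np.ndarray) -> np.ndarray:
        """Surface radius (mm) along unit directions u (…, 3)."""
        denom = np.linalg.norm(u / self.axes, axis=-1)
        return self._scale(u) / denom

    def contains(self, points_mm: np.ndarray) -> np.ndarray:
        d = np.asarray(points_mm, dtype=float) - self.center
        r = np.linalg.norm(d, axis=-1)
        safe = np.where(r[..., None] > 0, d / np.maximum(r, 1e-12)[..., None], 0.0)
        g = np.linalg.norm(d / self.axes, axis=-1) - self._scale(safe)
        return g <= 0

    def classify(self, points_mm: np.ndarray, half_diagonal_mm: float) -> np.ndarray:
        """Conservative voxel classification: -1 certainly inside, +1 certainly
        outside, 0 possibly boundary (for any point within half_diagonal_mm)."""
        d = np.asarray(points_mm, dtype=float) - self.center
        r = np.linalg.norm(d, axis=-1)
        u = np.where(r[..., None] > 0, d / np.maximum(r, 1e-12)[..., None], 0.0)
        g = np.linalg.norm(d / self.axes, axis=-1) - self._scale(u)
        min_ax = float(self.axes.min())
        inscribed = (1 - self.amp_total) * min_ax
        # Lipschitz bound of g wrt x: ||E|| plus the angular term of s
        r_floor = np.maximum(r - half_diagonal_mm, 0.5 * inscribed)
        lip = 1.0 / min_ax + _HARMONIC_GRAD_BOUND * self.amplitude * np.abs(self.coeffs).sum() / r_floor
        margin = lip * half_diagonal_mm
        out = np.zeros(g.shape, dtype=np.int8)
        out[g >= margin] = 1
        out[g <= -margin] = -1
        # whole voxel inside the inscribed ball -> certainly inside
        out[r + half_diagonal_mm <= inscribed] = -1
        return out

    @property
    def bounding_radius_mm(self) -> float:
        return float(self.axes.max()) * (1 + self.amp_total)

    def surface_points(self, n: int = 4096) -> np.ndarray:
        u = fibonacci_sphere(n)
        return self.center + self.radius(u)[:, None] * u


def fibonacci_sphere(n: int) -> np.ndarray:
    """n approximately uniform unit directions (Fibonacci lattice)."""
    i = np.arange(n) + 0.5
    phi = math.pi * (1 + math.sqrt(5)) * i
    z = 1 - 2 * i / n
    rho = np.sqrt(np.maximum(1 - z * z, 0.0))
    return np.stack([rho * np.cos(phi), rho * np.sin(phi), z], axis=-1)


def _max_pairwise(points: np.ndarray) -> float:
    """Maximum pairwise distance, via convex hull when it helps."""
    pts = points
    if len(pts) > 400:
        try:
            pts = pts[ConvexHull(pts).vertices]
        except QhullError:
            pass
    return float(pdist(pts).max())


def make_stone_shape(spec: StoneSpec, rng: np.random.Generator | None = None) -> tuple[StoneShape, GroundTruth]:
    """Build the implicit shape for a spec and its exact ground truth.

    Volume is closed-form for spheres/ellipsoids and a dense spherical
    quadrature of the star-convex radial function for perturbed shapes
    (V = (4π/3N) Σ r(u_i)^3); diameter is the largest axis for the symmetric
    families and the max pairwise distance over a dense surface sample for
    perturbed shapes.  ``rng`` draws harmonic coefficients when a perturbed
    spec omits them, keeping specs self-contained otherwise.
    """
    axes = np.asarray(spec.shape_params["semi_axes"], dtype=float)
    if spec.shape_family == "perturbed_ellipsoid":
        amp = float(spec.shape_params.get("amplitude", 0.1))
        coeffs = spec.shape_params.get("coeffs")
        if coeffs is None:
            if rng is None:
                raise InvalidSpecError("perturbed spec without coeffs needs an rng")
            coeffs = rng.normal(size=5)
            coeffs /= np.abs(coeffs).sum()
        coeffs = np.asarray(coeffs, dtype=float)
    else:
        amp, coeffs = 0.0, None

    shape = StoneShape(np.asarray(spec.center_mm, float), axes, amp, coeffs)
    if spec.shape_family in ("sphere", "ellipsoid"):
        volume_ml = 4 / 3 * math.pi * float(np.prod(axes)) / 1000.0
        diameter_mm = 2 * float(axes.max())
    else:
        u = fibonacci_sphere(16384)
        r = shape.radius(u)
        volume_ml = float(4 * math.pi / 3 * np.mean(r**3)) / 1000.0
        diameter_mm = _max_pairwise(shape.surface_points(8192))
    return shape, GroundTruth(spec.stone_id, volume_ml, diameter_mm)


def _shape_bounds(shape) -> tuple[np.ndarray, np.ndarray]:
    if hasattr(shape, "bounds_mm"):
        lo, hi = shape.bounds_mm()
        return np.asarray(lo, float), np.asarray(hi, float)
    c = np.asarray(shape.center, float)
    r = shape.bounding_radius_mm
    return c - r, c + r


def _rasterize_box(
    shape,
    grid_shape: tuple[int, int, int],
    spacing: np.ndarray,
    origin: np.ndarray,
    supersample: int,
) -> tuple[tuple[slice, slice, slice], np.ndarray]:
    """Occupancy of a shape inside its bounding sub-box of a voxel grid."""
    lo_mm, hi_mm = _shape_bounds(shape)
    grid_hi = origin + (np.asarray(grid_shape) - 1) * spacing
    if np.any(lo_mm < origin - spacing / 2) or np.any(hi_mm > grid_hi + spacing / 2):
        raise OutOfBoundsError("shape extends outside the grid")

    lo_idx = np.maximum(np.floor((lo_mm - origin) / spacing).astype(int) - 1, 0)
    hi_idx = np.minimum(np.ceil((hi_mm - origin) / spacing).astype(int) + 1, np.asarray(grid_shape) - 1)
    box = tuple(slice(int(l), int(h) + 1) for l, h in zip(lo_idx, hi_idx))
    nbox = hi_idx - lo_idx + 1

    idx = np.stack(
        np.meshgrid(*[np.arange(l, h + 1) for l, h in zip(lo_idx, hi_idx)], indexing="ij"),
        axis=-1,
    ).reshape(-1, 3)
    centers = origin + idx * spacing
    occ = np.zeros(len(centers))

    half_diag = float(np.linalg.norm(spacing)) / 2
    if hasattr(shape, "classify"):
        cls = np.asarray(shape.classify(centers, half_diag)).reshape(-1)
    else:
        cls = np.zeros(len(centers), dtype=np.int8)  # supersample everything
    occ[cls == -1] = 1.0

    boundary = np.flatnonzero(cls == 0)
    if boundary.size:
        if supersample == 1:
            occ[boundary] = shape.contains(centers[boundary]).astype(float)
        else:
            off1 = (np.arange(supersample) + 0.5) / supersample - 0.5
            offs = np.stack(np.meshgrid(off1, off1, off1, indexing="ij"), axis=-1).reshape(-1, 3)
            sub = centers[boundary][:, None, :] + offs[None, :, :] * spacing
            inside = shape.contains(sub.reshape(-1, 3)).reshape(len(boundary), -1)
            occ[boundary] = inside.mean(axis=1)
    return box, occ.reshape(tuple(int(n) for n in nbox))


def rasterize_partial_volume(
    shape,
    grid_shape: tuple[int, int, int],
    spacing_mm: np.ndarray,
    origin_mm: np.ndarray,
    supersample: int = 8,
) -> np.ndarray:
    """Occupancy fractions in [0, 1] for a shape on a voxel grid.

    Each voxel's value is the fraction of its supersample³ sub-points inside
    the shape; interior voxels are exactly 1, exterior exactly 0.  When the
    shape exposes a conservative ``classify``, only candidate boundary voxels
    are supersampled (verified against full supersampling in tests).
    """
    if supersample < 1:
        raise InvalidSpecError("supersample must be >= 1")
    spacing = np.asarray(spacing_mm, float)
    origin = np.asarray(origin_mm, float)
    box, occ = _rasterize_box(shape, grid_shape, spacing, origin, supersample)
    full = np.zeros(grid_shape)
    full[box] = occ
    return full


def render_ct(
    occupancy: np.ndarray,
    config: PhantomConfig,
    density_hu: float,
    rng: np.random.Generator | None = None,
) -> CTVolume:
    """Turn an occupancy grid into a CT volume: mixture HU, Gaussian PSF, noise.

    HU = background + occupancy·(density − background), blurred with an
    isotropic Gaussian of ``psf_sigma_mm``, plus zero-mean Gaussian noise of
    SD ``noise_sd_hu``.  Deterministic for a given seed.
    """
    occ = np.asarray(occupancy, dtype=float)
    hu = config.background_hu + occ * (density_hu - config.background_hu)
    hu = _blur_and_noise(hu, config, rng)
    return CTVolume(hu, np.asarray(config.spacing_mm))


def _blur_and_noise(hu: np.ndarray, config: PhantomConfig, rng: np.random.Generator | None) -> np.ndarray:
    if config.psf_sigma_mm > 0:
        sigma_vox = config.psf_sigma_mm / np.asarray(config.spacing_mm)
        hu = gaussian_filter(hu, sigma=sigma_vox, mode="constant", cval=config.background_hu)
    if config.noise_sd_hu > 0:
        if rng is None:
            rng = np.random.default_rng(config.seed)
        noise = rng.normal(0.0, config.noise_sd_hu, size=hu.shape)
        # truncate at 5 SD: bounded noise keeps rendered HU inside
        # [background, density] +/- 5 SD exactly; the truncation is
        # statistically negligible (P(|z|>5) ~ 6e-7 per voxel)
        np.clip(noise, -5 * config.noise_sd_hu, 5 * config.noise_sd_hu, out=noise)
        hu = hu + noise
    return hu


def simulate_raters(
    truth: GroundTruth, rater_noise_cv: float, rng: np.random.Generator
) -> RaterRecord:
    """Three independent multiplicative-noise reference measurements.

    Each rater reports truth · (1 + cv·z) (clipped positive), emulating
    caliper and water-displacement error that scales with magnitude.
    """
    if rater_noise_cv < 0:
        raise InvalidSpecError("rater_noise_cv must be >= 0")
    factors = 1.0 + rater_noise_cv * rng.standard_normal(6)
    factors = np.maximum(factors, 0.05)
    vols = tuple(float(truth.volume_ml * f) for f in factors[:3])
    diams = tuple(float(truth.diameter_mm * f) for f in factors[3:])
    return RaterRecord(truth.stone_id, vols, diams, float(np.mean(vols)), float(np.mean(diams)))


def sample_stone_specs(
    n: int, config: PhantomConfig, rng: np.random.Generator
) -> list[StoneSpec]:
    """Draw a stone population: families cycled evenly, max diameter
    log-uniform over ``diameter_range_mm``, density uniform over
    ``density_range_hu``, respecting the 4 mm minimum-diameter inclusion rule."""
    lo_d, hi_d = config.diameter_range_mm
    specs = []
    for i in range(n):
        family = SHAPE_FAMILIES[i % len(SHAPE_FAMILIES)]
        dmax = float(np.exp(rng.uniform(np.log(lo_d), np.log(hi_d))))
        a = dmax / 2
        if family == "sphere":
            axes = (a, a, a)
            params: dict = {"semi_axes": axes}
        else:
            amp = float(rng.uniform(0.05, 0.15)) if family == "perturbed_ellipsoid" else 0.0
            floor = (2.0 + 1e-6) / (1 - amp)  # keep min diameter >= 4 mm
            lo_ratio = min(max(0.55, floor / a), 1.0)
            b, c = a * rng.uniform(lo_ratio, 1.0, size=2)
            axes = (a, float(max(b, c)), float(min(b, c)))
            params = {"semi_axes": axes}
            if family == "perturbed_ellipsoid":
                coeffs = rng.normal(size=5)
                coeffs /= np.abs(coeffs).sum()
                params["amplitude"] = amp
                params["coeffs"] = tuple(float(x) for x in coeffs)
        density = float(rng.uniform(*config.density_range_hu))
        specs.append(StoneSpec(f"stone{i:03d}", family, params, density))
    return specs


@dataclass
class PhantomDataset:
    """Everything one simulated experiment produces."""

    volume: CTVolume
    annotations: list[Annotation]
    truths: list[GroundTruth]
    raters: list[RaterRecord]
    specs: list[StoneSpec]
    config: PhantomConfig = field(default_factory=PhantomConfig)


def make_phantom(
    n_stones: int = 101,
    config: PhantomConfig | None = None,
    specs: list[StoneSpec] | None = None,
) -> PhantomDataset:
    """Simulate one full phantom experiment.

    Stones are laid out on a jittered 3D lattice in a water volume, mutually
    separated so that their annotation spheres never overlap (emulating
    stones placed on separate pedestals).  Each stone gets one annotation
    whose sphere fully contains its true surface (centre at the stone
    centre, radius = max surface radius + margin), an analytic ground-truth
    record and a simulated 3-rater reference record.
    """
    config = config or PhantomConfig()
    ss = np.random.SeedSequence(config.seed)
    rng_spec, rng_noise, rng_rater, rng_place = (np.random.default_rng(c) for c in ss.spawn(4))

    if specs is None:
        specs = sample_stone_specs(n_stones, config, rng_spec)
    if len(specs) != n_stones:
        raise InvalidSpecError("specs length must equal n_stones")

    shapes, truths, ann_radii = [], [], []
    for spec in specs:
        shape, truth = make_stone_shape(spec, rng_spec)
        shapes.append(shape)
        truths.append(truth)
        r_surf = float(shape.radius(fibonacci_sphere(512)).max())
        ann_radii.append(max(truth.diameter_mm / 2, r_surf) + config.annotation_margin_mm)

    spacing = np.asarray(config.spacing_mm)
    r_max = max(ann_radii)
    pitch = 2 * r_max + config.clearance_mm
    ncell = int(math.ceil(n_stones ** (1 / 3)))
    dims = [ncell, ncell, int(math.ceil(n_stones / ncell**2))]
    pad = r_max + 4 * config.psf_sigma_mm + 2 * float(spacing.max())
    extent = np.array([d * pitch + 2 * pad for d in dims])
    grid_shape = tuple(int(math.ceil(e / s)) + 1 for e, s in zip(extent, spacing))

    centers = []
    cells = [(i, j, k) for i in range(dims[0]) for j in range(dims[1]) for k in range(dims[2])]
    for idx, (shape, r_ann) in enumerate(zip(shapes, ann_radii)):
        if idx >= len(cells):
            raise PlacementError("more stones than lattice cells")
        cell = np.asarray(cells[idx], float)
        base = pad + (cell + 0.5) * pitch
        wiggle = max(pitch / 2 - r_ann - 3 * config.psf_sigma_mm - float(spacing.max()), 0.0)
        center = base + rng_place.uniform(-wiggle, wiggle, size=3)
        centers.append(center)
        shape.center = center

    hu = np.full(grid_shape, float(config.background_hu))
    for shape, spec in zip(shapes, specs):
        box, occ = _rasterize_box(shape, grid_shape, spacing, np.zeros(3), config.supersample)
        hu[box] += occ * (spec.density_hu - config.background_hu)
    hu = _blur_and_noise(hu, config, rng_noise)
    volume = CTVolume(hu, spacing, np.zeros(3))

    annotations = [
        Annotation(spec.stone_id, tuple(float(x) for x in c), r_ann)
        for spec, c, r_ann in zip(specs, centers, ann_radii)
    ]
    truths = [replace(t) for t in truths]
    raters = [simulate_raters(t, config.rater_noise_cv, rng_rater) for t in truths]
    specs = [replace(s, center_mm=tuple(float(x) for x in c)) for s, c in zip(specs, centers)]
    return PhantomDataset(volume, annotations, truths, raters, specs, config)
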