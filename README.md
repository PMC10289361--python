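# lithoseg

Semi-automated segmentation and size measurement of urinary stones
(uroliths) in computed tomography, with the statistical machinery to
compare segmentation methods against a multi-rater reference standard —
plus a synthetic CT phantom simulator so the complete method-comparison
experiment runs end to end with no external data.

Accurate stone size matters clinically: treatment choice (ureterorenoscopy
vs. percutaneous approaches) keys on stone burden, and volume captures
burden better than a single caliper diameter, especially for irregular
stones. `lithoseg` is for imaging scientists and urology researchers who
want reproducible, parameter-transparent volumetry from CT.

## The methods

Within a spherical annotation (centre + radius) around each stone, four
threshold segmentations are implemented:

| method   | threshold                                   | surface PV correction |
|----------|---------------------------------------------|-----------------------|
| `abs`    | fixed absolute threshold P1 (HU)            | —                     |
| `abs-pv` | fixed absolute threshold P1 (HU)            | factor P2             |
| `med`    | P1 × median HU of a rough 20 HU segmentation | —                    |
| `med-pv` | P1 × median HU of a rough 20 HU segmentation | factor P2            |

After thresholding (HU ≥ t), the 26-connected component at the annotation
centre is kept and interior cavities are filled. From the binary mask:

- **volume** `V = (N − P2·N_surf) · dx·dy·dz` in mL, where `N_surf` counts
  6-face surface voxels — the PV correction compensates boundary voxels
  that are a partial mixture of stone and water;
- **maximum diameter** (Feret) `D = max pairwise distance between
  surface-voxel centres + one voxel edge` in mm.

Parameters are optimized against the rater reference by minimizing the
weighted L1 cost `Σ 4·|Ve − Vr| + |De − Dr|` on random training subsets
(default 80 of 101 stones), with validation metrics — ICC(A,1), mean and
SD of `reference − estimate` — evaluated on the held-out stones and
aggregated over repeated random splits. Method equivalence is assessed by
Bartlett's chi-square test on the per-method error variances, separately
for volume and diameter.

The phantom simulator generates stones (spheres, ellipsoids, perturbed
ellipsoids) with analytic ground truth in a water bath at 0.7 mm isotropic
resolution, modelling surface partial volume by supersampled rasterization,
scanner blur by an isotropic Gaussian PSF, additive HU noise, and three
noisy raters per stone whose mean is the reference standard.

## A worked example

```python
import lithoseg as ls

dataset = ls.make_phantom(20, ls.PhantomConfig(seed=12))
cache = ls.MeasurementCache(dataset.volume, dataset.annotations)
report = ls.cross_validate(ls.Method.MED, cache, dataset.raters,
                           n_reps=10, train_size=15, val_size=5, seed=12)
print(f"P1 = {report.p1_mean:.3f} ({report.p1_std:.3f})")
print(f"volume ICC = {report.icc_volume_mean:.4f}, "
      f"mean diff = {report.meandiff_volume_mean:+.3f} mL")
```

prints

```
P1 = 0.595 (0.047)
volume ICC = 0.9942, mean diff = +0.044 mL
```

i.e. the optimal adaptive threshold is ~0.60× the stone median HU, stable
across splits (std 0.047), and the segmented volumes agree with the
reference standard to ICC 0.994 with a +0.044 mL mean difference
(reference minus estimate). The `examples/` directory has one narrative
script per capability: phantom simulation, segmentation and morphometry,
threshold optimization, and method-agreement statistics.

A thin CLI wraps the same pipeline:

```sh
lithoseg simulate --n-stones 101 --seed 1 --out phantom/
lithoseg segment  --method abs --p1 272 --volume phantom/volume.nii.gz \
                  --annotations phantom/annotations.json --out masks/
lithoseg run      --config config.yaml --out results/
```

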