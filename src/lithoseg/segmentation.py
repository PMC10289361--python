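"""The four threshold-based stone segmentation methods.

Each stone is processed inside its circular annotation (a sphere in 3D:
centre + maximum radius).  The methods differ only in how the HU threshold
is chosen and whether a surface partial-volume correction is applied later
at the volume-computation step:

* ``abs`` / ``abs-pv`` — one absolute threshold P1 (HU) shared by all stones;
* ``med`` / ``med-pv`` — per-stone adaptive threshold: the stone is first
  roughly segmented at a low 20 HU threshold, and the working threshold is
  P1 times the median HU of that rough segmentation.

After thresholding, the connected component at the annotation centre is
selected (26-connectivity) and interior cavities are filled ("fill-hole").
The surface factor P2 never alters the mask; it only rescales the volume
(see :mod:`lithoseg.morphometry`).

Conventions: threshold comparison is inclusive (HU >= t); a voxel belongs
to the region of interest iff its centre lies within the annotation radius;
surface voxels are mask voxels with at least one of their 6 face neighbours
(or the grid boundary) outside the mask.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

from .core import Annotation, CTVolume, MethodParams, StoneMask
from .errors import EmptyRoiError, EmptySegmentationError

ROUGH_THRESHOLD_HU = 20.0

_CONN26 = np.ones((3, 3, 3), dtype=bool)
_CONN6 = ndimage.generate_binary_structure(3, 1)


def _roi_box(volume: CTVolume, annotation: Annotation):
    """Bounding-box slices of the annotation sphere, clipped to the grid."""
    c_idx = volume.world_to_index(np.asarray(annotation.center_mm))
    r_vox = annotation.radius_mm / volume.spacing_mm
    lo = np.maximum(np.floor(c_idx - r_vox).astype(int), 0)
    hi = np.minimum(np.ceil(c_idx + r_vox).astype(int), np.asarray(volume.shape) - 1)
    if np.any(lo > hi):
        raise EmptyRoiError(f"annotation {annotation.stone_id} lies outside the grid")
    return tuple(slice(int(a), int(b) + 1) for a, b in zip(lo, hi)), c_idx - lo


def _roi_mask_box(volume: CTVolume, annotation: Annotation):
    """(slices, roi bool grid over the box, centre voxel index within the box)."""
    box, c_local = _roi_box(volume, annotation)
    shape = tuple(s.stop - s.start for s in box)
    grids = np.ogrid[: shape[0], : shape[1], : shape[2]]
    d2 = sum(
        ((g - c) * s) ** 2 for g, c, s in zip(grids, c_local, volume.spacing_mm)
    )
    roi = d2 <= annotation.radius_mm**2
    if not roi.any():
        raise EmptyRoiError(f"annotation {annotation.stone_id} contains no voxel centre")
    center_vox = tuple(int(round(x)) for x in c_local)
    center_vox = tuple(np.clip(center_vox, 0, np.asarray(shape) - 1))
    return box, roi, center_vox


def roi_restrict(volume: CTVolume, annotation: Annotation) -> np.ndarray:
    """Full-grid boolean mask of voxels whose centres lie inside the annotation sphere."""
    box, roi, _ = _roi_mask_box(volume, annotation)
    full = np.zeros(volume.shape, dtype=bool)
    full[box] = roi
    return full


def _select_component(candidate: np.ndarray, center_vox, spacing: np.ndarray) -> np.ndarray:
    """26-connected component containing the annotation centre; if the centre
    voxel is below threshold, the component nearest to it (ties: largest, then
    lowest linear index)."""
    labels, n = ndimage.label(candidate, structure=_CONN26)
    if n == 0:
        raise EmptySegmentationError("no voxel above threshold in the annotation region")
    if n == 1:
        return labels == 1
    lab_center = labels[center_vox]
    if lab_center > 0:
        return labels == lab_center
    coords = np.argwhere(labels > 0)
    labs = labels[tuple(coords.T)]
    d2 = (((coords - np.asarray(center_vox)) * spacing) ** 2).sum(axis=1)
    dmin = d2.min()
    near_labs = np.unique(labs[d2 == dmin])
    if len(near_labs) > 1:
        sizes = np.array([(labels == l).sum() for l in near_labs])
        near_labs = near_labs[sizes == sizes.max()]
        if len(near_labs) > 1:
            firsts = [
                np.flatnonzero((labels == l).ravel())[0] for l in near_labs
            ]
            near_labs = [near_labs[int(np.argmin(firsts))]]
    return labels == near_labs[0]


def _fill_holes(mask: np.ndarray) -> np.ndarray:
    """3D fill-hole: include background regions not connected to the box border.

    Equivalent to scipy's binary_fill_holes (6-connected background reached
    from the border), implemented via one background labelling pass, which is
    faster on the small per-stone crops the optimizer grinds through.
    """
    inv = ~mask
    labels, n = ndimage.label(inv, structure=_CONN6)
    if n <= 1:  # background is a single region: nothing to fill
        return mask.copy() if n == 1 else np.ones_like(mask)
    outside = np.zeros(n + 1, dtype=bool)
    for face in (
        labels[0], labels[-1], labels[:, 0], labels[:, -1], labels[:, :, 0], labels[:, :, -1]
    ):
        outside[np.unique(face)] = True
    outside[0] = True
    return mask | ~outside[labels]


def rough_mask(
    volume: CTVolume,
    annotation: Annotation,
    rough_threshold_hu: float = ROUGH_THRESHOLD_HU,
) -> StoneMask:
    """Rough low-threshold segmentation used to derive the adaptive threshold.

    Voxels in the annotation sphere with HU >= 20 (default), reduced to the
    connected component at/nearest the annotation centre.  No hole filling:
    this mask only feeds the median-HU statistic.
    """
    box, roi, center_vox = _roi_mask_box(volume, annotation)
    hu = volume.values[box]
    comp = _select_component(roi & (hu >= rough_threshold_hu), center_vox, volume.spacing_mm)
    full = np.zeros(volume.shape, dtype=bool)
    full[box] = comp
    return StoneMask(full, annotation.stone_id, volume.spacing_mm)


def stone_threshold(
    volume: CTVolume,
    annotation: Annotation,
    params: MethodParams,
    rough_threshold_hu: float = ROUGH_THRESHOLD_HU,
) -> float:
    """Working threshold in HU for one stone under the given method.

    ABS methods return P1 unchanged; MED methods return
    P1 x median(HU over the rough segmentation of this stone).
    """
    if not params.method.adaptive:
        return float(params.p1)
    rough = rough_mask(volume, annotation, rough_threshold_hu)
    return float(params.p1) * float(np.median(volume.values[rough.values]))


def segment(
    volume: CTVolume,
    annotation: Annotation,
    params: MethodParams,
    rough_threshold_hu: float = ROUGH_THRESHOLD_HU,
) -> StoneMask:
    """Segment one stone: threshold, component selection, fill-hole.

    The returned mask satisfies the StoneMask invariants: one 26-connected
    component, every voxel inside the annotation sphere, grid-aligned with
    the source volume.  P2 does not act here.
    """
    thr = stone_threshold(volume, annotation, params, rough_threshold_hu)
    box, roi, center_vox = _roi_mask_box(volume, annotation)
    hu = volume.values[box]
    comp = _select_component(roi & (hu >= thr), center_vox, volume.spacing_mm)
    comp = _fill_holes(comp)
    full = np.zeros(volume.shape, dtype=bool)
    full[box] = comp
    return StoneMask(full, annotation.stone_id, volume.spacing_mm)


def surface_voxels(mask: StoneMask | np.ndarray) -> tuple[np.ndarray, int]:
    """Surface voxels: in the mask with a 6-face neighbour (or the grid
    boundary) outside it.  Returns (boolean grid, count)."""
    values = mask.values if isinstance(mask, StoneMask) else np.asarray(mask, dtype=bool)
    interior = ndimage.binary_erosion(values, structure=_CONN6, border_value=0)
    surf = values & ~interior
    return surf, int(surf.sum())
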