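"""Semiautomatic tumor segmentation, liver segmentation and mask morphometrics.

The tumor segmenter emulates a one-gesture clinical workflow: the user
draws a line across the maximal dimension of the lesion in any plane, and
the volume grows out from that line. The algorithm is deliberately simple
and parameter-transparent:

1. sample intensity statistics in a small sphere at the line midpoint;
2. connected-threshold region growing within ``mean +/- k*SD`` of the seed
   statistics, restricted to a bounding sphere of 1.5x the line length;
3. one-voxel morphological closing, then keep the connected component
   containing the midpoint.

Manual corrections are applied as explicit add/remove masks (`edit_mask`),
mirroring how a reader would fix an under- or over-grown margin.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.spatial import ConvexHull, QhullError
from scipy.spatial.distance import pdist

from .errors import EmptyRegionError, SegmentationFailedError, ValidationError


@dataclass(frozen=True)
class DiameterLine:
    """User-drawn line across the maximal tumor dimension (world mm)."""

    p1: tuple
    p2: tuple
    plane: str = "axial"  # metadata only

    def __post_init__(self):
        if tuple(self.p1) == tuple(self.p2):
            raise ValidationError("line endpoints must differ")

    @property
    def midpoint(self):
        return tuple((a + b) / 2.0 for a, b in zip(self.p1, self.p2))

    @property
    def length_mm(self) -> float:
        return float(np.linalg.norm(np.subtract(self.p2, self.p1)))


@dataclass(frozen=True)
class SegmentationParams:
    seed_radius_mm: float = 3.0
    k_sd: float = 2.5
    bbox_factor: float = 1.5  # bounding sphere diameter as multiple of line length
    closing_radius_voxels: int = 1


@dataclass
class SegmentationResult:
    mask: np.ndarray
    volume_ml: float
    max_diameter_mm: float
    line_length_mm: float
    edited: bool = False
    low_contrast: bool = False


def _check_inside(point, shape, spacing):
    for p, n, s in zip(point, shape, spacing):
        if not (0.0 <= p <= (n - 1) * s):
            raise ValidationError(f"point {point} lies outside the image extent")


def mask_metrics(mask: np.ndarray, spacing):
    """Volume (mL) and maximal 3-D diameter (mm) of a binary mask.

    Volume is the exact voxel count times the voxel volume. The maximal
    diameter is the 3-D Feret diameter: the largest pairwise Euclidean
    distance between surface-voxel centers, computed on the convex hull of
    the surface points.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise EmptyRegionError("mask is empty")
    spacing = np.asarray(spacing, dtype=float)
    volume_ml = int(mask.sum()) * float(np.prod(spacing)) / 1000.0

    surface = mask & ~ndimage.binary_erosion(mask)
    pts = np.argwhere(surface) * spacing
    if len(pts) == 1:
        return volume_ml, 0.0
    if len(pts) > 4:
        try:
            pts = pts[ConvexHull(pts).vertices]
        except QhullError:
            pass  # degenerate (coplanar/collinear): fall back to all points
    return volume_ml, float(pdist(pts).max())


def segment_tumor(
    image: np.ndarray,
    spacing,
    line: DiameterLine,
    params: SegmentationParams = SegmentationParams(),
) -> SegmentationResult:
    """Region-growing tumor segmentation seeded from a maximal-diameter line."""
    image = np.asarray(image, dtype=float)
    spacing = np.asarray(spacing, dtype=float)
    _check_inside(line.p1, image.shape, spacing)
    _check_inside(line.p2, image.shape, spacing)

    mid = np.asarray(line.midpoint)
    idx = [np.arange(n) * s for n, s in zip(image.shape, spacing)]
    X, Y, Z = np.meshgrid(*idx, indexing="ij")
    dist_mid = np.sqrt((X - mid[0]) ** 2 + (Y - mid[1]) ** 2 + (Z - mid[2]) ** 2)

    seed_region = dist_mid <= params.seed_radius_mm
    if not seed_region.any():
        seed_region = dist_mid <= dist_mid.min() + 1e-9
    seed_vals = image[seed_region]
    mu, sd = float(seed_vals.mean()), float(seed_vals.std())

    half_width = params.k_sd * sd + 1e-9  # zero-SD seeds admit exact matches only
    candidates = np.abs(image - mu) <= half_width

    bound_radius = params.bbox_factor * line.length_mm / 2.0
    bounding = dist_mid <= bound_radius
    candidates &= bounding

    mid_voxel = tuple(int(round(c / s)) for c, s in zip(mid, spacing))
    if not candidates[mid_voxel]:
        raise SegmentationFailedError(
            "seed statistics admit no region at the line midpoint"
        )

    labels, _ = ndimage.label(candidates)
    grown = labels == labels[mid_voxel]

    if params.closing_radius_voxels > 0:
        struct = ndimage.generate_binary_structure(3, 1)
        closed = ndimage.binary_closing(
            grown, structure=struct, iterations=params.closing_radius_voxels
        )
    else:
        closed = grown
    labels2, _ = ndimage.label(closed)
    if labels2[mid_voxel] == 0:
        mask = grown
    else:
        mask = labels2 == labels2[mid_voxel]

    if not mask.any():
        raise SegmentationFailedError("segmentation produced an empty mask")

    # growth stopped by the geometric constraint rather than by an intensity
    # edge: the mask reaches the bounding-sphere boundary
    boundary_shell = bounding & (dist_mid > bound_radius - 1.5 * float(spacing.max()))
    low_contrast = bool((mask & boundary_shell).any())
    volume_ml, max_diam = mask_metrics(mask, spacing)
    return SegmentationResult(
        mask=mask, volume_ml=volume_ml, max_diameter_mm=max_diam,
        line_length_mm=line.length_mm, low_contrast=low_contrast,
    )


def edit_mask(mask: np.ndarray, add=None, remove=None):
    """Manual correction: ``(mask | add) & ~remove``.

    Returns ``(edited_mask, changed)`` where ``changed`` is True when the
    edit altered any voxel.
    """
    mask = np.asarray(mask, dtype=bool)
    out = mask.copy()
    for other, op in ((add, "add"), (remove, "remove")):
        if other is not None and np.asarray(other).shape != mask.shape:
            raise ValidationError(f"{op} mask is on a different grid")
    if add is not None:
        out |= np.asarray(add, dtype=bool)
    if remove is not None:
        out &= ~np.asarray(remove, dtype=bool)
    return out, bool((out != mask).any())


def segment_liver(
    image: np.ndarray,
    spacing,
    hu_window: tuple = (0.0, 250.0),
    supplied_mask: np.ndarray | None = None,
):
    """Liver segmentation: threshold band, largest component, hole filling.

    Intended for phantom-grade images where soft tissue is well separated
    from air and the strongly enhancing aorta; externally supplied masks
    are accepted verbatim (``supplied_mask``).
    """
    if supplied_mask is not None:
        supplied = np.asarray(supplied_mask, dtype=bool)
        if supplied.shape != np.asarray(image).shape:
            raise ValidationError("supplied liver mask is on a different grid")
        return supplied
    image = np.asarray(image, dtype=float)
    band = (image >= hu_window[0]) & (image <= hu_window[1])
    if not band.any():
        raise SegmentationFailedError("no voxels in the liver HU window")
    labels, n = ndimage.label(band)
    sizes = ndimage.sum_labels(np.ones_like(labels), labels, index=range(1, n + 1))
    largest = 1 + int(np.argmax(sizes))
    mask = ndimage.binary_fill_holes(labels == largest)
    return mask


def dice(a: np.ndarray, b: np.ndarray) -> float:
    """Dice overlap coefficient between two masks."""
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    denom = a.sum() + b.sum()
    if denom == 0:
        return 1.0
    return 2.0 * float((a & b).sum()) / float(denom)
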