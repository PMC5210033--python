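"""Semi-automatic threshold segmentation of small hyperintense organs.

The procedure mirrors a radiologist's workstation workflow on the b = 500
s/mm^2 diffusion image, where a fat-saturated background is dark and the
gland is bright:

1. On each gland-bearing slice the reader marks two reference voxels —
   the brightest voxel just *outside* the gland and the dimmest voxel
   *inside* it.
2. The segmentation threshold is the midpoint of those two intensities.
3. The ROI is the connected set of voxels at or above the threshold that
   contains the interior reference, with any fully enclosed darker
   pockets filled in ("the interior of the surrounded area").

Segmentation is strictly 2-D per slice (8-connectivity); per-slice masks
are stacked into a 3-D ROI.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage import measure as skmeasure

from .dwi import DWISeries
from .errors import SeedRejectionError, ValidationError

__all__ = ["SeedPair", "ROIMask", "compute_threshold", "delineate_slice_roi", "segment_gland"]


@dataclass(frozen=True)
class SeedPair:
    """Reader-placed reference voxels for one slice of one gland.

    ``exterior_ref`` is the brightest voxel adjacent to (outside) the
    gland; ``interior_ref`` is the dimmest voxel within the gland. Both
    are 3-D voxel indices whose slice-axis component equals
    ``slice_index``.
    """

    slice_index: int
    exterior_ref: tuple[int, int, int]
    interior_ref: tuple[int, int, int]

    def __post_init__(self) -> None:
        if tuple(self.exterior_ref) == tuple(self.interior_ref):
            raise ValidationError("exterior_ref and interior_ref must differ")

    def validate_on_grid(self, shape: tuple[int, int, int], slice_axis: int) -> None:
        for name, ref in (("exterior_ref", self.exterior_ref), ("interior_ref", self.interior_ref)):
            if len(ref) != 3 or any(not (0 <= ref[a] < shape[a]) for a in range(3)):
                raise ValidationError(f"{name} {ref} out of bounds for grid {shape}")
            if ref[slice_axis] != self.slice_index:
                raise ValidationError(
                    f"{name} {ref} not on slice {self.slice_index} (axis {slice_axis})"
                )

    def inplane(self, slice_axis: int) -> tuple[tuple[int, int], tuple[int, int]]:
        """(exterior, interior) 2-D coordinates with the slice axis dropped."""
        keep = [a for a in range(3) if a != slice_axis]
        ext = tuple(self.exterior_ref[a] for a in keep)
        intr = tuple(self.interior_ref[a] for a in keep)
        return ext, intr  # type: ignore[return-value]


@dataclass
class ROIMask:
    """A per-gland boolean volume on the DWI grid."""

    mask: np.ndarray
    side: str
    source_b: float | None = None
    voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 3:
            raise ValidationError("mask must be a 3-D boolean array")
        if self.side not in ("left", "right"):
            raise ValidationError(f"side must be 'left' or 'right', got {self.side!r}")
        self.voxel_size = tuple(float(v) for v in self.voxel_size)

    @property
    def voxel_count(self) -> int:
        return int(self.mask.sum())


def compute_threshold(high_adjacent: float, low_interior: float) -> float:
    """Midpoint threshold: (brightest-outside + dimmest-inside) / 2."""
    h, l = float(high_adjacent), float(low_interior)
    for name, v in (("high_adjacent", h), ("low_interior", l)):
        if not np.isfinite(v) or v < 0:
            raise ValidationError(f"{name} must be finite and >= 0, got {v}")
    return (h + l) / 2.0


def delineate_slice_roi(slice_image: np.ndarray, interior_ref, threshold: float) -> np.ndarray:
    """Select one slice's ROI by iso-contour + interior fill.

    The ROI is the 8-connected component of ``{intensity >= threshold}``
    that contains ``interior_ref``, with holes (background pockets not
    reachable from the slice border) filled.

    ``interior_ref`` is a 2-D (row, col) index into ``slice_image`` and
    must itself sit at or above the threshold.
    """
    img = np.asarray(slice_image, dtype=float)
    if img.ndim != 2:
        raise ValidationError("slice_image must be 2-D")
    r, c = int(interior_ref[0]), int(interior_ref[1])
    if not (0 <= r < img.shape[0] and 0 <= c < img.shape[1]):
        raise ValidationError(f"interior_ref {interior_ref} out of bounds for {img.shape}")
    if img[r, c] < threshold:
        raise SeedRejectionError(
            f"interior seed at {(r, c)} has intensity {img[r, c]:g} "
            f"below threshold {threshold:g}"
        )
    above = img >= threshold
    labels = skmeasure.label(above, connectivity=2)
    comp = labels == labels[r, c]
    return ndimage.binary_fill_holes(comp)


def segment_gland(
    series: DWISeries,
    seeds: list[SeedPair],
    b_select: float = 500.0,
    side: str = "right",
    slice_axis: int = 2,
) -> ROIMask:
    """Segment one gland across its slices on the b = ``b_select`` image.

    Each :class:`SeedPair` yields its own per-slice threshold from the
    intensities at its two reference voxels; slices without a seed stay
    empty. Any per-slice failure aborts with the offending slice index.
    """
    if not seeds:
        raise ValidationError("seeds must be non-empty (one SeedPair per gland slice)")
    vol = series.volume_at(b_select)
    mask = np.zeros(vol.shape, dtype=bool)
    for seed in seeds:
        seed.validate_on_grid(vol.shape, slice_axis)
        img = np.take(vol, seed.slice_index, axis=slice_axis)
        ext2d, int2d = seed.inplane(slice_axis)
        thr = compute_threshold(img[ext2d], img[int2d])
        try:
            sl = delineate_slice_roi(img, int2d, thr)
        except SeedRejectionError as e:
            raise SeedRejectionError(f"slice {seed.slice_index}: {e}") from e
        idx = [slice(None)] * 3
        idx[slice_axis] = seed.slice_index
        mask[tuple(idx)] |= sl
    return ROIMask(
        mask=mask,
        side=side,
        source_b=float(b_select),
        voxel_size=series.voxel_size,
        origin=series.origin,
    )


def dice_coefficient(a: np.ndarray, b: np.ndarray) -> float:
    """Dice overlap 2|A∩B| / (|A| + |B|) between two boolean masks."""
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    if a.shape != b.shape:
        raise ValidationError("masks must share a shape")
    denom = a.sum() + b.sum()
    if denom == 0:
        return 1.0
    return 2.0 * np.logical_and(a, b).sum() / float(denom)
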