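"""Fusion of a DWI-derived ROI with the ADC map and per-gland measurement.

The ROI is drawn on the b = 500 s/mm^2 diffusion image where the gland is
conspicuous, then transferred onto the ADC map. Both volumes come from the
same acquisition, so the default transfer is the identity; grids that
differ in resolution are resampled nearest-neighbour in physical
coordinates (labels are never interpolated). The per-gland statistic is
the pooled arithmetic mean of ADC over all ROI voxels across slices.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .dwi import ADCMap
from .errors import MeasurementError, RegistrationError, ValidationError
from .segment import ROIMask

__all__ = ["GlandMeasurement", "coregister_mask", "measure_mean_adc"]


@dataclass(frozen=True)
class GlandMeasurement:
    """One (subject, side, reader, session) mean-ADC record.

    ``mean_adc`` is in mm^2/s (reported elsewhere as x10^-3 mm^2/s).
    This is the unit of every downstream statistic.
    """

    subject_id: str
    side: str
    reader_id: str
    session: int
    mean_adc: float
    voxel_count: int
    slice_count: int

    def __post_init__(self) -> None:
        if self.side not in ("left", "right"):
            raise ValidationError(f"side must be 'left' or 'right', got {self.side!r}")
        if self.voxel_count < 1:
            raise ValidationError("voxel_count must be >= 1")
        if self.slice_count < 1:
            raise ValidationError("slice_count must be >= 1")
        if not np.isfinite(self.mean_adc) or self.mean_adc < 0:
            raise ValidationError("mean_adc must be finite and >= 0")


def _extent(shape, voxel_size, origin):
    lo = np.asarray(origin, dtype=float)
    hi = lo + np.asarray(shape, dtype=float) * np.asarray(voxel_size, dtype=float)
    return lo, hi


def coregister_mask(mask: ROIMask, adc: ADCMap) -> ROIMask:
    """Transfer an ROI mask onto the ADC map's voxel grid.

    Identical grids (shape, voxel size, origin) pass through unchanged.
    Otherwise each ADC-grid voxel centre is mapped into the mask's grid
    and sampled nearest-neighbour. Disjoint physical fields of view raise
    :class:`RegistrationError`.
    """
    same = (
        mask.mask.shape == adc.spatial_shape
        and np.allclose(mask.voxel_size, adc.voxel_size)
        and np.allclose(mask.origin, adc.origin)
    )
    if same:
        return mask

    lo_m, hi_m = _extent(mask.mask.shape, mask.voxel_size, mask.origin)
    lo_a, hi_a = _extent(adc.spatial_shape, adc.voxel_size, adc.origin)
    if np.any(hi_m <= lo_a) or np.any(hi_a <= lo_m):
        raise RegistrationError(
            f"mask extent [{lo_m}, {hi_m}] mm and ADC extent [{lo_a}, {hi_a}] mm do not overlap"
        )

    # physical centres of every ADC voxel, mapped to mask indices
    idx = np.indices(adc.spatial_shape, dtype=float)
    out = np.zeros(adc.spatial_shape, dtype=bool)
    coords = []
    for a in range(3):
        centre = adc.origin[a] + (idx[a] + 0.5) * adc.voxel_size[a]
        j = np.floor((centre - mask.origin[a]) / mask.voxel_size[a]).astype(int)
        coords.append(j)
    inb = np.ones(adc.spatial_shape, dtype=bool)
    for a in range(3):
        inb &= (coords[a] >= 0) & (coords[a] < mask.mask.shape[a])
    out[inb] = mask.mask[coords[0][inb], coords[1][inb], coords[2][inb]]
    return ROIMask(
        mask=out,
        side=mask.side,
        source_b=mask.source_b,
        voxel_size=adc.voxel_size,
        origin=adc.origin,
    )


def measure_mean_adc(
    mask: ROIMask,
    adc: ADCMap,
    subject_id: str,
    reader_id: str = "reader1",
    session: int = 1,
    slice_axis: int = 2,
    method: str = "pooled",
) -> GlandMeasurement:
    """Mean ADC of one gland under its ROI mask.

    ``method="pooled"`` (default) averages every masked voxel across all
    slices with equal weight; ``method="slice_mean"`` averages the
    per-slice means instead (a sensitivity variant — the two coincide
    only when every slice contributes equally many voxels).

    Every masked voxel must carry a successful ADC fit.
    """
    reg = coregister_mask(mask, adc)
    m = reg.mask
    if not m.any():
        raise MeasurementError("empty ROI mask: nothing to measure")
    bad = m & ~adc.fit_mask
    if bad.any():
        where = np.argwhere(bad)[:10].tolist()
        raise MeasurementError(
            f"{int(bad.sum())} masked voxel(s) have no valid ADC fit, e.g. at {where}"
        )
    vals = adc.adc[m]
    sliced = np.moveaxis(m, slice_axis, 0)
    per_slice_n = sliced.reshape(sliced.shape[0], -1).sum(axis=1)
    slice_count = int((per_slice_n > 0).sum())
    if method == "pooled":
        mean = float(vals.mean())
    elif method == "slice_mean":
        adc_sl = np.moveaxis(adc.adc, slice_axis, 0)
        means = [
            float(adc_sl[k][sliced[k]].mean())
            for k in range(sliced.shape[0])
            if per_slice_n[k] > 0
        ]
        mean = float(np.mean(means))
    else:
        raise ValidationError(f"unknown method {method!r}; expected 'pooled' or 'slice_mean'")
    return GlandMeasurement(
        subject_id=subject_id,
        side=mask.side,
        reader_id=reader_id,
        session=session,
        mean_adc=mean,
        voxel_count=int(m.sum()),
        slice_count=slice_count,
    )
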