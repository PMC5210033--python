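"""Synthetic DWI phantoms, cohort rosters, and reader-measurement tables.

The phantom emulates a fat-saturated abdominal diffusion acquisition at
b = 0, 20, 500 and 1000 s/mm^2 on ~5 mm slices: a dark suppressed-fat
background, two kidney-shaped ellipsoids, and two small bright
inverted-Y adrenal glands sitting anterior-superior to them, one per
side, each spanning a few slices. Every compartment is monoexponential,

    S(b) = S0 * exp(-b * ADC),

and magnitude (Rician) noise is applied per voxel per b-value as
``|S + N(0, sigma) + i N(0, sigma)|`` — the standard magnitude-MRI noise
model. Ground truth (per-side masks, the true ADC volume, and per-slice
seed pairs imitating a reader's reference-voxel picks) is returned
alongside the series so the whole measurement pipeline can be validated
against known values.

The roster generator reproduces the measurement study's subject-flow
structure: a large screening population, a radiological filter, disjoint
clinical exclusions, missing-data removal, and PreP/PostP survivors with
ages and Tanner stages drawn from configured ranges. The reader table
generator produces (subject, reader, session) measurements as
``truth + reader bias + Gaussian noise`` for agreement analyses.

All randomness flows from the single integer seed in each spec through
one ``numpy.random.Generator``; there is no global RNG state.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.draw import line
from skimage.morphology import disk

from .cohort import CLINICAL_FLAGS, SubjectRecord
from .dwi import ADCMap, DWISeries
from .errors import ValidationError
from .measure import GlandMeasurement
from .segment import ROIMask, SeedPair

__all__ = [
    "Compartment",
    "PhantomSpec",
    "PhantomTruth",
    "RosterSpec",
    "generate_phantom",
    "generate_cohort_roster",
    "generate_reader_measurements",
]


@dataclass(frozen=True)
class Compartment:
    """A background structure: name, ellipsoid geometry (voxel units),
    true ADC (mm^2/s) and proton-density signal S0 (arbitrary units).

    ``shape="full"`` fills the whole background instead of an ellipsoid.
    """

    name: str
    adc: float
    s0: float
    shape: str = "ellipsoid"
    center: tuple[float, float, float] = (0.0, 0.0, 0.0)
    radii: tuple[float, float, float] = (1.0, 1.0, 1.0)


def _default_background() -> tuple[Compartment, ...]:
    # suppressed fat everywhere; two kidney ellipsoids posterior-inferior
    # to the glands, separated from them by >= 2 voxels of fat
    return (
        Compartment("fat_suppressed", adc=0.30e-3, s0=50.0, shape="full"),
        Compartment("kidney_right", adc=1.90e-3, s0=600.0,
                    center=(18.0, 45.0, 8.0), radii=(6.0, 7.0, 4.0)),
        Compartment("kidney_left", adc=1.90e-3, s0=600.0,
                    center=(46.0, 45.0, 8.0), radii=(6.0, 7.0, 4.0)),
    )


@dataclass(frozen=True)
class PhantomSpec:
    """Full description of one synthetic acquisition.

    Defaults give a 64 x 64 x 16 grid at 2.0 x 2.4 x 5.0 mm (axial
    slices along the last axis), the four-b abdominal protocol, and
    per-side gland ADCs at the scale reported for normal adrenal tissue.
    """

    grid_dims: tuple[int, int, int] = (64, 64, 16)
    voxel_size: tuple[float, float, float] = (2.0, 2.4, 5.0)
    slice_axis: int = 2
    gland_true_adc: dict = field(
        default_factory=lambda: {"right": 1.44e-3, "left": 1.58e-3}
    )
    background_compartments: tuple[Compartment, ...] = field(
        default_factory=_default_background
    )
    gland_s0: float = 1000.0
    b_values: tuple[float, ...] = (0.0, 20.0, 500.0, 1000.0)
    rician_sigma: float = 0.0
    rng_seed: int = 0
    # gland geometry knobs (voxels): in-plane Y-limb length, half-width,
    # slices spanned, and per-side in-plane anchor points
    gland_limb_len: int = 5
    gland_half_width: int = 1
    gland_n_slices: int = 3
    gland_centers: dict = field(
        default_factory=lambda: {"right": (20, 24), "left": (44, 24)}
    )

    def __post_init__(self) -> None:
        if len(self.grid_dims) != 3 or any(int(d) < 8 for d in self.grid_dims):
            raise ValidationError("grid_dims: all three dimensions must be >= 8 voxels")
        if len(self.voxel_size) != 3 or any(v <= 0 for v in self.voxel_size):
            raise ValidationError("voxel_size: all three extents must be positive (mm)")
        if self.slice_axis not in (0, 1, 2):
            raise ValidationError("slice_axis must be 0, 1 or 2")
        b = np.asarray(self.b_values, dtype=float)
        if b.size < 2 or not np.all(np.diff(b) > 0) or b[0] != 0:
            raise ValidationError("b_values must be strictly increasing and start at 0")
        for side, adc in self.gland_true_adc.items():
            if adc <= 0:
                raise ValidationError(f"gland_true_adc[{side!r}] must be > 0, got {adc}")
        if self.rician_sigma < 0:
            raise ValidationError("rician_sigma must be >= 0")
        if self.gland_s0 <= 0:
            raise ValidationError("gland_s0 must be > 0")
        if self.gland_n_slices < 2:
            raise ValidationError("gland_n_slices must be >= 2 (gland spans >= 2 slices)")


@dataclass
class PhantomTruth:
    """Ground truth accompanying a generated phantom."""

    true_masks: dict  # side -> ROIMask
    true_adc_map: ADCMap
    seeds: dict  # side -> list[SeedPair], one per gland-bearing slice


def _inverted_y(shape2d: tuple[int, int], center: tuple[int, int],
                limb_len: int, half_width: int) -> np.ndarray:
    """Rasterize an inverted-Y (three limbs meeting at a point), dilated
    to the requested half-width."""
    img = np.zeros(shape2d, dtype=bool)
    cx, cy = center
    for dx, dy in ((0, -1), (-1, 1), (1, 1)):  # stem up, limbs down-left/right
        x1 = int(np.clip(cx + dx * limb_len, 0, shape2d[0] - 1))
        y1 = int(np.clip(cy + dy * limb_len, 0, shape2d[1] - 1))
        rr, cc = line(cx, cy, x1, y1)
        img[rr, cc] = True
    if half_width > 0:
        img = ndimage.binary_dilation(img, structure=disk(half_width))
    return img


def _gland_mask(spec: PhantomSpec, side: str) -> np.ndarray:
    dims = spec.grid_dims
    plane = [dims[a] for a in range(3) if a != spec.slice_axis]
    nz = dims[spec.slice_axis]
    z0 = (nz - spec.gland_n_slices) // 2
    mask = np.zeros(dims, dtype=bool)
    for k in range(spec.gland_n_slices):
        # taper the outermost slices for a crescent-like tip
        shrink = 1 if k in (0, spec.gland_n_slices - 1) and spec.gland_limb_len > 2 else 0
        sl = _inverted_y(tuple(plane), spec.gland_centers[side],
                         spec.gland_limb_len - shrink, spec.gland_half_width)
        idx = [slice(None)] * 3
        idx[spec.slice_axis] = z0 + k
        mask[tuple(idx)] = sl
    return mask


def _ellipsoid_mask(dims, center, radii) -> np.ndarray:
    grids = np.indices(dims, dtype=float)
    q = sum(((grids[a] - center[a]) / radii[a]) ** 2 for a in range(3))
    return q <= 1.0


def generate_phantom(spec: PhantomSpec) -> tuple[DWISeries, PhantomTruth]:
    """Simulate one multi-b acquisition with ground truth.

    Compartments are painted in order (fat, then ellipsoids, then the two
    glands, which take precedence); each voxel's noiseless signal follows
    its compartment's monoexponential decay; Rician noise of scale
    ``rician_sigma`` is applied independently per voxel per b-value.
    The same spec (same seed) reproduces bit-identical output.
    """
    dims = spec.grid_dims
    adc_vol = np.zeros(dims, dtype=float)
    s0_vol = np.zeros(dims, dtype=float)
    painted = np.zeros(dims, dtype=bool)
    for comp in spec.background_compartments:
        if comp.shape == "full":
            region = np.ones(dims, dtype=bool)
        elif comp.shape == "ellipsoid":
            region = _ellipsoid_mask(dims, comp.center, comp.radii)
        else:
            raise ValidationError(
                f"background_compartments: unknown shape {comp.shape!r} in {comp.name!r}"
            )
        adc_vol[region] = comp.adc
        s0_vol[region] = comp.s0
        if comp.shape != "full":
            painted |= region

    true_masks: dict[str, ROIMask] = {}
    for side in spec.gland_true_adc:
        gm = _gland_mask(spec, side)
        if (gm & painted).any():
            raise ValidationError(
                f"gland_centers: {side} gland overlaps a background compartment"
            )
        adc_vol[gm] = spec.gland_true_adc[side]
        s0_vol[gm] = spec.gland_s0
        true_masks[side] = ROIMask(
            mask=gm, side=side, voxel_size=spec.voxel_size
        )

    b = np.asarray(spec.b_values, dtype=float)
    clean = s0_vol[..., None] * np.exp(-adc_vol[..., None] * b)
    rng = np.random.default_rng(spec.rng_seed)
    if spec.rician_sigma > 0:
        re = clean + rng.normal(0.0, spec.rician_sigma, clean.shape)
        im = rng.normal(0.0, spec.rician_sigma, clean.shape)
        signal = np.hypot(re, im)
    else:
        signal = clean

    series = DWISeries(
        signal=signal, b_values=b, voxel_size=spec.voxel_size, subject_id="phantom"
    )
    truth = PhantomTruth(
        true_masks=true_masks,
        true_adc_map=ADCMap(adc=adc_vol, voxel_size=spec.voxel_size),
        seeds=_pick_seeds(series, true_masks, spec),
    )
    return series, truth


def _pick_seeds(series: DWISeries, true_masks: dict, spec: PhantomSpec) -> dict:
    """Imitate the reader's reference picks on the (possibly noisy) image
    nearest b = 500: dimmest voxel inside the gland, brightest voxel in a
    thin shell just outside it."""
    b = series.b_values
    b_ref = b[np.argmin(np.abs(b - 500.0))]
    vol = series.volume_at(b_ref)
    axis = spec.slice_axis
    all_gland = np.zeros(spec.grid_dims, dtype=bool)
    for rm in true_masks.values():
        all_gland |= rm.mask
    seeds: dict[str, list[SeedPair]] = {}
    for side, rm in true_masks.items():
        shell = ndimage.binary_dilation(rm.mask, iterations=2) & ~all_gland
        side_seeds = []
        for z in range(spec.grid_dims[axis]):
            idx = [slice(None)] * 3
            idx[axis] = z
            msl = rm.mask[tuple(idx)]
            if not msl.any():
                continue
            isl = vol[tuple(idx)]
            ssl = shell[tuple(idx)]
            interior2d = np.unravel_index(
                np.argmin(np.where(msl, isl, np.inf)), msl.shape
            )
            exterior2d = np.unravel_index(
                np.argmax(np.where(ssl, isl, -np.inf)), ssl.shape
            )
            side_seeds.append(
                SeedPair(
                    slice_index=z,
                    exterior_ref=_to3d(exterior2d, z, axis),
                    interior_ref=_to3d(interior2d, z, axis),
                )
            )
        seeds[side] = side_seeds
    return seeds


def _to3d(plane_idx, z, axis) -> tuple[int, int, int]:
    coord = list(plane_idx)
    coord.insert(axis, z)
    return tuple(int(c) for c in coord)


# ---------------------------------------------------------------------------
# cohort roster


@dataclass(frozen=True)
class RosterSpec:
    """Structure of a screening roster: total size, per-stage exclusion
    counts, and age/sex/Tanner sampling ranges for the survivors.

    Defaults mirror a realistic subject flow for a retrospective
    normal-adrenal study: 1330 screened, 1273 with abnormal radiology,
    24 disjoint clinical exclusions, 1 missing dataset, and 32 survivors
    split 12 prepubertal / 20 postpubertal.
    """

    n_total: int = 1330
    n_abnormal_imaging: int = 1273
    clinical_exclusion_counts: dict = field(
        default_factory=lambda: {
            "hormonal_disturbance": 5,
            "neoplasia_history": 5,
            "ibd_suspicion": 3,
            "storage_disease_suspicion": 4,
            "high_bmi_for_age": 7,
        }
    )
    n_missing_radiologic: int = 1
    n_prepubertal: int = 12
    prep_age_range: tuple[float, float] = (0.17, 12.5)
    postp_age_range: tuple[float, float] = (11.9, 61.0)
    female_fraction: float = 23 / 32
    rng_seed: int = 0

    def __post_init__(self) -> None:
        unknown = set(self.clinical_exclusion_counts) - set(CLINICAL_FLAGS)
        if unknown:
            raise ValidationError(f"clinical_exclusion_counts: unknown reasons {sorted(unknown)}")
        if any(v < 0 for v in self.clinical_exclusion_counts.values()):
            raise ValidationError("clinical_exclusion_counts must be non-negative")
        excl = (
            self.n_abnormal_imaging
            + sum(self.clinical_exclusion_counts.values())
            + self.n_missing_radiologic
        )
        if excl > self.n_total:
            raise ValidationError(
                f"exclusion counts ({excl}) exceed n_total ({self.n_total})"
            )
        if self.n_prepubertal > self.n_total - excl:
            raise ValidationError(
                f"n_prepubertal ({self.n_prepubertal}) exceeds survivor count "
                f"({self.n_total - excl})"
            )
        if not 0 <= self.female_fraction <= 1:
            raise ValidationError("female_fraction must lie in [0, 1]")

    @property
    def n_survivors(self) -> int:
        return self.n_total - (
            self.n_abnormal_imaging
            + sum(self.clinical_exclusion_counts.values())
            + self.n_missing_radiologic
        )


def generate_cohort_roster(rspec: RosterSpec) -> list[SubjectRecord]:
    """Generate a roster whose flag totals match the spec exactly.

    Flags are assigned disjointly in cascade order (abnormal imaging
    first, then each clinical reason among the remainder, then missing
    data), so the downstream cascade recovers the configured counts
    exactly. Survivors receive ages, sexes and Tanner stages from the
    configured ranges; the record order is shuffled.
    """
    rng = np.random.default_rng(rspec.rng_seed)
    records: list[SubjectRecord] = []
    serial = 0

    def _new(**flags) -> SubjectRecord:
        nonlocal serial
        serial += 1
        age = float(np.round(rng.uniform(0.2, 80.0), 1))
        stage = None if age >= 18 else int(rng.integers(1, 6))
        return SubjectRecord(
            subject_id=f"S{serial:04d}",
            age=age,
            sex="F" if rng.random() < rspec.female_fraction else "M",
            tanner_stage=stage,
            **flags,
        )

    for _ in range(rspec.n_abnormal_imaging):
        records.append(_new(abnormal_imaging=True))
    for reason, count in rspec.clinical_exclusion_counts.items():
        for _ in range(count):
            records.append(_new(**{reason: True}))
    for _ in range(rspec.n_missing_radiologic):
        records.append(_new(missing_radiologic_data=True))

    for i in range(rspec.n_survivors):
        serial += 1
        prep = i < rspec.n_prepubertal
        lo, hi = rspec.prep_age_range if prep else rspec.postp_age_range
        age = float(np.round(rng.uniform(lo, hi), 1))
        if prep:
            stage = 1
        elif age >= 18:
            stage = None if rng.random() < 0.5 else int(rng.integers(2, 6))
        else:
            stage = int(rng.integers(2, 6))
        records.append(
            SubjectRecord(
                subject_id=f"S{serial:04d}",
                age=age,
                sex="F" if rng.random() < rspec.female_fraction else "M",
                tanner_stage=stage,
            )
        )

    order = rng.permutation(len(records))
    return [records[i] for i in order]


# ---------------------------------------------------------------------------
# reader-measurement tables


def generate_reader_measurements(
    true_values,
    reader_bias,
    noise_sd: float,
    n_readers: int = 2,
    n_sessions: int = 1,
    seed: int = 0,
    side: str = "right",
) -> list[GlandMeasurement]:
    """Simulate per-reader, per-session gland measurements.

    ``measurement(subject, reader, session) = truth + bias[reader] +
    N(0, noise_sd)``, drawn independently per cell. ``true_values`` maps
    subject id -> true mean ADC (or is a sequence, in which case ids are
    generated). ``reader_bias`` gives one additive bias per reader
    (shorter sequences are zero-padded). Values are clamped at 0 to keep
    measurements physical; at realistic ADC scales the clamp never binds.
    """
    if noise_sd < 0:
        raise ValidationError("noise_sd must be >= 0")
    if n_readers < 1 or n_sessions < 1:
        raise ValidationError("n_readers and n_sessions must be >= 1")
    if hasattr(true_values, "items"):
        items = list(true_values.items())
    else:
        items = [(f"S{i + 1:04d}", v) for i, v in enumerate(true_values)]
    if not items:
        raise ValidationError("true_values must be non-empty")
    bias = list(reader_bias) + [0.0] * max(0, n_readers - len(list(reader_bias)))
    rng = np.random.default_rng(seed)
    out: list[GlandMeasurement] = []
    for sid, truth in items:
        for r in range(n_readers):
            for s in range(1, n_sessions + 1):
                val = truth + bias[r] + (rng.normal(0.0, noise_sd) if noise_sd > 0 else 0.0)
                out.append(
                    GlandMeasurement(
                        subject_id=str(sid),
                        side=side,
                        reader_id=f"reader{r + 1}",
                        session=s,
                        mean_adc=max(float(val), 0.0),
                        voxel_count=1,
                        slice_count=1,
                    )
                )
    return out
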