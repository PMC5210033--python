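"""File round-trips: NIfTI volumes, b-value sidecars, CSV tables.

DWI series and ADC maps travel as NIfTI-1 (the affine carries the voxel
size; orientation handling beyond a diagonal affine is out of scope for
synthetic data), with the b-values in a JSON sidecar under the ``bvals``
key (s/mm^2). Rosters and measurement tables are plain CSV via pandas;
measured mean ADC is stored in the conventional reporting unit of
x10^-3 mm^2/s.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .cohort import SubjectRecord
from .dwi import ADCMap, DWISeries
from .errors import ValidationError
from .measure import GlandMeasurement
from .segment import ROIMask

__all__ = [
    "save_dwi", "load_dwi", "save_adc_map", "load_adc_map",
    "save_mask", "load_mask",
    "roster_to_frame", "frame_to_roster", "save_roster", "load_roster",
    "measurements_to_frame", "frame_to_measurements",
    "save_measurements", "load_measurements",
]

MEAS_COLUMNS = [
    "subject_id", "side", "reader_id", "session",
    "mean_adc_1e3_mm2_s", "voxel_count", "slice_count",
]


def _affine(voxel_size, origin) -> np.ndarray:
    aff = np.diag(list(voxel_size) + [1.0])
    aff[:3, 3] = origin
    return aff


def _grid_from(img) -> tuple[tuple, tuple]:
    zooms = tuple(float(z) for z in img.header.get_zooms()[:3])
    origin = tuple(float(v) for v in img.affine[:3, 3])
    return zooms, origin


def _sidecar_path(nifti_path: Path) -> Path:
    name = nifti_path.name
    for suf in (".nii.gz", ".nii"):
        if name.endswith(suf):
            return nifti_path.with_name(name[: -len(suf)] + ".bvals.json")
    return nifti_path.with_suffix(".bvals.json")


def save_dwi(series: DWISeries, path) -> Path:
    """Write a 4-D series as NIfTI plus a ``*.bvals.json`` sidecar."""
    path = Path(path)
    nib.save(
        nib.Nifti1Image(series.signal.astype(np.float32),
                        _affine(series.voxel_size, series.origin)),
        path,
    )
    sidecar = _sidecar_path(path)
    sidecar.write_text(json.dumps({
        "bvals": list(map(float, series.b_values)),
        "subject_id": series.subject_id,
    }))
    return sidecar


def load_dwi(path, sidecar=None) -> DWISeries:
    path = Path(path)
    img = nib.load(path)
    sidecar = Path(sidecar) if sidecar else _sidecar_path(path)
    if not sidecar.exists():
        raise ValidationError(f"b-value sidecar not found: {sidecar}")
    meta = json.loads(sidecar.read_text())
    zooms, origin = _grid_from(img)
    return DWISeries(
        signal=np.asarray(img.dataobj, dtype=float),
        b_values=meta["bvals"],
        voxel_size=zooms,
        subject_id=meta.get("subject_id", "unknown"),
        origin=origin,
    )


def save_adc_map(adc: ADCMap, path) -> Path:
    """Write the ADC volume plus a ``*_fitmask`` companion NIfTI."""
    path = Path(path)
    aff = _affine(adc.voxel_size, adc.origin)
    nib.save(nib.Nifti1Image(adc.adc.astype(np.float64), aff), path)
    mask_path = _companion(path, "_fitmask")
    nib.save(nib.Nifti1Image(adc.fit_mask.astype(np.uint8), aff), mask_path)
    return mask_path


def _companion(path: Path, tag: str) -> Path:
    name = path.name
    for suf in (".nii.gz", ".nii"):
        if name.endswith(suf):
            return path.with_name(name[: -len(suf)] + tag + suf)
    return path.with_name(name + tag)


def load_adc_map(path) -> ADCMap:
    path = Path(path)
    img = nib.load(path)
    zooms, origin = _grid_from(img)
    mask_path = _companion(path, "_fitmask")
    fit_mask = (
        np.asarray(nib.load(mask_path).dataobj) > 0 if mask_path.exists() else None
    )
    return ADCMap(
        adc=np.asarray(img.dataobj, dtype=float),
        voxel_size=zooms, fit_mask=fit_mask, origin=origin,
    )


def save_mask(mask: ROIMask, path) -> None:
    nib.save(
        nib.Nifti1Image(mask.mask.astype(np.uint8),
                        _affine(mask.voxel_size, mask.origin)),
        Path(path),
    )


def load_mask(path, side: str, source_b=None) -> ROIMask:
    img = nib.load(Path(path))
    zooms, origin = _grid_from(img)
    return ROIMask(
        mask=np.asarray(img.dataobj) > 0,
        side=side, source_b=source_b, voxel_size=zooms, origin=origin,
    )


# ---------------------------------------------------------------------------
# tabular I/O

_BOOL_FLAGS = [
    "abnormal_imaging", "hormonal_disturbance", "neoplasia_history",
    "ibd_suspicion", "storage_disease_suspicion", "high_bmi_for_age",
    "missing_radiologic_data",
]


def roster_to_frame(roster: list[SubjectRecord]) -> pd.DataFrame:
    rows = []
    for r in roster:
        row = {
            "subject_id": r.subject_id, "age": r.age, "sex": r.sex,
            "tanner_stage": r.tanner_stage if r.tanner_stage is not None else "",
        }
        row.update({f: int(getattr(r, f)) for f in _BOOL_FLAGS})
        rows.append(row)
    return pd.DataFrame(rows)


def frame_to_roster(df: pd.DataFrame) -> list[SubjectRecord]:
    out = []
    for _, row in df.iterrows():
        stage = row["tanner_stage"]
        stage = None if (pd.isna(stage) or stage == "") else int(stage)
        out.append(SubjectRecord(
            subject_id=str(row["subject_id"]), age=float(row["age"]),
            sex=str(row["sex"]), tanner_stage=stage,
            **{f: bool(int(row[f])) for f in _BOOL_FLAGS},
        ))
    return out


def save_roster(roster: list[SubjectRecord], path) -> None:
    roster_to_frame(roster).to_csv(Path(path), index=False)


def load_roster(path) -> list[SubjectRecord]:
    return frame_to_roster(pd.read_csv(Path(path), keep_default_na=False))


def measurements_to_frame(measurements: list[GlandMeasurement]) -> pd.DataFrame:
    """Measurement table with mean ADC in x10^-3 mm^2/s, 6 significant digits."""
    return pd.DataFrame([
        {
            "subject_id": m.subject_id, "side": m.side,
            "reader_id": m.reader_id, "session": m.session,
            "mean_adc_1e3_mm2_s": float(f"{m.mean_adc * 1e3:.6g}"),
            "voxel_count": m.voxel_count, "slice_count": m.slice_count,
        }
        for m in measurements
    ], columns=MEAS_COLUMNS)


def frame_to_measurements(df: pd.DataFrame) -> list[GlandMeasurement]:
    return [
        GlandMeasurement(
            subject_id=str(r["subject_id"]), side=str(r["side"]),
            reader_id=str(r["reader_id"]), session=int(r["session"]),
            mean_adc=float(r["mean_adc_1e3_mm2_s"]) * 1e-3,
            voxel_count=int(r["voxel_count"]), slice_count=int(r["slice_count"]),
        )
        for _, r in df.iterrows()
    ]


def save_measurements(measurements: list[GlandMeasurement], path) -> None:
    measurements_to_frame(measurements).to_csv(Path(path), index=False)


def load_measurements(path) -> list[GlandMeasurement]:
    return frame_to_measurements(pd.read_csv(Path(path)))
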