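"""Subject-level exclusion cascade and pubertal group assignment.

A retrospective roster of abdominal-MRI subjects is reduced to a healthy
study sample in three ordered stages: abnormal radiological findings
first, then any clinical exclusion (hormonal disturbance, neoplasia
history, suspected inflammatory bowel disease, suspected storage
disease, above-normal BMI for age), then missing radiologic data. A
subject carrying several flags is counted once, at the first stage that
removes it. Survivors are grouped by Tanner pubertal stage: stage 1 is
prepubertal (PreP); stages 2-5, and adults without staging, are
postpubertal (PostP).
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .errors import ClassificationError, ValidationError

__all__ = [
    "CLINICAL_FLAGS",
    "SubjectRecord",
    "CascadeAudit",
    "apply_exclusion_cascade",
    "assign_group",
]

CLINICAL_FLAGS = (
    "hormonal_disturbance",
    "neoplasia_history",
    "ibd_suspicion",
    "storage_disease_suspicion",
    "high_bmi_for_age",
)


@dataclass
class SubjectRecord:
    subject_id: str
    age: float
    sex: str
    tanner_stage: int | None = None
    abnormal_imaging: bool = False
    hormonal_disturbance: bool = False
    neoplasia_history: bool = False
    ibd_suspicion: bool = False
    storage_disease_suspicion: bool = False
    high_bmi_for_age: bool = False
    missing_radiologic_data: bool = False

    def __post_init__(self) -> None:
        if self.age < 0:
            raise ValidationError(f"age must be >= 0, got {self.age}")
        if self.sex not in ("M", "F"):
            raise ValidationError(f"sex must be 'M' or 'F', got {self.sex!r}")
        if self.tanner_stage is not None and self.tanner_stage not in (1, 2, 3, 4, 5):
            raise ValidationError(f"tanner_stage must be 1-5 or None, got {self.tanner_stage}")

    @property
    def has_clinical_flag(self) -> bool:
        return any(getattr(self, f) for f in CLINICAL_FLAGS)

    @property
    def has_any_flag(self) -> bool:
        return self.abnormal_imaging or self.has_clinical_flag or self.missing_radiologic_data


@dataclass
class CascadeAudit:
    """Per-stage removal counts, in cascade order, plus the eligible count."""

    n_input: int
    n_abnormal_imaging: int
    n_clinical: int
    n_missing_radiologic: int
    n_eligible: int
    clinical_breakdown: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        total = (
            self.n_abnormal_imaging + self.n_clinical + self.n_missing_radiologic + self.n_eligible
        )
        if total != self.n_input:
            raise ValidationError(
                f"audit stages ({total}) do not sum to roster size ({self.n_input})"
            )


def apply_exclusion_cascade(roster: list[SubjectRecord]) -> tuple[list[SubjectRecord], CascadeAudit]:
    """Filter a roster through the ordered exclusion cascade.

    Returns the eligible subjects (flag-free) and an audit whose stage
    counts sum exactly to the input size. Within the clinical stage the
    breakdown attributes each subject to its first applicable reason.
    """
    if not roster:
        raise ValidationError("roster must be non-empty")
    eligible: list[SubjectRecord] = []
    n_img = n_clin = n_miss = 0
    breakdown = {f: 0 for f in CLINICAL_FLAGS}
    for rec in roster:
        if rec.abnormal_imaging:
            n_img += 1
        elif rec.has_clinical_flag:
            n_clin += 1
            for f in CLINICAL_FLAGS:
                if getattr(rec, f):
                    breakdown[f] += 1
                    break
        elif rec.missing_radiologic_data:
            n_miss += 1
        else:
            eligible.append(rec)
    audit = CascadeAudit(
        n_input=len(roster),
        n_abnormal_imaging=n_img,
        n_clinical=n_clin,
        n_missing_radiologic=n_miss,
        n_eligible=len(eligible),
        clinical_breakdown=breakdown,
    )
    return eligible, audit


def assign_group(record: SubjectRecord, adult_age: float = 18.0) -> str:
    """Assign an eligible subject to ``"PreP"`` or ``"PostP"``.

    Tanner stage 1 is prepubertal; stages 2-5 postpubertal. Adults
    (age >= ``adult_age``) without a recorded stage default to PostP;
    a minor without a stage cannot be classified.
    """
    if record.tanner_stage is None:
        if record.age < adult_age:
            raise ClassificationError(
                f"subject {record.subject_id}: Tanner stage required for age {record.age} < {adult_age}"
            )
        return "PostP"
    return "PreP" if record.tanner_stage == 1 else "PostP"
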