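"""Student- and school-level record types and the fixed covariate codebook.

The student codebook mirrors the survey instrument: binary past-30-day use
outcome, demographics (sex, collapsed race/ethnicity, grade), family standard
of living, whether the student visited stores near school in the past 30
days, and recall of marketing / warning signage in those stores.  Schools
carry planar coordinates, the tobacco-retail-outlet (TRO) presence indicator
(at least one permitted outlet within the school's buffer), and three
zip-code socioeconomic covariates.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

CODEBOOK: dict[str, tuple[str, ...]] = {
    "sex": ("girls", "boys"),
    "race3": ("black", "hispanic", "white_other"),
    "grade": ("6th", "8th", "10th"),
    "family_sol": ("living_comfortably", "very_well_off", "just_getting_by_poor"),
    "visited_stores": ("no", "yes"),
    "recall_marketing": ("no", "yes"),
    "recall_warning": ("no", "yes"),
}
#: first entry of each codebook tuple is the dummy-coding reference level

STUDENT_COLUMNS = (
    "student_id",
    "school_id",
    "outcome",
    "sex",
    "race3",
    "grade",
    "family_sol",
    "visited_stores",
    "recall_marketing",
    "recall_warning",
    "samp_weight",
)

SCHOOL_COLUMNS = (
    "school_id",
    "x_km",
    "y_km",
    "tro",
    "zip_hs_grad_pct",
    "zip_med_income",
    "zip_poverty_pct",
    "n_students",
)

ZIP_COVARIATES = ("zip_hs_grad_pct", "zip_med_income", "zip_poverty_pct")


@dataclass
class StudentRecord:
    """One surveyed student (a row of students.csv).

    ``outcome`` is the binary current-use indicator for whichever product
    the file encodes; ``None`` marks item nonresponse (handled by the
    exclusion filter, never by the model).
    """

    student_id: str
    school_id: str
    outcome: Optional[int]
    sex: str
    race3: str
    grade: str
    family_sol: Optional[str]
    visited_stores: str
    recall_marketing: str
    recall_warning: str
    samp_weight: float
    county: Optional[str] = None

    def validate(self) -> None:
        if self.outcome is not None and self.outcome not in (0, 1):
            raise ValueError(f"outcome must be 0/1/missing, got {self.outcome!r}")
        if not self.samp_weight > 0:
            raise ValueError(f"samp_weight must be positive, got {self.samp_weight!r}")
        for field_name in CODEBOOK:
            val = getattr(self, field_name)
            if val is None and field_name == "family_sol":
                continue
            if val not in CODEBOOK[field_name]:
                raise ValueError(
                    f"unknown category {val!r} for {field_name}; "
                    f"expected one of {CODEBOOK[field_name]}"
                )


@dataclass
class SchoolRecord:
    """One school: location, TRO presence, zip-code covariates, enrolment."""

    school_id: str
    x_km: float
    y_km: float
    tro: int
    zip_hs_grad_pct: float
    zip_med_income: float
    zip_poverty_pct: float
    n_students: int

    def validate(self) -> None:
        if self.tro not in (0, 1):
            raise ValueError(f"tro must be 0/1, got {self.tro!r}")
        if self.n_students < 1:
            raise ValueError(f"n_students must be >= 1, got {self.n_students!r}")
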