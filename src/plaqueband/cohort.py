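"""Human biopsy-cohort demographics: BMI, HOMA-IR, metabolic grouping.

Reproduces the cohort-table arithmetic for the brain-biopsy subjects:
body-mass index from weight and height, insulin-resistance index from
fasting glucose and insulin, assignment to the three metabolic groups
(normal weight, obese, obese with T2D) and per-group summary rows.

A 12-subject demographics table ships as a packaged CSV fixture
(``data/inph_cohort.csv``).  Note: the published average row of the obese
non-T2D group is internally inconsistent with its three members (printed
mean BMI 32.6 vs recomputed 33.4, printed mean height 166 vs 164); the
loader flags that group so exact-reproduction checks can exclude it.  The
table is shipped as printed; it is not "corrected".
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

from .stats import round_half_up

GROUPS = ("BMI<25", "BMI>30", "BMI>30+T2D")

#: groups whose published average row does not recompute from its members
INCONSISTENT_SUMMARY_GROUPS = ("BMI>30",)


@dataclass
class Subject:
    id: str
    gender: str
    age: float
    weight_kg: float
    height_cm: float
    homa_ir: float | None = None
    t2d: bool = False
    hypertension: bool = False
    amyloid_positive: bool = True
    apoe: str = ""

    def __post_init__(self):
        if self.weight_kg <= 0 or self.height_cm <= 0 or self.age <= 0:
            raise ValueError("age, weight and height must be positive")

    @property
    def bmi_exact(self) -> float:
        """Unrounded BMI in kg/m^2."""
        return self.weight_kg / (self.height_cm / 100.0) ** 2

    @property
    def bmi(self) -> float:
        """BMI rounded half-up to 1 decimal (the printed precision)."""
        return bmi(self.weight_kg, self.height_cm)


@dataclass
class GroupSummary:
    group: str
    n: int
    mean_age: float
    mean_weight_kg: float
    mean_height_cm: float
    mean_bmi: float
    mean_homa_ir: float


def bmi(weight_kg: float, height_cm: float) -> float:
    """Body-mass index ``weight (kg) / [height (m)]^2``, half-up to 1 decimal.

    Computed in decimal arithmetic so printed-precision values (e.g.
    80 kg / 160 cm = 31.25 -> 31.3) round exactly, free of binary
    floating-point artifacts.
    """
    if weight_kg <= 0 or height_cm <= 0:
        raise ValueError("weight and height must be positive")
    from decimal import ROUND_HALF_UP, Decimal

    value = Decimal(repr(float(weight_kg))) * 10000 / Decimal(repr(float(height_cm))) ** 2
    return float(value.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


def homa_ir(glucose: float, insulin: float, variant: str) -> float:
    """HOMA-IR from fasting glucose and insulin.

    ``variant`` must be given explicitly because the units differ:

    * ``"si"``            — glucose in mmol/L: ``glucose * insulin / 22.5``
    * ``"conventional"``  — glucose in mg/dL:  ``glucose * insulin / 405``

    with insulin in uU/mL in both.
    """
    if glucose <= 0 or insulin <= 0:
        raise ValueError("glucose and insulin must be positive")
    if variant == "si":
        return glucose * insulin / 22.5
    if variant == "conventional":
        return glucose * insulin / 405.0
    raise ValueError("HOMA-IR variant must be 'si' or 'conventional' (no default)")


def assign_group(subject: Subject) -> str:
    """Metabolic group of a subject, or ``"unclassified"``.

    BMI < 25 without T2D -> normal weight; BMI > 30 without T2D -> obese;
    BMI > 30 with T2D -> obese + T2D.  The gap (25 <= BMI <= 30) and
    lean T2D cases fall outside the design and are left unclassified.
    """
    b = subject.bmi
    if b < 25 and not subject.t2d:
        return "BMI<25"
    if b > 30 and not subject.t2d:
        return "BMI>30"
    if b > 30 and subject.t2d:
        return "BMI>30+T2D"
    return "unclassified"


def group_summary(subjects: list[Subject], group: str) -> GroupSummary:
    """Mean demographic row for one metabolic group.

    Means are taken over unrounded per-subject BMI (then rounded to the
    printed 1 decimal); HOMA-IR is averaged over the recorded (printed)
    values, also to 1 decimal.
    """
    members = [s for s in subjects if assign_group(s) == group]
    if not members:
        raise ValueError(f"group {group!r} has no members")
    homa = [s.homa_ir for s in members if s.homa_ir is not None]
    return GroupSummary(
        group=group,
        n=len(members),
        mean_age=round_half_up(float(np.mean([s.age for s in members])), 1),
        mean_weight_kg=round_half_up(float(np.mean([s.weight_kg for s in members])), 1),
        mean_height_cm=round_half_up(float(np.mean([s.height_cm for s in members])), 1),
        mean_bmi=round_half_up(float(np.mean([s.bmi_exact for s in members])), 1),
        mean_homa_ir=round_half_up(float(np.mean(homa)), 1) if homa else float("nan"),
    )


def load_cohort(path=None) -> list[Subject]:
    """Load a cohort CSV (defaults to the packaged biopsy-cohort fixture)."""
    if path is None:
        with resources.files("plaqueband.data").joinpath("inph_cohort.csv").open() as fh:
            df = pd.read_csv(fh)
    else:
        df = pd.read_csv(path)
    subjects = []
    for _, row in df.iterrows():
        subjects.append(
            Subject(
                id=str(row["subject_id"]),
                gender=str(row["gender"]),
                age=float(row["age_years"]),
                weight_kg=float(row["weight_kg"]),
                height_cm=float(row["height_cm"]),
                homa_ir=float(row["homa_ir"]) if not pd.isna(row.get("homa_ir")) else None,
                t2d=str(row.get("t2d", "no")).lower() in ("yes", "true", "1"),
                hypertension=str(row.get("hypertension", "no")).lower() in ("yes", "true", "1"),
                amyloid_positive=str(row.get("abeta_positive", "yes")).lower()
                in ("yes", "true", "1"),
                apoe=str(row.get("apoe", "")),
            )
        )
    return subjects


def cohort_table(subjects: list[Subject]) -> pd.DataFrame:
    """Per-subject table with computed BMI and assigned group."""
    return pd.DataFrame(
        {
            "subject_id": [s.id for s in subjects],
            "group": [assign_group(s) for s in subjects],
            "gender": [s.gender for s in subjects],
            "age_years": [s.age for s in subjects],
            "weight_kg": [s.weight_kg for s in subjects],
            "height_cm": [s.height_cm for s in subjects],
            "bmi": [s.bmi for s in subjects],
            "homa_ir": [s.homa_ir for s in subjects],
            "t2d": [s.t2d for s in subjects],
        }
    )
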