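"""Map raw clinical measurements to MetS components (revised AHA/NHLBI criteria).

Cutoffs, with the Asian waist-circumference values:

======================  =======================  =======================
component               men                      women
======================  =======================  =======================
abdominal obesity       waist > 90 cm            waist > 80 cm
high triglycerides      TG >= 150 mg/dl          TG >= 150 mg/dl
low HDL                 HDL < 40 mg/dl           HDL < 50 mg/dl
high blood pressure     >= 130/85 mmHg or meds   >= 130/85 mmHg or meds
high fasting glucose    FPG >= 100 mg/dl or meds FPG >= 100 mg/dl or meds
======================  =======================  =======================

The BP criterion reads 130/85 as systolic >= 130 OR diastolic >= 85.
Antihypertensive or antidiabetic medication forces the corresponding
component regardless of the measured value; lipid-lowering medication is
deliberately not a criterion for high TG / low HDL.

Whether the numeric cutoffs for TG, BP and FPG are inclusive (>=, the
consensus definition; the default) or strict (>) is switchable through
:class:`ThresholdPolicy`.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import pandas as pd

from .states import ComponentProfile, MetabolicState, profile_to_state

VALID_SEXES = ("male", "female")

WAIST_CUTOFF_CM = {"male": 90.0, "female": 80.0}
HDL_CUTOFF_MG_DL = {"male": 40.0, "female": 50.0}
TG_CUTOFF_MG_DL = 150.0
SYSTOLIC_CUTOFF_MMHG = 130.0
DIASTOLIC_CUTOFF_MMHG = 85.0
FPG_CUTOFF_MG_DL = 100.0


@dataclass(frozen=True)
class ThresholdPolicy:
    """Boundary convention at the numeric cutoffs.

    ``strict`` = False (default): TG/BP/FPG use inclusive >=; True: strict >.
    HDL is always strict < its cutoff and waist always strict > its cutoff,
    matching the wording of the criteria.
    """

    strict: bool = False

    def at_or_above(self, value: float, cutoff: float) -> bool:
        return value > cutoff if self.strict else value >= cutoff


DEFAULT_POLICY = ThresholdPolicy()


@dataclass(frozen=True)
class ComponentMeasurements:
    """Raw measurements for one person at one wave (cm, mg/dl, mmHg)."""

    sex: str
    waist_cm: float
    triglycerides_mg_dl: float
    hdl_mg_dl: float
    systolic_mmHg: float
    diastolic_mmHg: float
    fpg_mg_dl: float
    on_antihypertensives: bool = False
    on_antidiabetics: bool = False

    def __post_init__(self) -> None:
        if self.sex not in VALID_SEXES:
            raise ValueError(f"unknown sex {self.sex!r}; expected 'male' or 'female'")
        for name in (
            "waist_cm",
            "triglycerides_mg_dl",
            "hdl_mg_dl",
            "systolic_mmHg",
            "diastolic_mmHg",
            "fpg_mg_dl",
        ):
            v = getattr(self, name)
            if v is None or pd.isna(v):
                raise ValueError(f"missing required field: {name}")
            if not v > 0:
                raise ValueError(f"{name} must be > 0, got {v}")
        if not self.systolic_mmHg > self.diastolic_mmHg:
            raise ValueError(
                f"systolic ({self.systolic_mmHg}) must exceed diastolic "
                f"({self.diastolic_mmHg})"
            )


def evaluate_components(
    m: ComponentMeasurements, policy: ThresholdPolicy = DEFAULT_POLICY
) -> ComponentProfile:
    """Apply the five criteria to one set of measurements."""
    return ComponentProfile(
        abdominal_obesity=m.waist_cm > WAIST_CUTOFF_CM[m.sex],
        high_tg=policy.at_or_above(m.triglycerides_mg_dl, TG_CUTOFF_MG_DL),
        low_hdl=m.hdl_mg_dl < HDL_CUTOFF_MG_DL[m.sex],
        high_bp=(
            m.on_antihypertensives
            or policy.at_or_above(m.systolic_mmHg, SYSTOLIC_CUTOFF_MMHG)
            or policy.at_or_above(m.diastolic_mmHg, DIASTOLIC_CUTOFF_MMHG)
        ),
        high_fpg=m.on_antidiabetics or policy.at_or_above(m.fpg_mg_dl, FPG_CUTOFF_MG_DL),
    )


def classify(
    m: ComponentMeasurements, policy: ThresholdPolicy = DEFAULT_POLICY
) -> MetabolicState:
    """Measurements -> metabolic state in one step."""
    return profile_to_state(evaluate_components(m, policy))


#: Fixed header of the raw-measurement panel CSV, one row per subject per wave.
MEASUREMENT_COLUMNS = (
    "subject_id",
    "wave",
    "sex",
    "waist_cm",
    "triglycerides_mg_dl",
    "hdl_mg_dl",
    "systolic_mmHg",
    "diastolic_mmHg",
    "fpg_mg_dl",
    "on_antihypertensives",
    "on_antidiabetics",
)


def read_measurement_panel(path: str | Path) -> pd.DataFrame:
    """Read a raw-measurement panel CSV and append a ``state`` column.

    The file must carry exactly the :data:`MEASUREMENT_COLUMNS` header; rows
    are classified with the default threshold policy.
    """
    df = pd.read_csv(path)
    missing = [c for c in MEASUREMENT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"measurement panel missing required columns: {missing}")
    df = df.copy()
    df["state"] = [
        classify(
            ComponentMeasurements(
                sex=row.sex,
                waist_cm=row.waist_cm,
                triglycerides_mg_dl=row.triglycerides_mg_dl,
                hdl_mg_dl=row.hdl_mg_dl,
                systolic_mmHg=row.systolic_mmHg,
                diastolic_mmHg=row.diastolic_mmHg,
                fpg_mg_dl=row.fpg_mg_dl,
                on_antihypertensives=bool(row.on_antihypertensives),
                on_antidiabetics=bool(row.on_antidiabetics),
            )
        ).name
        for row in df.itertuples()
    ]
    return df


def classify_many(
    measurements: Iterable[ComponentMeasurements],
    policy: ThresholdPolicy = DEFAULT_POLICY,
) -> list[MetabolicState]:
    return [classify(m, policy) for m in measurements]
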