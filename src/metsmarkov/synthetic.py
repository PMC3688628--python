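"""Synthetic two-wave panels and raw measurements with known ground truth.

The study's raw cohort data are not public, so everything downstream is
exercised on synthetic cohorts whose generating process is fully known:

* :func:`generate_panel` draws each subject's baseline state from a chosen
  distribution and their follow-up state from the true annual matrix
  compounded over the inter-wave interval in whole yearly cycles (the model
  itself is annual-cycle; 5.4 years of follow-up compounds 5 cycles by
  default).  Estimation can then be checked against the generating matrix
  rather than against any invented number.
* :func:`generate_measurements` emits raw clinical values (waist, lipids,
  BP, glucose) consistent with a requested state, drawn from truncated
  normal distributions kept clear of the diagnostic cutoffs, so that
  classification round-trips exactly.

The generator emulates threshold consistency only: it does not model the
joint correlation structure of the five components, within-person drift,
or medication use, and its default follow-up interval (5.4 years) and
cohort sizes mirror a two-wave population survey of young adults.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .classification import ComponentMeasurements
from .estimation import PanelObservation
from .projection import StateDistribution, TransitionMatrix
from .states import COMPONENT_NAMES, N_STATES, MetabolicState


@dataclass(frozen=True)
class GeneratorConfig:
    true_matrix: TransitionMatrix
    n_subjects: int
    baseline_distribution: StateDistribution
    interval_years: float = 5.4
    seed: int = 0
    jitter_intervals: bool = False

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        if not self.interval_years > 0:
            raise ValueError("interval_years must be > 0")


@dataclass(frozen=True)
class PanelAudit:
    """Record of the generator's draws: baseline counts and transition tallies."""

    baseline_counts: np.ndarray
    transition_counts: np.ndarray
    compounded_matrix: np.ndarray
    n_cycles: int
    seed: int = 0


def _sex_for_matrix(matrix: TransitionMatrix) -> str:
    return matrix.sex if matrix.sex in ("male", "female") else "male"


def generate_panel(
    config: GeneratorConfig, return_audit: bool = False
) -> list[PanelObservation] | tuple[list[PanelObservation], PanelAudit]:
    """Draw a synthetic two-wave panel under a known annual matrix.

    Follow-up states are multinomial draws from the true matrix raised to
    ``round(interval_years)`` (at least 1 cycle).  With ``jitter_intervals``
    each subject's recorded interval is perturbed uniformly by up to ±0.5
    years around the configured value while the generating dynamics keep
    the integer cycle count, mimicking field-visit scheduling noise.
    """
    rng = np.random.default_rng(config.seed)
    n_cycles = max(1, round(config.interval_years))
    compounded = np.linalg.matrix_power(config.true_matrix.probs, n_cycles)
    sex = _sex_for_matrix(config.true_matrix)

    baseline = rng.choice(
        N_STATES, size=config.n_subjects, p=config.baseline_distribution.occupancy
    )
    if config.jitter_intervals:
        intervals = config.interval_years + rng.uniform(
            -0.5, 0.5, size=config.n_subjects
        )
        intervals = np.maximum(intervals, 0.1)
    else:
        intervals = np.full(config.n_subjects, config.interval_years)

    baseline_counts = np.bincount(baseline, minlength=N_STATES)
    transition_counts = np.zeros((N_STATES, N_STATES), dtype=np.int64)
    followup = np.empty(config.n_subjects, dtype=np.int64)
    # draw follow-up states state-by-state so the tally is exactly the draws
    for s in np.nonzero(baseline_counts)[0]:
        idx = np.nonzero(baseline == s)[0]
        draws = rng.choice(N_STATES, size=idx.size, p=compounded[s])
        followup[idx] = draws
        transition_counts[s] = np.bincount(draws, minlength=N_STATES)

    panel = [
        PanelObservation(
            subject_id=f"S{i:06d}",
            sex=sex,
            state_t0=MetabolicState(int(baseline[i])),
            state_t1=MetabolicState(int(followup[i])),
            interval_years=float(intervals[i]),
        )
        for i in range(config.n_subjects)
    ]
    if not return_audit:
        return panel
    audit = PanelAudit(
        baseline_counts=baseline_counts,
        transition_counts=transition_counts,
        compounded_matrix=compounded,
        n_cycles=n_cycles,
        seed=config.seed,
    )
    return panel, audit


# ---------------------------------------------------------------------------
# Raw measurement generation
# ---------------------------------------------------------------------------

#: Truncated-normal sampling windows (low, high, mean, sd) on each side of
#: every diagnostic cutoff.  Windows stop half a unit clear of the cutoff so
#: boundary conventions (inclusive vs strict) cannot flip the component.
NORMAL_RANGES = {
    ("waist_cm", "male"): (70.0, 89.5, 80.0, 6.0),
    ("waist_cm", "female"): (60.0, 79.5, 70.0, 6.0),
    ("triglycerides_mg_dl", None): (50.0, 145.0, 95.0, 30.0),
    ("hdl_mg_dl", "male"): (42.0, 80.0, 52.0, 10.0),
    ("hdl_mg_dl", "female"): (52.0, 90.0, 62.0, 10.0),
    ("systolic_mmHg", None): (95.0, 127.0, 112.0, 9.0),
    ("diastolic_mmHg", None): (60.0, 82.0, 72.0, 7.0),
    ("fpg_mg_dl", None): (70.0, 97.0, 86.0, 8.0),
}
ABNORMAL_RANGES = {
    ("waist_cm", "male"): (91.0, 120.0, 97.0, 6.0),
    ("waist_cm", "female"): (81.0, 110.0, 88.0, 6.0),
    ("triglycerides_mg_dl", None): (155.0, 450.0, 210.0, 60.0),
    ("hdl_mg_dl", "male"): (25.0, 38.0, 34.0, 4.0),
    ("hdl_mg_dl", "female"): (30.0, 48.0, 42.0, 5.0),
    ("systolic_mmHg", None): (133.0, 180.0, 144.0, 10.0),
    ("diastolic_mmHg", None): (87.0, 110.0, 93.0, 6.0),
    ("fpg_mg_dl", None): (103.0, 180.0, 115.0, 15.0),
}

_SUBSETS_BY_STATE: dict[MetabolicState, list[tuple[str, ...]]] = {
    MetabolicState.NO_COMPONENT: [()],
    MetabolicState.ISO_ABDOMINAL_OBESITY: [("abdominal_obesity",)],
    MetabolicState.ISO_HIGH_TG: [("high_tg",)],
    MetabolicState.ISO_LOW_HDL: [("low_hdl",)],
    MetabolicState.ISO_HIGH_BP: [("high_bp",)],
    MetabolicState.ISO_HIGH_FPG: [("high_fpg",)],
    MetabolicState.TWO_COMPONENT: [
        c for c in itertools.combinations(COMPONENT_NAMES, 2)
    ],
    MetabolicState.METS: [
        c
        for k in (3, 4, 5)
        for c in itertools.combinations(COMPONENT_NAMES, k)
    ],
}


def _draw(table: dict, key: str, sex: str, rng: np.random.Generator) -> float:
    spec = table.get((key, sex)) or table[(key, None)]
    low, high, mean, sd = spec
    a, b = (low - mean) / sd, (high - mean) / sd
    return float(stats.truncnorm.rvs(a, b, loc=mean, scale=sd, random_state=rng))


def generate_measurements(
    state: MetabolicState, sex: str, seed: int
) -> ComponentMeasurements:
    """Raw measurements guaranteed to classify back to ``state``.

    For the pooled states the abnormal component subset is chosen uniformly
    among valid subsets (10 pairs for TWO_COMPONENT, 16 subsets of size >= 3
    for METS).  Medication flags are never set: abnormality is always
    expressed through the measured value.
    """
    if sex not in ("male", "female"):
        raise ValueError(f"unknown sex {sex!r}")
    rng = np.random.default_rng(seed)
    subsets = _SUBSETS_BY_STATE[MetabolicState(state)]
    abnormal = set(subsets[rng.integers(len(subsets))])

    def pick(field: str, component: str) -> float:
        table = ABNORMAL_RANGES if component in abnormal else NORMAL_RANGES
        return _draw(table, field, sex, rng)

    systolic = pick("systolic_mmHg", "high_bp")
    diastolic = pick("diastolic_mmHg", "high_bp")
    return ComponentMeasurements(
        sex=sex,
        waist_cm=pick("waist_cm", "abdominal_obesity"),
        triglycerides_mg_dl=pick("triglycerides_mg_dl", "high_tg"),
        hdl_mg_dl=pick("hdl_mg_dl", "low_hdl"),
        systolic_mmHg=systolic,
        diastolic_mmHg=min(diastolic, systolic - 5.0),
        fpg_mg_dl=pick("fpg_mg_dl", "high_fpg"),
        on_antihypertensives=False,
        on_antidiabetics=False,
    )
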