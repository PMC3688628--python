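"""Annualized transition-matrix estimation from two-wave panel data.

A two-wave panel records, for each subject, the metabolic state at baseline,
the state at follow-up, and the interval between the waves.  Estimation
proceeds in three steps:

1. tally transitions and person-years by origin state
   (:func:`count_transitions`);
2. convert tallies to annual incidence rates r_ij = n_ij / person-years_i
   (:func:`estimate_rates`);
3. annualize each off-diagonal rate with P = 1 - exp(-r t) at t = 1 year and
   set the diagonal to the residual 1 - sum of off-diagonal probabilities
   (:func:`build_transition_matrix`), which guarantees row-stochasticity.

Each subject contributes their full inter-wave interval to their baseline
state: with only two observation waves no intermediate states are known, so
this is the simplest person-time attribution consistent with an annual
incidence rate, and it is an approximation.

The module also loads the two published annual matrices (men and women)
shipped as percentage tables, renormalizing the rounded rows onto the
probability simplex.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .projection import TransitionMatrix
from .states import N_STATES, MetabolicState, state_from_name

logger = logging.getLogger(__name__)

FIXTURE_SEX = {"men_table2": "male", "women_table3": "female"}

#: Printed percentage rows must sum to within this band before renormalizing.
PRINTED_ROW_SUM_RANGE = (99.5, 100.5)


@dataclass(frozen=True)
class PanelObservation:
    """One subject's (baseline state, follow-up state, interval) record."""

    subject_id: str
    sex: str
    state_t0: MetabolicState
    state_t1: MetabolicState
    interval_years: float

    def __post_init__(self) -> None:
        if self.sex not in ("male", "female"):
            raise ValueError(f"unknown sex {self.sex!r}")
        if not self.interval_years > 0:
            raise ValueError(f"interval_years must be > 0, got {self.interval_years}")


@dataclass(frozen=True)
class EstimationConfig:
    """Options resolving the under-determined corners of the estimator.

    continuity_correction
        Add 0.5 events to zero-count off-diagonal cells of rows that have
        any follow-up time, so no transition the data cannot rule out gets
        probability exactly 0.  Off by default.
    use_mean_interval
        Replace each subject's recorded interval with the panel mean when
        accumulating person-years (published analyses sometimes use the
        mean follow-up).  Off by default: exact per-subject intervals.
    """

    continuity_correction: bool = False
    use_mean_interval: bool = False


@dataclass(frozen=True)
class TransitionCountTable:
    """Transition tallies n_ij plus person-years at risk per origin state."""

    counts: np.ndarray
    person_years: np.ndarray
    sex: str = "unspecified"

    def __post_init__(self) -> None:
        c = np.asarray(self.counts)
        py = np.asarray(self.person_years, dtype=float)
        if c.shape != (N_STATES, N_STATES) or py.shape != (N_STATES,):
            raise ValueError("counts must be 8x8 and person_years length 8")
        if np.any(c < 0) or np.any(py < 0):
            raise ValueError("counts and person-years must be nonnegative")
        c.setflags(write=False)
        py.setflags(write=False)
        object.__setattr__(self, "counts", c)
        object.__setattr__(self, "person_years", py)

    @property
    def origin_totals(self) -> np.ndarray:
        return self.counts.sum(axis=1)


@dataclass(frozen=True)
class RateMatrix:
    """Annual incidence rates r_ij per person-year; the diagonal is unused."""

    rates: np.ndarray
    sex: str = "unspecified"

    def __post_init__(self) -> None:
        r = np.asarray(self.rates, dtype=float)
        if r.shape != (N_STATES, N_STATES):
            raise ValueError("rates must be 8x8")
        off = r[~np.eye(N_STATES, dtype=bool)]
        if np.any(off < 0) or not np.all(np.isfinite(off)):
            raise ValueError("off-diagonal rates must be finite and >= 0")
        r.setflags(write=False)
        object.__setattr__(self, "rates", r)


def count_transitions(panel: list[PanelObservation]) -> TransitionCountTable:
    """Tally n_ij and person-years by origin state for one sex stratum."""
    if not panel:
        warnings.warn("empty panel: returning an all-zero count table", stacklevel=2)
        return TransitionCountTable(
            np.zeros((N_STATES, N_STATES), dtype=int), np.zeros(N_STATES)
        )
    sexes = {obs.sex for obs in panel}
    if len(sexes) > 1:
        raise ValueError(
            f"panel mixes sex strata {sorted(sexes)}; estimate each sex separately"
        )
    counts = np.zeros((N_STATES, N_STATES), dtype=int)
    person_years = np.zeros(N_STATES)
    for obs in panel:
        counts[int(obs.state_t0), int(obs.state_t1)] += 1
        person_years[int(obs.state_t0)] += obs.interval_years
    return TransitionCountTable(counts, person_years, sex=sexes.pop())


def estimate_rates(
    table: TransitionCountTable, config: EstimationConfig = EstimationConfig()
) -> RateMatrix:
    """Annual incidence rates r_ij = n_ij / person-years_i, off-diagonal only."""
    counts = table.counts.astype(float)
    py = table.person_years
    events_off_diag = counts - np.diag(np.diag(counts))
    inconsistent = (py == 0) & (events_off_diag.sum(axis=1) > 0)
    if np.any(inconsistent):
        names = [MetabolicState(i).name for i in np.where(inconsistent)[0]]
        raise ValueError(f"rows {names} have events but zero person-time")
    if config.continuity_correction:
        off = ~np.eye(N_STATES, dtype=bool)
        zero_cells = off & (counts == 0) & (py[:, None] > 0)
        counts = counts + 0.5 * zero_cells
    rates = np.zeros((N_STATES, N_STATES))
    with np.errstate(invalid="ignore", divide="ignore"):
        nonzero = py > 0
        rates[nonzero] = counts[nonzero] / py[nonzero, None]
    np.fill_diagonal(rates, 0.0)
    empty = ~(py > 0)
    if np.any(empty):
        warnings.warn(
            "origin states with zero person-years get all-zero rates: "
            + ", ".join(MetabolicState(i).name for i in np.where(empty)[0]),
            stacklevel=2,
        )
    return RateMatrix(rates, sex=table.sex)


def annualize_probability(rate: float, t: float) -> float:
    """Convert an annual incidence rate to a transition probability.

    P = 1 - exp(-r t), the exponential-waiting-time conversion; returns a
    value in [0, 1).
    """
    if rate < 0:
        raise ValueError(f"rate must be >= 0, got {rate}")
    if not t > 0:
        raise ValueError(f"duration must be > 0 years, got {t}")
    return -math.expm1(-rate * t)


def build_transition_matrix(
    rate_matrix: RateMatrix, cycle_years: float = 1.0
) -> TransitionMatrix:
    """Annualize each off-diagonal rate; diagonal is the residual mass.

    Rejects any row whose off-diagonal probabilities exceed 1 (rates too
    large for per-cell annualization at this cycle length).
    """
    probs = -np.expm1(-rate_matrix.rates * cycle_years)
    np.fill_diagonal(probs, 0.0)
    off_sum = probs.sum(axis=1)
    bad = np.where(off_sum > 1.0)[0]
    if bad.size:
        names = [MetabolicState(i).name for i in bad]
        raise ValueError(
            f"off-diagonal probabilities exceed 1 in rows {names} "
            f"(sums {off_sum[bad]}); per-cell annualization is invalid here"
        )
    probs[np.eye(N_STATES, dtype=bool)] = 1.0 - off_sum
    return TransitionMatrix(probs, sex=rate_matrix.sex, source="estimated from panel")


def estimate_transition_matrix(
    panel: list[PanelObservation], config: EstimationConfig = EstimationConfig()
) -> TransitionMatrix:
    """Full pipeline: panel -> counts -> rates -> annual transition matrix."""
    table = count_transitions(panel)
    if config.use_mean_interval and panel:
        mean_t = float(np.mean([o.interval_years for o in panel]))
        py = table.origin_totals * mean_t
        table = TransitionCountTable(table.counts, py, sex=table.sex)
    return build_transition_matrix(estimate_rates(table, config))


def load_printed_matrix(
    percent: np.ndarray, sex: str = "unspecified", source: str = "printed table"
) -> TransitionMatrix:
    """Turn an 8x8 table of printed percentages into a valid annual matrix.

    Each row must sum to within 99.5-100.5 (rounding slack of a table
    printed to 2 decimals); entries are divided by 100 and the row is
    renormalized to sum exactly to 1.  Original row sums are logged so the
    renormalization applied is auditable.
    """
    p = np.asarray(percent, dtype=float)
    if p.shape != (N_STATES, N_STATES):
        raise ValueError(f"printed table must be 8x8, got {p.shape}")
    if np.any(p < 0):
        raise ValueError("printed percentages must be nonnegative")
    row_sums = p.sum(axis=1)
    lo, hi = PRINTED_ROW_SUM_RANGE
    bad = np.where((row_sums < lo) | (row_sums > hi))[0]
    if bad.size:
        names = [MetabolicState(i).name for i in bad]
        raise ValueError(
            f"rows {names} sum to {row_sums[bad]}%, outside [{lo}, {hi}]"
        )
    for i, s in enumerate(row_sums):
        logger.info(
            "printed row %s sums to %.2f%%; renormalizing by %.6f",
            MetabolicState(i).name, s, 100.0 / s,
        )
    probs = (p / 100.0) / (row_sums[:, None] / 100.0)
    return TransitionMatrix(probs, sex=sex, source=source)


def _read_matrix_percent_csv(path_or_buf) -> np.ndarray:
    df = pd.read_csv(path_or_buf, index_col=0)
    expected = [s.name for s in MetabolicState]
    if list(df.index) != expected or list(df.columns) != expected:
        raise ValueError(
            "matrix CSV must carry the canonical state order in both header "
            f"and index: {expected}"
        )
    return df.to_numpy(dtype=float)


def load_fixture(name: str) -> TransitionMatrix:
    """Load a bundled published matrix: ``men_table2`` or ``women_table3``.

    Fixtures ship the printed percentages bit-exact; rows are renormalized
    on load.
    """
    if name not in FIXTURE_SEX:
        raise ValueError(f"unknown fixture {name!r}; expected {sorted(FIXTURE_SEX)}")
    ref = resources.files("metsmarkov.data").joinpath(f"{name}.csv")
    with ref.open() as fh:
        percent = _read_matrix_percent_csv(fh)
    return load_printed_matrix(percent, sex=FIXTURE_SEX[name], source=f"fixture:{name}")


def load_matrix_csv(path: str | Path, sex: str = "unspecified") -> TransitionMatrix:
    """Load a percentage matrix CSV (same dialect as the fixtures)."""
    return load_printed_matrix(
        _read_matrix_percent_csv(path), sex=sex, source=str(path)
    )


def write_matrix_csv(matrix: TransitionMatrix, path: str | Path) -> None:
    """Write a matrix as percentages in the fixture CSV dialect."""
    names = [s.name for s in MetabolicState]
    pd.DataFrame(matrix.probs * 100.0, index=names, columns=names).rename_axis(
        "state"
    ).to_csv(path, float_format="%.6f")


PANEL_COLUMNS = ("subject_id", "sex", "state_t0", "state_t1", "interval_years")


def read_panel_csv(path: str | Path) -> list[PanelObservation]:
    """Read a two-wave panel CSV (states by canonical name)."""
    df = pd.read_csv(path)
    missing = [c for c in PANEL_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"panel CSV missing required columns: {missing}")
    return [
        PanelObservation(
            subject_id=str(r.subject_id),
            sex=str(r.sex),
            state_t0=state_from_name(str(r.state_t0)),
            state_t1=state_from_name(str(r.state_t1)),
            interval_years=float(r.interval_years),
        )
        for r in df.itertuples()
    ]


def write_panel_csv(panel: list[PanelObservation], path: str | Path) -> None:
    pd.DataFrame(
        {
            "subject_id": [o.subject_id for o in panel],
            "sex": [o.sex for o in panel],
            "state_t0": [o.state_t0.name for o in panel],
            "state_t1": [o.state_t1.name for o in panel],
            "interval_years": [o.interval_years for o in panel],
        }
    ).to_csv(path, index=False)
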