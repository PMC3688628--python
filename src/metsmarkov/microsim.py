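"""Individual-level Monte-Carlo cohort simulation with percentile intervals.

Each simulated individual occupies one of the 8 metabolic states and, every
annual cycle, draws their next state from the multinomial row of their
current state.  Replicating the whole cohort and taking percentiles of the
per-replicate occupancy proportions yields a nonparametric sampling interval
around the deterministic matrix-power projection; the point estimate is the
mean across replicates.

Individuals are exchangeable given their current state, so the cohort is
advanced by drawing, for each occupied state, a single multinomial count
vector for how its occupants disperse — distributionally identical to
simulating individuals one by one, and fast enough for cohorts of 10^5.

Random-number discipline: one integer seed per run; replicate substreams
are spawned deterministically from it, so any replicate can be reproduced
in isolation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .projection import StateDistribution, TransitionMatrix
from .states import N_STATES, MetabolicState


@dataclass(frozen=True)
class SimConfig:
    n_individuals: int = 10_000
    horizon_years: int = 15
    n_replicates: int = 200
    seed: int = 0
    ci_level: float = 0.95

    def __post_init__(self) -> None:
        if self.n_individuals < 1:
            raise ValueError("n_individuals must be >= 1")
        if self.horizon_years < 1:
            raise ValueError("horizon_years must be >= 1")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        if not 0.0 < self.ci_level < 1.0:
            raise ValueError("ci_level must lie strictly between 0 and 1")


@dataclass(frozen=True)
class CohortResult:
    """Per-replicate, per-year occupancy proportions plus summaries.

    ``occupancy`` has shape (n_replicates, horizon+1, 8); each year slice of
    each replicate sums to exactly 1 (every individual is counted once).
    """

    occupancy: np.ndarray
    ci_level: float

    def __post_init__(self) -> None:
        occ = np.asarray(self.occupancy, dtype=float)
        if occ.ndim != 3 or occ.shape[2] != N_STATES:
            raise ValueError("occupancy must be (replicates, years+1, 8)")
        occ.setflags(write=False)
        object.__setattr__(self, "occupancy", occ)

    @property
    def n_replicates(self) -> int:
        return self.occupancy.shape[0]

    @property
    def point_estimate(self) -> np.ndarray:
        """Mean occupancy across replicates, shape (years+1, 8)."""
        return self.occupancy.mean(axis=0)


def _simulate_one_replicate(
    probs: np.ndarray, start_counts: np.ndarray, horizon: int, rng: np.random.Generator
) -> np.ndarray:
    n = int(start_counts.sum())
    occ = np.empty((horizon + 1, N_STATES), dtype=float)
    counts = start_counts.astype(np.int64)
    occ[0] = counts / n
    for year in range(1, horizon + 1):
        nxt = np.zeros(N_STATES, dtype=np.int64)
        for s in np.nonzero(counts)[0]:
            nxt += rng.multinomial(counts[s], probs[s])
        counts = nxt
        occ[year] = counts / n
    return occ


def simulate_cohort(
    matrix: TransitionMatrix, initial: StateDistribution, config: SimConfig
) -> CohortResult:
    """Monte-Carlo cohort realizations of the annual-cycle Markov model.

    The initial cohort composition is itself a multinomial draw from the
    initial distribution, so sampling error at year 0 is represented unless
    the initial distribution is a point mass.
    """
    seed_seq = np.random.SeedSequence(config.seed)
    streams = seed_seq.spawn(config.n_replicates)
    occ = np.empty((config.n_replicates, config.horizon_years + 1, N_STATES))
    for r, stream in enumerate(streams):
        rng = np.random.default_rng(stream)
        start_counts = rng.multinomial(config.n_individuals, initial.occupancy)
        occ[r] = _simulate_one_replicate(
            matrix.probs, start_counts, config.horizon_years, rng
        )
    return CohortResult(occ, ci_level=config.ci_level)


def occupancy_interval(
    result: CohortResult, state: MetabolicState, year: int
) -> tuple[float, float]:
    """Percentile interval across replicates for one state-year occupancy."""
    if result.n_replicates < 2:
        raise ValueError(
            "percentile intervals need at least 2 replicates; rerun with "
            "n_replicates >= 2 (200 is a reasonable default)"
        )
    values = result.occupancy[:, year, int(state)]
    alpha = 1.0 - result.ci_level
    lo, hi = np.quantile(values, [alpha / 2.0, 1.0 - alpha / 2.0])
    return float(lo), float(hi)


def occupancy_point(result: CohortResult, state: MetabolicState, year: int) -> float:
    return float(result.point_estimate[year, int(state)])
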