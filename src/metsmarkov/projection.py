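"""Deterministic yearly-cycle projection of state occupancy.

The model is a discrete-time, time-homogeneous, reversible Markov chain on
the 8 metabolic states with an annual cycle and no absorbing state.  A
cohort's occupancy after k years is the initial distribution left-multiplied
by the k-th power of the annual transition matrix; all headline quantities
(15-year MetS development, remaining no-component fraction, ...) are entries
of such products.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .states import N_STATES, MetabolicState

ROW_SUM_TOL = 1e-9


@dataclass(frozen=True)
class TransitionMatrix:
    """Row-stochastic 8x8 annual transition probabilities, sex-stratified.

    Rows are from-states, columns to-states, both in canonical state order.
    The cycle length is fixed at one year.  Rows must sum to 1 within 1e-9:
    matrices read from printed percentage tables must be renormalized (see
    :func:`metsmarkov.estimation.load_printed_matrix`) before projection.
    """

    probs: np.ndarray
    sex: str = "unspecified"
    source: str = ""

    def __post_init__(self) -> None:
        p = np.asarray(self.probs, dtype=float)
        if p.shape != (N_STATES, N_STATES):
            raise ValueError(f"transition matrix must be 8x8, got {p.shape}")
        if np.any(p < 0) or np.any(p > 1):
            raise ValueError("transition probabilities must lie in [0, 1]")
        row_sums = p.sum(axis=1)
        bad = np.where(np.abs(row_sums - 1.0) > ROW_SUM_TOL)[0]
        if bad.size:
            raise ValueError(
                f"rows {[MetabolicState(i).name for i in bad]} do not sum to 1 "
                f"(sums {row_sums[bad]}); renormalize before projecting"
            )
        p.setflags(write=False)
        object.__setattr__(self, "probs", p)

    def power(self, k: int) -> np.ndarray:
        return np.linalg.matrix_power(self.probs, k)


@dataclass(frozen=True)
class StateDistribution:
    """Occupancy probabilities over the 8 states (sums to 1)."""

    occupancy: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.occupancy, dtype=float)
        if v.shape != (N_STATES,):
            raise ValueError(f"occupancy must have 8 entries, got shape {v.shape}")
        if np.any(v < 0) or np.any(v > 1):
            raise ValueError("occupancy entries must lie in [0, 1]")
        if abs(v.sum() - 1.0) > ROW_SUM_TOL:
            raise ValueError(f"occupancy must sum to 1, got {v.sum()}")
        v.setflags(write=False)
        object.__setattr__(self, "occupancy", v)

    @classmethod
    def point_mass(cls, state: MetabolicState) -> "StateDistribution":
        v = np.zeros(N_STATES)
        v[int(state)] = 1.0
        return cls(v)

    def __getitem__(self, state: MetabolicState) -> float:
        return float(self.occupancy[int(state)])


@dataclass(frozen=True)
class StateTrajectory:
    """Yearly occupancy distributions, year 0 (the initial) through horizon."""

    distributions: tuple[StateDistribution, ...] = field(default_factory=tuple)

    def __len__(self) -> int:
        return len(self.distributions)

    def __getitem__(self, year: int) -> StateDistribution:
        return self.distributions[year]

    def occupancy_series(self, state: MetabolicState) -> np.ndarray:
        """Occupancy of one state across all years, as a vector."""
        return np.array([d[state] for d in self.distributions])

    def to_array(self) -> np.ndarray:
        """(horizon+1, 8) array of occupancies."""
        return np.vstack([d.occupancy for d in self.distributions])


def project(
    initial: StateDistribution, matrix: TransitionMatrix, horizon: int
) -> StateTrajectory:
    """Project a cohort's occupancy over ``horizon`` annual cycles.

    trajectory[k] is the initial distribution after k left-multiplications
    by the annual matrix; trajectory[0] is the initial distribution itself.
    The horizon must be a non-negative whole number of years.
    """
    if isinstance(horizon, bool) or not isinstance(horizon, (int, np.integer)):
        raise TypeError(f"horizon must be an integer number of years, got {horizon!r}")
    if horizon < 0:
        raise ValueError(f"horizon must be >= 0, got {horizon}")
    out = [initial]
    occ = initial.occupancy
    for _ in range(horizon):
        occ = occ @ matrix.probs
        # guard against drift accumulating over long horizons
        out.append(StateDistribution(occ / occ.sum()))
    return StateTrajectory(tuple(out))


def occupancy_at(
    start: MetabolicState,
    target: MetabolicState,
    matrix: TransitionMatrix,
    year: int,
) -> float:
    """P(in ``target`` after ``year`` cycles | started in ``start``)."""
    traj = project(StateDistribution.point_mass(start), matrix, year)
    return traj[year][target]


def stationary_distribution(matrix: TransitionMatrix) -> StateDistribution:
    """Left eigenvector of the annual matrix for eigenvalue 1, normalized."""
    vals, vecs = np.linalg.eig(matrix.probs.T)
    i = int(np.argmin(np.abs(vals - 1.0)))
    v = np.real(vecs[:, i])
    v = np.abs(v) / np.abs(v).sum()
    return StateDistribution(v)
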