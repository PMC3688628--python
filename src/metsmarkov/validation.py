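"""Compare model-projected prevalence with empiric cohort proportions.

The natural check on the projection is the follow-up wave itself: run the
model to the cohort's follow-up horizon (5 years) and ask whether the
projected MetS prevalence is consistent with the observed proportion.
Consistency is judged against an exact (Clopper-Pearson) binomial interval
around the empiric proportion, since the sampling distribution of a
count/denominator proportion is binomial and no particular CI method is
imposed by the data.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

from scipy import stats


@dataclass(frozen=True)
class ValidationComparison:
    model_estimate: float
    empiric_count: int
    empiric_n: int
    empiric_proportion: float
    empiric_interval: tuple[float, float]
    level: float
    consistent: bool

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)

    def summary(self) -> str:
        lo, hi = self.empiric_interval
        verdict = "consistent" if self.consistent else "NOT consistent"
        return (
            f"model estimate {self.model_estimate:.4f} vs empiric "
            f"{self.empiric_count}/{self.empiric_n} = {self.empiric_proportion:.4f} "
            f"({self.level:.0%} CI {lo:.4f}-{hi:.4f}): {verdict}"
        )


def clopper_pearson_interval(
    count: int, n: int, level: float = 0.95
) -> tuple[float, float]:
    """Exact binomial interval via beta-quantile tail inversion."""
    if n <= 0:
        raise ValueError("n must be positive")
    if not 0 <= count <= n:
        raise ValueError(f"count must lie in [0, n]; got count={count}, n={n}")
    if not 0.0 < level < 1.0:
        raise ValueError("level must lie strictly between 0 and 1")
    alpha = 1.0 - level
    lower = 0.0 if count == 0 else float(stats.beta.ppf(alpha / 2, count, n - count + 1))
    upper = 1.0 if count == n else float(stats.beta.ppf(1 - alpha / 2, count + 1, n - count))
    return lower, upper


def validate_against_empiric(
    model_estimate: float,
    empiric_count: int,
    empiric_n: int,
    level: float = 0.95,
) -> ValidationComparison:
    """Judge a projected prevalence against an observed count/denominator."""
    if not 0.0 <= model_estimate <= 1.0:
        raise ValueError("model_estimate must be a probability")
    lo, hi = clopper_pearson_interval(empiric_count, empiric_n, level)
    proportion = empiric_count / empiric_n
    return ValidationComparison(
        model_estimate=float(model_estimate),
        empiric_count=int(empiric_count),
        empiric_n=int(empiric_n),
        empiric_proportion=proportion,
        empiric_interval=(lo, hi),
        level=level,
        consistent=lo <= model_estimate <= hi,
    )
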