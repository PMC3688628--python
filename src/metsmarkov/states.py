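"""The 8-state metabolic state space and the component-profile partition.

Metabolic syndrome (MetS) is defined by five binary components: abdominal
obesity, high triglycerides, low HDL cholesterol, high blood pressure and
high fasting plasma glucose.  The 32 possible component profiles are
collapsed onto 8 mutually exclusive, collectively exhaustive health states:
no component, the five isolated single-component states, a pooled
2-component state (any pair), and MetS itself (3 or more components).

The integer values of :class:`MetabolicState` fix the canonical row/column
order used by every transition matrix in the package.
"""

from __future__ import annotations

from dataclasses import dataclass, fields
from enum import IntEnum


class MetabolicState(IntEnum):
    """Canonical 8-state space; values are the matrix row/column indices."""

    NO_COMPONENT = 0
    ISO_ABDOMINAL_OBESITY = 1
    ISO_HIGH_TG = 2
    ISO_LOW_HDL = 3
    ISO_HIGH_BP = 4
    ISO_HIGH_FPG = 5
    TWO_COMPONENT = 6
    METS = 7


N_STATES = len(MetabolicState)

#: Component order shared by ComponentProfile and the isolated states.
COMPONENT_NAMES = ("abdominal_obesity", "high_tg", "low_hdl", "high_bp", "high_fpg")

_ISOLATED_BY_COMPONENT = {
    "abdominal_obesity": MetabolicState.ISO_ABDOMINAL_OBESITY,
    "high_tg": MetabolicState.ISO_HIGH_TG,
    "low_hdl": MetabolicState.ISO_LOW_HDL,
    "high_bp": MetabolicState.ISO_HIGH_BP,
    "high_fpg": MetabolicState.ISO_HIGH_FPG,
}


@dataclass(frozen=True)
class ComponentProfile:
    """The five MetS component indicators for one person at one wave."""

    abdominal_obesity: bool
    high_tg: bool
    low_hdl: bool
    high_bp: bool
    high_fpg: bool

    def __post_init__(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            if not isinstance(v, bool):
                raise TypeError(f"{f.name} must be a bool, got {v!r}")

    @property
    def count(self) -> int:
        return sum(getattr(self, name) for name in COMPONENT_NAMES)

    def active(self) -> tuple[str, ...]:
        """Names of the components that are present, in canonical order."""
        return tuple(n for n in COMPONENT_NAMES if getattr(self, n))


def profile_to_state(profile: ComponentProfile) -> MetabolicState:
    """Collapse a 5-component profile onto the 8-state space.

    0 components -> NO_COMPONENT; exactly 1 -> the matching isolated state;
    exactly 2 -> TWO_COMPONENT (the pair identity is discarded); 3 or more
    -> METS.  Total on all 32 profiles.
    """
    k = profile.count
    if k == 0:
        return MetabolicState.NO_COMPONENT
    if k == 1:
        return _ISOLATED_BY_COMPONENT[profile.active()[0]]
    if k == 2:
        return MetabolicState.TWO_COMPONENT
    return MetabolicState.METS


def state_from_name(name: str) -> MetabolicState:
    """Resolve a state from its canonical name, case-insensitively."""
    try:
        return MetabolicState[name.strip().upper()]
    except KeyError:
        valid = ", ".join(s.name for s in MetabolicState)
        raise ValueError(f"unknown state {name!r}; expected one of: {valid}") from None
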