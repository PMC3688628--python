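#!/usr/bin/env python
"""15-year MetS development from every possible starting state, by sex.

Repeats the projection with a point mass on each of the 8 states.

Finding: starting with any single component or a 2-component profile
substantially accelerates MetS development relative to the component-free
start (men: 12.7% from no component vs 24.6% from isolated abdominal
obesity and 29.7% from 2 components; women: 10.6% vs 27.6% and 21.7%).
High BP and the 2-component state are the strongest male initiators;
abdominal obesity leads in women.
"""

from pathlib import Path

import pandas as pd

from metsmarkov import MetabolicState, load_fixture, occupancy_at

OUT = Path(__file__).resolve().parent.parent / "results"
OUT.mkdir(exist_ok=True)

rows = []
for name, label in (("men_table2", "men"), ("women_table3", "women")):
    matrix = load_fixture(name)
    for start in MetabolicState:
        rows.append({
            "sex": label,
            "start_state": start.name,
            "mets_15yr_pct": 100 * occupancy_at(start, MetabolicState.METS,
                                                matrix, 15),
        })
df = pd.DataFrame(rows)
df.to_csv(OUT / "mets_15yr_by_start.csv", index=False, float_format="%.4f")
for label in ("men", "women"):
    sub = df[df.sex == label].sort_values("mets_15yr_pct", ascending=False)
    top = sub[sub.start_state != "METS"].iloc[0]
    print(f"{label}: strongest initiator {top.start_state} "
          f"({top.mets_15yr_pct:.1f}% MetS at 15 years)")
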