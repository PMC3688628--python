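#!/usr/bin/env python
"""Project 15 years of metabolic-state occupancy from a component-free start.

For each sex, a cohort starting entirely in the no-component state is
projected through 15 annual cycles of its published transition matrix.

Finding: MetS develops in ~12.7% of men and ~10.6% of women within 15
years; a 2-component profile in ~16.3% and ~14.3%; only ~46.8% of men and
~49.8% of women remain component-free. Development of MetS is monotone
increasing in time for both sexes.
"""

from pathlib import Path

import pandas as pd

from metsmarkov import MetabolicState, StateDistribution, load_fixture, project

OUT = Path(__file__).resolve().parent.parent / "results"
OUT.mkdir(exist_ok=True)

start = StateDistribution.point_mass(MetabolicState.NO_COMPONENT)
for name, label in (("men_table2", "men"), ("women_table3", "women")):
    traj = project(start, load_fixture(name), 15)
    df = pd.DataFrame(traj.to_array() * 100,
                      columns=[s.name for s in MetabolicState])
    df.insert(0, "year", range(16))
    df.to_csv(OUT / f"projection_no_component_{label}.csv", index=False,
              float_format="%.4f")
    y15 = traj[15]
    print(f"{label}: 15-year MetS {y15[MetabolicState.METS]*100:.2f}%, "
          f"2-component {y15[MetabolicState.TWO_COMPONENT]*100:.2f}%, "
          f"still no component {y15[MetabolicState.NO_COMPONENT]*100:.2f}%")
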