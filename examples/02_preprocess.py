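"""The target pre-processor: predefined CV splits as table columns.

Simulates a small confounded dataset, then materializes 3 CV splits as
indicator + residual-target column pairs (plus one whole-input residual
column used only after the search ends), with a 20% holdout kept aside.
"""

import numpy as np

from resadj import SimConfig, build_resadj_dataset, identify_split, make_split_plan, simulate

table, collection, amap, truth = simulate(SimConfig(m=120, n_sets=4, set_size=6, seed=7))
m_work = 120 - int(round(120 * 0.2))
plan = make_split_plan(m_work, n_splits=3, scheme="shuffle", train_fraction=0.75, seed=7)
ds = build_resadj_dataset(table, amap, plan, holdout_fraction=0.2, seed=7)

appended = [c for c in ds.table.df.columns if c.startswith("__")]
print("appended columns:", appended)
print("work rows:", ds.table.m, "| holdout rows:", ds.holdout_table.m)

# a component handed split 1's training rows can recover which split it is in
train, test = plan.splits[1]
print("identify train rows of split 1 ->", identify_split(ds, train))
print("identify test rows of split 1  ->", identify_split(ds, test))
print("identify all work rows         ->", identify_split(ds, np.arange(ds.table.m)))
# The residual column for split 1 holds target residuals from a covariate
# model fitted on exactly those training rows - never on the test rows.
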