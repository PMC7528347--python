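"""Should I adjust for this covariate?  Cluster-based diagnostics.

Clusters the simulated expression features with k-means over a k sweep,
keeps the k maximizing the Dunn index, then asks how homogeneous the
clusters are with respect to each covariate (BHI).  A covariate whose BHI
clearly exceeds a random annotation's is organizing the data and is a
candidate for adjustment.
"""

import numpy as np

from resadj import SimConfig, bhi, kmeans_sweep, simulate

table, _, _, truth = simulate(SimConfig(seed=0))
X = table.df[table.feature_names].to_numpy(dtype=float)
best, sweep = kmeans_sweep(X, k_min=2, k_max=10, seed=0)
print(sweep.to_string(index=False))
print(f"best k = {best.k} (Dunn = {best.dunn:.3f})")

ann = truth.covariate_assignments
rng = np.random.default_rng(0)
for name in ("compound", "dose", "time"):
    print(f"BHI w.r.t. {name:>8s}: {bhi(best.labels, ann[name].to_numpy()):.3f}")
random_ann = rng.permutation(ann["compound"].to_numpy())
print(f"BHI w.r.t. random  : {bhi(best.labels, random_ann):.3f}")
# The confound h mixes all covariates, so covariate BHIs sit above the
# shuffled baseline; on unconfounded data they would match it.
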