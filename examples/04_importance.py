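"""Permutation importance of a fitted pipeline, and cross-run aggregation.

Runs one adjusted search, permutes each input column across the holdout
rows, and reports the mean holdout-score decrease.  Covariate bit columns
are scored too (they feed the in-pipeline residualization); columns the
pipeline never uses are exactly 0.
"""

from resadj import (
    ImportanceRecord,
    SimConfig,
    aggregate_importance,
    permutation_importance,
    run_once,
    simulate,
)

table, collection, amap, truth = simulate(SimConfig(seed=0))
res = run_once(table, collection, amap, "adjusted", seed=11,
               gp_population=20, gp_generations=5)
fitted, data = res["fitted"], res["data"]
dec = permutation_importance(
    fitted, data.holdout_table.df, data.holdout_residual, "r2",
    n_repeats=10, seed=11,
)
top = sorted(dec.items(), key=lambda kv: kv[1], reverse=True)[:5]
print(f"holdout R2 = {res['holdout_score']:.3f}; top 5 columns by score decrease:")
for col, d in top:
    print(f"  {col:>16s}  {d:+.4f}")

# aggregate this run with a (hypothetical) second run, weighting by score
records = [
    ImportanceRecord("run0", res["holdout_score"], dec, 10, 11),
    ImportanceRecord("run1", 0.5 * res["holdout_score"],
                     {k: 0.5 * v for k, v in dec.items()}, 10, 12),
]
weighted, report = aggregate_importance(records)
best_col = max(weighted, key=weighted.get)
print(f"aggregated over {report['n_included']} runs: top column {best_col} "
      f"at {weighted[best_col]:.1f}% of testing score")
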