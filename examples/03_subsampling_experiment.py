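"""Run a scaled-down symmetric subsampling experiment.

Fits the full 6+6 dataset, then for each size k in 1..5 draws 6 subsampled
datasets (both haplotypes of k individuals per population), fits each
best-of-2, and prints per-size means with standard errors plus the SRMSE
table and its regression on N. Expect SRMSE to grow as k shrinks, i.e. a
negative slope. (The study-scale protocol uses 25 replicates and 5 runs;
this example trades replicates for speed.)
"""

from splitmig import (
    ExperimentDesign,
    FitConfig,
    SimulationConfig,
    SplitMigParams,
    build_joint_sfs,
    fit_best_of,
    regress_srmse,
    run_experiment,
    simulate_dataset,
    srmse_table,
    summarize,
)

truth = SplitMigParams(nu1=2.0, nu2=4.0, T=0.5, m=0.5)
ds = simulate_dataset(SimulationConfig(n1=6, n2=6, L=3000, params=truth, seed=1))
sfs = build_joint_sfs(ds)
full = fit_best_of(
    sfs, FitConfig(start=truth, k_runs=2, engine_R=5000, engine_seed=0, seed=0)
)
print("full-data fit:", {k: round(v, 3) for k, v in zip(
    ("nu1", "nu2", "T", "m"), full.params_hat.as_array())})

design = ExperimentDesign(
    dataset=ds, full_fit=full, sizes=[1, 2, 3, 4, 5],
    reps_per_size=6, runs_per_rep=2, engine_R=5000, seed=0,
)
result = run_experiment(design)
print(f"failed replicates: {result.n_failed}")
print(summarize(result).round(3).to_string(index=False))

table = srmse_table(result, full)
print(table.round(3).to_string(index=False))
for param in ("nu1", "nu2", "T", "theta"):
    fit = regress_srmse(table, param)
    print(
        f"SRMSE({param}) = {fit.slope:+.4f} * N + {fit.intercept:.4f}"
        f"  (r2={fit.r_squared:.2f})"
    )
# Negative slopes say accuracy degrades as fewer individuals are sampled.
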