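"""Proteome pseudotime and early/mid/late module staging.

Simulates a cohort with a planted disease progression and three protein
modules that switch on at the amyloid, tau and cognition milestones, infers
pseudotime from the proteome alone (PCA -> kNN graph -> spectral embedding
-> principal path), and recovers each module's stage from its LOESS curve.
"""

import numpy as np
from scipy import stats

import proteotrans as pt
from proteotrans.association import module_summary
from proteotrans.trajectory import classify_stage, loess_fit, milestone_pseudotime

cfg = pt.GenerativeConfig.trajectory_benchmark(seed=0)
dataset, truth = pt.simulate_dataset(cfg)
res = pt.compute_pseudotime(dataset.protein.values.T, n_pcs=40, k=10, seed=0,
                            anchor=dataset.metadata["global_pathology"].to_numpy())
rho = stats.spearmanr(res.pseudotime, truth.true_pseudotime).statistic
print(f"pseudotime vs planted progression: Spearman = {rho:.3f} (n={cfg.n_samples})")

milestones = {}
for name in ("amyloid", "tau", "cognition"):
    grid, curve = loess_fit(res.pseudotime, dataset.metadata[name].to_numpy())
    milestones[name] = milestone_pseudotime(grid, curve)
print("clinical milestones (25% of overall variation): "
      + ", ".join(f"{k}={v:.2f}" for k, v in milestones.items()))

summ = module_summary(dataset.protein, truth.module_assignments)
curves = {m: loess_fit(res.pseudotime, summ.loc[m].to_numpy())
          for m in summ.index}
print("module staging:")
for s in classify_stage(curves, milestones):
    planted = truth.module_stages[s.module_id]
    print(f"  {s.module_id:8s} crossing={s.crossing_pseudotime:.2f} "
          f"stage={s.stage:6s} (planted: {planted})")

out = pt.relative_importance(
    dataset.metadata["cognitive_slope"].to_numpy(),
    np.column_stack([res.pseudotime, dataset.metadata["age"],
                     dataset.metadata["education"]]),
    names=["pseudotime", "age", "education"])
print("LMG share of cognitive-slope variance:")
print(out.round(3).to_string())
print("-> amyloid-stage modules change before tau- and cognition-stage "
      "modules; pseudotime carries the cognition-related variance, the "
      "demographic covariates do not.")
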