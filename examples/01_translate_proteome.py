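"""Out-of-fold proteome translation on a small synthetic cohort.

Simulates paired transcriptome/proteome data in which each protein couples
only weakly to its own mRNA but strongly to a shared latent tissue state,
then runs stratified out-of-fold training with a reduced submodel grid and
compares the concordance of the estimated proteome against the raw-mRNA
baseline.
"""

from dataclasses import replace

import proteotrans as pt
from proteotrans.model import enumerate_submodels

cfg = pt.GenerativeConfig(n_samples=200, n_genes=500, n_proteins=200, seed=0)
dataset, truth = pt.simulate_dataset(cfg)
print(f"simulated {cfg.n_samples} samples, {cfg.n_genes} genes, "
      f"{cfg.n_proteins} proteins")

grid = [replace(c, encoder_size=60 if c.encoder_representation == "hvg" else 40,
                latent_dim=8, hidden_dims=(32,), max_epochs=60, patience=10,
                batch_size=32)
        for c in enumerate_submodels({"representations": ("pc",)})]
folds = pt.stratified_folds(dataset.metadata, n_folds=5,
                            strat_columns=["diagnosis", "global_pathology"],
                            seed=0)
result = pt.out_of_fold_predict(dataset, grid, folds)
summary = pt.evaluate_against_baseline(result.oof_prediction, dataset.protein,
                                       dataset.mrna)

print(f"mean per-protein r, estimated protein vs actual: "
      f"{summary['mean_r_pred']:.3f}")
print(f"mean per-protein r, raw mRNA vs actual:          "
      f"{summary['mean_r_mrna']:.3f}")
print(f"proteins positively concordant at FDR 5%: "
      f"{summary['n_significant_pred']} (estimated) vs "
      f"{summary['n_significant_mrna']} (mRNA) of {cfg.n_proteins}")
print("-> the ensemble recovers the tissue-state component of the proteome "
      "that per-gene mRNA levels alone miss; every prediction is out-of-fold "
      "(made by models that never saw that sample).")
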