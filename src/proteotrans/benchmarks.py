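"""Self-contained benchmark experiments on synthetic data with ground truth.

Each function generates its inputs from a seed, runs one slice of the
pipeline end to end, and returns the measured quantities.  The experiment
scales (sample sizes, gene counts, network widths, epoch caps) are the
package's benchmark conditions: large enough for the statistical properties
being measured, small enough to run on a single CPU in minutes.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np
import pandas as pd
from scipy import stats

from .association import module_summary
from .attribution import (LinearModel, check_local_accuracy,
                          expected_gradient_attribution,
                          remove_input_contribution)
from .core import MultiOmicsDataset, OmicsMatrix
from .crossval import (evaluate_against_baseline, out_of_fold_predict,
                       per_feature_correlation, stratified_folds)
from .model import SubmodelConfig, enumerate_submodels
from .simdata import (GenerativeConfig, NoiseModelConfig,
                      expected_replicate_correlation, simulate_dataset,
                      simulate_replicate_pair,
                      solve_noise_sd_for_mean_correlation)
from .trajectory import (classify_stage, compute_pseudotime, loess_fit,
                         milestone_pseudotime, pseudotime_robustness,
                         relative_importance)

__all__ = [
    "noise_model_benchmark",
    "benchmark_grid",
    "translation_gain_benchmark",
    "leakage_benchmark",
    "attribution_benchmark",
    "trajectory_recovery_benchmark",
    "staging_benchmark",
    "lmg_benchmark",
]


def _row_correlations(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Pearson r per row between two equally shaped matrices."""
    aa = a - a.mean(axis=1, keepdims=True)
    bb = b - b.mean(axis=1, keepdims=True)
    denom = np.sqrt((aa * aa).sum(axis=1) * (bb * bb).sum(axis=1))
    denom = np.where(denom > 0, denom, np.nan)
    return (aa * bb).sum(axis=1) / denom


# ---------------------------------------------------------------------------
# replicate-measurement noise model
# ---------------------------------------------------------------------------

def noise_model_benchmark(seed: int = 0, target_mean_r: float = 0.20,
                          n_samples: int = 400, n_proteins: int = 1000) -> dict:
    """Replicate-pair dissociation: low abundance correlation, high effect concordance.

    The noise sd is solved so the closed-form mean replicate correlation hits
    ``target_mean_r`` given the drawn per-protein effects; the function then
    measures the empirical mean replicate correlation and the correlation of
    the per-protein OLS effect estimates between the two replicates.
    """
    base = NoiseModelConfig(n_samples=n_samples, n_proteins=n_proteins,
                            effect_sd=1.0, noise_sd=1.0,
                            phenotype_type="binary", seed=seed)
    _, _, x0, b = simulate_replicate_pair(base)
    var_x = float(np.var(x0.to_numpy()))
    sd = solve_noise_sd_for_mean_correlation(b, var_x, target_mean_r)
    cfg = replace(base, noise_sd=sd)
    rep1, rep2, x, b = simulate_replicate_pair(cfg)
    xv = x.to_numpy()

    r = _row_correlations(rep1.values, rep2.values)
    closed = expected_replicate_correlation(b, var_x, sd)

    xc = xv - xv.mean()
    denom = float(xc @ xc)
    bhat1 = (rep1.values @ xc) / denom
    bhat2 = (rep2.values @ xc) / denom
    effect_r = float(np.corrcoef(bhat1, bhat2)[0, 1])
    return {
        "noise_sd": sd,
        "closed_form_mean_r": float(closed.mean()),
        "empirical_mean_r": float(np.nanmean(r)),
        "effect_estimate_correlation": effect_r,
        "n_samples": n_samples,
        "n_proteins": n_proteins,
    }


# ---------------------------------------------------------------------------
# out-of-fold translation gain
# ---------------------------------------------------------------------------

def benchmark_grid(seed: int = 0, max_epochs: int = 100,
                   hvg_size: int = 500, pc_size: int = 100) -> list[SubmodelConfig]:
    """The 12-member grid at benchmark scale (narrow network, capped epochs)."""
    grid = enumerate_submodels({"common": dict(
        latent_dim=16, hidden_dims=(64,), max_epochs=max_epochs, patience=10,
        batch_size=64, seed=seed)})
    return [replace(c, encoder_size=hvg_size if c.encoder_representation == "hvg"
                    else pc_size) for c in grid]


def translation_gain_benchmark(seed: int = 0, n_folds: int = 10,
                               verbose: bool = False) -> dict:
    """10-fold out-of-fold ensemble prediction vs the raw-mRNA baseline.

    Runs the full 12-submodel grid on the translation benchmark dataset
    (600 samples, 2000 genes, mean mRNA-protein r ~ 0.10 by construction)
    and reports the mean per-protein correlation of the out-of-fold ensemble
    prediction with actual protein abundance, the raw-mRNA baseline, the
    translation gain, and the per-member means (for the ensemble-dominance
    comparison).
    """
    cfg = GenerativeConfig.translation_benchmark(seed=seed)
    dataset, truth = simulate_dataset(cfg)
    grid = benchmark_grid(seed=seed)
    folds = stratified_folds(dataset.metadata, n_folds=n_folds,
                             strat_columns=["diagnosis", "global_pathology"],
                             seed=seed)
    oof = out_of_fold_predict(dataset, grid, folds, verbose=verbose)
    summary = evaluate_against_baseline(oof.oof_prediction, dataset.protein,
                                        dataset.mrna)
    member_means = []
    for mem in oof.member_oof_predictions:
        r = _row_correlations(mem.values, dataset.protein.values)
        member_means.append(float(np.nanmean(r)))
    return {
        "mean_r_pred": summary["mean_r_pred"],
        "mean_r_mrna": summary["mean_r_mrna"],
        "translation_gain": summary["mean_r_pred"] - summary["mean_r_mrna"],
        "n_significant_pred": summary["n_significant_pred"],
        "n_significant_mrna": summary["n_significant_mrna"],
        "member_mean_r": member_means,
        "median_member_mean_r": float(np.median(member_means)),
        "ensemble_minus_median_member": summary["mean_r_pred"]
        - float(np.median(member_means)),
        "n_samples": cfg.n_samples,
        "n_proteins": cfg.n_proteins,
    }


def leakage_benchmark(seed: int = 0) -> dict:
    """Permuted-protein-label tripwire: out-of-fold r must collapse to ~0.

    Uses a reduced dataset and a 2-member grid; with sample labels of the
    protein layer permuted before training there is nothing to learn, so the
    mean out-of-fold correlation with the (permuted) truth must sit at 0.
    """
    cfg = GenerativeConfig(n_samples=200, n_genes=400, n_proteins=150, seed=seed)
    dataset, _ = simulate_dataset(cfg)
    rng = np.random.default_rng(seed + 1)
    perm = rng.permutation(cfg.n_samples)
    prot = dataset.protein
    permuted = OmicsMatrix(list(prot.feature_ids), list(prot.sample_ids),
                           prot.values[:, perm])
    ds_perm = MultiOmicsDataset(mrna=dataset.mrna, premrna=dataset.premrna,
                                utr=dataset.utr, protein=permuted,
                                metadata=dataset.metadata)
    grid = [replace(c, encoder_size=50 if c.encoder_representation == "hvg" else 30,
                    latent_dim=8, hidden_dims=(32,), max_epochs=40, patience=8,
                    batch_size=32, seed=seed)
            for c in enumerate_submodels({"representations": ("pc",),
                                          "merge_sets": (("decoded", "mrna"),)})]
    folds = stratified_folds(dataset.metadata, n_folds=5,
                             strat_columns=["diagnosis"], seed=seed)
    oof = out_of_fold_predict(ds_perm, grid, folds)
    r = _row_correlations(oof.oof_prediction.values, permuted.values)
    return {"permuted_label_mean_r": float(np.nanmean(r)),
            "n_proteins": cfg.n_proteins}


# ---------------------------------------------------------------------------
# attribution
# ---------------------------------------------------------------------------

def attribution_benchmark(seed: int = 0, n_seeds: int = 50) -> dict:
    """Linear closed form, local accuracy, and trait-signal removal."""
    rng0 = np.random.default_rng(seed)
    lin_errs = []
    for s in rng0.integers(0, 2 ** 31 - 1, size=n_seeds):
        rng = np.random.default_rng(int(s))
        d, t, nbg = 6, 3, 5
        W = rng.standard_normal((d, t))
        model = LinearModel(W, rng.standard_normal(t))
        X = rng.standard_normal((4, d))
        B = rng.standard_normal((nbg, d))
        attr = expected_gradient_attribution(model, X, B, n_draws=10, seed=int(s))
        expected = (X - B.mean(0))[:, :, None] * W[None, :, :]
        lin_errs.append(float(np.abs(attr.contributions - expected).max()))

    # smooth nonlinear model for the local-accuracy property
    class _Smooth:
        def __init__(self, s: int):
            r = np.random.default_rng(s)
            self.W = r.standard_normal((8, 2))
            self.V = r.standard_normal((8, 2)) * 0.5

        def value_and_grad(self, x):
            h = np.tanh(x @ self.V)
            vals = x @ self.W + h.sum(axis=1, keepdims=True)
            grads = np.broadcast_to(self.W[None], (x.shape[0], *self.W.shape)).copy()
            grads += ((1 - h ** 2) @ self.V.T)[:, :, None]
            return vals, grads

    smooth = _Smooth(seed)
    rng = np.random.default_rng(seed + 1)
    X = rng.standard_normal((10, 8))
    B = rng.standard_normal((20, 8))
    attr = expected_gradient_attribution(smooth, X, B, n_draws=200, seed=seed)
    local_dev = check_local_accuracy(attr, smooth, X)

    # planted trait-carrying input: removal must strip the trait association
    n, d = 300, 5
    rng = np.random.default_rng(seed + 2)
    trait = rng.standard_normal(n)
    X = rng.standard_normal((n, d))
    X[:, 0] = trait
    w = np.array([[2.0], [0.5], [0.3], [0.2], [0.1]])
    model = LinearModel(w)
    preds, _ = model.value_and_grad(X)
    attr = expected_gradient_attribution(model, X, X[:100], n_draws=100, seed=seed)
    adjusted = remove_input_contribution(preds, attr, attr.input_ids[0])

    def _r2(y):
        r = np.corrcoef(y[:, 0], trait)[0, 1]
        return float(r * r)

    r2_orig, r2_adj = _r2(preds), _r2(adjusted)
    return {
        "linear_max_abs_error": max(lin_errs),
        "local_accuracy_deviation": local_dev,
        "trait_r2_original": r2_orig,
        "trait_r2_after_removal": r2_adj,
        "trait_r2_removal_ratio": r2_adj / r2_orig,
    }


# ---------------------------------------------------------------------------
# trajectory and staging
# ---------------------------------------------------------------------------

def trajectory_recovery_benchmark(seed: int = 0) -> dict:
    """Planted-progression recovery and robustness across kNN settings."""
    cfg = GenerativeConfig.trajectory_benchmark(seed=seed)
    dataset, truth = simulate_dataset(cfg)
    values = dataset.protein.values.T
    anchor = dataset.metadata["global_pathology"].to_numpy()
    res = compute_pseudotime(values, n_pcs=40, k=10, seed=0, anchor=anchor)
    rec = abs(float(stats.spearmanr(res.pseudotime,
                                    truth.true_pseudotime).statistic))
    rob = pseudotime_robustness(values, k_values=(5, 10, 25, 50),
                                pc_values=(40,), seed=0)
    return {"pseudotime_recovery_spearman": rec,
            "robustness_mean_abs_spearman": rob["mean_abs_spearman"],
            "n_samples": cfg.n_samples}


def staging_benchmark(seed: int = 0, n_seeds: int = 10) -> dict:
    """Stage recovery of planted early/mid/late modules over several draws.

    Runs the full pipeline per draw: pseudotime inferred from the proteome,
    clinical milestones from LOESS of the (noisy) pathology scores, module
    curves from z-scored module means, staging against the milestones.  A
    sine-shaped control curve must come out "unspecified" every time.
    """
    ok = tot = sine_ok = 0
    base = np.random.default_rng(seed).integers(0, 2 ** 31 - 10)
    for s in range(int(base), int(base) + n_seeds):
        cfg = GenerativeConfig.trajectory_benchmark(seed=s)
        dataset, truth = simulate_dataset(cfg)
        res = compute_pseudotime(dataset.protein.values.T, n_pcs=40, k=10, seed=0,
                                 anchor=dataset.metadata["global_pathology"].to_numpy())
        milestones = {}
        for name in ("amyloid", "tau", "cognition"):
            grid, curve = loess_fit(res.pseudotime,
                                    dataset.metadata[name].to_numpy())
            milestones[name] = milestone_pseudotime(grid, curve)
        summ = module_summary(dataset.protein, truth.module_assignments)
        curves = {m: loess_fit(res.pseudotime, summ.loc[m].to_numpy())
                  for m in summ.index}
        grid = np.linspace(0.0, 1.0, 100)
        curves["control_sine"] = (grid, np.sin(2 * np.pi * grid))
        for sa in classify_stage(curves, milestones):
            if sa.module_id == "control_sine":
                sine_ok += sa.stage == "unspecified"
                continue
            tot += 1
            ok += sa.stage == truth.module_stages[sa.module_id]
    return {"stage_accuracy": ok / tot, "n_modules": tot,
            "sine_unspecified_fraction": sine_ok / n_seeds}


def lmg_benchmark(seed: int = 0) -> dict:
    """LMG conservation (shares sum to R^2) and orthogonal-marginal identity."""
    rng = np.random.default_rng(seed)
    n, p = 200, 4
    X = rng.standard_normal((n, p))
    beta = rng.standard_normal(p)
    y = X @ beta + rng.standard_normal(n)
    shares = relative_importance(y, X)
    ones = np.column_stack([np.ones(n), X])
    b, *_ = np.linalg.lstsq(ones, y, rcond=None)
    resid = y - ones @ b
    yc = y - y.mean()
    r2 = 1.0 - float(resid @ resid) / float(yc @ yc)
    sum_err = abs(float(shares.sum()) - r2)

    # exactly orthogonal two-predictor design
    q, _ = np.linalg.qr(rng.standard_normal((n, 2)))
    Xo = q - q.mean(axis=0, keepdims=True)
    Xo[:, 1] -= Xo[:, 0] * (Xo[:, 0] @ Xo[:, 1]) / (Xo[:, 0] @ Xo[:, 0])
    yo = 1.5 * Xo[:, 0] - 0.7 * Xo[:, 1] + rng.standard_normal(n)
    shares_o = relative_importance(yo, Xo)
    marg = []
    for j in range(2):
        Xj = np.column_stack([np.ones(n), Xo[:, j]])
        bj, *_ = np.linalg.lstsq(Xj, yo, rcond=None)
        rj = yo - Xj @ bj
        yoc = yo - yo.mean()
        marg.append(1.0 - float(rj @ rj) / float(yoc @ yoc))
    orth_err = float(np.max(np.abs(shares_o.to_numpy() - np.array(marg))))
    return {"share_sum_abs_error": sum_err,
            "orthogonal_marginal_abs_error": orth_err}
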