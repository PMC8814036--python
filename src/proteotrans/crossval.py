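"""Stratified 10-fold out-of-fold training/prediction and concordance evaluation.

Samples are split into K folds balancing cognitive status and brain pathology
(categorical columns crossed with tertile-binned continuous columns).  For
each fold, every submodel in the grid is trained on the remaining folds —
with encoder feature spaces fitted on non-holdout samples only — and the
ensemble predicts the holdout.  Holdout predictions are z-scored per protein
within each fold, then concatenated in the original sample order, so every
sample's prediction comes from models that never saw it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .core import MultiOmicsDataset, OmicsMatrix
from .model import (EnsembleModel, SubmodelConfig, TrainedSubmodel,
                    ensemble_predict, predict, train_submodel, _zscore_rows)

__all__ = [
    "FoldAssignment",
    "stratified_folds",
    "out_of_fold_predict",
    "OutOfFoldResult",
    "per_feature_correlation",
    "bh_fdr",
    "evaluate_against_baseline",
]


class CrossvalError(ValueError):
    pass


@dataclass
class FoldAssignment:
    assignments: dict[str, int]     # sample_id -> fold index in {1..K}
    n_folds: int
    strat_columns: list[str]
    seed: int

    def fold_samples(self, fold: int) -> list[str]:
        return [s for s, f in self.assignments.items() if f == fold]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"sample_id": list(self.assignments),
                             "fold": list(self.assignments.values())})


def stratified_folds(
    metadata: pd.DataFrame,
    n_folds: int = 10,
    strat_columns: Sequence[str] = (),
    seed: int = 0,
) -> FoldAssignment:
    """Deal samples round-robin into folds within each stratum.

    Continuous stratification columns are binned into tertiles before
    crossing; within each stratum samples are shuffled by the seed and dealt
    round-robin (fold sizes within a stratum differ by at most 1).  The
    starting fold rotates with the running total so overall fold sizes stay
    balanced as well.
    """
    if n_folds < 2:
        raise CrossvalError("n_folds must be >= 2")
    if n_folds > len(metadata):
        raise CrossvalError("more folds than samples")
    for col in strat_columns:
        if col not in metadata.columns:
            raise CrossvalError(f"stratification column {col!r} not in metadata")

    keys = pd.Series("", index=metadata.index)
    for col in strat_columns:
        s = metadata[col]
        if pd.api.types.is_numeric_dtype(s) and s.nunique() > 3:
            binned = pd.qcut(s, 3, labels=False, duplicates="drop")
        else:
            binned = s
        keys = keys + "|" + binned.astype(str)

    rng = np.random.default_rng(seed)
    assignments: dict[str, int] = {}
    start = 0
    for _, group in sorted(keys.groupby(keys), key=lambda kv: str(kv[0])):
        ids = list(map(str, group.index))
        order = rng.permutation(len(ids))
        for j, k in enumerate(order):
            assignments[ids[k]] = (start + j) % n_folds + 1
        start += len(ids)
    return FoldAssignment(assignments=assignments, n_folds=n_folds,
                          strat_columns=list(strat_columns), seed=seed)


@dataclass
class OutOfFoldResult:
    oof_prediction: OmicsMatrix                       # per-fold z-scored, concatenated
    member_oof_predictions: list[OmicsMatrix]         # same, per grid member
    per_fold_models: dict[int, list[TrainedSubmodel]]
    folds: FoldAssignment


def out_of_fold_predict(
    dataset: MultiOmicsDataset,
    grid: Sequence[SubmodelConfig],
    folds: FoldAssignment,
    verbose: bool = False,
) -> OutOfFoldResult:
    """Train the grid per fold on the other folds; predict each holdout.

    Within each fold, every protein's holdout predictions (ensemble and per
    member) are z-scored, then concatenated across folds in the original
    sample order.
    """
    samples = dataset.sample_ids
    missing = [s for s in samples if s not in folds.assignments]
    if missing:
        raise CrossvalError(f"folds do not cover samples {missing[:5]}")
    protein_ids = dataset.protein.feature_ids
    n_members = len(grid)
    oof = np.full((len(protein_ids), len(samples)), np.nan)
    member_oof = [np.full_like(oof, np.nan) for _ in range(n_members)]
    col = {s: j for j, s in enumerate(samples)}
    per_fold_models: dict[int, list[TrainedSubmodel]] = {}

    for fold in range(1, folds.n_folds + 1):
        hold = [s for s in samples if folds.assignments[s] == fold]
        train_ids = [s for s in samples if folds.assignments[s] != fold]
        if not hold:
            continue
        train_ds = dataset.subset_samples(train_ids)
        hold_ds = dataset.subset_samples(hold)
        members: list[TrainedSubmodel] = []
        for cfg in grid:
            sub = train_submodel(train_ds, cfg, feature_fit_sample_ids=train_ids)
            # out-of-fold purity: no holdout sample may appear in training
            leaked = set(sub.training_sample_ids) & set(hold)
            assert not leaked, f"holdout samples leaked into training: {leaked}"
            members.append(sub)
        per_fold_models[fold] = members
        cols = [col[s] for s in hold]
        for mi, sub in enumerate(members):
            member_oof[mi][:, cols] = _zscore_rows(predict(sub, hold_ds).values)
        ens = ensemble_predict(EnsembleModel(members), hold_ds)
        oof[:, cols] = _zscore_rows(ens.values)
        if verbose:
            print(f"fold {fold}/{folds.n_folds}: trained {n_members} submodels, "
                  f"predicted {len(hold)} holdout samples")

    return OutOfFoldResult(
        oof_prediction=OmicsMatrix(list(protein_ids), list(samples), oof),
        member_oof_predictions=[OmicsMatrix(list(protein_ids), list(samples), m)
                                for m in member_oof],
        per_fold_models=per_fold_models,
        folds=folds,
    )


def per_feature_correlation(pred: OmicsMatrix, actual: OmicsMatrix) -> pd.DataFrame:
    """Pearson r per shared feature, with one-sided p for r > 0 (t transform).

    Missing cells are dropped pairwise; features with fewer than 3 paired
    samples or zero variance get NaN statistics.
    """
    shared = [f for f in pred.feature_ids if f in set(actual.feature_ids)]
    if not shared:
        raise CrossvalError("no shared features between prediction and actual")
    a = pred.subset_features(shared)
    b = actual.subset_features(shared).subset_samples(a.sample_ids)
    out = []
    for i, f in enumerate(shared):
        x, y = a.values[i], b.values[i]
        ok = ~(np.isnan(x) | np.isnan(y))
        n = int(ok.sum())
        if n < 3 or np.std(x[ok]) == 0 or np.std(y[ok]) == 0:
            out.append((f, np.nan, np.nan, n))
            continue
        r = float(np.corrcoef(x[ok], y[ok])[0, 1])
        r = min(max(r, -1.0), 1.0)
        if abs(r) == 1.0:
            p = 0.0 if r > 0 else 1.0
        else:
            t = r * np.sqrt(n - 2) / np.sqrt(1.0 - r * r)
            p = float(stats.t.sf(t, df=n - 2))
        out.append((f, r, p, n))
    return pd.DataFrame(out, columns=["feature", "r", "p_one_sided", "n"])


def bh_fdr(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values: q_(i) = min_{j>=i}(p_(j) m / j)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.nanmin(p) < 0 or np.nanmax(p) > 1:
        raise CrossvalError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def evaluate_against_baseline(
    oof_pred: OmicsMatrix,
    actual_protein: OmicsMatrix,
    mrna: OmicsMatrix,
    fdr: float = 0.05,
) -> dict:
    """Concordance of predictions and of raw mRNA with actual protein abundance.

    Returns mean r and the number of features positively correlated at the
    requested FDR for both the estimated protein and the gene's own mRNA,
    plus a tidy per-feature table with the improvement delta_r.
    """
    tab_pred = per_feature_correlation(oof_pred, actual_protein)
    tab_mrna = per_feature_correlation(mrna, actual_protein)
    merged = tab_pred.merge(tab_mrna, on="feature", suffixes=("_pred", "_mrna"))
    if merged.empty:
        raise CrossvalError("no shared features between prediction and mRNA baseline")

    def _signif(tab: pd.DataFrame) -> int:
        ok = tab["p_one_sided"].notna()
        q = bh_fdr(tab.loc[ok, "p_one_sided"].to_numpy())
        return int((q < fdr).sum())

    merged["delta_r"] = merged["r_pred"] - merged["r_mrna"]
    return {
        "mean_r_pred": float(np.nanmean(merged["r_pred"])),
        "mean_r_mrna": float(np.nanmean(merged["r_mrna"])),
        "n_significant_pred": _signif(tab_pred),
        "n_significant_mrna": _signif(tab_mrna),
        "table": merged,
    }
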