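"""Trait association, multiple-testing correction, concordance and enrichment.

Per-feature association is ordinary least squares of feature ~ trait +
covariates (age, sex, education by default), reporting the trait coefficient,
its t-statistic and two-sided p-value, with Bonferroni (or BH) adjustment.
Cross-dataset concordance compares t-statistics over shared features; the
top-N validation experiment mirrors candidate selection for targeted protein
follow-up; Fisher enrichment is the exact one-sided hypergeometric tail; and
module summary scores are the mean of z-scored member features.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .core import OmicsMatrix

__all__ = [
    "linear_association",
    "bonferroni",
    "statistic_concordance",
    "top_n_validation",
    "fisher_enrichment",
    "module_summary",
]


class AssociationError(ValueError):
    pass


def _design_matrix(metadata: pd.DataFrame, trait: str,
                   covariates: Sequence[str]) -> tuple[np.ndarray, list[str]]:
    cols = [trait, *covariates]
    for c in cols:
        if c not in metadata.columns:
            raise AssociationError(f"column {c!r} not in metadata")
    parts = [np.ones(len(metadata))]
    names = ["intercept"]
    for c in cols:
        s = metadata[c]
        if pd.api.types.is_numeric_dtype(s):
            parts.append(s.to_numpy(dtype=float))
            names.append(c)
        else:
            # categorical -> indicator columns, first level as reference
            dummies = pd.get_dummies(s, prefix=c, drop_first=True)
            if c == trait and dummies.shape[1] != 1:
                raise AssociationError(
                    f"categorical trait {c!r} must have exactly two levels")
            for dc in dummies.columns:
                parts.append(dummies[dc].to_numpy(dtype=float))
                names.append(dc)
    return np.column_stack(parts), names


def linear_association(
    matrix: OmicsMatrix,
    metadata: pd.DataFrame,
    trait: str,
    covariates: Sequence[str] = ("age", "sex", "education"),
    adjust: str = "bonferroni",
) -> pd.DataFrame:
    """OLS of each feature on trait + covariates.

    Returns a table with the per-unit trait effect, t-statistic, two-sided
    p-value, adjusted p and the number of samples used (samplewise deletion
    of missing cells / covariates per feature).
    """
    meta = metadata.loc[matrix.sample_ids]
    X, names = _design_matrix(meta, trait, covariates)
    trait_col = 1  # first column after the intercept is the trait (or its indicator)
    base_ok = np.all(np.isfinite(X), axis=1)
    k = X.shape[1]
    if np.linalg.matrix_rank(X[base_ok]) < k:
        raise AssociationError(f"rank-deficient design; columns: {names}")

    rows = []
    Y = matrix.values
    for i, feat in enumerate(matrix.feature_ids):
        y = Y[i]
        ok = base_ok & np.isfinite(y)
        n = int(ok.sum())
        if n < k + 2:
            rows.append((feat, np.nan, np.nan, np.nan, n))
            continue
        Xi, yi = X[ok], y[ok]
        beta, _, rank, _ = np.linalg.lstsq(Xi, yi, rcond=None)
        if rank < k:
            rows.append((feat, np.nan, np.nan, np.nan, n))
            continue
        resid = yi - Xi @ beta
        dof = n - k
        sigma2 = float(resid @ resid) / dof
        xtx_inv = np.linalg.inv(Xi.T @ Xi)
        se = np.sqrt(max(sigma2 * xtx_inv[trait_col, trait_col], 0.0))
        if se == 0:
            t = np.inf if beta[trait_col] > 0 else (-np.inf if beta[trait_col] < 0 else 0.0)
            p = 0.0 if beta[trait_col] != 0 else 1.0
        else:
            t = float(beta[trait_col] / se)
            p = float(2.0 * stats.t.sf(abs(t), df=dof))
        rows.append((feat, float(beta[trait_col]), t, p, n))
    tab = pd.DataFrame(rows, columns=["feature", "effect", "t_statistic",
                                      "p_value", "n_used"])
    p = tab["p_value"].to_numpy()
    if adjust == "bonferroni":
        tab["adjusted_p"] = bonferroni(p)
    elif adjust == "bh":
        from .crossval import bh_fdr
        finite = np.isfinite(p)
        adj = np.full_like(p, np.nan)
        adj[finite] = bh_fdr(p[finite])
        tab["adjusted_p"] = adj
    else:
        raise AssociationError(f"unknown adjustment {adjust!r}")
    return tab


def bonferroni(p_values: Sequence[float]) -> np.ndarray:
    """min(p * m, 1), with m the number of (finite) tests."""
    p = np.asarray(p_values, dtype=float)
    finite = np.isfinite(p)
    if finite.any() and (np.nanmin(p) < 0 or np.nanmax(p) > 1):
        raise AssociationError("p-values must lie in [0, 1]")
    m = int(finite.sum())
    out = np.where(finite, np.minimum(p * m, 1.0), np.nan)
    return out


def statistic_concordance(table_a: pd.DataFrame, table_b: pd.DataFrame) -> dict:
    """Pearson r of t-statistics over shared features."""
    merged = table_a[["feature", "t_statistic"]].merge(
        table_b[["feature", "t_statistic"]], on="feature", suffixes=("_a", "_b"))
    merged = merged.dropna()
    if len(merged) < 3:
        raise AssociationError("need at least 3 shared features with statistics")
    r = float(np.corrcoef(merged["t_statistic_a"], merged["t_statistic_b"])[0, 1])
    return {"r": r, "n_shared": int(len(merged))}


def top_n_validation(discovery: pd.DataFrame, validation: pd.DataFrame,
                     n: int) -> dict:
    """Follow up the discovery top-N in the validation statistics.

    Picks the n smallest discovery p-values (ties broken by |t| then feature
    ID), counts validation features with the same effect sign, and those also
    at validation p < 0.05; the random baseline is the chance rate of sign
    agreement times the overall validation p < 0.05 fraction.
    """
    shared = discovery.merge(validation, on="feature", suffixes=("_d", "_v")).dropna(
        subset=["p_value_d", "p_value_v", "t_statistic_d", "t_statistic_v"])
    if n > len(shared):
        raise AssociationError(f"n={n} exceeds {len(shared)} shared features")
    shared = shared.sort_values(
        by=["p_value_d", "t_statistic_d", "feature"],
        key=lambda s: -s.abs() if s.name == "t_statistic_d" else s,
    )
    top = shared.head(n)
    same_sign = np.sign(top["t_statistic_d"]) == np.sign(top["t_statistic_v"])
    p05 = top["p_value_v"] < 0.05
    frac_p05_all = float((shared["p_value_v"] < 0.05).mean())
    return {
        "n": n,
        "direction_match": int(same_sign.sum()),
        "direction_and_p05": int((same_sign & p05).sum()),
        "random_baseline_rate": 0.5 * frac_p05_all,
    }


def fisher_enrichment(set_a: set, set_b: set, universe: set) -> tuple[float, float]:
    """One-sided Fisher's exact enrichment test of two gene sets.

    Returns (odds ratio, one-sided p), the p-value being the exact
    hypergeometric tail P(X >= overlap).  The odds ratio is the sample odds
    ratio with a Haldane 0.5 correction when a zero cell occurs.
    """
    universe = set(universe)
    if not universe:
        raise AssociationError("empty universe")
    a = set(set_a) & universe
    b = set(set_b) & universe
    n = len(universe)
    k = len(a & b)
    n11, n12 = k, len(a) - k
    n21 = len(b) - k
    n22 = n - len(a) - len(b) + k
    p = float(stats.hypergeom.sf(k - 1, n, len(a), len(b)))
    cells = np.array([n11, n12, n21, n22], dtype=float)
    if (cells == 0).any():
        cells = cells + 0.5
    odds = (cells[0] * cells[3]) / (cells[1] * cells[2])
    return float(odds), min(max(p, 0.0), 1.0)


def module_summary(matrix: OmicsMatrix,
                   module_assignments: Mapping[str, Sequence[str]]) -> pd.DataFrame:
    """Module expression: mean of z-scored member features, modules x samples."""
    import warnings

    idx = matrix.feature_index()
    vals = matrix.values
    with np.errstate(invalid="ignore"):
        mean = np.nanmean(vals, axis=1, keepdims=True)
        sd = np.nanstd(vals, axis=1, ddof=1, keepdims=True)
    z = (vals - mean) / np.where(sd > 0, sd, np.nan)
    rows = {}
    for mod, members in module_assignments.items():
        present = [m for m in members if m in idx]
        if not present:
            raise AssociationError(f"module {mod!r} has no features in the matrix")
        mrows = [idx[m] for m in present]
        zi = z[mrows, :]
        degenerate = [present[i] for i in range(len(present))
                      if np.all(np.isnan(zi[i]))]
        if degenerate:
            warnings.warn(f"module {mod!r}: zero-variance features excluded: "
                          f"{degenerate[:5]}")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            rows[mod] = np.nanmean(zi, axis=0)
    return pd.DataFrame(rows, index=matrix.sample_ids).T
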