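"""Leak-safe encoder input spaces: highly variable features or principal components.

A :class:`FeatureSpace` is fitted on an explicit set of samples and is a pure
function of those samples' values — by construction no held-out sample can
influence the selection, centering or loadings.  Two kinds are supported:

``hvg``
    The ``size`` largest-variance features over the fitting samples (unbiased
    sample variance, missing cells ignored; ties broken by feature ID).  At
    transform time the selected rows are z-scored with the fitting statistics;
    missing cells impute to the fitting mean, i.e. to 0 after scaling.

``pc``
    Top ``size`` principal components fitted on the fitting samples only
    (mean-centered SVD, orthonormal loadings).  Transform is the centered
    projection; missing cells impute to the center and so contribute 0.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .core import OmicsMatrix

__all__ = ["FeatureSpace", "fit_feature_space", "transform"]


class FeatureSpaceError(ValueError):
    pass


@dataclass
class FeatureSpace:
    source: str                      # which omics layer this space was fitted on
    kind: str                        # "hvg" | "pc"
    size: int
    fit_sample_ids: list[str]
    # hvg state
    selected_ids: list[str] | None = None
    means: np.ndarray | None = None          # per selected feature
    sds: np.ndarray | None = None
    # pc state
    feature_ids: list[str] | None = None     # ordering the loadings refer to
    centers: np.ndarray | None = None        # per feature
    loadings: np.ndarray | None = None       # (n_features, size), orthonormal cols
    eigenvalues: np.ndarray | None = None    # variance of each component on fit data

    @property
    def input_ids(self) -> list[str]:
        """Names of the encoder input columns this space produces."""
        if self.kind == "hvg":
            assert self.selected_ids is not None
            return list(self.selected_ids)
        return [f"PC{i + 1}" for i in range(self.size)]

    # -- serialization (JSON + .npz sidecar for arrays) --------------------
    def save(self, path) -> None:
        path = Path(path)
        arrays = {}
        meta = {
            "source": self.source,
            "kind": self.kind,
            "size": self.size,
            "fit_sample_ids": self.fit_sample_ids,
            "selected_ids": self.selected_ids,
            "feature_ids": self.feature_ids,
            "arrays": str(path.with_suffix(".npz").name),
        }
        for name in ("means", "sds", "centers", "loadings", "eigenvalues"):
            v = getattr(self, name)
            if v is not None:
                arrays[name] = v
        np.savez(path.with_suffix(".npz"), **arrays)
        path.write_text(json.dumps(meta, indent=1))

    @classmethod
    def load(cls, path) -> "FeatureSpace":
        path = Path(path)
        meta = json.loads(path.read_text())
        arrs = dict(np.load(path.parent / meta["arrays"]))
        return cls(
            source=meta["source"], kind=meta["kind"], size=meta["size"],
            fit_sample_ids=meta["fit_sample_ids"],
            selected_ids=meta["selected_ids"], feature_ids=meta["feature_ids"],
            **{k: arrs.get(k) for k in ("means", "sds", "centers", "loadings",
                                        "eigenvalues")},
        )


def _nan_mean_sd(values: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-row mean, unbiased sd and variance ignoring NaN (0 sd if degenerate)."""
    import warnings
    with np.errstate(invalid="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mean = np.nanmean(values, axis=1)
        n = np.sum(~np.isnan(values), axis=1)
        dev = values - mean[:, None]
        ss = np.nansum(dev * dev, axis=1)
        var = np.where(n > 1, ss / np.maximum(n - 1, 1), 0.0)
    mean = np.where(np.isnan(mean), 0.0, mean)
    return mean, np.sqrt(var), var


def fit_feature_space(
    matrix: OmicsMatrix,
    kind: str,
    size: int,
    fit_sample_ids: list[str],
    source: str = "mrna",
) -> FeatureSpace:
    """Fit an encoder input space using only ``fit_sample_ids``."""
    if kind not in ("hvg", "pc"):
        raise FeatureSpaceError(f"unknown feature-space kind {kind!r}")
    fit = matrix.subset_samples(fit_sample_ids)
    if kind == "hvg":
        if size > fit.n_features:
            raise FeatureSpaceError(
                f"requested {size} variable features but only {fit.n_features} available")
        mean, sd, var = _nan_mean_sd(fit.values)
        # stable selection: sort by (-variance, feature ID)
        order = sorted(range(fit.n_features), key=lambda i: (-var[i], fit.feature_ids[i]))
        top = order[:size]
        sds = sd[top]
        return FeatureSpace(
            source=source, kind="hvg", size=size, fit_sample_ids=list(fit_sample_ids),
            selected_ids=[fit.feature_ids[i] for i in top],
            means=mean[top], sds=np.where(sds > 0, sds, 1.0),
        )
    # pc
    max_rank = min(fit.n_features, len(fit_sample_ids))
    if size > max_rank:
        raise FeatureSpaceError(
            f"pc size {size} exceeds min(#features, #fit samples) = {max_rank}")
    mean, _, _ = _nan_mean_sd(fit.values)
    x = fit.values - mean[:, None]
    x = np.where(np.isnan(x), 0.0, x)          # missing -> center
    # SVD on samples x features
    u, s, vt = np.linalg.svd(x.T, full_matrices=False)
    # sign convention: largest-magnitude loading positive per component
    load = vt[:size].T                          # (features, size)
    for j in range(size):
        i = int(np.argmax(np.abs(load[:, j])))
        if load[i, j] < 0:
            load[:, j] = -load[:, j]
    eig = (s[:size] ** 2) / max(len(fit_sample_ids) - 1, 1)
    return FeatureSpace(
        source=source, kind="pc", size=size, fit_sample_ids=list(fit_sample_ids),
        feature_ids=list(fit.feature_ids), centers=mean, loadings=load, eigenvalues=eig,
    )


def transform(space: FeatureSpace, matrix: OmicsMatrix) -> np.ndarray:
    """Project a matrix into the space; returns samples x size array."""
    if space.kind == "hvg":
        idx = matrix.feature_index()
        missing = [f for f in space.selected_ids if f not in idx]
        if missing:
            raise FeatureSpaceError(f"matrix lacks required features {missing[:5]}")
        rows = np.array([idx[f] for f in space.selected_ids])
        vals = matrix.values[rows, :]
        z = (vals - space.means[:, None]) / space.sds[:, None]
        z = np.where(np.isnan(z), 0.0, z)       # impute to fitting mean
        return z.T
    idx = matrix.feature_index()
    missing = [f for f in space.feature_ids if f not in idx]
    if missing:
        raise FeatureSpaceError(f"matrix lacks required features {missing[:5]}")
    rows = np.array([idx[f] for f in space.feature_ids])
    x = matrix.values[rows, :] - space.centers[:, None]
    x = np.where(np.isnan(x), 0.0, x)
    return x.T @ space.loadings
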