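"""Expected-gradient (SHAP-style) attribution and contribution removal.

For a differentiable model f and a background distribution B, the expected
gradient of input i for sample x and a target output is

    phi_i(x) = E_{b ~ B, a ~ U(0,1)} [ (x_i - b_i) * df/dx_i(b + a (x - b)) ]

which satisfies local accuracy: sum_i phi_i(x) = f(x) - E_b[f(b)].  The inner
path integral over ``a`` is evaluated with Gauss-Legendre quadrature per
background sample; backgrounds are visited round-robin in a seeded random
order with equal weight, so with n_draws >= n_background every background
contributes and the attribution of a linear model is exact.

Attribution targets the final merged prediction, so encoder inputs (PCs) and
each target protein's own merge inputs are ranked on the same footing.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Protocol, Sequence

import numpy as np

from .core import MultiOmicsDataset, OmicsMatrix
from .model import TrainedSubmodel, _prepare_inputs

__all__ = [
    "AttributionResult",
    "DifferentiableModel",
    "LinearModel",
    "SubmodelPredictor",
    "expected_gradient_attribution",
    "check_local_accuracy",
    "rank_inputs",
    "remove_input_contribution",
    "variance_explained_delta",
]


class AttributionError(ValueError):
    pass


class DifferentiableModel(Protocol):
    """A model exposing values and input gradients for selected targets."""

    def value_and_grad(self, x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """x: (n, d) -> values (n, t) and gradients (n, d, t)."""
        ...


@dataclass
class LinearModel:
    """f(x) = x @ W + b, the closed-form reference for attribution tests."""

    weights: np.ndarray   # (d, t)
    bias: np.ndarray | float = 0.0

    def value_and_grad(self, x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        w = np.atleast_2d(self.weights)
        vals = x @ w + self.bias
        grads = np.broadcast_to(w[None, :, :], (x.shape[0], *w.shape)).copy()
        return vals, grads


class SubmodelPredictor:
    """Adapter exposing a trained submodel as a differentiable model.

    The input vector per sample is the concatenation of the encoder inputs
    with, for each target protein, its own merge features; the gradient of a
    target with respect to another target's merge features is zero.
    """

    def __init__(self, submodel: TrainedSubmodel, dataset: MultiOmicsDataset,
                 target_ids: Sequence[str]):
        self.submodel = submodel
        pid_index = {p: i for i, p in enumerate(submodel.protein_ids)}
        unknown = [t for t in target_ids if t not in pid_index]
        if unknown:
            raise AttributionError(f"unknown target proteins {unknown[:5]}")
        self.target_ids = list(target_ids)
        self.target_idx = [pid_index[t] for t in target_ids]
        enc, feats = _prepare_inputs(submodel, dataset)
        self._n_enc = enc.shape[1]
        self._sources = submodel.config.merge_sources
        self.input_ids = list(submodel.feature_space.input_ids) + [
            f"{src}:{t}" for t in self.target_ids for src in self._sources]
        self.inputs = np.concatenate(
            [enc] + [feats[src][:, [j]] for j in self.target_idx
                     for src in self._sources], axis=1)

    def _split(self, x: np.ndarray) -> tuple[np.ndarray, dict[str, np.ndarray]]:
        enc = x[:, : self._n_enc]
        feats = {src: np.zeros((x.shape[0], len(self.submodel.protein_ids)))
                 for src in self._sources}
        col = self._n_enc
        for j in self.target_idx:
            for src in self._sources:
                feats[src][:, j] = x[:, col]
                col += 1
        return enc, feats

    def value_and_grad(self, x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        net = self.submodel.network
        enc, feats = self._split(x)
        cache = net.forward(enc, feats, mode="infer")
        vals = cache["yhat"][:, self.target_idx]
        n, d, t = x.shape[0], x.shape[1], len(self.target_idx)
        grads = np.zeros((n, d, t))
        grads[:, : self._n_enc, :] = net.output_gradients(cache, self.target_idx)
        col = self._n_enc
        c = net.merge_weights()["c"]
        for k, j in enumerate(self.target_idx):
            for src in self._sources:
                grads[:, col, k] = c[src][j]
                col += 1
        return vals, grads


@dataclass
class AttributionResult:
    target_ids: list[str]
    input_ids: list[str]
    contributions: np.ndarray        # samples x inputs x targets
    baseline_prediction: np.ndarray  # per target: mean model output over background
    used_background_index: np.ndarray


def expected_gradient_attribution(
    model: DifferentiableModel,
    inputs: np.ndarray,
    background: np.ndarray,
    n_draws: int = 200,
    seed: int = 0,
    target_ids: Sequence[str] | None = None,
    input_ids: Sequence[str] | None = None,
) -> AttributionResult:
    """Expected-gradient contributions of every input to every target."""
    inputs = np.atleast_2d(np.asarray(inputs, dtype=float))
    background = np.atleast_2d(np.asarray(background, dtype=float))
    if background.shape[0] < 1:
        raise AttributionError("background must contain at least one sample")
    if n_draws < 1:
        raise AttributionError("n_draws must be >= 1")
    rng = np.random.default_rng(seed)
    n_bg = background.shape[0]
    if n_draws < n_bg:
        used = np.sort(rng.choice(n_bg, size=n_draws, replace=False))
        node_counts = np.ones(len(used), dtype=int)
    else:
        used = np.arange(n_bg)
        perm = rng.permutation(n_bg)
        node_counts = np.full(n_bg, n_draws // n_bg)
        node_counts[perm[: n_draws % n_bg]] += 1

    vals_x, _ = model.value_and_grad(inputs)
    n, d = inputs.shape
    t = vals_x.shape[1]
    contrib = np.zeros((n, d, t))
    baseline = np.zeros(t)
    for bi, m in zip(used, node_counts):
        b = background[bi]
        diff = inputs - b[None, :]
        nodes, weights = np.polynomial.legendre.leggauss(int(m))
        alphas = 0.5 * (nodes + 1.0)          # map to (0, 1)
        wts = 0.5 * weights                   # sum to 1
        est = np.zeros((n, d, t))
        for a, w in zip(alphas, wts):
            pts = b[None, :] + a * diff
            _, grads = model.value_and_grad(pts)
            est += w * grads * diff[:, :, None]
        contrib += est / len(used)
        vb, _ = model.value_and_grad(b[None, :])
        baseline += vb[0] / len(used)

    return AttributionResult(
        target_ids=list(target_ids) if target_ids is not None
        else [f"T{i}" for i in range(t)],
        input_ids=list(input_ids) if input_ids is not None
        else [f"X{i}" for i in range(d)],
        contributions=contrib,
        baseline_prediction=baseline,
        used_background_index=used,
    )


def check_local_accuracy(attr: AttributionResult, model: DifferentiableModel,
                         inputs: np.ndarray, eps: float = 1e-8) -> float:
    """Max relative deviation of sum(contributions) from f(x) - baseline."""
    inputs = np.atleast_2d(np.asarray(inputs, dtype=float))
    vals, _ = model.value_and_grad(inputs)
    total = attr.contributions.sum(axis=1)            # samples x targets
    delta = vals - attr.baseline_prediction[None, :]
    dev = np.abs(total - delta) / (np.abs(delta) + eps)
    return float(dev.max())


def rank_inputs(attr: AttributionResult, aggregation: str = "mean_abs"):
    """Inputs ordered by descending mean |contribution| (ties by input ID)."""
    if aggregation != "mean_abs":
        raise AttributionError(f"unknown aggregation {aggregation!r}")
    if attr.contributions.size == 0:
        raise AttributionError("empty attributions")
    score = np.abs(attr.contributions).mean(axis=(0, 2))
    order = sorted(range(len(attr.input_ids)),
                   key=lambda i: (-score[i], attr.input_ids[i]))
    return [(attr.input_ids[i], float(score[i])) for i in order]


def remove_input_contribution(
    predictions: np.ndarray, attr: AttributionResult, input_id: str | Sequence[str]
) -> np.ndarray:
    """Subtract the named input's contribution from predictions (samples x targets)."""
    names = [input_id] if isinstance(input_id, str) else list(input_id)
    idx = []
    for name in names:
        if name not in attr.input_ids:
            raise AttributionError(f"unknown input {name!r}")
        idx.append(attr.input_ids.index(name))
    adjusted = np.asarray(predictions, dtype=float).copy()
    for i in idx:
        adjusted = adjusted - attr.contributions[:, i, :]
    return adjusted


def _partial_r2(y: np.ndarray, trait: np.ndarray, covariates: np.ndarray | None) -> float:
    """Variance in y explained by trait after removing covariates (partial R^2)."""
    n = y.shape[0]
    if covariates is None or covariates.size == 0:
        c = np.ones((n, 1))
    else:
        c = np.column_stack([np.ones(n), covariates])
    py = y - c @ np.linalg.lstsq(c, y, rcond=None)[0]
    pt = trait - c @ np.linalg.lstsq(c, trait, rcond=None)[0]
    denom = float(py @ py)
    vt = float(pt @ pt)
    if vt == 0:
        raise AttributionError("trait is constant after covariate adjustment")
    if denom == 0:
        return 0.0
    beta = float(pt @ py) / vt
    resid = py - beta * pt
    return 1.0 - float(resid @ resid) / denom


def variance_explained_delta(
    original: np.ndarray,
    adjusted: np.ndarray,
    trait: np.ndarray,
    covariates: np.ndarray | None = None,
) -> np.ndarray:
    """Per-target drop in trait-explained variance after contribution removal.

    Returns, per target, 100 * (partial R^2 of the original prediction minus
    partial R^2 of the adjusted prediction), i.e. the input's contribution to
    the protein variance explained by the trait, in percent.
    """
    original = np.atleast_2d(np.asarray(original, dtype=float))
    adjusted = np.atleast_2d(np.asarray(adjusted, dtype=float))
    trait = np.asarray(trait, dtype=float)
    if np.std(trait) == 0:
        raise AttributionError("trait is constant")
    out = np.empty(original.shape[1])
    for j in range(original.shape[1]):
        r2_orig = _partial_r2(original[:, j], trait, covariates)
        r2_adj = _partial_r2(adjusted[:, j], trait, covariates)
        out[j] = 100.0 * (r2_orig - r2_adj)
    return out
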