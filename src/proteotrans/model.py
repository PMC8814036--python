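"""The translation submodel and its 12-member ensemble.

Each submodel maps a transcriptome representation to the proteome in two
blocks:

* a variational *encoder/decoder* block: the encoder input (top variable
  features or top principal components of one transcriptome layer) is encoded
  into a latent Gaussian (mu, logvar); a latent vector (sampled during
  training, the mean at inference) is decoded into a per-protein value
  ``d_g``;
* a per-protein *linear-regression merge* block: the final prediction for
  protein g in sample s is

      yhat[s, g] = a_g * d[s, g] + sum_f c_{g,f} * x[s, g, f] + b0_g

  where f ranges over the configured transcript features of the protein's own
  gene (mRNA, pre-mRNA, 3'UTR length).

Training minimizes masked MSE on z-scored protein targets plus a small
KL(N(mu, sigma) || N(0, 1)) penalty, jointly for both blocks but with two
Adam parameter groups (encoder/decoder at lr 0.001, merge at lr 0.01), early
stopping on a 10% validation split with patience 30 (defaults).

The ensemble averages the z-scored predictions of 12 submodels spanning
{mRNA, pre-mRNA, UTR} x {hvg, pc} encoder inputs x two merge-input sets.
"""

from __future__ import annotations

import copy
import itertools
import warnings
from dataclasses import dataclass, field, replace
from typing import Literal, Mapping, Sequence

import numpy as np

from ._nn import Adam, Linear, Param, ReLU, Sequential
from .core import MultiOmicsDataset, OmicsMatrix
from .features import FeatureSpace, fit_feature_space, transform

__all__ = [
    "SubmodelConfig",
    "LatentDistribution",
    "TrainedSubmodel",
    "EnsembleModel",
    "enumerate_submodels",
    "encode",
    "sample_latent",
    "decode",
    "lr_merge",
    "loss",
    "train_submodel",
    "predict",
    "ensemble_predict",
    "save_submodel",
    "load_submodel",
]

LOGVAR_CLAMP = 15.0
MERGE_SET_FULL = ("decoded", "mrna", "premrna", "utr")
MERGE_SET_MRNA = ("decoded", "mrna")


class ModelError(ValueError):
    pass


@dataclass(frozen=True)
class SubmodelConfig:
    encoder_source: Literal["mrna", "premrna", "utr"] = "mrna"
    encoder_representation: Literal["hvg", "pc"] = "pc"
    encoder_size: int | None = None          # None -> 5000 for hvg, 100 for pc
    lr_inputs: tuple[str, ...] = MERGE_SET_FULL
    latent_dim: int = 32
    hidden_dims: tuple[int, ...] = (800, 800)
    kl_weight: float = 0.005
    lr_scgen: float = 0.001
    lr_merge: float = 0.01
    max_epochs: int = 10000
    patience: int = 30
    validation_fraction: float = 0.10
    batch_size: int = 64
    seed: int = 0

    def __post_init__(self) -> None:
        # tolerate JSON-origin lists in a frozen, hashable dataclass
        object.__setattr__(self, "lr_inputs", tuple(self.lr_inputs))
        object.__setattr__(self, "hidden_dims", tuple(self.hidden_dims))
        if self.latent_dim < 1:
            raise ModelError("latent_dim must be >= 1")
        if self.patience < 1:
            raise ModelError("patience must be >= 1")
        if not (0 < self.validation_fraction < 1):
            raise ModelError("validation_fraction must be in (0,1)")
        if "decoded" not in self.lr_inputs:
            raise ModelError("lr_inputs must contain 'decoded'")
        if self.encoder_source not in ("mrna", "premrna", "utr"):
            raise ModelError(f"unknown encoder source {self.encoder_source!r}")
        if self.encoder_representation not in ("hvg", "pc"):
            raise ModelError(f"unknown representation {self.encoder_representation!r}")

    @property
    def resolved_encoder_size(self) -> int:
        if self.encoder_size is not None:
            return self.encoder_size
        return 5000 if self.encoder_representation == "hvg" else 100

    @property
    def merge_sources(self) -> tuple[str, ...]:
        return tuple(s for s in self.lr_inputs if s != "decoded")


def enumerate_submodels(
    overrides: Mapping | None = None,
) -> list[SubmodelConfig]:
    """The default 12-member grid, fully overridable.

    Default axes: encoder source in {mrna, premrna, utr} x representation in
    {hvg, pc} (6 encoder inputs) x two merge-input sets ({decoded, mrna,
    premrna, utr} and {decoded, mrna}).  ``overrides`` may replace any axis
    (``encoder_sources``, ``representations``, ``merge_sets``) and/or set
    shared config fields (``common``).
    """
    overrides = dict(overrides or {})
    sources = overrides.pop("encoder_sources", ("mrna", "premrna", "utr"))
    reps = overrides.pop("representations", ("hvg", "pc"))
    merge_sets = overrides.pop("merge_sets", (MERGE_SET_FULL, MERGE_SET_MRNA))
    common = dict(overrides.pop("common", {}))
    if overrides:
        raise ModelError(f"unknown override keys: {sorted(overrides)}")
    configs = [
        SubmodelConfig(encoder_source=src, encoder_representation=rep,
                       lr_inputs=tuple(ms), **common)
        for src, rep, ms in itertools.product(sources, reps, merge_sets)
    ]
    if len(set(configs)) != len(configs):
        raise ModelError("override produced duplicate submodel configs")
    return configs


@dataclass
class LatentDistribution:
    mu: np.ndarray       # samples x latent_dim
    logvar: np.ndarray   # samples x latent_dim, clamped to [-15, 15]


class TranslationNetwork:
    """Encoder trunk + (mu, logvar) heads, decoder, per-protein merge layer."""

    def __init__(self, n_enc_in: int, n_proteins: int,
                 merge_sources: Sequence[str], latent_dim: int,
                 hidden_dims: Sequence[int], rng: np.random.Generator):
        self.n_enc_in = n_enc_in
        self.n_proteins = n_proteins
        self.merge_sources = tuple(merge_sources)
        trunk: list = []
        prev = n_enc_in
        for h in hidden_dims:
            trunk += [Linear(prev, h, rng), ReLU()]
            prev = h
        self.trunk = Sequential(trunk)
        self.mu_head = Linear(prev, latent_dim, rng)
        self.logvar_head = Linear(prev, latent_dim, rng)
        dec: list = []
        prev = latent_dim
        for h in hidden_dims:
            dec += [Linear(prev, h, rng), ReLU()]
            prev = h
        dec.append(Linear(prev, n_proteins, rng))
        self.decoder = Sequential(dec)
        self.merge_a = Param(np.ones(n_proteins))
        self.merge_b0 = Param(np.zeros(n_proteins))
        self.merge_c = {src: Param(np.zeros(n_proteins)) for src in self.merge_sources}

    # parameter groups ------------------------------------------------------
    def scgen_params(self) -> list[Param]:
        return (self.trunk.params() + self.mu_head.params()
                + self.logvar_head.params() + self.decoder.params())

    def merge_params(self) -> list[Param]:
        return [self.merge_a, self.merge_b0, *self.merge_c.values()]

    def all_params(self) -> list[Param]:
        return self.scgen_params() + self.merge_params()

    def get_state(self) -> list[np.ndarray]:
        return [p.value.copy() for p in self.all_params()]

    def set_state(self, state: list[np.ndarray]) -> None:
        for p, v in zip(self.all_params(), state):
            p.value[...] = v

    # forward/backward ------------------------------------------------------
    def encode(self, enc_in: np.ndarray) -> LatentDistribution:
        if enc_in.shape[1] != self.n_enc_in:
            raise ModelError(
                f"encoder input has {enc_in.shape[1]} columns, expected {self.n_enc_in}")
        h = self.trunk.forward(enc_in)
        mu = self.mu_head.forward(h)
        logvar_raw = self.logvar_head.forward(h)
        self._clamp_mask = np.abs(logvar_raw) < LOGVAR_CLAMP
        return LatentDistribution(mu, np.clip(logvar_raw, -LOGVAR_CLAMP, LOGVAR_CLAMP))

    def forward(self, enc_in: np.ndarray, merge_feats: Mapping[str, np.ndarray],
                mode: str = "infer", rng: np.random.Generator | None = None) -> dict:
        dist = self.encode(enc_in)
        if mode == "train":
            if rng is None:
                raise ModelError("train mode requires an rng for the latent draw")
            eps = rng.standard_normal(dist.mu.shape)
            z = dist.mu + np.exp(0.5 * dist.logvar) * eps
        elif mode == "infer":
            eps = None
            z = dist.mu
        else:
            raise ModelError(f"unknown mode {mode!r}")
        decoded = self.decoder.forward(z)
        yhat = lr_merge(decoded, merge_feats, self.merge_weights())
        return {"dist": dist, "eps": eps, "z": z, "decoded": decoded,
                "merge_feats": merge_feats, "yhat": yhat, "mode": mode}

    def merge_weights(self) -> dict:
        return {"a": self.merge_a.value, "b0": self.merge_b0.value,
                "c": {src: p.value for src, p in self.merge_c.items()}}

    def backward(self, cache: dict, dyhat: np.ndarray,
                 dmu_extra: np.ndarray | None = None,
                 dlogvar_extra: np.ndarray | None = None) -> np.ndarray:
        """Backpropagate from d(loss)/d(yhat); returns d(loss)/d(encoder input)."""
        decoded = cache["decoded"]
        # merge layer
        self.merge_a.grad += (dyhat * decoded).sum(axis=0)
        self.merge_b0.grad += dyhat.sum(axis=0)
        for src, p in self.merge_c.items():
            p.grad += (dyhat * cache["merge_feats"][src]).sum(axis=0)
        dd = dyhat * self.merge_a.value[None, :]
        dz = self.decoder.backward(dd)
        dist: LatentDistribution = cache["dist"]
        dmu = dz.copy()
        if cache["mode"] == "train":
            dlogvar = dz * 0.5 * np.exp(0.5 * dist.logvar) * cache["eps"]
        else:
            dlogvar = np.zeros_like(dz)
        if dmu_extra is not None:
            dmu += dmu_extra
        if dlogvar_extra is not None:
            dlogvar += dlogvar_extra
        dlogvar = np.where(self._clamp_mask, dlogvar, 0.0)
        g = self.mu_head.backward(dmu) + self.logvar_head.backward(dlogvar)
        return self.trunk.backward(g)

    def output_gradients(self, cache: dict, targets: Sequence[int]) -> np.ndarray:
        """d(yhat[:, t])/d(encoder input) per target, infer mode.

        Returns an array (samples, n_enc_in, n_targets).  Gradients of a
        target with respect to its own merge features are the constant merge
        weights ``c`` and are handled by the caller.
        """
        n = cache["yhat"].shape[0]
        out = np.empty((n, self.n_enc_in, len(targets)))
        for j, t in enumerate(targets):
            seed = np.zeros_like(cache["yhat"])
            seed[:, t] = 1.0
            dd = seed * self.merge_a.value[None, :]
            dz = self.decoder.backward(dd)
            g = self.mu_head.backward(dz)
            out[:, :, j] = self.trunk.backward(g)
        return out


# ---------------------------------------------------------------------------
# functional pieces (also exposed for tests / small-scale use)
# ---------------------------------------------------------------------------

def encode(submodel: "TrainedSubmodel", enc_in: np.ndarray) -> LatentDistribution:
    return submodel.network.encode(enc_in)


def sample_latent(dist: LatentDistribution, mode: str = "infer",
                  seed: int | np.random.Generator = 0) -> np.ndarray:
    if mode == "infer":
        return dist.mu.copy()
    if mode != "train":
        raise ModelError(f"unknown mode {mode!r}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    eps = rng.standard_normal(dist.mu.shape)
    return dist.mu + np.exp(0.5 * dist.logvar) * eps


def decode(submodel: "TrainedSubmodel", latent: np.ndarray) -> np.ndarray:
    return submodel.network.decoder.forward(latent)


def lr_merge(decoded: np.ndarray, per_protein_features: Mapping[str, np.ndarray],
             merge_weights: Mapping) -> np.ndarray:
    """yhat[s,g] = a_g d[s,g] + sum_f c_{g,f} x[s,g,f] + b0_g."""
    yhat = decoded * np.asarray(merge_weights["a"])[None, :] \
        + np.asarray(merge_weights["b0"])[None, :]
    for src, c in merge_weights["c"].items():
        if src not in per_protein_features:
            raise ModelError(f"merge input {src!r} not supplied")
        yhat = yhat + per_protein_features[src] * np.asarray(c)[None, :]
    return yhat


def kl_term(dist: LatentDistribution) -> float:
    """Mean per-(sample, unit) KL(N(mu, exp(logvar)) || N(0, 1))."""
    kl = 0.5 * (np.exp(dist.logvar) + dist.mu ** 2 - 1.0 - dist.logvar)
    return float(kl.mean())


def loss(prediction: np.ndarray, target: np.ndarray, dist: LatentDistribution,
         kl_weight: float, missing_mask: np.ndarray | None = None) -> float:
    """Masked MSE over observed protein cells + kl_weight * mean KL."""
    if missing_mask is None:
        missing_mask = ~np.isnan(target)
    n_obs = int(missing_mask.sum())
    if n_obs == 0:
        raise ModelError("loss over a fully-masked batch is undefined")
    err = np.where(missing_mask, prediction - np.where(missing_mask, target, 0.0), 0.0)
    mse = float((err ** 2).sum() / n_obs)
    return mse + kl_weight * kl_term(dist)


# ---------------------------------------------------------------------------
# fitted model containers
# ---------------------------------------------------------------------------

@dataclass
class TrainedSubmodel:
    config: SubmodelConfig
    feature_space: FeatureSpace
    network: TranslationNetwork
    protein_ids: list[str]
    target_mean: np.ndarray              # per protein, training-split stats
    target_sd: np.ndarray
    merge_means: dict[str, np.ndarray]   # per source, per protein gene
    merge_sds: dict[str, np.ndarray]
    enc_mean: np.ndarray                 # encoder-input standardization
    enc_sd: np.ndarray                   # (training-split statistics)
    training_sample_ids: list[str]
    history: dict


@dataclass
class EnsembleModel:
    members: list[TrainedSubmodel]

    def __post_init__(self) -> None:
        if not self.members:
            raise ModelError("ensemble needs at least one member")
        ids0 = self.members[0].protein_ids
        for m in self.members[1:]:
            if m.protein_ids != ids0:
                raise ModelError("ensemble members predict different protein sets")

    @property
    def protein_ids(self) -> list[str]:
        return self.members[0].protein_ids


def _merge_feature_matrix(dataset: MultiOmicsDataset, source: str,
                          protein_ids: Sequence[str]) -> np.ndarray:
    """samples x proteins matrix of each protein gene's own value in a layer."""
    layer = dataset.layer(source)
    idx = layer.feature_index()
    n = len(layer.sample_ids)
    out = np.full((n, len(protein_ids)), np.nan)
    for j, pid in enumerate(protein_ids):
        i = idx.get(pid)
        if i is not None:
            out[:, j] = layer.values[i, :]
    return out


def _scale_merge_features(raw: np.ndarray, mean: np.ndarray, sd: np.ndarray) -> np.ndarray:
    z = (raw - mean[None, :]) / sd[None, :]
    return np.where(np.isnan(z), 0.0, z)   # missing genes contribute 0


def train_submodel(
    dataset: MultiOmicsDataset,
    config: SubmodelConfig,
    feature_fit_sample_ids: Sequence[str] | None = None,
) -> TrainedSubmodel:
    """Fit one submodel on an aligned dataset with protein targets.

    ``feature_fit_sample_ids`` restricts the samples used to fit the encoder
    feature space (leak avoidance in cross-validation); defaults to the
    training samples themselves.
    """
    if dataset.protein is None:
        raise ModelError("training requires a protein layer")
    samples = dataset.sample_ids
    if len(samples) < 20:
        raise ModelError("training requires at least 20 samples")

    ss = np.random.SeedSequence(config.seed).spawn(3)
    rng_split, rng_init, rng_train = [np.random.default_rng(s) for s in ss]

    # encoder feature space (leak-safe: fitted only on the stated samples)
    fit_ids = list(feature_fit_sample_ids) if feature_fit_sample_ids is not None \
        else list(samples)
    size = min(config.resolved_encoder_size,
               dataset.layer(config.encoder_source).n_features
               if config.encoder_representation == "hvg"
               else min(dataset.layer(config.encoder_source).n_features, len(fit_ids)))
    space = fit_feature_space(dataset.layer(config.encoder_source),
                              config.encoder_representation, size, fit_ids,
                              source=config.encoder_source)
    enc_raw = transform(space, dataset.layer(config.encoder_source))

    protein_ids = list(dataset.protein.feature_ids)
    y_raw = dataset.protein.values.T                     # samples x proteins

    # validation split (seeded)
    n = len(samples)
    n_val = max(1, int(round(config.validation_fraction * n)))
    perm = rng_split.permutation(n)
    val_idx, tr_idx = perm[:n_val], perm[n_val:]
    if len(tr_idx) < 1:
        raise ModelError("no training samples left after validation split")

    # standardize encoder inputs (keeps the network on unit scale regardless
    # of the representation's natural scale; PC scores can be large)
    enc_mean = enc_raw[tr_idx].mean(axis=0)
    enc_sd = enc_raw[tr_idx].std(axis=0, ddof=1)
    enc_sd = np.where(enc_sd > 0, enc_sd, 1.0)
    enc_all = (enc_raw - enc_mean[None, :]) / enc_sd[None, :]

    # per-protein target scaling from the training split
    tr_y = y_raw[tr_idx]
    with np.errstate(invalid="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        t_mean = np.nanmean(tr_y, axis=0)
        t_sd = np.nanstd(tr_y, axis=0, ddof=1)
    t_mean = np.where(np.isnan(t_mean), 0.0, t_mean)
    t_sd = np.where((t_sd > 0) & np.isfinite(t_sd), t_sd, 1.0)
    y = (y_raw - t_mean[None, :]) / t_sd[None, :]
    mask = ~np.isnan(y)
    y = np.where(mask, y, 0.0)

    # merge features scaled with training-split statistics
    merge_means: dict[str, np.ndarray] = {}
    merge_sds: dict[str, np.ndarray] = {}
    merge_all: dict[str, np.ndarray] = {}
    for src in config.merge_sources:
        raw = _merge_feature_matrix(dataset, src, protein_ids)
        with np.errstate(invalid="ignore"), warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            m = np.nanmean(raw[tr_idx], axis=0)
            s = np.nanstd(raw[tr_idx], axis=0, ddof=1)
        s = np.where((s > 0) & np.isfinite(s), s, 1.0)
        merge_means[src], merge_sds[src] = m, s
        merge_all[src] = _scale_merge_features(raw, m, s)

    net = TranslationNetwork(
        n_enc_in=enc_all.shape[1], n_proteins=len(protein_ids),
        merge_sources=config.merge_sources, latent_dim=config.latent_dim,
        hidden_dims=config.hidden_dims, rng=rng_init,
    )
    opt = Adam([(net.scgen_params(), config.lr_scgen),
                (net.merge_params(), config.lr_merge)])

    def eval_val() -> float:
        feats = {src: merge_all[src][val_idx] for src in config.merge_sources}
        cache = net.forward(enc_all[val_idx], feats, mode="infer")
        return loss(cache["yhat"], np.where(mask[val_idx], y[val_idx], np.nan),
                    cache["dist"], config.kl_weight, mask[val_idx])

    best_val = np.inf
    best_state = net.get_state()
    best_epoch = 0
    bad = 0
    train_hist: list[float] = []
    val_hist: list[float] = []
    n_latent = config.latent_dim

    for epoch in range(1, config.max_epochs + 1):
        order = rng_train.permutation(tr_idx)
        ep_loss = 0.0
        n_batches = 0
        for start in range(0, len(order), config.batch_size):
            bi = order[start:start + config.batch_size]
            bmask = mask[bi]
            if not bmask.any():
                continue
            feats = {src: merge_all[src][bi] for src in config.merge_sources}
            cache = net.forward(enc_all[bi], feats, mode="train", rng=rng_train)
            dist = cache["dist"]
            err = np.where(bmask, cache["yhat"] - y[bi], 0.0)
            n_obs = bmask.sum()
            mse = float((err ** 2).sum() / n_obs)
            batch_loss = mse + config.kl_weight * kl_term(dist)
            if not np.isfinite(batch_loss):
                raise ModelError(f"non-finite training loss at epoch {epoch}")
            opt.zero_grad()
            dyhat = 2.0 * err / n_obs
            denom = dist.mu.size
            dmu = config.kl_weight * dist.mu / denom
            dlogvar = config.kl_weight * 0.5 * (np.exp(dist.logvar) - 1.0) / denom
            net.backward(cache, dyhat, dmu_extra=dmu, dlogvar_extra=dlogvar)
            opt.step()
            ep_loss += batch_loss
            n_batches += 1
        train_hist.append(ep_loss / max(n_batches, 1))
        v = eval_val()
        val_hist.append(v)
        if not np.isfinite(v):
            raise ModelError(f"non-finite validation loss at epoch {epoch}")
        if v < best_val - 1e-12:
            best_val = v
            best_state = net.get_state()
            best_epoch = epoch
            bad = 0
        else:
            bad += 1
            if bad >= config.patience:
                break

    net.set_state(best_state)
    history = {"train_loss": train_hist, "val_loss": val_hist,
               "best_epoch": best_epoch, "stopped_epoch": len(val_hist),
               "best_val_loss": best_val}
    return TrainedSubmodel(
        config=config, feature_space=space, network=net, protein_ids=protein_ids,
        target_mean=t_mean, target_sd=t_sd,
        merge_means=merge_means, merge_sds=merge_sds,
        enc_mean=enc_mean, enc_sd=enc_sd,
        training_sample_ids=list(samples), history=history,
    )


def save_submodel(submodel: TrainedSubmodel, directory) -> None:
    """Persist a trained submodel as a checkpoint directory.

    Layout: config.json, feature_space.json (+ .npz arrays), weights.npz,
    scaling.json (target and merge-feature statistics, training samples,
    history).
    """
    import json
    from dataclasses import asdict
    from pathlib import Path

    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    (d / "config.json").write_text(json.dumps(asdict(submodel.config)))
    submodel.feature_space.save(d / "feature_space.json")
    state = submodel.network.get_state()
    np.savez(d / "weights.npz", **{f"p{i}": v for i, v in enumerate(state)})
    scaling = {
        "protein_ids": submodel.protein_ids,
        "target_mean": submodel.target_mean.tolist(),
        "target_sd": submodel.target_sd.tolist(),
        "merge_means": {k: v.tolist() for k, v in submodel.merge_means.items()},
        "merge_sds": {k: v.tolist() for k, v in submodel.merge_sds.items()},
        "enc_mean": submodel.enc_mean.tolist(),
        "enc_sd": submodel.enc_sd.tolist(),
        "training_sample_ids": submodel.training_sample_ids,
        "history": submodel.history,
    }
    (d / "scaling.json").write_text(json.dumps(scaling))


def load_submodel(directory) -> TrainedSubmodel:
    """Load a checkpoint written by :func:`save_submodel`."""
    import json
    from pathlib import Path

    d = Path(directory)
    cfg_raw = json.loads((d / "config.json").read_text())
    config = SubmodelConfig(**cfg_raw)
    space = FeatureSpace.load(d / "feature_space.json")
    scaling = json.loads((d / "scaling.json").read_text())
    net = TranslationNetwork(
        n_enc_in=space.size, n_proteins=len(scaling["protein_ids"]),
        merge_sources=config.merge_sources, latent_dim=config.latent_dim,
        hidden_dims=config.hidden_dims, rng=np.random.default_rng(0),
    )
    weights = np.load(d / "weights.npz")
    net.set_state([weights[f"p{i}"] for i in range(len(weights.files))])
    return TrainedSubmodel(
        config=config, feature_space=space, network=net,
        protein_ids=list(scaling["protein_ids"]),
        target_mean=np.asarray(scaling["target_mean"]),
        target_sd=np.asarray(scaling["target_sd"]),
        merge_means={k: np.asarray(v) for k, v in scaling["merge_means"].items()},
        merge_sds={k: np.asarray(v) for k, v in scaling["merge_sds"].items()},
        enc_mean=np.asarray(scaling["enc_mean"]),
        enc_sd=np.asarray(scaling["enc_sd"]),
        training_sample_ids=list(scaling["training_sample_ids"]),
        history=scaling["history"],
    )


def _prepare_inputs(submodel: TrainedSubmodel, dataset: MultiOmicsDataset
                    ) -> tuple[np.ndarray, dict[str, np.ndarray]]:
    enc = transform(submodel.feature_space, dataset.layer(submodel.config.encoder_source))
    enc = (enc - submodel.enc_mean[None, :]) / submodel.enc_sd[None, :]
    feats = {}
    for src in submodel.config.merge_sources:
        raw = _merge_feature_matrix(dataset, src, submodel.protein_ids)
        feats[src] = _scale_merge_features(raw, submodel.merge_means[src],
                                           submodel.merge_sds[src])
    return enc, feats


def predict(submodel: TrainedSubmodel, dataset: MultiOmicsDataset) -> OmicsMatrix:
    """Deterministic prediction (latent mean), on the original protein scale."""
    enc, feats = _prepare_inputs(submodel, dataset)
    cache = submodel.network.forward(enc, feats, mode="infer")
    pred = cache["yhat"] * submodel.target_sd[None, :] + submodel.target_mean[None, :]
    return OmicsMatrix(list(submodel.protein_ids), list(dataset.sample_ids), pred.T)


def _zscore_rows(values: np.ndarray) -> np.ndarray:
    mean = values.mean(axis=1, keepdims=True)
    sd = values.std(axis=1, ddof=1, keepdims=True)
    sd = np.where(sd > 0, sd, 1.0)
    return (values - mean) / sd


def ensemble_predict(ensemble: EnsembleModel, dataset: MultiOmicsDataset) -> OmicsMatrix:
    """Equal-weight mean of the members' per-protein z-scored predictions."""
    acc = None
    for member in ensemble.members:
        pred = predict(member, dataset)
        scaled = _zscore_rows(pred.values)
        acc = scaled if acc is None else acc + scaled
    acc /= len(ensemble.members)
    return OmicsMatrix(list(ensemble.protein_ids), list(dataset.sample_ids), acc)
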