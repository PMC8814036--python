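"""Synthetic paired multi-omics generator with known ground truth.

The generator embodies the assumptions under which transcriptome-to-proteome
translation is both hard and possible:

* a low-dimensional latent *tissue state* ``z`` drives all omics layers —
  mRNA, pre-mRNA and 3'UTR length are noisy linear read-outs of ``z``;
* each protein couples weakly to its own mRNA (per-gene coupling ``c_g``)
  and diffusely to the tissue state (loadings ``w_g``), plus independent
  measurement noise, so the per-gene mRNA–protein correlation is low
  (~0.1) even though the proteome is largely predictable from the
  transcriptome as a whole;
* a planted one-dimensional disease progression ``t`` in [0, 1] tilts the
  first latent coordinate and generates clinical milestone curves (amyloid,
  tau, cognitive impairment) as logistic functions of ``t`` with staggered
  centers;
* optional *stage modules*: blocks of proteins whose abundance follows a
  logistic of ``t`` centered at each clinical milestone, giving ground-truth
  early/mid/late module labels for trajectory staging.

A separate replicate-measurement model expresses measured protein abundance
as ``p = b*x + N(0, sigma^2)`` — a phenotype effect plus independent noise —
which reproduces the dissociation between low between-platform abundance
correlation and high effect-estimate concordance.

All randomness flows from a single seed through ``numpy.random.SeedSequence``
spawning, so sub-streams (latent state, loadings, each noise layer, ...) are
independent and the output is bit-identical under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .core import OmicsMatrix, MultiOmicsDataset

__all__ = [
    "GenerativeConfig",
    "NoiseModelConfig",
    "SyntheticTruth",
    "simulate_dataset",
    "simulate_replicate_pair",
    "expected_replicate_correlation",
    "solve_noise_sd_for_mean_correlation",
    "analytic_mrna_protein_correlation",
]


class ConfigError(ValueError):
    pass


def _logistic(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


@dataclass(frozen=True)
class GenerativeConfig:
    """Parameters of the paired multi-omics generator.

    Defaults are the conditions of the translation benchmark: 600 samples,
    2000 genes of which 1000 have a measured protein, a 10-dimensional tissue
    state, and noise levels placing the mean per-gene mRNA-protein Pearson
    correlation near 0.10.
    """

    n_samples: int = 600
    n_genes: int = 2000
    n_proteins: int = 1000
    latent_dim_true: int = 10
    loading_scale: float = 1.0
    coupling_mean: float = 0.15        # per-gene mRNA->protein coupling c_g ~ N(mean, sd)
    coupling_sd: float = 0.05
    mrna_noise_sd: float = 1.0
    premrna_noise_sd: float = 1.2      # extra noise on the shared latent signal
    utr_noise_sd: float = 1.0
    protein_noise_sd: float = 3.0
    trait_effect_sd: float = 0.3       # per-protein diagnosis effect b_g ~ N(0, sd)
    progression_weight: float = 0.8    # strength of planted progression in latent dim 0
    milestone_times: tuple[float, float, float] = (0.2, 0.5, 0.8)
    milestone_slope: float = 10.0      # logistic slope of the clinical curves
    pathology_noise_sd: float = 0.05   # measurement noise on the clinical scores
    utr_missing_fraction: float = 0.2  # fraction of genes with UTR length missing
    stage_module_size: int = 0         # proteins per planted stage module (0 = off)
    stage_module_amplitude: float = 4.0
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_samples, self.n_genes, self.n_proteins,
               self.latent_dim_true) < 1:
            raise ConfigError("all counts must be >= 1")
        if self.n_proteins > self.n_genes:
            raise ConfigError("n_proteins must not exceed n_genes")
        a, b, c = self.milestone_times
        if not (0 < a < b < c < 1):
            raise ConfigError("milestone_times must be strictly increasing in (0,1)")
        if min(self.mrna_noise_sd, self.premrna_noise_sd, self.utr_noise_sd) <= 0:
            raise ConfigError("noise sds must be positive")
        if self.protein_noise_sd < 0:
            raise ConfigError("protein_noise_sd must be >= 0")
        if not (0 <= self.utr_missing_fraction < 1):
            raise ConfigError("utr_missing_fraction must be in [0, 1)")
        if 3 * self.stage_module_size > self.n_proteins:
            raise ConfigError("stage modules cannot cover more proteins than exist")

    # Named study conditions -------------------------------------------------
    @classmethod
    def translation_benchmark(cls, seed: int = 0) -> "GenerativeConfig":
        """Conditions of the out-of-fold translation-gain experiment."""
        return cls(seed=seed)

    @classmethod
    def trajectory_benchmark(cls, seed: int = 0) -> "GenerativeConfig":
        """Strong planted progression with stage modules for pseudotime work."""
        return cls(
            n_samples=500, n_genes=1200, n_proteins=600, latent_dim_true=10,
            progression_weight=4.0, protein_noise_sd=1.5,
            stage_module_size=60, stage_module_amplitude=8.0, seed=seed,
        )


@dataclass(frozen=True)
class NoiseModelConfig:
    """Replicate-measurement model p = b*x + N(0, sigma^2)."""

    n_samples: int = 400
    n_proteins: int = 1000
    effect_sd: float = 1.0
    noise_sd: float = 1.0
    phenotype_type: Literal["binary", "continuous"] = "binary"
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_samples, self.n_proteins) < 1:
            raise ConfigError("counts must be >= 1")
        if self.noise_sd < 0:
            raise ConfigError("noise_sd must be >= 0")
        if self.phenotype_type not in ("binary", "continuous"):
            raise ConfigError("phenotype_type must be binary or continuous")


@dataclass
class SyntheticTruth:
    """Ground truth accompanying a simulated dataset."""

    latent_states: np.ndarray            # samples x latent_dim
    true_pseudotime: np.ndarray          # per-sample, in [0, 1]
    per_gene_coupling: np.ndarray        # per protein: c_g
    noiseless_protein: OmicsMatrix
    true_effects: np.ndarray             # per protein: b_g
    gene_loadings: np.ndarray            # genes x latent_dim (mRNA signal loadings)
    protein_latent_loadings: np.ndarray  # proteins x latent_dim (w_g)
    phenotype: np.ndarray                # the x used for the b_g * x term (diagnosis)
    module_assignments: dict[str, list[str]] = field(default_factory=dict)
    module_stages: dict[str, str] = field(default_factory=dict)


def simulate_dataset(config: GenerativeConfig) -> tuple[MultiOmicsDataset, SyntheticTruth]:
    """Draw one paired multi-omics dataset plus its ground truth."""
    cfg = config
    streams = np.random.SeedSequence(cfg.seed).spawn(12)
    (r_t, r_z, r_load, r_coup, r_w, r_mn, r_pn, r_un, r_prn, r_eff, r_demo,
     r_mod) = [np.random.default_rng(s) for s in streams]

    n, g, p, d = cfg.n_samples, cfg.n_genes, cfg.n_proteins, cfg.latent_dim_true
    samples = [f"S{i:04d}" for i in range(n)]
    genes = [f"G{i:04d}" for i in range(g)]

    t = r_t.uniform(0.0, 1.0, size=n)
    t_std = (t - 0.5) * np.sqrt(12.0)          # unit-variance progression score
    z = r_z.standard_normal((n, d))
    z[:, 0] = z[:, 0] + cfg.progression_weight * t_std

    L = r_load.standard_normal((g, d)) * cfg.loading_scale
    signal = L @ z.T                            # genes x samples, shared latent signal
    mrna = signal + r_mn.standard_normal((g, n)) * cfg.mrna_noise_sd
    premrna = signal + r_pn.standard_normal((g, n)) * cfg.premrna_noise_sd

    Lu = r_load.standard_normal((g, d)) * cfg.loading_scale
    utr = Lu @ z.T + r_un.standard_normal((g, n)) * cfg.utr_noise_sd
    n_missing = int(round(cfg.utr_missing_fraction * g))
    if n_missing:
        missing_genes = r_un.choice(g, size=n_missing, replace=False)
        utr[missing_genes, :] = np.nan          # gene-level missingness

    # proteins: the first n_proteins genes carry a measured protein
    c = r_coup.normal(cfg.coupling_mean, cfg.coupling_sd, size=p)
    W = r_w.standard_normal((p, d)) * cfg.loading_scale
    b = r_eff.normal(0.0, cfg.trait_effect_sd, size=p)

    m_amyloid, m_tau, m_cog = cfg.milestone_times
    diagnosis = (t >= m_tau).astype(float)      # tau-onset proxy for case status

    # a stage module's progression dependence IS its planted sigmoid: remove
    # the linear progression channel from its members' latent loadings so the
    # module trend is not confounded by the global trend
    if cfg.stage_module_size > 0:
        W[: 3 * cfg.stage_module_size, 0] = 0.0

    noiseless = (c[:, None] * mrna[:p, :] + W @ z.T + b[:, None] * diagnosis[None, :])

    module_assignments: dict[str, list[str]] = {}
    module_stages: dict[str, str] = {}
    if cfg.stage_module_size > 0:
        stages = ["early", "mid", "late"]
        for k, (stage, center) in enumerate(zip(stages, cfg.milestone_times)):
            lo = k * cfg.stage_module_size
            members = list(range(lo, lo + cfg.stage_module_size))
            sign = 1.0 if r_mod.random() < 0.5 else -1.0
            curve = _logistic(cfg.milestone_slope * (t - center))
            noiseless[members, :] += sign * cfg.stage_module_amplitude * curve[None, :]
            mid = f"M{stage}"
            module_assignments[mid] = [genes[i] for i in members]
            module_stages[mid] = stage

    protein = noiseless + r_prn.standard_normal((p, n)) * cfg.protein_noise_sd

    def _score(center: float) -> np.ndarray:
        return (_logistic(cfg.milestone_slope * (t - center))
                + r_demo.normal(0.0, cfg.pathology_noise_sd, size=n))

    amyloid = _score(m_amyloid)
    tau = _score(m_tau)
    cognition = _score(m_cog)
    metadata = pd.DataFrame(
        {
            "diagnosis": diagnosis.astype(int),
            "amyloid": amyloid,
            "tau": tau,
            "cognition": cognition,
            "global_pathology": 0.5 * (amyloid + tau),
            "cognitive_slope": -cognition + r_demo.normal(0.0, 0.1, size=n),
            "age": r_demo.normal(85.0, 5.0, size=n),
            "sex": r_demo.integers(0, 2, size=n),
            "education": r_demo.normal(16.0, 2.0, size=n),
        },
        index=pd.Index(samples, name="sample_id"),
    )

    dataset = MultiOmicsDataset(
        mrna=OmicsMatrix(genes, samples, mrna),
        premrna=OmicsMatrix(genes, samples, premrna),
        utr=OmicsMatrix(genes, samples, utr),
        protein=OmicsMatrix(genes[:p], samples, protein),
        metadata=metadata,
    )
    truth = SyntheticTruth(
        latent_states=z, true_pseudotime=t, per_gene_coupling=c,
        noiseless_protein=OmicsMatrix(genes[:p], samples, noiseless),
        true_effects=b, gene_loadings=L, protein_latent_loadings=W,
        phenotype=diagnosis,
        module_assignments=module_assignments, module_stages=module_stages,
    )
    return dataset, truth


def analytic_mrna_protein_correlation(
    config: GenerativeConfig, truth: SyntheticTruth
) -> np.ndarray:
    """Closed-form per-gene Pearson r(mRNA_g, protein_g) from the drawn coefficients.

    Valid when ``progression_weight == 0`` so the latent state is standard
    normal and independent of the phenotype; the phenotype term then only adds
    variance.  r_g = cov / (sd_m * sd_p) with

        var_m = |l_g|^2 + s_m^2
        cov   = c_g * var_m + l_g . w_g
        var_p = c_g^2 var_m + 2 c_g (l_g . w_g) + |w_g|^2 + b_g^2 var(x) + s_p^2
    """
    if config.progression_weight != 0:
        raise ValueError("closed form requires progression_weight == 0")
    p = config.n_proteins
    l = truth.gene_loadings[:p]
    w = truth.protein_latent_loadings
    c = truth.per_gene_coupling
    b = truth.true_effects
    x = truth.phenotype
    var_x = x.var()
    l2 = np.sum(l * l, axis=1)
    lw = np.sum(l * w, axis=1)
    w2 = np.sum(w * w, axis=1)
    var_m = l2 + config.mrna_noise_sd ** 2
    cov = c * var_m + lw
    var_p = c ** 2 * var_m + 2 * c * lw + w2 + b ** 2 * var_x + config.protein_noise_sd ** 2
    return cov / np.sqrt(var_m * var_p)


# ---------------------------------------------------------------------------
# Replicate-measurement noise model
# ---------------------------------------------------------------------------

def simulate_replicate_pair(
    config: NoiseModelConfig,
) -> tuple[OmicsMatrix, OmicsMatrix, pd.Series, np.ndarray]:
    """Two replicate protein measurements sharing the same b*x signal.

    Returns (rep1, rep2, phenotype, true effects b).  Both replicates are
    ``b_g * x_s`` plus independent N(0, sigma^2) noise.
    """
    cfg = config
    streams = np.random.SeedSequence(cfg.seed).spawn(4)
    r_x, r_b, r_n1, r_n2 = [np.random.default_rng(s) for s in streams]
    n, p = cfg.n_samples, cfg.n_proteins
    samples = [f"S{i:04d}" for i in range(n)]
    proteins = [f"P{i:04d}" for i in range(p)]

    if cfg.phenotype_type == "binary":
        x = np.zeros(n)
        x[r_x.permutation(n)[: n // 2]] = 1.0   # balanced case-control analog
    else:
        x = r_x.standard_normal(n)
    b = r_b.normal(0.0, cfg.effect_sd, size=p)
    signal = b[:, None] * x[None, :]
    rep1 = signal + r_n1.standard_normal((p, n)) * cfg.noise_sd
    rep2 = signal + r_n2.standard_normal((p, n)) * cfg.noise_sd
    return (
        OmicsMatrix(proteins, samples, rep1),
        OmicsMatrix(proteins, samples, rep2),
        pd.Series(x, index=samples, name="phenotype"),
        b,
    )


def expected_replicate_correlation(b: np.ndarray, var_x: float, noise_sd: float) -> np.ndarray:
    """Per-protein expected correlation between replicates: b^2 v / (b^2 v + s^2)."""
    b = np.asarray(b, dtype=float)
    sig = b * b * var_x
    denom = sig + noise_sd ** 2
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.where(denom > 0, sig / denom, 1.0)
    return r


def solve_noise_sd_for_mean_correlation(
    b: np.ndarray, var_x: float, target_mean_r: float
) -> float:
    """Noise sd at which the closed-form mean replicate correlation hits a target."""
    if not (0 < target_mean_r < 1):
        raise ValueError("target must be in (0, 1)")

    def f(sd: float) -> float:
        return float(expected_replicate_correlation(b, var_x, sd).mean()) - target_mean_r

    lo, hi = 1e-9, 1.0
    while f(hi) > 0:
        hi *= 2.0
        if hi > 1e6:
            raise RuntimeError("could not bracket noise sd")
    return float(brentq(f, lo, hi, xtol=1e-12))
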