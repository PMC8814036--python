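# Methods

## Translation model

Each submodel is a two-block network. The *encoder/decoder block* maps an
encoder input u (one transcriptome representation) through a feed-forward
trunk to two linear heads producing μ(u) and log σ²(u) (log-variance clamped
to [−15, 15]); during training z = μ + exp(logvar/2)·ε with ε ~ N(0, I), at
inference z = μ, so predictions are deterministic and downstream statistics
are reproducible. The decoder maps z through the same hidden widths to one
value d_g per protein. The *merge block* is a per-protein linear regression
ŷ_g = a_g d_g + Σ_f c_{g,f} x_{g,f} + β0_g over the gene's own transcript
features (mRNA, pre-mRNA, 3′UTR length), z-scored with training statistics;
a gene missing from a layer contributes 0 after scaling (its mean), so
prediction still covers it.

The loss is the masked mean-squared error over observed protein cells of the
final merged prediction (joint end-to-end training — the two distinct
learning rates imply a single objective) plus kl_weight × mean per-unit
KL(N(μ, σ²) ‖ N(0, 1)), KL = ½(σ² + μ² − 1 − log σ²). Defaults: latent 32,
hidden (800, 800), kl_weight 0.005, batch 64, Adam lr 0.001
(encoder/decoder) and 0.01 (merge), max 10000 epochs, early stopping with
patience 30 on a seeded 10% validation split, best-epoch weights restored.
kl_weight is small because the decoder targets a *different* modality
(translation, not reconstruction), so the latent prior acts only as a mild
regularizer. Protein targets are z-scored per protein with training-split
statistics (inverted at prediction). Encoder inputs are standardized with
training-split statistics internally; PC scores otherwise enter at the scale
of their eigenvalues and destabilize initialization. A decoder-level loss
variant was considered and rejected: the merge layer would then never shape
the representation.

The network (dense layers, ReLU, Adam, backprop, input gradients) is
implemented directly in numpy; the models here are small enough that a
deep-learning framework would add nothing but a dependency, and explicit
backpropagation supplies the input-level gradients attribution needs.

The ensemble enumerates {mRNA, pre-mRNA, UTR} × {HVG(5000), PC(100)} × two
merge-input sets ({decoded, mRNA, pre-mRNA, UTR}, {decoded, mRNA}) = 12
configurations, each fully overridable. Member predictions are z-scored per
protein (each member's own statistics) before equal-weight averaging, so no
member dominates through scale. Input-layer ablations are expressed purely
through grid overrides; the merge is linear, so zeroing an input equals
zeroing its weight.

## Feature spaces and leakage control

HVG selection takes the `size` largest unbiased sample variances (missing
cells ignored, ties broken by feature ID); PC spaces store the centering
vector and orthonormal loadings fitted by SVD. Both are pure functions of
the stated fitting samples — in cross-validation, feature spaces are fitted
on non-holdout samples only, and a tripwire test asserts bit-identical
spaces when held-out samples are perturbed. Missing values impute to the
fitting mean at transform time (0 after centering/z-scoring), neutral under
linear projection. Whether HVG inputs should be z-scored before encoding is
not externally fixed; z-scoring was chosen so both representations enter on
comparable scales.

## Out-of-fold evaluation

Stratified folds cross categorical columns with tertile-binned continuous
ones (default: diagnosis × global-pathology tertiles), shuffle within
stratum and deal round-robin, so fold sizes within each stratum differ by at
most one. For each fold the whole grid is retrained without it and the
ensemble predicts the holdout; per-fold per-protein z-scoring precedes
concatenation. Concordance uses Pearson r per protein with a one-sided
(positive) t-test p-value — the discovery claim is positive concordance —
and Benjamini–Hochberg FDR. Association scans use two-sided OLS t-tests.

## Attribution

Expected gradients: φ_i(x) = E_{b,α}[(x_i − b_i) · ∂f/∂x_i(b + α(x − b))].
The α-integral is evaluated with Gauss–Legendre nodes per background sample;
backgrounds are visited round-robin in a seeded order and weighted equally,
which makes linear-model attributions exact whenever n_draws ≥ n_background
and gives near-machine local accuracy on smooth models at the default
n_draws = 200 (background 100). On ReLU networks quadrature accuracy is
limited by kinks; the decomposition still holds to a few percent of the
prediction scale. Attribution targets the final merged prediction, so
encoder PCs and a protein's own merge inputs are ranked on one footing
(mean |contribution|, ties by input ID). Removing an input's contribution
subtracts it from the prediction; removal is linear and order-independent.
Contribution-to-association is quantified as the drop (in percentage points)
of the trait's partial R², after covariate adjustment, between original and
adjusted predictions.

## Trajectory and staging

Pseudotime: top 40 centered PCs → kNN graph (k = 10, Euclidean, union
symmetrization, binary weights, ties by sample index) → eigenvectors 2..3 of
the symmetric normalized Laplacian (degree-renormalized; only the largest
component is embedded if the graph is disconnected) → a principal path
seeded by 3 k-means centers ordered for minimal polyline length, densified
with midpoints, and refined by moving vertices toward tricube-weighted local
means along arc length under a 0.1 smoothing pull (tolerance 1e-6); terminal
segments are extended so extreme samples are not clamped to endpoints.
Pseudotime is arc-length position min-max normalized to [0, 1]; orientation
is arbitrary unless an anchor column (e.g. global pathology) is supplied, in
which case the anchor increases along pseudotime.

LOESS is a tricube-weighted local polynomial of degree 2 (span 0.75,
100-point grid), exact on polynomials up to its degree. A curve's milestone
is the first grid time where it has altered 25% of its overall variation
(max − min of the fitted curve). Staging compares module milestones with the
amyloid/tau/cognition milestones: early ≤ amyloid < mid ≤ tau < late ≤
cognition, else unspecified. Two numerical rules are deliberate choices
where no canonical rule exists: (1) monotonicity is movement-weighted —
counter-trend movement above 15% of total movement marks a curve
non-monotone (noisy monotone curves sit near 0, a sine at 50%, so the
separation is wide); (2) milestone comparisons carry a guard band of 5 grid
steps, absorbing the crossing-estimation noise and the small systematic
range inflation that degree-2 LOESS edge overshoot induces in noisy module
curves (a module crossing *at* a milestone is a tie, resolved to the earlier
stage). Both scales are far below the inter-milestone spacing, so modules
genuinely inside a stage window are unaffected.

LMG relative importance averages each predictor's sequential R² gain over
all predictor orderings (subset-R² cached; capped at 6 predictors); shares
sum to the full-model R², and orthogonal predictors receive exactly their
marginal R².

## Synthetic data generator

The generator draws a latent tissue state z ∈ R^10 per sample; mRNA,
pre-mRNA and UTR length are linear read-outs L·z plus independent Gaussian
noise (pre-mRNA shares the mRNA signal with its own noise; a seeded gene
subset has UTR length missing for all samples). Protein g is
c_g·mRNA_g + w_g·z + b_g·x + noise: weak direct coupling
(c_g ~ N(0.15, 0.05²)), diffuse tissue-state dependence, a per-protein
phenotype effect, and measurement noise. A planted progression t ~ U(0, 1)
tilts the first latent coordinate by progression_weight × standardized t;
clinical scores (amyloid, tau, cognitive impairment) are logistics of t with
slope 10, centers (0.2, 0.5, 0.8) and measurement noise (sd 0.05); diagnosis
is t ≥ tau-center. All randomness flows from one seed through
`SeedSequence.spawn`, so sub-streams are independent and output is
bit-identical per seed.

Two named conditions are used throughout. The *translation benchmark*
(600 samples, 2000 genes, 1000 proteins, protein noise sd 3.0) places the
mean per-gene mRNA–protein correlation near 0.10 — the closed form
r_g = cov/(sd·sd) from the drawn coefficients is exposed for verification.
The *trajectory benchmark* (500 samples, progression weight 4 so the
planted ordering is recoverable in principle at Spearman ≈ 0.97, protein
noise sd 1.5) plants three 60-protein stage modules whose abundance is an
amplitude-8 logistic of t at each clinical milestone; module members carry
no loading on the progression coordinate, so a module's progression
dependence is exactly its planted sigmoid rather than a mixture with the
global linear trend.

The replicate-measurement model p = b·x + N(0, σ²) generates two replicates
sharing identical effects; per-protein replicate correlation has the closed
form b²Var(x)/(b²Var(x) + σ²), and a solver returns the σ achieving a target
mean correlation (0.20 in the benchmark). Because noise is independent of
the phenotype, OLS effect estimates between replicates correlate near 0.99
even when abundances correlate at 0.20 — the dissociation that justifies
doing association studies on noisy or estimated proteomes.

What the generator does *not* emulate: read counts and their mean–variance
structure, isoform-level structure, batch effects, cell-type deconvolution,
non-linear gene regulation, or realistic missingness patterns in proteomics.
Passing tests therefore demonstrate that the implementation is correct and
that the method behaves as designed under its own assumptions — not that
those assumptions hold in any particular real tissue.

## Benchmark scales and numerical choices

Benchmark networks use latent 16, one hidden layer of 64, HVG 500 / PC 100,
epoch cap 100 with patience 10 — sizes chosen so the full 10-fold ×
12-submodel experiment completes in a few minutes on one CPU while leaving
the measured properties far from their thresholds (measured translation gain
≈ 0.59 against a required 0.05). Degenerate cases: zero-variance features
are never selected as HVGs and are excluded from module summaries with a
warning; zero-variance targets scale by 1; fully masked loss batches raise;
constant traits and rank-deficient designs raise with the offending columns
named. Known limitations: single-trajectory (non-branching) pseudotime only;
plain OLS t-statistics rather than moderated (empirical-Bayes) statistics;
attribution assumes encoder inputs are approximately independent, which
holds for PCs but not for HVG inputs — rankings on HVG submodels should be
read qualitatively.
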