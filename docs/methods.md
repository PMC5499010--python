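# Methods

## The model and the two artifact mechanisms

Bulk deconvolution regresses a sample's expression vector on a signature
matrix `X` (genes × cell types) and interprets the coefficients as
cell-type fractions under the constraints `f ≥ 0`, `Σ f = 1`. This package
studies two ways that pipeline manufactures negative correlations between
estimated fractions across a cohort:

- **Closure.** Any fixed-sum constraint makes the components of the
  estimate compositional. For two components closed onto the 2-simplex,
  `g1 + g2 = 1` identically, so `corr(g1, g2) = −1` regardless of the joint
  distribution of the underlying pair. With 22 components the effect is
  diluted but persistent: mass gained by one component is lost by the
  ensemble of others.
- **Collinearity.** If two signature columns are similar (profile
  correlation r), the design is ill-conditioned — for two standardized
  columns the condition number is `sqrt((1+r)/(1−r))`, i.e. 1 at r = 0 and
  ≈ 4.36 at r = 0.9. The data cannot identify how signal splits between the
  columns, so their coefficients are anti-coupled sample by sample, which
  both inflates their sampling variance and drives their cross-sample
  correlation negative, on top of the closure baseline.

The mixture experiments hold everything fixed except the planted profile
correlation of the focal pair (0 vs 0.9) and compare the estimate–estimate
correlation at identical seeds.

## Synthetic data

**Profiles.** Expression profiles are moment-matched lognormal (default
mean 10, SD 10 in linear-scale expression units): strictly positive and
right-skewed, the shape of linear-scale signature values. A pair with a
controlled Pearson correlation is built from a shared standard-normal base
vector and an independent one; the latent mixing coefficient is driven by
bisection until the *achieved sample correlation* matches the target
(default tolerance ±0.02), so targets are met by construction, not on
average. With lognormal marginals the Fréchet lower bound caps achievable
negative correlations near −0.48; unreachable targets raise an error that
reports the achievable range. Background (unconstrained) columns are
redrawn against a `2.2/sqrt(n_genes)` correlation bound with every
already-placed column, so "near-independent" is a guarantee (|r| < 0.1 at
500 genes), not a hope.

**Mixtures.** Each cohort mixes exactly two cell types:
`Y_i = f1_i·X1 + f2_i·X2 + ε_i`, fractions independent Uniform(0, 0.5)
(midpoint constants 0.25/0.25 in fixed mode), `ε` i.i.d. Gaussian per gene
with a single global SD equal to the sample SD of `X1` across genes — a
deliberately noisy regime in which the signal component's SD is at most
half the noise SD. A per-gene-proportional noise variant exists behind a
flag for sensitivity analysis. Mixtures are not clipped at zero: the
solvers standardize the data, and clipping would distort the stated noise
model (a `clip` flag exists for solvers needing non-negative input). All
generators are bit-reproducible given their seed.

**Tumor cohorts.** Per sample, expression is
`purity·malignant + (1−purity)·immune mixture + |N(0, σ)|` with purity
Uniform(0.2, 0.95) (spanning typical tumor purity without degenerate
endpoints) and immune weights renormalized to sum to one. The malignant
profile is zero except on a random `⌈q·n_genes⌉` subset where it equals
`malignant_magnitude ×` that gene's mean signature expression (defaults
q = 0.25 — a quarter of signature genes not immune-specific — and
magnitude 2). Default noise SD is 10% of the mean signature expression.
Genes planted into the malignant profile correlate positively with purity;
purely immune genes correlate negatively (their contribution is scaled by
1 − purity).

**What the generator does not emulate.** Real signature matrices have
marker structure (each gene high in one or two cell types) and a block of
mutually correlated columns (e.g. seven T-cell subsets); the synthetic
background columns are mutually independent by design. There is no
count/library-size noise, no batch effects, and no read-level simulation.
Passing tests therefore demonstrate the statistical mechanisms, not
performance on any particular real cohort; the experiment runners accept a
real signature TSV for that purpose.

## Solvers

- **svr** — linear-kernel ν-SVR (scikit-learn), regularization constant
  C = 1, ν grid {0.25, 0.5, 0.75}, model selected by lowest RMSE between
  fitted and observed standardized mixture, ties broken toward the smallest
  ν for determinism. The mixture vector is z-scored across genes; the
  signature matrix is standardized by its grand mean and grand SD. The
  grand-SD choice (rather than per-column z-scoring) is deliberate:
  per-column scaling multiplies coefficient j by `sd(X_j)`, which distorts
  the recovered proportions on any signature whose columns differ in
  spread, breaking even noiseless two-component recovery. Negative
  coefficients are clipped to zero *then* the vector is renormalized —
  order matters and is tested. All-zero coefficient vectors are flagged
  degenerate (never silently NaN), excluded pairwise from correlation
  summaries and counted in the report; coercing them to uniform would
  fabricate anticorrelation.
- **nnls** — `scipy.optimize.nnls` on unstandardized values, no sum
  constraint. Its raw coefficients are the closure-free reference point.
- **cls** — least squares over the probability simplex, solved by the
  standard weighted-row reduction (the sum-to-one equality appended as a
  row weighted 10⁶ × the data scale, then non-negative least squares, then
  exact renormalization). Verified against 1-D grid search at 10⁻³ and
  noiseless recovery at 10⁻⁶.

## Statistics

Spearman is Pearson on midranks (scipy `rankdata`); this identity is tested
exactly, including ties. The partial Spearman correlation given a
conditioning variable z uses the partial-correlation-of-ranks formula
`(r_xy − r_xz·r_yz)/sqrt((1−r_xz²)(1−r_yz²))` on midrank-transformed data —
numerically simpler than, and tested to 10⁻¹⁰ against, regressing ranks on
ranks and correlating residuals. Denominators within 10⁻¹² of zero (a
variable rank-degenerate in z) raise an undefined-correlation error, as do
constant inputs everywhere: undefined correlations are reported as missing,
never coerced to 0. The purity ranking counts `r > 0` strictly, with no
significance filter, and ranks constant genes last with missing r.

## Experiment design and problem sizes

Experiments run at 22 cell types, 500-sample cohorts and 10 seed
replicates, reporting the headline correlation as mean ± SD across
replicates (a single-cohort correlation under ν-SVR is itself a random
variable). Synthetic signatures use 250 genes: ν-SVR training cost grows
roughly quadratically in the gene count, and 250 genes keeps a full 10-seed
experiment to a few minutes on one CPU while leaving the gene:cell-type
ratio (≈ 11:1) in the regime of published signature matrices. The
variance-inflation comparison (fixed truth, planted ρ ∈ {0, 0.5, 0.9})
uses 200-sample cohorts for the same reason. Seed replicates are derived
from the base seed via `numpy.random.SeedSequence`, so every run is
reproducible end to end and report files are byte-identical across
re-runs of the same config.

## Known limitations

- The fixed-fraction design (constant truth, all variation from noise)
  does not reliably produce negative estimate–estimate correlations on
  *independent-background* synthetic signatures: the pairwise closure pull
  (negative) is nearly cancelled by a common-denominator effect in which
  high-noise samples push mass onto the 20 background columns, shrinking
  both focal estimates together (positive coupling). The net is ≈ 0 at 250
  genes and mildly positive at 500. On real signature matrices, whose
  background columns are correlated with the focal ones, the reported
  strong negative correlations are plausible; with a real signature file
  supplied, the same runner executes that design unchanged.
- The ν-SVR settings mirror the published description of the
  CIBERSORT-style pipeline, but the exact preprocessing of the original
  online service is not recoverable; comparisons to its reported
  correlations are therefore qualitative, with tolerance.
- No permutation p-values, absolute mode, or quantile normalization; no
  gene-symbol remapping or log transformation in signature I/O.
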