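# Methods

This note records the statistical model, the defaults and the design
choices made where the design was genuinely open, in enough detail to
reproduce or audit any stage.

## Additive cis model and two-stage fitting

Expression enters the model after three normalizations: median-of-ratios
size factors (computed on genes with strictly positive counts in every
sample; no pseudo-reference fallback is implemented, a degenerate matrix
fails loudly), a per-gene rank-based inverse normal transform (INT), and,
after covariate regression, a second INT of the residuals. The INT uses
the Blom offset c = 3/8, Φ⁻¹((rank − c)/(n − 2c + 1)), with average ranks
on ties; the offset is configurable. Because the INT is rank-based it is
invariant to any monotone rescaling of its input, so the first INT is
applied directly to normalized counts without a log step.

Stage 1 regresses each gene's INT expression on an intercept, genotype
PCs (default 5), hidden expression factors (default 15), sex, and the
gene's somatic state: extreme copy-number code in {−1, 0, +1} and
inactivating-mutation indicator in {0, 1}. Constant somatic columns are
dropped with a log note; any remaining rank deficiency is an error that
names the collinear columns. Stage 2 regresses the re-normalized
residuals on each cis variant separately (±1 Mb around the gene body,
inclusive; minor allele count ≥ 5 on hard calls rounded from dosage).
This two-stage scheme slightly miscounts degrees of freedom relative to a
joint per-variant fit; that is accepted as the price of the fast scan, as
is usual for permutation-based cis mappers, and the permutation
calibration absorbs the approximation.

Hidden factors are the top principal components of the standardized
log2(normalized + 1) matrix. PCA plays the role a Bayesian factor model
(PEER-style) plays in older pipelines: absorbing broad technical and
biological variation. PCs are cheaper, deterministic, and in cohorts of
this size capture the same directions; the count is configurable and
should be reduced for small gene panels (the tests use 5 factors for a
25-gene fixture, since 15 PCs of a 25-gene matrix would absorb individual
gene signal rather than shared variation).

All PCA outputs fix signs by making each component's largest-magnitude
loading positive, so repeated runs are bit-identical.

## Permutation pass and Beta approximation

Gene-level significance uses the minimum nominal p over cis variants,
calibrated by permuting the phenotype: `n_perm_min` (default 1,000)
permutations are drawn; if fewer than 30 permuted minima undercut the
observed minimum, permutations continue to `n_perm_max` (default 10,000).
The empirical p uses the (1 + hits)/(1 + N) estimator so it is never
zero. The permuted minima are then fitted with a Beta(α, β) distribution
by maximum likelihood — method-of-moments start, Newton refinement on the
digamma/trigamma score, falling back to the moment estimates with a log
warning if Newton fails — and the adjusted p is the Beta CDF at the
observed minimum. For k independent null variants the minimum of k
uniform p-values is exactly Beta(1, k), which anchors the approximation;
correlated variants shift the effective k downward and the fit tracks
that. The Beta extrapolation is what gives adjusted p-values below the
1/N permutation resolution for strong effects.

Permutations are vectorized: permuted phenotypes are correlated against
the centered dosage matrix in chunked matrix products, and the minimum p
per permutation is derived from the maximum |correlation| (the t statistic
is monotone in |r| at fixed df).

## Storey q-values

π₀ is estimated on the λ grid 0.05…0.95 (step 0.05) via
π₀(λ) = #{p > λ}/(m(1 − λ)) and extrapolated to λ → 1 with a cubic
polynomial smoother, clipped to (0, 1]. For families smaller than 100
tests the smoother is unstable, so the fixed λ = 0.5 estimator is used
instead (logged). Setting π₀ = 1 reproduces Benjamini–Hochberg exactly,
which the tests assert against statsmodels. eGenes are q ≤ 0.05; somQTL
coefficients (per gene-predictor, t tests within the stage-1 style joint
model) share the same correction. somQTL significance is per coefficient,
not per gene omnibus — matching the additive model in which each somatic
term has its own effect.

## Allelic fold change

Effect sizes on the biological scale use
aFC = log2((β₀ + 2β₁)/β₀) from a linear-space fit of covariate-adjusted
normalized expression on dosage; covariates are removed on the log2 scale
and the adjustment re-centered before back-transforming. Values are
clamped to ±log2(100); a non-positive fitted homozygous-reference mean
(β₀ ≤ 0 or β₀ + 2β₁ ≤ 0) yields NaN with a log flag.

## Interaction model

The purity-interaction model adds centered purity and genotype × centered
purity to the stage-1 design and tests the product coefficient.
Centering decorrelates the main and product terms; because the genotype
main effect is in the model, the product-term coefficient and its p are
identical with or without centering (an OLS invariance the tests assert
numerically). The per-variant fit uses Frisch–Waugh–Lovell projection:
nuisance terms (intercept, covariates, somatic, purity) are projected out
once per gene, and each variant's (genotype, interaction) block is solved
as a 2×2 system.

Gene-level calibration permutes the genotype rows jointly across samples,
which preserves the purity–expression–covariate relationship and tests
exactly the hypothesis "no genotype-linked structure", with the same
adaptive stop and Beta machinery as the cis pass. The permutation loop
stays in BLAS by permuting the small left-hand factors instead of the
dosage matrix (Mᵀ P G = (Pᵀ M)ᵀ G) and by exploiting that the projected
phenotype is orthogonal to the nuisance basis. ieGenes use Storey q ≤ 0.10,
reflecting the interaction test's intrinsically low power: with purity
concentrated around 0.7 (see below) the product term carries far less
identifiable variance than the main effect.

Significant genes are classified by splitting samples at the 1/3 and 2/3
purity quantiles (linear interpolation, boundary ties to the lower
tertile, ≥ 10 samples per tertile required) and regressing expression on
the lead dosage separately in the low and high tertiles at nominal
α = 0.05 per side. This threshold is configurable; it is a reading of a
figure-level convention rather than a published rule. A caveat worth
stating: when purity is bounded well away from zero, an effect strictly
proportional to purity retains most of its magnitude in the low tertile,
so with realistic purity spreads the "high-purity-only" label is rare
even for genuinely tumor-restricted effects — the low-tertile regression
is simply also significant. The classification is most informative for
effects restricted to the *minority* cell compartment.

## Synthetic cohorts

The generator emulates the data-generating process the model assumes,
one synthetic chromosome with genes tiled at 500 kb spacing (gene body
10 kb) and variant positions uniform; each gene must have ≥ 50 cis
variants or generation fails naming the deficit. Dosages are
Hardy–Weinberg hard calls from per-variant frequencies uniform on the
configured MAF range (default 0.05–0.5), plus bounded uniform noise
(±0.05) mimicking imputation uncertainty.

Latent log-expression per gene is
baseline + hidden factors + somatic shifts + cis term + N(0, σ²) noise,
with defaults σ_hidden = σ_resid = 0.6 (5 hidden factors), somatic shift
±1 latent SD (amplification up, deletion and mutation down, rates
2%/2%/3% per gene-sample), and baselines spanning ~50–2,000 expected
counts. The cis term is β·d for shared effects, β·d·ρ for
tumor-restricted and β·d·(1 − ρ) for stroma-restricted effects (ρ =
purity); β is calibrated per gene so the cis term explains `effect_r2`
(default 0.1) of the *latent* variance. Counts are negative-binomial
(gamma–Poisson) with dispersion 0.1 — the standard bulk RNA-seq
observation model — and log-normal library-size multipliers (σ = 0.3) so
size-factor estimation is non-trivial. Purity is Beta(5, 2) truncated to
[0.1, 0.99], emulating consensus-purity-like spread. Mutation tables
draw CCFs around configurable subclone modes (default 1.0/0.5/0.25,
SD 0.04), assign local copy number from {1, 2, 3, 4}, and convert to VAFs
by the mixture identity VAF = CCF·ρ·m/(ρ·CNt + (1 − ρ)·CNn), optionally
with binomial read sampling at depth 200. The truth registry records
every injected effect and each gene's realized latent variance fractions.

What the generator does **not** emulate — LD between variants, batch
effects beyond linear hidden factors, trans effects, purity-correlated
expression programs beyond the injected terms, mapping or quantification
artifacts — bounds what passing tests show: they validate the inference
machinery under the stated model, not robustness to real-data pathologies.
Two consequences of the stated model are worth knowing. First, because β
is calibrated on latent variance, the NB observation layer makes the
realized R² on the mapped phenotype somewhat smaller than `effect_r2`,
so full-generator power at a given `effect_r2` is below what the same R²
on the tested phenotype would give. Second, the truncated-Beta purity has
variance ≈ 0.026, which makes purity-interaction effects weakly
identified at a few hundred samples — matching the field's experience
that interaction eQTL detection needs laxer thresholds.

## Numerical and reproducibility choices

- Lead-variant ties (equal minimum p) break to the smaller genomic
  position, then lexicographic id — determinism, not biology.
- Empirical p estimator (1 + x)/(1 + N); adjusted p clipped to
  (tiny, 1].
- Mean imputation of residual missing dosages after QC preserves the
  allele frequency and is the simplest contract for already-imputed data.
- Genotype QC defaults: MAF ≥ 0.01, per-variant missingness ≤ 0.95 (the
  lax cap is deliberate and exposed as a parameter; per-sample
  missingness ≤ 0.025 is the operative filter), imputation r² ≥ 0.3 when
  present. A generic per-call quality mask stands in for array-specific
  call-quality filtering.
- Gene filter: TPM ≥ 0.1 and count ≥ 6 jointly in ≥ 20% of samples, all
  boundaries inclusive. Outlier samples: > 3 SD on any of the first 6
  PCs of log2(normalized + 1); the variance-stabilizing transform this
  stands in for serves the same screening role.
- Variance partitioning is a fixed-effect semi-partial R² decomposition:
  fraction of group G = (RSS₋G − RSS_full)/TSS floored at 0, residual =
  RSS_full/TSS, renormalized to sum to 1. For mutually orthogonal groups
  this equals the marginal R² decomposition exactly. A mixed-model
  decomposition with random effects would shrink estimates for
  high-cardinality categorical predictors; for the numeric, low-dimension
  designs used here the fixed-effect version agrees and is transparent.
- MATH defaults to the verbatim ratio MAD/median (no 1.4826 consistency
  constant, no ×100); the conventional scaled variant is available via
  `scaled=True`. CCF defaults: CN_normal = 2, CN_tumor = 2 and
  multiplicity = 1 when absent; values in (1, 1.5] are retained as
  flagged super-clonal artifacts, larger values clamp at 1.5.
- Jaccard similarity scaling is min–max over off-diagonal pairs; if all
  off-diagonal values tie, scaled values are 0 with a log note.
- Pipeline stage seeds are master_seed + CRC-32(stage name) mod 2³¹, so
  stages rerun in isolation reproduce the full run. All result TSVs are
  byte-identical across reruns of the same config (fixed float format,
  `NA` for missing).
- Problem sizes in the test-suite: the oracle-equivalence check uses 50
  genes × 10,000 permutations at n = 200; FDR/power uses 5 × 300 genes;
  interaction calibration uses 10,000 single-variant nulls and 300
  gene-level nulls; the end-to-end run uses 200 samples × 200 genes ×
  5,000 variants. These sizes make every Monte-Carlo bound tight enough
  to be meaningful while keeping the whole suite in a few minutes.

## Known limitations

- No LD-aware fine-mapping, conditional secondary signals or trans
  analysis; the lead variant is a statistical representative, not a
  causal call.
- The interaction pass assumes purity enters linearly; saturating or
  threshold cell-composition effects would be mis-specified.
- The tertile classification inherits the low power of subgroup testing
  and, as noted above, is asymmetric between minority- and
  majority-compartment effects under realistic purity distributions.
- Storey's smoother needs a few hundred tests to be stable; small
  families silently switch to the fixed-λ estimator (logged).
- The fixed-effect variance decomposition attributes shared variance of
  correlated predictor groups to neither group (both semi-partial
  contributions shrink); interpret fractions for correlated designs with
  care.
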