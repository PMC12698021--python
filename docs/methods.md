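# Methods

This note documents the models, estimators and design choices behind
`pangls`, in the order the pipeline runs them.

## Phylogenetic covariance and Pagel's λ

A rooted tree with branch lengths induces the Brownian-motion covariance
V, where V_ij is the path length from the root to the most recent common
ancestor of tips i and j and the diagonal holds root-to-tip depths.  The
root's own stem edge, if present, is excluded: shared history is counted
from the MRCA of the tips under analysis, so pruning an outgroup does not
leak a constant into every entry of V.  Trees need not be ultrametric.

Pagel's λ multiplies the off-diagonal of V, interpolating between
phylogenetic independence (λ = 0) and full Brownian covariance (λ = 1).
The search is bounded to [0, 1] even where V would admit λ > 1, matching
the conventional corPagel bounds and the fixed 0/1 alternatives used in
model selection.

## GLS estimation

`gls_fit` whitens through the Cholesky factor of V rather than inverting
it; a ridge of 10⁻¹⁰·mean(diag V) is added only if factorization fails, and
is logged.  The reported log-likelihood profiles σ² at its maximum-
likelihood value,

    lnL = −½ [ n·ln(2π σ̂²_ML) + ln|V| + n ],   σ̂²_ML = rᵀV⁻¹r / n,

so that models with λ profiled, λ = 0 and λ = 1 are comparable on a single
AIC scale.  This is a deliberate divergence from the REML default of
`nlme::gls`-style software: REML likelihoods with different covariance
structures but a common design are comparable, but mixing REML with the
fixed-λ ML alternatives is not, and ML keeps the AIC bookkeeping honest.  A
`reml=True` flag is available for comparison.  Reported standard errors use
the small-sample divisor n − p (σ̂²_adj), the usual GLS software convention;
both variance estimates are recorded.

λ is profiled by bounded scalar optimization (tolerance 10⁻⁶), with both
endpoints always evaluated.  A profile flat to within 10⁻⁷ log-likelihood
units reports λ̂ = 0 with a `profile_flat` flag — parsimony tie-break;
otherwise a star tree would return an arbitrary λ.  On trees with ≤ 6 tips
the optimizer agrees with a dense grid search (step 10⁻⁴) to 10⁻³.

A near-perfect fit (residual variance below 10⁻¹² of the whitened trait
variance) raises a "degenerate likelihood" error rather than returning an
unbounded likelihood.

## Signal tests

Pagel's λ for a single trait uses the intercept-only model and the
likelihood-ratio statistic 2(lnL(λ̂) − lnL(0)) against the upper tail of
χ²₁.  Because λ̂ lies on the boundary half the time under the null, the
test is conservative (measured type-I error ≈ 0.01 at α = 0.05 on 48-tip
trees); λ̂ = 0 reports p = 1 exactly.

Blomberg's K follows the ratio-of-mean-squares construction: the
phylogenetic mean ā = (1ᵀV⁻¹y)/(1ᵀV⁻¹1), MSE₀ = (y−ā)ᵀ(y−ā)/(n−1),
MSE = (y−ā)ᵀV⁻¹(y−ā)/(n−1), and K is MSE₀/MSE divided by its Brownian
expectation (tr V − n/1ᵀV⁻¹1)/(n−1).  On a star tree with unit branches K
is exactly 1 for any non-constant trait.  The p-value is the
add-one-corrected upper tail over tip-label permutations,
(1 + #{K_perm ≥ K_obs})/(n_perm + 1), deterministic for a fixed seed; the
permutation statistics are computed vectorized against a single
pre-factorized V⁻¹.

## The association screen

Orthogroups enter the screen when their copy-number variance across genomes
(population variance, divisor n) exceeds 0.25 and they are present
(count ≥ 1) in at least ⌈0.25·n_genomes⌉ genomes.  The variance threshold
0.25 follows the procedural description of the emulated workflow; a
conflicting mention of 0.2 elsewhere in its narrative was not adopted.  The
prevalence rule rounds up, so "a quarter of 48" means 12.

Each analyzed orthogroup is fit under the three error structures with
design [1, x].  AIC counts intercept, slope and σ², plus one for a profiled
λ; exact AIC ties go to the model with fewer parameters (when λ̂ = 0 the
free model's AIC is exactly the fixed model's plus 2, and the fixed model
is selected).  The robustness filters are applied to the selected model:
SE < 0.25 and slope > 0.25 on the raw copy-number scale (signed by default,
with an `absolute` option; trait and predictor standard deviations are
reported in the summary so the implied standardized effect is visible), and
Shapiro–Wilk p ≥ 0.05 on the *whitened* residuals L⁻¹(y − Xβ̂) — raw GLS
residuals are correlated by construction, so normality is assessed after
decorrelation.  No per-orthogroup p-value threshold exists and no multiple-
testing correction runs across orthogroups; "significant" means passing
all three filters.  Per-orthogroup numerical failures are recorded with a
reason and stay in the background count.

The screen is fully deterministic, so it takes no seed.

## Enrichment

Each COG letter present in the annotated background is tested with the
upper hypergeometric tail P(X ≥ k) (via the stable survival function);
equivalence to one-sided Fisher's exact tests and to exhaustive enumeration
is covered by tests.  Multi-letter annotations (e.g. "IQ") count once per
letter; a first-letter-only mode exists.  By default the universe counts
only annotated orthogroups — unannotated ones are unknowable rather than
evidence of absence — with a flag to count them as non-carriers instead.
BH runs across the ≤ 26 tested letters; both p and q are reported.

## Pangenome statistics

ANI pairs classify as genus (< 95), species (95–99 inclusive of both
boundaries) and strain (> 99); the inclusive-boundary choice follows the
threshold statement "Genus: <95%, Species: 95%–99%, Strain: >99%" over a
conflicting "species (ANI > 95%)" phrasing elsewhere.  fastANI's asymmetric
directions are symmetrized by arithmetic mean.  Fluidity, sharing counts
and rarefaction use presence = count ≥ 1; core means presence in 100% of
sampled genomes, with a soft-core fraction exposed as an option.  Curve
fits run on the mean curves across permutations (the usual presentation),
by nonlinear least squares with data-driven starting values; the log-log
linear Heaps fit is returned as a diagnostic.

## The synthetic-study generator

The generator's defaults encode the emulated design: 48 isolates plus a
long-branch outgroup, 4 qPCR replicates per condition, trait variance 1.16
on the log₂ scale (the observed DE variance), λ_true = 0 (the study found
essentially no phylogenetic signal in DE), 500 orthogroups of which 20 are
planted with target slope 0.5, and one COG category (I) at 5× carrier odds
among planted orthogroups.

*Trees* are pure-birth (Yule): the analysis never uses extinct lineages,
and ultrametricity is the natural null for an isolate phylogeny.  The
simulator stops at the n-th birth, which would leave two zero-length sister
branches (a singular V at λ = 1); all terminal branches are therefore
extended by a single Exponential(n·b) waiting time, preserving
ultrametricity.  A documented jitter helper produces non-ultrametric test
trees.

*Traits* are drawn from N(0, σ²·V(λ_true)).

*Copy numbers.*  Null orthogroups combine a core fraction (default 0.4,
present in every genome) with accessory orthogroups whose occupancy
probability is Beta(0.3, 0.7) — a U-shaped gene-frequency spectrum — and
per-copy counts of 1 + negative binomial.  This yields an open pangenome
(fitted γ ≈ 0.08 at the default size), a strict core, and fluidity ≈ 0.10,
inside the 0.04–0.12 range reported for real within-species comparisons.
Presence is independent of the phylogeny, so synthetic fluidity does not
vary by ANI level the way real data would; passing tests demonstrate the
estimators, not phylogenetic structure in gene content.

*Planted orthogroups* are coupled to the trait generatively: the latent
trait u is drawn first, and planted counts are Poisson with mean
μ_p + κ·(u/s), where s = sd(u) and κ is the smaller root of
κ²β − κs + βμ_p = 0, so the population regression slope of u on a planted
column equals the configured β.  An additive construction
(y = Σ_planted β·x_j + noise) was rejected on analysis: with m planted
columns entering one trait, every per-column regression carries an
irreducible SE floor of β·√((m−1)/n) ≈ 0.31 at the default design — above
the 0.25 SE filter — because the other m − 1 planted columns act as omitted
variables.  The generative direction keeps each planted orthogroup
individually recoverable while leaving non-planted columns exactly null.
When the target β is unreachable for a given trait scale (discriminant
< 0), the coupling falls back to the maximum-slope vertex κ = s/(2β).

*qPCR.*  Water replicates are LogNormal(ln W, τ) and drought replicates
LogNormal(ln(W·2^DE), τ) with τ = 0.3 by default; at τ = 0 the arithmetic
replicate means invert exactly to the true DE, and for τ > 0 the recovered
DE is unbiased in Monte-Carlo mean.  Replicate abundances are treated as
directly comparable across samples (no per-root-mass normalization), which
mirrors the assumption of the emulated protocol.

*Annotations.*  Each annotated orthogroup (90% of all) carries the
enriched letter with probability 0.1 in the background — a moderately
common COG class — and with odds multiplied by the configured factor among
planted orthogroups, so "odds = 5" is exactly a 5× carrier odds ratio and
odds = 1 is exactly null.  One uniformly drawn letter from the other
19 commonly populated categories is always added (a second with
probability 0.25).

*ANI* is a plumbing stand-in mapped linearly from patristic distance
(most distant ingroup pair 8 points below 100), spanning the strain/
species/genus bins; it carries no fragment-mapping realism.

All generators draw from per-stage seeds derived from one master seed by
SHA-256 (stable across platforms, < 2³¹), so the full pipeline is
byte-reproducible and stages remain independently reproducible.

## Problem sizes used in validation

The replicated validation experiments run at the design scale the emulated
study used where that is cheap (48-tip trees, 200–1,000 replicate traits,
500-orthogroup screens) and at reduced scale where only the estimator's
correctness is at stake (rarefaction permutations default to 30–100;
Blomberg permutations to 199 in replicated calibration runs and 999 for
single analyses).  The pipeline's synthetic matrix uses 500 orthogroups
rather than the ~17,500 of a real pangenome; the screen is linear in
orthogroups, so conclusions about calibration and recall transfer.

## Known limitations

- Error structures are limited to Pagel's λ; no Ornstein–Uhlenbeck or other
  correlation models, and no ancestral state reconstruction.
- The screen's slope/SE thresholds are scale-dependent by design (they
  mirror the emulated procedure); users with differently scaled predictors
  should consult the logged trait/predictor standard deviations.
- Synthetic gene content is phylogeny-independent (see above), and the
  synthetic ANI is distance-derived; neither emulates recombination,
  lateral transfer or fragment-level ANI behavior.
- qPCR efficiency, primer bias and absolute normalization are out of scope;
  the log-normal replicate model captures multiplicative noise only.
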