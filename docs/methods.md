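# Methods

This note records the models, the numerical choices, and the places where
the design was genuinely open, in the order the pipeline runs.

## Study design and the synthetic-data generator

The generator emulates a three-group dosed-exposure study: a vehicle
control and two dose groups ("low", "high"), 16 fish per group, half
male, split evenly over two experimental weeks with two tanks per
group-week cell (a water control group can be added for the two-level
control contrast). All downstream defaults assume this design; the
sample-design table is a deterministic function of the configuration.

Counts for gene g in sample j are negative binomial with variance
m + αm² and mean

    m_gj = s_j · 2^( b_g + Δ_g(group_j) + λ_{g,group_j}·f_{m(g),j} + σ_m·ε_gj )

- `s_j` — size factor, lognormal (σ = 0.15 on the natural-log scale),
  renormalised to geometric mean 1.
- `b_g` — baseline log2 mean, Normal(6, 2): median ~64 counts with a
  realistic dynamic range.
- `Δ_g` — planted differential-expression shift per dosed group;
  same-sign pairs give additive dose patterns, mixed signs the
  opposite-direction patterns seen in real dose-response data. Defaults:
  10 genes at (+0.8, +1.2), 10 at (−0.5, −0.8), 5 at (−0.8, +0.4),
  magnitudes inside the range such studies report.
- `λ·f + σ·ε` — planted co-expression: module members share one
  standard-normal latent factor per sample with a group-specific loading
  λ, plus member-specific noise σ (default 1). The expected within-group
  pairwise correlation is ρ = λ²/(λ²+σ²);
  `ModuleSpec.from_rho` inverts this. Defaults plant a connectivity-gain
  module (ρ 0.1/0.4/0.8 over dose), a loss module (0.7/0.4/0.3) and a
  stable module (0.5), 50 genes each.
- `α_g` — dispersion, lognormal with median 0.05 (σ = 0.5 in log space),
  typical of bulk RNA-seq at this depth.

The module signal is injected on the log2 scale, so planted correlations
survive the downstream log2(count/s + 1) transform up to attenuation by
the NB sampling noise, roughly ρ_observed = λ²/(λ²+σ²+v) with
v ≈ (1/μ + α)/ln²2; at the default baselines this attenuation is a few
hundredths. Log2 means above 30 are capped with a warning. Gene lengths
are lognormal (median ~1.8 kb); a `length_bias` shift of member genes'
log-lengths creates the membership-length confounding that the
enrichment correction exists for. Behaviour observations are multinomial
over (bottom, middle, top) per fish × session, 30 observations per
session, with default zone probabilities shifting toward the top with
dose. Health metrics are positive normal draws with no group effect
unless requested.

Every planted effect is recorded in a `GroundTruth` object. One global
seed drives everything; each component draws from its own spawn-key
substream, so stages can be regenerated independently.

What the generator does **not** emulate: batch/tank effects on
expression (tank labels exist but carry no effect, matching the analysed
model which omits tank), gene-gene correlation outside planted modules,
GC or positional biases, outlier samples, and library-composition shifts
beyond lognormal depth. Passing tests therefore show that the estimators
recover the structure they model, not that they are robust to every
artefact of real data.

## Preprocessing

Genes are kept when at least 10 reads appear in at least 16 samples (the
exposure group size); both thresholds are inclusive and the filter is
idempotent. The gene list chosen on the dosed sample set is reused
unchanged for the water-vs-vehicle contrast (`CountFilter` carries the
list between sample sets). Size factors are median-of-ratios: reference
genes are those with strictly positive counts in every sample, each
sample's factor is the median ratio of its counts to the per-gene
geometric mean, median ties resolved by the midpoint. A universe in
which most genes carry strong shared signal (e.g. a simulation that is
all module genes, or a large fraction of one-directional DE) breaks the
estimator's "most genes unchanged" assumption — size factors then absorb
the signal itself; simulated studies should keep planted genes a
minority, as real transcriptomes do. Expression is log2(count/s + 1),
which is 0 at count 0 and strictly monotone.

## Differential expression

Per gene, a log-link negative-binomial GLM of counts on dummy-coded
exposure (+ sex + week; optional exposure×sex interaction columns) with
log size factors as offsets, fitted by iteratively reweighted least
squares (weights μ/(1+αμ), convergence when the largest coefficient
change is below 1e-8, 100 iterations, linear predictor clipped at ±30 so
all-zero genes stay finite; non-converged genes are reported with NA
p-values and excluded from the multiple-testing count, never silently
dropped).

Dispersions are method-of-moments: the within-cell residual variance of
normalised counts (cells = exposure × sex × week combinations), pooled,
solved against Var(q) ≈ μ·mean(1/s) + αμ², floored at 1e-8. The raw
moment estimate is noisy at n = 48, and genes with understated α̂
dominate the tail of the statistics (inflating the realised FDR), so by
default each estimate is averaged with a parametric trend
α(μ) = a₀/μ + a₁ fitted across genes by least squares — the same idea as
trended-dispersion estimation in the standard count-GLM tools, without
their empirical-Bayes shrinkage. No fold-change shrinkage is applied
anywhere; this is a deliberate simplification and the reported log2 fold
changes are plain maximum-likelihood coefficients divided by ln 2.

The exposure test is a likelihood-ratio chi-square with df = 2 (the two
exposure dummies), with the gene's dispersion held fixed between the
full and reduced fits — the standard convention for this model family.
The two-level control contrast is a Wald z = β̂/se with two-sided normal
p. Cook's distance per observation is (r_P²/p)·h/(1−h)² from the full
fit; observations above the 99th percentile of F(p, n−p) are replaced by
the gene's 20 %-trimmed mean of normalised counts, rescaled by the
sample's size factor and rounded, and the gene is refitted. Cutoff
quantile and trimming fraction are conventional values and configurable.
Multiple testing is Benjamini–Hochberg step-up with NAs excluded from m;
the significance surface is FDR < 0.10.

## Signed network and module detection

Pearson correlations (zero-variance genes get correlation 0 and a
warning), signed adjacency a = ((1+r)/2)^β with β = 12, topological
overlap TOM_ij = (Σ_{u≠i,j} a_iu a_uj + a_ij)/(min(k_i,k_j)+1−a_ij), and
average-linkage clustering of 1 − TOM. Above `max_block_size` (default
5 000) genes are pre-partitioned by k-means on standardised profiles
into ⌈n/max⌉ blocks (capacity-constrained: overflow genes move to the
nearest centre with room) and detection runs per block; module labels
are re-ranked by size across blocks.

The tree cut is the one genuinely open design point. Soft thresholding
at β = 12 compresses TOM dissimilarities toward 1, so absolute height
gaps carry almost no information; a fixed-height cut is likewise
unstable because the working height range depends on the gene count
through the connectivity k. The cut used here is scale-free: a subtree
qualifies as a module when (a) it has at least `min_module_size` leaves,
(b) its mean within-subtree TOM is at least `min_cohesion` (default 5)
times its mean TOM to all remaining genes, and (c) its merge into the
parent jumps by at least `min_relative_gap` (default 1/3) of the
subtree's remaining similarity scale, (h_parent − h)/(1 − h). Among
nested qualifying subtrees the one with the largest cohesion ratio wins:
dropping true members raises the outside mean, absorbing background
lowers the inside mean, so the ratio peaks at the module boundary. The
root never qualifies, which makes "no separable structure → everything
unassigned (module 0)" an explicit property rather than an accident. The
defaults were chosen from the separation observed between module
subtrees (ratios ≳ 10) and the chained subtrees of structureless data
(ratios ≲ 4). A static-height cut (`cut="static"`) is kept as a simple
fallback. Background genes whose sample correlation with a module's
factor is large by chance (at n = 48 the expected maximum over a few
hundred genes is r ≈ 0.4) are statistically indistinguishable from weak
members and may attach to a module; recovery of planted partitions is
therefore scored over the planted genes.

## Differential connectivity

For each exposure group separately (correlations within that group's 16
samples only), gene i in module M gets
kWithin_i = Σ_{j∈M, j≠i} |r_ij|^β. Note the asymmetry kept on purpose:
the network that defines the modules is signed, but the connectivity
statistic uses absolute correlations raised to β — that is the statistic
as defined in this analysis; `use_signed=True` switches to the signed
adjacency. Per module, a one-way ANOVA treats each gene's kWithin as an
observation and the groups as levels (explicit sums of squares; zero
within-group variance with unequal means reports F = ∞, p = 0 and a
`degenerate` flag; modules with fewer than two genes are skipped with a
warning). Significance is Bonferroni at α/M with α = 0.05 and M the
number of modules tested.

Genes within a module are correlated, so the gene-level F test is
anti-conservative under the null — it answers "do these computed
kWithin values differ between groups", not "would they differ under
resampling of animals". The procedure is reproduced as defined because
the statistic is the object of interest; a sample-label permutation null
(`permutation_module_pvalues`) is provided and verified to be calibrated
where the gene-level test is not.

## Enrichment

Terms are intersected with the analysis universe (default: all analysed
genes, configurable) and dropped below 10 genes. Per tested module, the
probability weighting function is fitted with membership flag "gene is
in this module": genes are grouped into up to 40 length-quantile bins,
per-bin membership proportions are isotonically regressed
(non-decreasing) on bin mean length with bin-occupancy weights, linearly
interpolated to each gene, clipped to [1e-6, 1−1e-6] and rescaled so the
weights sum to the member count. Isotonic regression replaces the usual
monotone spline: same monotone-smoother contract, fewer moving parts.

The per-term p-value is the upper tail of Wallenius' noncentral
hypergeometric with odds w = [p_in/(1−p_in)]/[p_out/(1−p_out)] from the
mean PWF weight inside/outside the term. The mass function is evaluated
through its integral representation
P(x) = C(m1,x)·C(m2,n−x)·∫₀¹ D u^{D−1}(1−u^w)^x(1−u)^{n−x} du with
D = w(m1−x)+(m2−n+x), computed in log space with peak normalisation
before adaptive quadrature, so instances up to genome scale neither
under- nor overflow; at w = 1 it reduces to the central hypergeometric
to ~1e-14. Tails are logsumexp sums over the support. Only
over-representation is tested. The Monte-Carlo null draws |module| genes
without replacement with probability proportional to the PWF weights
(Gumbel-perturbed top-k, which realises successive weighted sampling
exactly) — note this matches the single-odds Wallenius model exactly
only when weights are two-valued and small; with a fitted, gene-varying
PWF the analytic test is an approximation and the two agree to a few
hundredths. The family for the Bonferroni bound is the set of distinct
retained terms annotating at least one gene of any tested module.

## Phenotype and behaviour

k = 100·w/L³ (w in g, L in cm); HSI = 100·liver/(total−liver);
BBR = 100·brain/(total−liver), all weights in mg — the BBR denominator
subtracts the liver weight, following the definition used by this
analysis verbatim. Health metrics are tested per sex: OLS of each metric
on exposure + week with a type-II F test for the exposure factor (dosed
analysis) or a two-level regression t-test (control contrast); constant
responses raise an explicit error rather than returning NaN. Behaviour:
per zone × session type, the zone count (out of 30 observations, days as
independent records) is regressed on exposure + sex + week (tank
optional, off by default as in the analysed model); raw counts are
modelled, not proportions. The Bonferroni threshold is 0.05/18, reading
the 18 as 3 zones × 3 session types × 2 analyses; the count is
configurable.

## Pipeline

Stages run in a fixed order (simulate → filter → normalize → de →
network → connectivity → enrich → phenotype → behaviour), each reading
the previous stage's files from the run directory; a missing dependency
aborts with the failing stage named, and a stage that throws renames its
outputs to `.partial`. Configuration is a single YAML file with unknown
keys rejected; CLI flags override it. Every printed threshold (10
reads/16 samples, β = 12, FDR 0.10, α/M, α/18, α/family) is echoed in
the per-stage log. The manifest records the config hash and SHA-256 of
every output; identical configurations reproduce identical checksums
(all floating-point reductions are over deterministically ordered
operands).

## Problem sizes used in tests

The test suite and the acceptance script run scaled-down versions of the
Monte-Carlo designs: simulations use 100–2 500 genes, null calibrations
use 200–2 000 genes or 200–400 replicates, dispersion-recovery examples
use 100 replicates, and the sampling-oracle cross-check uses 30 000 to
100 000 draws. These sizes were chosen so each property is measured with
comfortable statistical margin; the quantities themselves are
size-independent.

## Known limitations

- No dispersion or fold-change shrinkage; at very small counts the LRT
  relies on the chi-square approximation.
- The cohesion tree cut is a simplified stand-in for hybrid dynamic tree
  cutting; very weak modules (within-group ρ well below ~0.3 after
  attenuation) fall below its cohesion floor and stay unassigned.
- The single-odds Wallenius test inherits the usual approximation of
  collapsing a gene-varying PWF to one odds ratio.
- The gene-level connectivity ANOVA is anti-conservative by
  construction; use the permutation null when calibration matters.
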