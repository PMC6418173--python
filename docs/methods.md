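# Methods

This note documents the models, the synthetic-data generator, the
numerical choices and the known limitations of the package. Nothing here
states an empirical result that the test suite or `scripts/acceptance.py`
does not itself compute.

## Mixed-model association with reliability weights

The GWAS phenotype is a de-regressed proof (predicted transmitting
ability): a progeny-based estimate of a sire's genetic merit whose error
variance shrinks as its reliability r² → 1. The model

y = μ + Xb + g + e, g ~ N(0, σ²_g G), e ~ N(0, σ²_e R), R_ii = 1/r²ᵢ − 1

makes the residual variance of each record proportional to 1/r² − 1, so a
proof with r² = 1 is treated as the breeding value itself. To keep R
invertible, reliabilities of exactly 1 are floored at 1 − 1e-6 (residual
weight ≈ 1e-6 instead of 0); with typical bull reliabilities (0.8–0.99)
the floor is never active.

*REML.* The null model (no marker) is fitted by whitening with R^(−1/2)
and eigendecomposing A = R^(−1/2) G R^(−1/2) once. The likelihood is then
profiled over λ = σ²_g/σ²_e on a log grid over λ ∈ [1e-6, 1e6] (81
points, plus the λ = 0 boundary) and refined by bounded scalar
minimisation between the best grid point's neighbours (tolerance 1e-8 on
log₁₀ λ). This is exact, deterministic and adequate at desk scale; no
stochastic optimiser is involved. When A is diagonal (identity G,
homogeneous weights) the eigendecomposition is skipped. A flat or
boundary likelihood returns the boundary estimate with a warning.

*Marker tests.* Each marker's effect is estimated by GLS with covariance
σ²_g G + σ²_e R held at the null estimates (the standard "EMMAX-style"
approximation), and a two-sided Wald P from the normal approximation is
reported. Wald was chosen because downstream stages consume (b, SE)
summary statistics; score or LRT variants would not change the exchange
format. With G = I, equal weights and σ²_g = 0 the test reduces exactly
to ordinary least squares (checked to 1e-8 in the suite).

*QC.* MAF > 0.01 and HWE P > 1e-6 (chi-square, 1 df, no continuity
correction). The chi-square rather than exact HWE test is used because at
a 1e-6 cutoff and the sample sizes involved, the choice is immaterial;
monomorphic variants are defined to have P = 1 and fail the MAF filter
anyway. The GRM is VanRaden method 1 with observed allele frequencies,
over variants with MAF > 0.01.

## Fine-mapping

The per-variant evidence is a Wakefield approximate Bayes factor,
ABF = sqrt(se²/(se² + W)) · exp(W b²/(2 se²(se² + W))), with prior effect
variance W = 0.04 on the standardised trait scale (a common default;
configurable). Within a candidate region (significant span ± 1 Mb,
overlapping spans merged, clipped at chromosome bounds), the
single-causal-variant posterior is PPC_i = ABF_i / Σ_j ABF_j under a
uniform causal prior, computed in log space for numerical safety.
Independent signals are separated by forward conditioning: the lead
variant joins the fixed covariates (QR-orthogonalised in the whitened
basis) and the rest are re-tested; iteration stops when the minimum
conditional P ≥ 1e-6 (configurable; no stopping rule is canonical).
Gene PPC sums variant PPCs within gene ± 2 kb, reported per signal and
totalled — per-signal sums are bounded by 1, totals by the number of
signals; the candidate flag uses the best per-signal sum against the 0.05
cutoff. Multi-causal joint posteriors and functional priors are out of
scope.

## Cyclical-permutation enrichment

T_sum = Σ b² over a feature's variants is compared with rotations of the
genome-ordered b² vector: offset k ∈ {1, …, m−1}, feature positions
fixed. Rotation preserves the ordering — hence the local LD correlation —
of the statistics, which is what makes the null honest for clustered
features. Choices:

- chromosomes are concatenated ascending by numeric label, then
  lexicographically, to form the rotation circle (no order is canonical);
- the identity rotation is excluded (the observed statistic is k = 0);
- ties count as exceedances ("≥", conservative), and the empirical P uses
  add-one smoothing (1 + count)/(1 + n_perm) so permutation P-values are
  valid and never zero; the literal proportion and strict ">" are exposed
  as options;
- when n_perm ≥ m − 1 all rotations are enumerated exactly and the result
  is flagged `enumerated`; otherwise offsets are sampled uniformly
  without replacement;
- rotated sums are computed by direct gather in chunks, or by FFT
  circular cross-correlation when the work exceeds ~5e6 operations, with
  a 1e-9 relative tolerance on tie comparisons to absorb FFT round-off;
- variant-to-gene-set masks use gene bodies with a configurable flank
  (default 0). Gene intervals are matched as 1-based inclusive after BED
  conversion; plain interval masks (DMR tiles) use the half-open
  convention `start ≤ pos < end` directly on the stored coordinates. The
  two conventions are deliberate, mirror how each input is produced, and
  are pinned by boundary tests.

## Tile-based differential methylation

CpG records (1-based, methylKit-style columns) are filtered to ≥ 10
reads, symmetric strands merged onto the plus-strand coordinate (CpG
methylation is strand-symmetric; destranding doubles coverage without
changing proportions), and counts summarised on 2000-bp tiles with
2000-bp step. Tiles with fewer than 3 covered CpGs in any sample are
dropped so a single CpG cannot masquerade as a region; no per-tile CpG
minimum is canonical, 3 is this package's choice.

The group test is a binomial logistic regression of methylated fraction
on the group indicator with one observation per sample. Because the only
covariate is binary, the MLE is the pair of group-pooled proportions and
the likelihood-ratio statistic has a closed form (the G-test on pooled
group totals); the suite verifies the identity against a per-sample
statsmodels GLM fit. The reported difference is the coverage-weighted
high-minus-low proportion × 100. No overdispersion correction is applied
by default (none is canonical for this design); an optional Pearson
dispersion deflation is available for replicate sets more variable than
binomial. P-values are adjusted by Benjamini–Hochberg — a deliberate,
reproducible substitute for dissertation-grade q-value estimators; BH is
conservative under independence and the substitution is recorded in
output metadata. DMRs require q < cutoff and |difference| > 5 points;
Gain/Loss partition members exactly by sign.

## DMR-set statistics

Membership rules: ≥ 1 bp intersection throughout (the minimal defensible
reading of "intersects"); pathway genes are extended ±10 kb to cover
proximal regulation. The count statistic T_count = #{pathway tiles with
q < q₀}, q₀ = 0.01, is tested against Hyper(m, m_g, m_f) — identical to
the one-sided Fisher exact test on the induced 2×2 table (verified to
1e-12). Cross-pathway adjustment is Benjamini–Hochberg at 0.05.
Element-density enrichment is per-bp: (DMRs in class / class span) over
(all DMRs / genome size). The overlap universe for cross-trait Fisher
tests is the set of tested tiles — untested tiles cannot be DMRs, so any
larger universe would inflate enrichment.

## Effect correlations

Genetic correlations are approximated by the Pearson correlation of raw
per-variant effects (a standardised-scale option multiplies by
sqrt(2p(1−p))). A seeded percentile bootstrap over variants (1000
resamples) quantifies uncertainty. The estimate is attenuated toward zero
by marker-level estimation noise — correlating b̂ = b + ε across traits
with independent ε divides the true effect correlation by
(1 + var(ε)/var(b)) — so recovery assertions compare Monte-Carlo averages
against the simulated value with a tolerance that accommodates the
attenuation at the problem sizes used (below).

## The synthetic-data generator

The generator emulates exactly the structure the models assume, which is
what makes recovery tests interpretable:

- *Genotypes*: haplotypes from a first-order copying process — each
  allele copies its left neighbour with probability `ld_copy_prob`
  (default 0.9), else is drawn at the variant's target frequency (uniform
  on `maf_range`, default 0.05–0.5). One parameter produces the LD blocks
  the cyclical permutation null must respect; copying restarts at
  chromosome boundaries.
- *Traits*: causal effects are Gaussian; the genetic value is scaled to
  variance h², and noise for individual i has variance
  (1 − h²)(1/r²ᵢ − 1) with r²ᵢ uniform on 0.8–0.99 — the GWAS weighting
  model is exactly correct on these data, and the REML ratio targets h².
- *Trait pairs*: effects drawn from a bivariate normal with correlation
  rg at a shared causal set, then scaled per trait.
- *Methylomes*: CpG sites at geometric spacing (mean 150 bp), coverage
  Poisson around the mean (negative binomial optional), methylated counts
  binomial around a per-tile baseline uniform on 0.1–0.9; in each of
  `n_dmr` tile-aligned truth intervals the high group's proportion shifts
  by `effect_size`, clamped into [0, 1] with clamping recorded.
- *Reproducibility*: every operation derives its own stream from
  (master seed, CRC32 of the operation tag); identical configurations are
  bit-identical.

What the generator does **not** emulate — and hence what passing tests do
not show about real data: population structure and relatedness beyond the
GRM's reach, imputation error, distance-decaying recombination maps,
overdispersed or spatially autocorrelated methylation beyond tile
baselines, batch effects, and any real annotation content. Null
calibration and recovery results certify the statistical machinery, not
field performance.

## Problem sizes used in the checks

The suite and the acceptance script run at desk scale, chosen so the full
stack (not a shortcut) is exercised: type-I calibration uses 500 random
10-gene features over five null GWAS replicates (n = 400, m = 2000);
REML recovery uses n = 2000, m = 4000; DMR recovery uses ten 4-vs-4
spike-in studies on a 1-Mb genome (≈ 500 tiles each, coverage 30, 30-point
shift); gene-PPC recovery uses 100 one-causal regions (n = 2000, 200
variants, 1% variance); effect-correlation recovery uses ten studies at
n = 1000, m = 5000, 500 causal variants, rg = 0.6. The fine-mapping
recovery metric evaluates the marginal single-signal posterior over the
region: it measures PPC aggregation, not the forward-selection stopping
rule, whose threshold (P < 1e-6) is intentionally stricter than a 1%
variance signal at n = 2000.

## Known limitations

- The per-marker GLS holds variance components at their null estimates;
  for very large effects the SEs are slightly optimistic.
- Single-causal-per-signal posteriors cannot represent allelic series
  within one signal; forward conditioning approximates them greedily.
- BH q-values control FDR under independence/PRDS; tile P-values are
  locally correlated, so realised FDR can differ modestly.
- The effect-correlation estimator is a noisy-proxy approximation of the
  genetic correlation; it is attenuated and LD-unaware by design.
- The cyclical permutation null conditions on feature positions; features
  covering most of the genome are untestable (P = 1 by invariance).
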