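# Methods

This note documents the models, numerical choices, and limitations of
`mesoaxes`. Nothing here states an empirical result that the test suite
or `scripts/acceptance.py` does not itself compute.

## The synthetic cohort generator

The generator (`mesoaxes.simulate`) is first-class, tested code. It
emulates the geometry of a multiomic tumor cohort in which samples form
continuous gradients between extreme profiles rather than clusters.

**Latent factors.** Four per-sample factors are planted. Factor 1 is a
standardized Gaussian driving ploidy, `ploidy = 2 + a·z₁ + N(0, sd)`
clipped to [1, 4.5] (near-haploid to near-tetraploid); defaults a = 0.8,
sd = 0.2. Factors 2–3 are the centered/scaled coordinates of Dirichlet(α)
mixtures of a planted triangle, default vertices (0,0), (4,0), (2,3.5)
(non-degenerate, unequal edge lengths so archetype matching is
exercised) and α = 0.5, so samples fill the triangle with some mass near
the vertices. Factor 4 is a standardized Gaussian driving island
methylation. With the default vertex set the two triangle coordinates
are uncorrelated in expectation, so the four factors are approximately
orthogonal.

**Expression.** `Y = Z Wᵀ + N(0, 0.5)` with loadings N(0,1) masked at
sparsity 0.8 (20% nonzero). Planted marker blocks carry interpretable
signal: a proliferation set on factor 2, adaptive-immune (positive) and
innate (negative) sets on factor 3, and five "silenced" genes loading
negatively on factor 4, all kept autosomal so the sex-chromosome filter
cannot remove them. A positive-scale FPKM companion matrix feeds the
range filter and the alteration expression floor. About 2% of genes sit
on chrX/chrY to exercise that filter.

**Methylation.** 2,000 islands × 5 CpGs by default. Island mean beta is
`logistic(c_i + b·z₄) + N(0, 0.02)`, truncated (not resampled) to [0,1]
so the monotone coupling to z₄ is preserved; b = 4. The island baselines
c_i ~ N(−2, 4): the wide baseline spread relative to the slope keeps the
cohort-level island *fraction* (the CIMP index) near-linear in z₄, while
each island's beta profile across samples remains bimodal (CIMP-low vs
CIMP-high), which is the phenotype the index summarizes. CpG betas
scatter around their island mean (sd 0.05); M = log2(β/(1−β)) with β
clipped to [10⁻⁶, 1−10⁻⁶]. Islands are assigned wholesale to
promoter/body/enhancer regions.

**Copy number.** Per-sample baseline CN equals ploidy; contiguous
50-gene segments acquire sporadic integer deviations (probability 0.05
per segment, ±1 or ±2). No per-gene measurement noise is added: genes in
one segment have bit-identical profiles, as in segment-level CN calls,
which is what makes the identical-profile grouping rule meaningful.
Purity is Uniform(0.3, 0.95).

**Alterations.** For a planted displacement d at prevalence q, carrier
probability is the linear tilt `p_i = q + q(1−q)(x_i − x̄)ᵀ Σ⁻¹ d`
(clipped to [0,1], re-centered so the marginal stays q), where Σ is the
covariance of the 2-D positions. This construction makes the *expected*
carrier-minus-wild-type centroid difference exactly d, so "planted
displacement" is well defined for recovery tests; it is monotone in the
projection toward the displaced target. Defaults: three alterations at
prevalence 0.3 with displacement norm 0.8 pointing at the three vertices.

**Survival.** Exponential proportional hazards,
`h_i = h₀ exp(Σ_k β_k z_ik)` with defaults h₀ = 0.02 per month and
β = (0.5, −0.4, −0.4, 0.3). Censoring is independent Uniform(0, c_max)
with c_max solved by bisection on the realized event times so the
expected censored fraction matches the configured rate (default 0.3) —
the simplest mechanism compatible with proportional hazards.

**Randomness.** One global seed spawns named, independent child streams
(one per layer), so regenerating a single layer standalone reproduces it
bit-for-bit regardless of call order.

**What the generator does not emulate:** batch effects, probe-level
array artifacts, read-level noise, multi-region sampling, immune
deconvolution output, or realistic gene–gene correlation beyond the
planted low-rank structure. Passing tests demonstrate that the pipeline
recovers planted structure under Gaussian low-rank noise; they do not
certify performance on real array or sequencing data.

## Preprocessing rules

Per layer, in this order:

- **Expression:** drop genes with FPKM range < 1 across samples; drop
  sex chromosomes (chromosome names compared after stripping a leading
  "chr"); keep the top 5,000 by variance of the normalized values.
- **Methylation:** drop CpGs with beta range < 0.1; split by region into
  MethPro/MethEnh/MethBod; per region keep the top 5,000 by M-value
  variance (M, not beta — a CpG near β = 0.5 can outrank one near the
  boundaries); outputs carry M values.
- **Copy number:** purity-adjust to the observed mixture scale,
  `value = purity·CN + (1−purity)·2` (diploid normal contamination);
  merge features with bit-identical profiles (concatenated id, first id
  canonical); call a feature "altered" in a sample when |value − 2| >
  0.5 (half-copy margin — the altered margin is this package's choice,
  chosen to separate single-copy events from noise); keep features
  altered in ≥ 3 samples; center and scale; top 5,000 by pre-scaling
  variance.
- **Alterations:** Booleanize (gene, sample) events; keep genes altered
  in ≥ 3 samples, autosomal, with max FPKM ≥ 0.01.

Variance ranking uses the n−1 sample variance with ties broken by
feature id, so results are independent of input feature order. All
filters are idempotent. Expression and methylation are centered (not
scaled) before factorization; copy number is centered and scaled.

## Multi-view factor model

Alternating least squares on
`Σ_v w_v/σ²_v ‖Y_v − Z W_vᵀ‖²` with view balancing `w_v = 1/p_v`
(configurable off) so large views do not dominate. Initialization is the
left singular vectors of the column-concatenated, per-view
variance-normalized matrix. Noise variances σ²_v are estimated once from
the initialization residuals and then held fixed, which makes each ALS
half-step a weighted least-squares minimization and the objective
provably non-increasing (asserted per iteration in the tests).
Convergence: relative objective change < 10⁻⁶ (max 1000 iterations).
Missing entries are masked out of the normal equations, supporting
partial views. Factors are ordered by total variance explained and
sign-fixed so the largest-magnitude loading is positive.

This is a deterministic surrogate for variational Bayesian multi-omics
factor analysis (no ARD priors, no ELBO, no factor pruning): the
quantities this package consumes downstream are factor scores and
per-view variance explained, for which weighted ALS suffices and is
exactly reproducible. Ill-conditioned Gram matrices get a relative ridge
(10⁻⁹ × mean eigenvalue).

The covariate R² of a layer is pooled across features:
`1 − Σ_f SS_res(f) / Σ_f SS_tot(f)` after a group-mean fit, with
zero-variance features excluded. Pooled (rather than per-feature
averaged) weighting was a genuinely open choice; pooled weights features
by their variance, which matches how the factor model itself sees the
layer.

## CIMP index and proxies

Island beta is the unweighted mean over the island's CpGs; the index is
the fraction of islands with mean beta ≥ 0.3 per sample (inclusive
threshold). The silencing screen runs two two-sided Pearson tests per
gene (expression vs index, expression vs own island beta), BH-adjusts
each family across genes, and reports genes with both r < 0 and both
q < 0.05.

Proxies for the four axes: mean |CN − modal CN| for aneuploidy (modal =
per-sample median rounded to integer — a pragmatic burden measure, this
package's own formula); % sarcomatoid from the clinical table; mean
z-scored adaptive-set expression minus innate-set expression; mean
island beta over a configured island set for the CIMP proxy. The default
five-gene proxy list (CBFA2T3, FBLN2, PRF1, SLC34A2, WT1) is a
configurable stand-in; users with curated sets should override it.

## Archetypal analysis

Principal convex hull: minimize `‖X − A B X‖²` with A (samples × k) and
B (k × samples) row-stochastic and non-negative. The A-step is solved
*exactly* by support enumeration: the optimum's active set is one of the
2ᵏ−1 support subsets, each solved via a precomputed KKT inverse,
vectorized across samples (practical for k ≤ ~8; the package targets
k ≤ 6). The B-step computes the unconstrained archetypes
`Y* = (AᵀA)⁻¹AᵀX` and projects each row onto convex combinations of the
data by penalty NNLS; a B-update that would increase the objective is
rejected (safeguard), so the SSE trace is non-increasing by
construction. Initialization is furthest-sum vertex seeding. The fit is
performed in centered coordinates with a rotation-invariant penalty
scale, making it exactly equivariant under rigid rotation and
translation of X (tested). The archetype relaxation parameter δ is
accepted for interface compatibility but only δ = 0 is supported.

Fit statistics: SSE, variance explained (1 − SSE/SST), and in 2-D the
t-ratio = archetype-polygon area / data convex-hull area. Significance
is a one-sided randomization test: permute each coordinate column
independently (destroys the multivariate shape, preserves marginals),
refit, and count null statistics ≥ observed, p = (1 + #)/(1 + n_perm);
for d > 2 the statistic falls back to variance explained because
polytope volume ratios are numerically unstable in higher dimension.
Bootstrap stability uses 200 replicates of 75% subsamples *without*
replacement, warm-started from the reference archetypes (so frac = 1
reproduces the reference exactly) and aligned by Hungarian matching.
For k selection the var_expl elbow (largest second difference over
k = 2…6) is available, but k is user-settable and the canonical map
uses k = 3.

## Interpretation

Gene–archetype association is a two-sided Pearson correlation of each
gene with each archetype-proportion column. Directional gene-set
enrichment ranks the genes with the requested sign of r by ascending p
and computes, per set, the minimum one-sided hypergeometric tail over
all rank cutoffs (evaluated only at member positions, where the minimum
must occur). The min-over-cutoffs scan is anti-conservative, so the
observed minimum is calibrated against 1,000 random same-size subsets
(cached per set size): the reported p is the permutation tail
probability of the minimum, then BH-adjusted across sets. Set size
bounds default to [20, 1000]. This is single-source directional
enrichment; no cross-omics p-value merging is attempted.

Effect vectors: carrier-centroid minus wild-type-centroid on the factor
plane, defined only when both groups have ≥ 3 samples; per-alteration
significance is a one-way MANOVA (Pillai trace) of the coordinates on
carrier status — multivariate rather than per-axis, since the question
is displacement on the plane — BH-adjusted across alterations. The
global specialization statistic is the mean effect-vector norm; its null
permutes the sample order of the coordinates *jointly* (one permutation
per replicate), preserving alteration co-occurrence, so the test targets
the coordinates-alteration linkage rather than the alteration structure.

## Survival

Cox proportional hazards via the partial likelihood with Efron tie
handling; covariates standardized to unit sd by default so hazard
ratios are per-sd (forest-plot convention; configurable). Per-covariate
Wald tests; the model-level test is the score ("logrank") test of the
partial likelihood at β = 0, computed analytically — for one binary
covariate it reduces to the classical logrank test (verified against an
independent implementation in the tests). Non-convergence yields a
flagged result rather than an exception. Model comparison reports
Harrell's concordance and the IPCW cumulative/dynamic AUC at a
configurable horizon (the AUC variant was an open choice; IPCW
cumulative/dynamic is the standard estimator under right censoring).

## Problem sizes and determinism

Default analyses run at cohort scale n = 120 (n = 150–200 for the
geometry tests), 5,000-feature layers, K = 10, 999 permutations for
randomization tests, 200 bootstrap replicates. The full test suite and
the reproduction script each run in a couple of minutes on one CPU.
Every stochastic component takes an explicit seed; the pipeline spawns
per-stage streams from the single run seed, and identical seeds produce
byte-identical output files.

## Known limitations

- The ALS factor model does not quantify posterior uncertainty and will
  mix planted factors when their singular values are close.
- The archetype A-step's support enumeration is exponential in k
  (fine for k ≤ 6, the supported range).
- The randomization and permutation p-values have resolution
  1/(n_perm + 1).
- The CN "altered" margin (0.5) and the aneuploidy proxy formula are
  package conventions, not community standards.
- The generator's noise is Gaussian and independent across features;
  real layers have heavier tails and correlated noise.
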