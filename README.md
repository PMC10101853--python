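# mesoaxes

Tumor cohorts profiled across several molecular layers — gene expression,
CpG methylation, gene-level copy number, Boolean gene alterations — often
do not split into discrete subtypes. Instead samples spread along a small
number of continuous axes between extreme molecular profiles. `mesoaxes`
implements a complete, tested pipeline for that continuous-gradient view
of tumor heterogeneity, built around four analysis ideas:

1. **Multi-view latent factors.** Each layer `Y_v` (samples × features,
   centered) is modeled as `Y_v ≈ Z W_vᵀ` with a *shared* factor matrix
   `Z` (samples × K, default K = 10), fitted by alternating least squares
   on the view-balanced objective
   `Σ_v (σ²_v p_v)⁻¹ ‖Y_v − Z W_vᵀ‖²_F`. Per-factor variance explained in
   layer v is `r²_{kv} = 1 − ‖Y_v − z_k w_{vk}ᵀ‖² / ‖Y_v‖²`, and "major"
   factors are those with `r² > 0.10` in at least one layer. On the
   synthetic cohort the four planted axes — ploidy, morphology, immune
   response, CIMP — are recovered exactly as the four major factors.
2. **CIMP index.** Per sample, the fraction of CpG islands whose mean
   beta value is ≥ 0.3 — a one-number summary of the CpG-island
   methylator phenotype, plus a screen for genes silenced by island
   methylation (expression negatively correlated with both the index and
   the gene's own island, both BH-adjusted).
3. **Pareto / archetype analysis.** On the factor map, samples are
   modeled as convex mixtures of k archetypes (principal convex hull /
   archetypal analysis). Fit quality is the t-ratio (archetype-polytope
   area over convex-hull area in 2-D) and significance is a one-sided
   randomization test that permutes each coordinate column independently.
4. **Alteration effect vectors and survival.** Each alteration's effect
   vector is `mean(coords | altered) − mean(coords | wild-type)`, tested
   per-alteration by MANOVA (Pillai trace) and globally by a
   joint-permutation test of the mean vector norm; factors are tied to
   overall survival with Cox proportional-hazards models (Efron ties,
   per-sd hazard ratios, IPCW time-dependent AUC).

Real cohorts of this kind are controlled-access, so the package ships a
first-class synthetic generator (`mesoaxes.simulate`) that plants all of
the above structure — triangle geometry, ploidy and CIMP couplings,
alteration displacements, proportional-hazards survival — with known
ground truth, making every stage testable end to end.

## Worked example

```python
import mesoaxes as mx
from mesoaxes.factor import fit_multiview_factors, select_major_factors, \
    correlate_factor_with_covariate
from mesoaxes.preprocess import (center_view, filter_expression,
    filter_methylation, gene_level_copy_number, group_and_select_cn)

ds = mx.generate_dataset(mx.GeneratorConfig(seed=1))
expr = filter_expression(ds.expression, ds.expression_fpkm)
meth = filter_methylation(ds.meth_beta, ds.meth_M, ds.region_map)
cn = group_and_select_cn(gene_level_copy_number(
    ds.copy_number, mx.PurityTable(purity=ds.purity, ploidy=ds.truth.ploidy_true)))
views = {"expression": center_view(expr),
         **{k: center_view(v) for k, v in meth.items()}, "copy_number": cn}
model = fit_multiview_factors(views, K=10, seed=1)
print(select_major_factors(model))
print(correlate_factor_with_covariate(model.Z, ds.truth.ploidy_true)["r"].abs().max())
```

prints

```
['LF1', 'LF2', 'LF3', 'LF4']
0.9577201446070432
```

i.e. exactly the four planted factors pass the >10% rule, and the best
factor–ploidy Pearson correlation is 0.96: the copy-number-driven ploidy
axis is recovered almost perfectly. The scripts in `examples/` walk
through each capability the same way (simulation, factorization, CIMP,
archetypes, effect vectors, survival) and print what the numbers mean.

A thin CLI orchestrates the whole pipeline with one config and writes a
run manifest:

```bash
mesoaxes run-all --out-dir run1 --seed 1
```

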