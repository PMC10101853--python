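"""Generate a synthetic multiomic cohort with planted four-factor structure.

The generator emulates the qualitative geometry of a mesothelioma
multiomic cohort: continuous gradients (no clusters), a triangular
sample distribution in two latent dimensions, a ploidy axis from
near-haploid to near-tetraploid, and a bimodal CpG-island methylation
(CIMP) axis.
"""

import mesoaxes as mx

ds = mx.generate_dataset(mx.GeneratorConfig(seed=1))

print(f"samples: {ds.expression.n_samples}")
print(f"expression genes: {ds.expression.n_features}")
print(f"methylation CpGs: {ds.meth_beta.n_features} in {len(ds.island_map)} islands")
print(f"copy-number genes: {ds.copy_number.n_features}")
print(f"alterations: {list(ds.alterations.columns)} "
      f"(prevalence {ds.alterations.mean().round(2).to_dict()})")
print(f"ploidy range: {ds.truth.ploidy_true.min():.2f}-{ds.truth.ploidy_true.max():.2f}")
print(f"true CIMP range: {ds.truth.cimp_true.min():.2f}-{ds.truth.cimp_true.max():.2f}")
# ploidy spans roughly haploid to tetraploid; CIMP spans low to high because
# island methylation is logistically coupled to the fourth latent factor.
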