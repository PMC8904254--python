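"""Compute summary metrics for a T-cell receptor repertoire sample.

Generates a synthetic blood repertoire, then computes Simpson clonality and
rarefied richness, comparing the Monte-Carlo rarefaction estimate with its
closed-form hypergeometric expectation.
"""

from immunotrack import (
    RepertoireModel,
    gen_repertoire,
    rarefied_richness,
    rarefied_richness_expectation,
    simpson_clonality,
)

model = RepertoireModel(seed=11)
sample = gen_repertoire(model, "baseline", sample_id="blood_baseline")

print(f"total templates:     {sample.total_templates}")
print(f"simpson clonality:   {simpson_clonality(sample):.4f}")

depth = sample.total_templates // 2
counts = sample.clonotypes.loc[sample.clonotypes["productive"], "templates"].to_numpy()
mc = rarefied_richness(sample, depth=depth, n_draws=100, seed=1)
exact = rarefied_richness_expectation(counts, depth)
print(f"rarefied richness at depth {depth}: {mc:.1f} (Monte Carlo)")
print(f"closed-form expectation:        {exact:.1f}")
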