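"""Identify vaccine-associated clones and track them over time.

Compares a baseline blood repertoire against an antigen-sorted T-cell
sample with the per-clone conditional binomial test (FDR 0.01), builds the
vaccine-associated clone set, and follows its cumulative frequency across
on-treatment timepoints.
"""

from immunotrack import (
    RepertoireModel,
    cumulative_vaccine_frequency,
    differential_abundance,
    gen_repertoire,
    gen_sorted_sample,
    vaccine_associated_set,
)

model = RepertoireModel(
    seed=21,
    vaccine_clones={10: "IDO", 20: "IDO", 30: "PDL1", 40: "PDL1"},
    expansion_fold={"C3": 4.0, "C6": 6.0},
)
baseline = gen_repertoire(model, "baseline", sample_id="blood_baseline")
sorted_ido = gen_sorted_sample(model, "IDO", purity=0.8, sample_id="sorted_IDO")

result = differential_abundance(baseline, sorted_ido, alpha=0.01)
print(f"clones tested: {len(result)}, enriched: {int(result['enriched'].sum())}")

vaccine_set = vaccine_associated_set("S01", [result])
print(f"vaccine-associated clones: {sorted(vaccine_set.clones)}")

for tp in ("baseline", "C3", "C6"):
    blood = gen_repertoire(model, tp, sample_id=f"blood_{tp}")
    freq = cumulative_vaccine_frequency(vaccine_set.clones, blood)
    print(f"cumulative vaccine-clone frequency at {tp:>8}: {freq:.4f}")
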