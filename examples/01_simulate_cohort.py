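"""Simulate a structured multi-ancestry cohort with planted founder variants.

Two ancestries diverged at Fst 0.05, trio families with affected
probands, duplicate samples, 5% self-report errors, and one founder
variant planted at carrier frequency 1/50 in the first ancestry.
"""

from carrierpanel import FounderVariantSpec, SimulationConfig, simulate_cohort

config = SimulationConfig(
    population_sizes=(400, 300),
    population_names=("ancestry_a", "ancestry_b"),
    fst_per_population=0.05,
    n_background_variants=2000,
    founder_variant_specs=(FounderVariantSpec("ancestry_a", 0.02, gene="GENE1"),),
    n_trios_per_population=5,
    n_duplicates=3,
    seed=42,
)
matrix, meta, annotations = simulate_cohort(config)

print(f"cohort: {matrix.n_samples} samples x {matrix.n_variants} variants")
print("roles:", meta["role"].value_counts().to_dict())
founder_key = annotations.index[annotations["is_founder"]][0]
j = matrix.variant_index(founder_key)
carriers = int((matrix.dosages[:, j] >= 1).sum())
print(f"planted founder variant {founder_key}: {carriers} carriers in the cohort")
# 0.02 x 400 = 8 planted heterozygotes, plus any trio children who
# inherited the allele; the variant is absent from ancestry_b.
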