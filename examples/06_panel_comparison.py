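"""Compare candidates with existing panels and validate sensitivity.

Variant-based panels match on the canonical allele key, gene-based
panels on the gene symbol.  Validation converts reference allele
frequencies to expected carrier frequencies under Hardy-Weinberg
(2p(1-p)) and measures how many reference variants above 1/200 the
pipeline's candidate set recovered.
"""

from fractions import Fraction

from carrierpanel import (
    PanelDefinition,
    compare_to_panels,
    hwe_carrier_frequency,
    sensitivity_validation,
)

variants = {"1:100:A:G": "GENE1", "2:200:C:T": "GENE2", "3:300:G:A": "GENE3"}
panels = [
    PanelDefinition("targeted", "variant_based", frozenset({"1:100:A:G"})),
    PanelDefinition("panethnic", "gene_based", frozenset({"GENE2", "CFTR"})),
]
matrix = compare_to_panels(variants, panels)
print(matrix.to_string(index=False))

p = 0.0075
print(f"\nallele frequency {p} -> HWE carrier frequency "
      f"{hwe_carrier_frequency(p):.5f} (~1/{1 / hwe_carrier_frequency(p):.0f})")

reference_afs = {f"1:{i}:A:G": 0.01 for i in range(20)}  # all > 1/200 as carriers
candidates = {f"1:{i}:A:G" for i in range(18)}           # two never genotyped
result = sensitivity_validation(reference_afs, candidates, Fraction(1, 200))
print(f"recall: {result['n_recovered']}/{result['n_reference']} "
      f"= {result['recall']:.2f}")
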