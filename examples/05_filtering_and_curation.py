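"""Candidate selection, the exclusion cascade, and evidence curation.

Starting from an annotation table: keep P/LP-reported variants,
subtract an existing panel, drop common / repeatedly-homozygous / mild
variants, then decide each survivor from structured evidence.
"""

import pandas as pd

from carrierpanel import (
    EvidenceItem,
    PanelDefinition,
    curate_variant,
    exclusion_filters,
    select_reported_plp,
    subtract_panel,
    summarize_curation,
)

annotations = pd.DataFrame(
    {
        "classifications": ["clinvar=P", "community=LP", "clinvar=VUS",
                            "clinvar=P", "clinvar=P"],
        "severity": ["severe", "severe", "severe", "mild", "severe"],
        "reference_overall_af": [0.001, 0.002, 0.001, 0.0005, 0.02],
        "reference_homozygote_count": [0, 1, 0, 0, 12],
    },
    index=pd.Index(
        ["1:100:A:G", "2:200:C:T", "3:300:G:A", "4:400:T:C", "5:500:A:C"],
        name="variant_key",
    ),
)

candidates = select_reported_plp(annotations)
print(f"P/LP-reported candidates: {len(candidates)} of {len(annotations)}")

existing = PanelDefinition("national", "variant_based", frozenset({"2:200:C:T"}))
novel = subtract_panel(candidates, existing)
print(f"novel after panel subtraction: {novel}")

result = exclusion_filters(novel, annotations)
print(f"retained after exclusion cascade: {result.retained}")
print(f"excluded with reasons: {result.excluded}")

evidence = {
    "1:100:A:G": [EvidenceItem("1:100:A:G", "community_case", "homozygous",
                               "affected_concordant", "case_17")],
}
decisions = [
    curate_variant(k, evidence.get(k, []), annotations.loc[k, "severity"])
    for k in result.retained
]
counts, panel = summarize_curation(decisions, genes={"1:100:A:G": "GENE1"})
print(f"curation outcomes: {dict(counts)}")
print(f"final panel:\n{panel.to_string(index=False)}")
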