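"""Rule-based curation of candidate founder variants from structured evidence.

Evidence arrives as structured records (community cases with zygosity
and phenotype status, literature reports, database submissions).  The
decision rules formalize the usual manual triage, with a fixed
precedence:

1. a homozygous or compound-het case in a *healthy* individual — or one
   with no associated phenotype — is benign evidence and excludes the
   variant (this always wins, even against affected cases);
2. a mild associated condition excludes the variant from a screening
   panel;
3. a homozygous/compound-het case with a concordant affected phenotype,
   or a literature report marked causal, confirms the variant;
4. anything else leaves the variant of uncertain significance.

The decision is a pure function of the evidence multiset and severity:
reordering evidence never changes the outcome.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

EVIDENCE_KINDS = {"community_case", "literature_report", "clinvar_submission"}
ZYGOSITIES = {"homozygous", "compound_het", "heterozygous", "NA"}
PHENOTYPES = {"affected_concordant", "healthy", "unknown"}

CONFIRMED = "confirmed_pfv"
EXCLUDED_BENIGN = "excluded_benign_evidence"
EXCLUDED_MILD = "excluded_mild"
UNCERTAIN = "uncertain"

OUTCOMES = (CONFIRMED, EXCLUDED_BENIGN, EXCLUDED_MILD, UNCERTAIN)


@dataclass(frozen=True)
class EvidenceItem:
    """One structured piece of evidence about a candidate variant."""

    variant_key: str
    kind: str
    zygosity: str = "NA"
    phenotype_status: str = "unknown"
    source_id: str = ""
    causal: bool = False  # literature reports: asserted causal

    def __post_init__(self) -> None:
        if self.kind not in EVIDENCE_KINDS:
            raise ValueError(f"unknown evidence kind {self.kind!r}")
        if self.zygosity not in ZYGOSITIES:
            raise ValueError(f"unknown zygosity {self.zygosity!r}")
        if self.phenotype_status not in PHENOTYPES:
            raise ValueError(f"unknown phenotype status {self.phenotype_status!r}")
        if self.kind == "community_case" and self.zygosity == "NA":
            raise ValueError("community_case evidence must carry a zygosity")


@dataclass(frozen=True)
class CurationDecision:
    variant_key: str
    outcome: str
    supporting_items: tuple[str, ...] = ()
    flagged_for_review: bool = False

    def __post_init__(self) -> None:
        if self.outcome not in OUTCOMES:
            raise ValueError(f"unknown outcome {self.outcome!r}")
        if self.outcome == CONFIRMED and not self.supporting_items:
            raise ValueError("confirmed_pfv requires at least one supporting item")


def _biallelic(item: EvidenceItem) -> bool:
    return item.kind == "community_case" and item.zygosity in ("homozygous", "compound_het")


def curate_variant(
    variant_key: str,
    evidence: Iterable[EvidenceItem],
    severity: str = "",
) -> CurationDecision:
    """Decide one candidate's fate from its evidence and condition severity."""
    items = list(evidence)
    for item in items:
        if item.variant_key != variant_key:
            raise ValueError(
                f"evidence for {item.variant_key} supplied to candidate {variant_key}"
            )

    benign = [
        it for it in items
        if _biallelic(it) and it.phenotype_status in ("healthy", "unknown")
    ]
    confirming = [
        it for it in items
        if (_biallelic(it) and it.phenotype_status == "affected_concordant")
        or (it.kind == "literature_report" and it.causal)
    ]
    contradictory = bool(benign) and bool(confirming)

    if benign:
        return CurationDecision(
            variant_key,
            EXCLUDED_BENIGN,
            tuple(sorted(it.source_id for it in benign)),
            flagged_for_review=contradictory,
        )
    if severity == "mild":
        return CurationDecision(variant_key, EXCLUDED_MILD)
    if confirming:
        return CurationDecision(
            variant_key,
            CONFIRMED,
            tuple(sorted(it.source_id for it in confirming)),
        )
    return CurationDecision(variant_key, UNCERTAIN)


def summarize_curation(
    decisions: Iterable[CurationDecision],
    tiers: Mapping[str, int] | None = None,
    genes: Mapping[str, str] | None = None,
) -> tuple[Counter, pd.DataFrame]:
    """Outcome counts plus the final panel (confirmed variants only).

    The panel is ordered by tier, then gene, then variant key — a
    deterministic, review-friendly ordering.  Duplicate decisions for
    one variant are an error.
    """
    decisions = list(decisions)
    seen = Counter(d.variant_key for d in decisions)
    dupes = [k for k, c in seen.items() if c > 1]
    if dupes:
        raise ValueError(f"duplicate curation decisions for: {dupes}")
    counts = Counter(d.outcome for d in decisions)
    rows = []
    for d in decisions:
        if d.outcome != CONFIRMED:
            continue
        rows.append(
            {
                "variant_key": d.variant_key,
                "gene": (genes or {}).get(d.variant_key, ""),
                "tier": (tiers or {}).get(d.variant_key, pd.NA),
                "supporting_items": ";".join(d.supporting_items),
            }
        )
    panel = pd.DataFrame(rows, columns=["variant_key", "gene", "tier", "supporting_items"])
    if len(panel):
        panel = panel.sort_values(
            ["tier", "gene", "variant_key"], na_position="last"
        ).reset_index(drop=True)
    return counts, panel
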