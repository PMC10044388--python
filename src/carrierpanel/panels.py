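"""Variant-key normalization, panel membership, and sensitivity validation.

Carrier-screening panels come in two flavours: variant-based (explicit
genotype lists, matched on the canonical allele key) and gene-based
(full-gene sequencing panels, matched on the gene symbol).  Cross-panel
matching requires one canonical representation per variant, so all keys
are trimmed, left-aligned where a reference sequence is available, and
uppercased before comparison.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction
from typing import Iterable, Mapping

import pandas as pd

_VALID_BASES = frozenset("ACGT")


def normalize_variant_key(
    chrom: str,
    pos: int,
    ref: str,
    alt: str,
    reference: str | None = None,
) -> tuple[str, int, str, str]:
    """Canonicalize one variant to (chrom, 1-based pos, ref, alt).

    Shared suffix bases are trimmed first, then shared prefix bases
    (advancing the position).  When ``reference`` (the full chromosome
    sequence, 0-based string) is supplied, indels are left-aligned
    against it in the usual fashion: while both alleles end in the same
    base, drop that base and prepend the reference base to the left.

    Raises
    ------
    ValueError
        for empty or non-ACGT alleles, or when ref == alt after
        normalization (not a variant).
    """
    ref = ref.upper()
    alt = alt.upper()
    if not ref or not alt:
        raise ValueError(f"empty allele at {chrom}:{pos}")
    if not (_VALID_BASES.issuperset(ref) and _VALID_BASES.issuperset(alt)):
        raise ValueError(f"non-ACGT allele at {chrom}:{pos} ({ref}>{alt})")
    if ref == alt:
        raise ValueError(f"ref equals alt at {chrom}:{pos} ({ref})")

    # trim shared suffix, keeping at least one base in each allele
    while len(ref) > 1 and len(alt) > 1 and ref[-1] == alt[-1]:
        ref, alt = ref[:-1], alt[:-1]

    # left-align indels against the reference when available
    if reference is not None:
        while (
            len(ref) != len(alt)
            and ref[-1] == alt[-1]
            and pos > 1
        ):
            prev = reference[pos - 2].upper()
            ref = prev + ref[:-1]
            alt = prev + alt[:-1]
            pos -= 1

    # trim shared prefix, advancing the position
    while len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
        ref, alt = ref[1:], alt[1:]
        pos += 1
    if ref == alt:
        raise ValueError(f"ref equals alt at {chrom}:{pos} after trimming")
    return str(chrom), int(pos), ref, alt


def variant_key_str(chrom: str, pos: int, ref: str, alt: str) -> str:
    """Render a normalized tuple as the canonical ``chrom:pos:ref:alt`` key."""
    return f"{chrom}:{pos}:{ref}:{alt}"


@dataclass
class PanelDefinition:
    """A carrier-screening panel: either explicit variant keys or gene symbols."""

    name: str
    kind: str  # "variant_based" | "gene_based"
    entries: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if self.kind not in ("variant_based", "gene_based"):
            raise ValueError(f"unknown panel kind {self.kind!r}")
        self.entries = frozenset(self.entries)

    def contains_variant(self, variant_key: str) -> bool:
        return self.kind == "variant_based" and variant_key in self.entries

    def contains_gene(self, gene: str) -> bool:
        return self.kind == "gene_based" and gene in self.entries


def compare_to_panels(
    variants: Mapping[str, str],
    panels: Iterable[PanelDefinition],
) -> pd.DataFrame:
    """Membership matrix of variants against a list of panels.

    Parameters
    ----------
    variants:
        mapping of canonical variant key -> gene symbol.
    panels:
        panel definitions; variant-based panels match on the key,
        gene-based panels on the gene symbol.

    Returns
    -------
    DataFrame with one row per (variant, panel) recording key-level and
    gene-level membership plus the combined ``covered`` call.
    """
    rows = []
    for key, gene in variants.items():
        for panel in panels:
            key_match = panel.contains_variant(key)
            gene_match = panel.contains_gene(gene)
            rows.append(
                {
                    "variant_key": key,
                    "gene": gene,
                    "panel": panel.name,
                    "panel_kind": panel.kind,
                    "variant_match": key_match,
                    "gene_match": gene_match,
                    "covered": key_match or gene_match,
                }
            )
    columns = [
        "variant_key", "gene", "panel", "panel_kind",
        "variant_match", "gene_match", "covered",
    ]
    return pd.DataFrame(rows, columns=columns)


def hwe_carrier_frequency(allele_frequency: float, approximate: bool = False) -> float:
    """Expected carrier (heterozygote) frequency under Hardy-Weinberg.

    For allele frequency p the heterozygote frequency is 2p(1-p); the
    ``approximate`` flag returns 2p instead, which agrees to <0.5%
    relative at rare-variant scale.
    """
    p = float(allele_frequency)
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"allele frequency {p} outside [0, 1]")
    if approximate:
        return 2.0 * p
    return 2.0 * p * (1.0 - p)


def sensitivity_validation(
    reference_afs: Mapping[str, float],
    candidate_set: Iterable[str],
    min_frequency: Fraction | float = Fraction(1, 200),
    candidate_tiers: Mapping[str, int] | None = None,
    reference_tiers: Mapping[str, int] | None = None,
) -> dict:
    """Recall of a reference panel's common variants by the pipeline.

    The reference tier-2/3 set consists of panel variants whose
    HWE-derived carrier frequency strictly exceeds ``min_frequency``
    (strict ">", as used when validating against an external allele
    frequency resource).  Recall is the fraction of that set present in
    the pipeline's candidate set.  When tier assignments are supplied
    for both sides, a cross-tabulation of reference vs cohort tiers is
    included for the overlapping variants.
    """
    candidates = set(candidate_set)
    threshold = float(min_frequency)
    reference_set = {
        key for key, af in reference_afs.items()
        if hwe_carrier_frequency(af) > threshold
    }
    overlap = reference_set & candidates
    result = {
        "reference_set": reference_set,
        "n_reference": len(reference_set),
        "n_recovered": len(overlap),
        "recall": (len(overlap) / len(reference_set)) if reference_set else None,
    }
    if candidate_tiers is not None and reference_tiers is not None:
        pairs = [
            (reference_tiers.get(k), candidate_tiers.get(k))
            for k in sorted(overlap)
        ]
        frame = pd.DataFrame(pairs, columns=["reference_tier", "cohort_tier"])
        result["concordance"] = pd.crosstab(frame["reference_tier"], frame["cohort_tier"])
    return result
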