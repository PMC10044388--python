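"""Per-ancestry carrier frequencies, proband-parent correction and ACMG tiers.

The central statistic is the carrier frequency: the fraction of
individuals in an ancestry group with at least one alternate allele at
a variant, conventionally rendered "1 in N".  Tier thresholds follow
the ACMG carrier-screening strata: tier 1 via an explicit gene list,
tier 2 at carrier frequency >= 1/100, tier 3 at >= 1/200 or X-linked
inheritance, tier 4 below 1/200.  Frequencies are compared as exact
fractions; the rounded "1/N" string is presentation only.

Because clinical cohorts are enriched for affected families, parents of
probands homozygous (or compound heterozygous) for a variant inflate
that variant's carrier count.  ``remove_homozygous_proband_parents``
excludes such parents from the affected variant's numerator and
denominator only, leaving every other variant untouched.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from fractions import Fraction
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .containers import MISSING, GenotypeMatrix

TIER2_THRESHOLD = Fraction(1, 100)
TIER3_THRESHOLD = Fraction(1, 200)


@dataclass(frozen=True)
class FrequencyRecord:
    """Carrier counts for one (ancestry, variant) cell.

    ``group_size`` counts samples of the ancestry with a non-missing
    call at the variant, so the frequency is an exact ratio of observed
    counts.
    """

    ancestry: str
    variant_key: str
    n_carriers: int
    n_homozygous: int
    group_size: int

    def __post_init__(self) -> None:
        if not 0 <= self.n_homozygous <= self.n_carriers <= max(self.group_size, 0):
            raise ValueError(
                f"inconsistent counts for {self.variant_key} in {self.ancestry}: "
                f"{self.n_homozygous} hom <= {self.n_carriers} carriers <= {self.group_size}"
            )

    @property
    def frequency(self) -> Fraction:
        if self.group_size == 0:
            return Fraction(0)
        return Fraction(self.n_carriers, self.group_size)

    @property
    def one_in_n(self) -> str | None:
        """Rounded "1/N" rendering (half away from zero); None when no carriers."""
        if self.n_carriers == 0 or self.group_size == 0:
            return None
        n = math.floor(self.group_size / self.n_carriers + 0.5)
        return f"1/{n}"


@dataclass(frozen=True)
class TierResult:
    tier: int  # 1..4
    basis: str  # "tier1_list" | "frequency" | "x_linked"


def carrier_frequencies(
    matrix: GenotypeMatrix,
    ancestry_labels: pd.Series | Mapping[str, str],
    variant_keys: Sequence[str] | None = None,
    excluded_samples: Mapping[str, set[str]] | None = None,
) -> list[FrequencyRecord]:
    """Carrier counts per (ancestry, variant) over non-missing calls.

    ``ancestry_labels`` maps sample id -> ancestry; samples labelled
    ``unassigned`` form their own group (reported, but normally ignored
    downstream).  ``excluded_samples`` optionally maps a variant key to
    sample ids dropped from that variant's counts only (the
    proband-parent correction uses this hook).
    """
    labels = pd.Series(ancestry_labels)
    if variant_keys is None:
        variant_keys = list(matrix.variant_keys)
    sample_pos = {s: i for i, s in enumerate(matrix.sample_ids)}
    missing_samples = [s for s in labels.index if s not in sample_pos]
    if missing_samples:
        raise KeyError(f"labelled samples absent from matrix: {missing_samples[:5]}")

    groups: dict[str, np.ndarray] = {
        str(anc): np.array([sample_pos[s] for s in idx], dtype=np.intp)
        for anc, idx in labels.groupby(labels).groups.items()
    }
    records: list[FrequencyRecord] = []
    for key in variant_keys:
        j = matrix.variant_index(key)
        col = matrix.dosages[:, j]
        dropped = (excluded_samples or {}).get(key, set())
        dropped_rows = {sample_pos[s] for s in dropped if s in sample_pos}
        for anc in sorted(groups):
            rows = groups[anc]
            if dropped_rows:
                rows = rows[~np.isin(rows, list(dropped_rows))]
            calls = col[rows]
            called = calls != MISSING
            records.append(
                FrequencyRecord(
                    ancestry=anc,
                    variant_key=key,
                    n_carriers=int(np.sum(calls[called] >= 1)),
                    n_homozygous=int(np.sum(calls[called] == 2)),
                    group_size=int(called.sum()),
                )
            )
    return records


def homozygous_proband_parents(
    matrix: GenotypeMatrix,
    meta: pd.DataFrame,
    variant_keys: Sequence[str],
    gene_of: Mapping[str, str] | None = None,
) -> dict[str, set[str]]:
    """Map variant key -> parent sample ids to exclude from its counts.

    A parent is excluded for a variant when their proband (same family,
    role ``proband``) is homozygous for it, or compound heterozygous
    involving it — i.e. heterozygous there and at a second variant of
    the same gene (gene map required to detect this).
    """
    probands = meta.index[(meta["role"] == "proband")]
    keyset = [k for k in variant_keys if k in set(matrix.variant_keys)]
    key_idx = {k: matrix.variant_index(k) for k in keyset}
    out: dict[str, set[str]] = {k: set() for k in keyset}
    for proband in probands:
        fam = meta.loc[proband, "family_id"]
        if not fam:
            continue
        parents = meta.index[
            (meta["family_id"] == fam) & (meta["role"] == "parent")
        ].tolist()
        if not parents:
            warnings.warn(f"proband {proband} has no linked parents", stacklevel=2)
            continue
        if proband not in set(matrix.sample_ids):
            warnings.warn(f"proband {proband} has no genotypes", stacklevel=2)
            continue
        row = matrix.dosages[matrix.sample_index(proband), :]
        for key in keyset:
            dose = row[key_idx[key]]
            hit = dose == 2
            if not hit and dose == 1 and gene_of is not None:
                gene = gene_of.get(key)
                if gene is not None:
                    for other, j2 in key_idx.items():
                        if other != key and gene_of.get(other) == gene and row[j2] >= 1:
                            hit = True
                            break
            if hit:
                out[key].update(parents)
    return {k: v for k, v in out.items() if v}


def remove_homozygous_proband_parents(
    records: Iterable[FrequencyRecord],
    matrix: GenotypeMatrix,
    meta: pd.DataFrame,
    variant_keys: Sequence[str],
    ancestry_labels: pd.Series | Mapping[str, str],
    gene_of: Mapping[str, str] | None = None,
) -> list[FrequencyRecord]:
    """Recompute records excluding parents of homozygous/compound-het probands.

    Only the affected variants' records change; every exclusion is an
    exact recount over the reduced sample set.
    """
    exclusions = homozygous_proband_parents(matrix, meta, variant_keys, gene_of)
    if not exclusions:
        return list(records)
    adjusted = carrier_frequencies(
        matrix,
        ancestry_labels,
        variant_keys=list(exclusions),
        excluded_samples=exclusions,
    )
    lookup = {(r.ancestry, r.variant_key): r for r in adjusted}
    return [
        lookup.get((r.ancestry, r.variant_key), r)
        for r in records
    ]


def assign_tier(
    record: FrequencyRecord,
    inheritance: str,
    tier1_genes: Iterable[str] = (),
    gene: str | None = None,
    strict_tier3: bool = False,
) -> TierResult:
    """ACMG tier for one frequency record.

    Tier 1 only via explicit gene-list membership; otherwise the
    frequency rule on the exact fraction: >= 1/100 tier 2, >= 1/200 (or
    X-linked inheritance) tier 3, else tier 4.  ``strict_tier3``
    switches the 1/200 comparison to a strict ">".
    """
    if record.group_size <= 0:
        raise ValueError(f"tier undefined for empty group ({record.variant_key})")
    if gene is not None and gene in set(tier1_genes):
        return TierResult(1, "tier1_list")
    f = record.frequency
    if f >= TIER2_THRESHOLD:
        return TierResult(2, "frequency")
    passes_t3 = f > TIER3_THRESHOLD if strict_tier3 else f >= TIER3_THRESHOLD
    if passes_t3:
        return TierResult(3, "frequency")
    if inheritance == "XL":
        return TierResult(3, "x_linked")
    return TierResult(4, "frequency")


def frequency_table(
    records: Iterable[FrequencyRecord],
    annotations: pd.DataFrame | None = None,
    tier1_genes: Iterable[str] = (),
    strict_tier3: bool = False,
) -> pd.DataFrame:
    """Tidy frame of records, with gene/tier columns when annotations are given."""
    rows = []
    tier1 = set(tier1_genes)
    for r in records:
        row = {
            "ancestry": r.ancestry,
            "variant_key": r.variant_key,
            "n_carriers": r.n_carriers,
            "n_homozygous": r.n_homozygous,
            "group_size": r.group_size,
            "frequency": float(r.frequency) if r.group_size else 0.0,
            "one_in_n": r.one_in_n or "",
        }
        if annotations is not None and r.variant_key in annotations.index:
            gene = annotations.loc[r.variant_key, "gene"]
            inh = annotations.loc[r.variant_key, "inheritance"]
            row["gene"] = gene
            if r.group_size > 0:
                row["tier"] = assign_tier(
                    r, inh, tier1, gene=gene, strict_tier3=strict_tier3
                ).tier
            else:
                row["tier"] = pd.NA
        rows.append(row)
    return pd.DataFrame(rows)


def wilson_interval(n_carriers: int, group_size: int, confidence: float = 0.95) -> tuple[float, float]:
    """Wilson score interval for a carrier frequency (reporting utility;
    never used for tiering)."""
    from scipy.stats import norm

    if group_size <= 0:
        raise ValueError("group_size must be positive")
    z = norm.ppf(0.5 + confidence / 2.0)
    p = n_carriers / group_size
    denom = 1.0 + z * z / group_size
    center = (p + z * z / (2 * group_size)) / denom
    half = z * math.sqrt(p * (1 - p) / group_size + z * z / (4 * group_size**2)) / denom
    return max(0.0, center - half), min(1.0, center + half)
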