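"""Candidate founder-variant selection and the exclusion cascade.

Candidates are variants with at least one pathogenic / likely
pathogenic (P/LP) classification from any source, not already covered
by an existing panel, and at or above a minimum carrier frequency in at
least one target ancestry.  Three automatable exclusion rules then
remove variants unlikely to be true founder variants: common in the
reference population (overall AF > 0.5%), repeatedly seen homozygous in
the reference database (>= 3 homozygotes), or associated with a mild
condition.  The rules commute, every exclusion carries its triggering
reasons, and variants with missing annotation stay in play with a
"not evaluable" warning (manual review decides, not silent dropping).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .freqtier import FrequencyRecord
from .panels import PanelDefinition

PLP_CLASSES = {"P", "LP"}

AF_RULE = "af_gt_0.5pct"
HOM_RULE = "hom_ge_3"
MILD_RULE = "mild_condition"

AF_CUTOFF = 0.005
HOM_CUTOFF = 3


def parse_classifications(value: str) -> list[tuple[str, str]]:
    """Parse "source=class;source=class" into (source, class) pairs."""
    if not value or pd.isna(value):
        return []
    pairs = []
    for item in str(value).split(";"):
        item = item.strip()
        if not item:
            continue
        if "=" not in item:
            raise ValueError(f"malformed classification entry {item!r}")
        source, cls = item.split("=", 1)
        pairs.append((source.strip(), cls.strip()))
    return pairs


def select_reported_plp(annotations: pd.DataFrame) -> list[str]:
    """Variant keys with >= 1 P or LP classification call from any source."""
    out = []
    for key, value in annotations["classifications"].items():
        calls = parse_classifications(value)
        if any(cls in PLP_CLASSES for _, cls in calls):
            out.append(key)
    return out


def subtract_panel(candidates: Iterable[str], panel: PanelDefinition) -> list[str]:
    """Remove exact key matches against a variant-based panel."""
    if panel.kind != "variant_based":
        raise ValueError("subtract_panel requires a variant-based panel")
    return [key for key in candidates if key not in panel.entries]


def frequency_gate(
    records: Iterable[FrequencyRecord],
    target_ancestries: Sequence[str],
    min_frequency: Fraction | float = Fraction(1, 200),
) -> list[str]:
    """Variants at carrier frequency >= min_frequency in >= 1 target ancestry.

    Exact-fraction comparison; the boundary is inclusive.
    """
    threshold = (
        min_frequency if isinstance(min_frequency, Fraction) else Fraction(min_frequency).limit_denominator(10**9)
    )
    targets = set(target_ancestries)
    retained: dict[str, None] = {}
    for r in records:
        if r.ancestry in targets and r.group_size > 0 and r.frequency >= threshold:
            retained.setdefault(r.variant_key, None)
    return list(retained)


@dataclass
class ExclusionResult:
    retained: list[str]
    excluded: dict[str, list[str]]  # variant key -> triggering rules
    warnings: list[str] = field(default_factory=list)


def exclusion_filters(
    candidates: Iterable[str],
    annotations: pd.DataFrame,
    af_cutoff: float = AF_CUTOFF,
    hom_cutoff: int = HOM_CUTOFF,
) -> ExclusionResult:
    """Apply the three exclusion rules; order-independent by construction.

    A variant is excluded iff reference_overall_af > ``af_cutoff``
    (strict) OR reference_homozygote_count >= ``hom_cutoff`` OR
    severity == "mild".  Missing fields leave the corresponding rule
    un-triggered and add a not-evaluable warning.
    """
    retained: list[str] = []
    excluded: dict[str, list[str]] = {}
    warns: list[str] = []
    for key in candidates:
        reasons = []
        if key not in annotations.index:
            warns.append(f"{key}: no annotation; not evaluable, retained")
            retained.append(key)
            continue
        row = annotations.loc[key]
        af = row.get("reference_overall_af")
        hom = row.get("reference_homozygote_count")
        severity = row.get("severity")
        if pd.isna(af):
            warns.append(f"{key}: reference AF missing; AF rule not evaluable")
        elif float(af) > af_cutoff:
            reasons.append(AF_RULE)
        if pd.isna(hom):
            warns.append(f"{key}: homozygote count missing; rule not evaluable")
        elif int(hom) >= hom_cutoff:
            reasons.append(HOM_RULE)
        if isinstance(severity, str) and severity == "mild":
            reasons.append(MILD_RULE)
        if reasons:
            excluded[key] = reasons
        else:
            retained.append(key)
    return ExclusionResult(retained=retained, excluded=excluded, warnings=warns)


def exclusion_report(result: ExclusionResult) -> pd.DataFrame:
    rows = [
        {"variant_key": k, "status": "retained", "reasons": ""} for k in result.retained
    ] + [
        {"variant_key": k, "status": "excluded", "reasons": ";".join(v)}
        for k, v in result.excluded.items()
    ]
    return pd.DataFrame(rows, columns=["variant_key", "status", "reasons"])
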