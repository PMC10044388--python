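"""Readers/writers for the standard formats the pipeline exchanges.

Genotypes travel as multi-sample VCF v4.2 (GT only, 1-based positions);
sample metadata, variant annotations, panels, evidence and reference
allele frequencies as tab-separated files.  Multi-allelic VCF records
are split into biallelic rows and every allele pair is normalized to
the canonical key convention before entering the matrix.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
from cyvcf2 import VCF

from .containers import (
    MISSING,
    SAMPLE_META_COLUMNS,
    GenotypeMatrix,
    validate_sample_meta,
    validate_variant_annotation,
)
from .curation import EvidenceItem
from .panels import PanelDefinition, normalize_variant_key, variant_key_str

_GT_STRINGS = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}


def write_vcf(matrix: GenotypeMatrix, path: str | Path, build: str = "GRCh37") -> None:
    """Write the cohort as a minimal multi-sample VCF v4.2 (GT only)."""
    path = Path(path)
    parsed = []
    for key in matrix.variant_keys:
        chrom, pos, ref, alt = key.split(":")
        parsed.append((chrom, int(pos), ref, alt))
    chroms = list(dict.fromkeys(c for c, *_ in parsed))
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##reference={build}\n")
        for c in chroms:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(matrix.sample_ids)
            + "\n"
        )
        for j, (chrom, pos, ref, alt) in enumerate(parsed):
            gts = "\t".join(_GT_STRINGS[int(d)] for d in matrix.dosages[:, j])
            fh.write(f"{chrom}\t{pos}\t.\t{ref}\t{alt}\t.\tPASS\t.\tGT\t{gts}\n")


def read_vcf(path: str | Path) -> GenotypeMatrix:
    """Read a multi-sample VCF into a dosage matrix.

    Diploid GT is parsed to {0,1,2}; half-calls and "./." become
    missing.  Multi-allelic records are split into one biallelic row
    per alternate allele, then normalized to the canonical key.
    """
    vcf = VCF(str(path))
    samples = list(vcf.samples)
    keys: list[str] = []
    columns: list[np.ndarray] = []
    for record in vcf:
        gts = record.genotypes  # list of [a0, a1, phased]
        for ai, alt in enumerate(record.ALT, start=1):
            try:
                chrom, pos, ref, alt_n = normalize_variant_key(
                    record.CHROM, record.POS, record.REF, alt
                )
            except ValueError as exc:
                raise ValueError(f"malformed record at {record.CHROM}:{record.POS}: {exc}")
            key = variant_key_str(chrom, pos, ref, alt_n)
            col = np.empty(len(samples), dtype=np.int8)
            for i, gt in enumerate(gts):
                alleles = gt[:-1]
                if len(alleles) != 2 or any(a < 0 for a in alleles):
                    col[i] = MISSING
                else:
                    col[i] = sum(1 for a in alleles if a == ai)
            keys.append(key)
            columns.append(col)
    if not keys:
        raise ValueError(f"no variant records in {path}")
    dosages = np.stack(columns, axis=1)
    return GenotypeMatrix(dosages, samples, keys)


def write_sample_meta(meta: pd.DataFrame, path: str | Path) -> None:
    validate_sample_meta(meta)
    meta.to_csv(path, sep="\t", index=True, index_label="sample_id")


def read_sample_meta(path: str | Path) -> pd.DataFrame:
    meta = pd.read_csv(
        path, sep="\t", index_col="sample_id", keep_default_na=False,
        dtype={"family_id": str, "duplicate_of": str},
    )
    if "affected" in meta.columns:
        meta["affected"] = meta["affected"].astype(str).str.lower().isin(("true", "1"))
    validate_sample_meta(meta)
    return meta


def write_variant_annotations(ann: pd.DataFrame, path: str | Path) -> None:
    validate_variant_annotation(ann)
    ann.to_csv(path, sep="\t", index=True, index_label="variant_key")


def read_variant_annotations(path: str | Path) -> pd.DataFrame:
    ann = pd.read_csv(
        path, sep="\t", index_col="variant_key", keep_default_na=False,
        dtype={"chrom": str, "classifications": str, "severity": str},
    )
    ann["reference_overall_af"] = pd.to_numeric(ann["reference_overall_af"], errors="coerce")
    ann["reference_homozygote_count"] = pd.to_numeric(
        ann["reference_homozygote_count"], errors="coerce"
    )
    validate_variant_annotation(ann)
    return ann


def read_cohort(vcf_path: str | Path, meta_path: str | Path) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Read genotypes + metadata, requiring identical sample id sets."""
    matrix = read_vcf(vcf_path)
    meta = read_sample_meta(meta_path)
    vcf_ids = set(matrix.sample_ids)
    meta_ids = set(meta.index)
    if vcf_ids != meta_ids:
        diff = sorted(vcf_ids.symmetric_difference(meta_ids))
        raise ValueError(f"sample ids differ between VCF and metadata: {diff[:10]}")
    return matrix, meta.loc[matrix.sample_ids]


def read_panel(path: str | Path, name: str, kind: str) -> PanelDefinition:
    """Read a panel TSV.

    Variant-based panels carry (gene, transcript, hgvs_c, chrom, pos,
    ref, alt) and are normalized to canonical keys; gene-based panels
    carry a single ``gene`` column.
    """
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str}, keep_default_na=False)
    if kind == "gene_based":
        if "gene" not in df.columns:
            raise ValueError(f"gene-based panel {path} lacks a 'gene' column")
        return PanelDefinition(name, kind, frozenset(df["gene"].astype(str)))
    required = ["chrom", "pos", "ref", "alt"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"variant-based panel {path} lacks columns {missing}")
    keys = []
    for line_no, row in enumerate(df.itertuples(index=False), start=2):
        try:
            chrom, pos, ref, alt = normalize_variant_key(
                str(row.chrom), int(row.pos), str(row.ref), str(row.alt)
            )
        except (ValueError, TypeError) as exc:
            raise ValueError(f"malformed panel entry at {path}:{line_no}: {exc}")
        keys.append(variant_key_str(chrom, pos, ref, alt))
    return PanelDefinition(name, "variant_based", frozenset(keys))


def read_evidence(path: str | Path) -> list[EvidenceItem]:
    """Read structured evidence records from TSV."""
    df = pd.read_csv(path, sep="\t", keep_default_na=False)
    items = []
    for row in df.itertuples(index=False):
        items.append(
            EvidenceItem(
                variant_key=str(row.variant_key),
                kind=str(row.kind),
                zygosity=str(getattr(row, "zygosity", "NA") or "NA"),
                phenotype_status=str(getattr(row, "phenotype_status", "unknown") or "unknown"),
                source_id=str(getattr(row, "source_id", "")),
                causal=str(getattr(row, "causal", "")).lower() in ("true", "1"),
            )
        )
    return items


def read_reference_afs(path: str | Path) -> dict[str, float]:
    """Reference allele frequencies keyed by canonical variant key."""
    df = pd.read_csv(path, sep="\t", dtype={"variant_key": str})
    return dict(zip(df["variant_key"], df["af"].astype(float)))
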