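"""End-to-end pipeline: QC -> ancestry -> frequencies -> tiers -> panel.

Every stage writes its tab-separated artifact into the output
directory plus one JSON log line with input/output record counts, so a
run is fully inspectable stage by stage.  Identical configuration and
seed produce byte-identical outputs.
"""

from __future__ import annotations

import json
from fractions import Fraction
from pathlib import Path

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field

from . import ancestry as anc
from . import filters, freqtier, qc
from .curation import curate_variant, summarize_curation
from .io import (
    read_cohort,
    read_evidence,
    read_panel,
    read_reference_afs,
    read_variant_annotations,
)
from .panels import compare_to_panels, sensitivity_validation


class PanelFile(BaseModel):
    model_config = ConfigDict(extra="forbid")
    name: str
    kind: str  # variant_based | gene_based
    path: str


class PipelineConfig(BaseModel):
    """All inputs and thresholds of the end-to-end run.

    Unknown keys are rejected; every threshold is validated against its
    documented domain.
    """

    model_config = ConfigDict(extra="forbid")

    vcf: str
    sample_meta: str
    annotations: str
    output_dir: str
    existing_panel: str | None = None  # variant-based panel to subtract
    compare_panels: list[PanelFile] = Field(default_factory=list)
    evidence: str | None = None
    reference_afs: str | None = None
    tier1_genes: list[str] = Field(default_factory=list)
    target_ancestries: list[str] | None = None  # default: two largest groups

    dup_threshold: float = Field(qc.DUPLICATE_THRESHOLD, gt=0, lt=1)
    second_degree_threshold: float = Field(qc.SECOND_DEGREE_THRESHOLD, gt=0, lt=1)
    kinship_max_sites: int | None = Field(20000, ge=100)
    maf_min: float = Field(0.05, ge=0, le=0.5)
    call_rate_min: float = Field(0.95, ge=0, le=1)
    n_components: int = Field(10, ge=2)
    confidence_threshold: float = Field(0.8, ge=0, le=1)
    training_samples_per_label: int = Field(44, ge=12)
    min_target_frequency: str = "1/200"  # exact fraction, e.g. "1/200"
    af_cutoff: float = Field(0.005, ge=0, le=1)
    hom_cutoff: int = Field(3, ge=0)
    strict_tier3: bool = False
    genome_build: str = "GRCh37"
    seed: int = 0

    @property
    def min_target_fraction(self) -> Fraction:
        return Fraction(self.min_target_frequency)


def _log(fh, stage: str, **counts) -> None:
    fh.write(json.dumps({"stage": stage, **counts}, sort_keys=True) + "\n")


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every stage and write the report bundle.

    Returns a dict of the key in-memory results (retained ids, ancestry
    assignments, frequency table, final panel, ...).
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    results: dict = {}
    with open(out / "log.jsonl", "w") as log:
        matrix, meta = read_cohort(config.vcf, config.sample_meta)
        annotations = read_variant_annotations(config.annotations)
        _log(log, "read_cohort", n_samples=matrix.n_samples, n_variants=matrix.n_variants)

        # ---- QC: probands, duplicates, relatives ----------------------
        retained = qc.prune_cohort(
            matrix,
            meta,
            dup_threshold=config.dup_threshold,
            second_degree_threshold=config.second_degree_threshold,
            max_sites=config.kinship_max_sites,
        )
        (out / "retained_samples.txt").write_text("\n".join(retained) + "\n")
        _log(
            log, "qc_prune",
            n_input=matrix.n_samples,
            n_retained=len(retained),
            n_removed=matrix.n_samples - len(retained),
        )
        qc_matrix = matrix.subset_samples(retained)
        qc_meta = meta.loc[retained]
        results["retained"] = retained

        # ---- ancestry inference ---------------------------------------
        subset = anc.select_common_variants(
            qc_matrix, annotations, maf_min=config.maf_min,
            call_rate_min=config.call_rate_min,
        )
        _log(log, "common_variants", n_input=qc_matrix.n_variants, n_retained=len(subset))
        model = anc.fit_pca(
            qc_matrix, subset, n_components=config.n_components,
            confidence_threshold=config.confidence_threshold,
        )
        scores = model.transform(qc_matrix)
        reported = qc_meta["reported_population"].astype(str)

        rng = np.random.default_rng(config.seed)
        train_idx: list[int] = []
        for label in sorted(reported.unique()):
            rows = np.flatnonzero((reported == label).to_numpy())
            take = min(config.training_samples_per_label, len(rows))
            train_idx.extend(rng.choice(rows, size=take, replace=False))
        train_idx = sorted(train_idx)
        keep = anc.remove_label_outliers(
            scores[train_idx], reported.iloc[train_idx].to_numpy()
        )
        kept_idx = [i for i, k in zip(train_idx, keep) if k]
        _log(
            log, "label_outliers",
            n_input=len(train_idx), n_retained=len(kept_idx),
            n_removed=len(train_idx) - len(kept_idx),
        )
        model = anc.train_classifier(
            scores[kept_idx], reported.iloc[kept_idx].to_numpy(), model
        )
        model.save(out / "ancestry_model.npz")
        assignments = anc.predict_ancestry(model, qc_matrix)
        assignments.to_csv(out / "ancestry_assignments.tsv", sep="\t")
        labels = assignments["ancestry"]
        assigned = labels[labels != "unassigned"]
        _log(
            log, "ancestry_predict",
            n_samples=len(labels), n_assigned=int((labels != "unassigned").sum()),
            n_labels=int(assigned.nunique()),
        )
        results["assignments"] = assignments

        # ---- candidate P/LP variants and their frequencies ------------
        plp = filters.select_reported_plp(annotations)
        plp = [k for k in plp if k in set(qc_matrix.variant_keys)]
        _log(log, "select_plp", n_input=len(annotations), n_retained=len(plp))

        records = freqtier.carrier_frequencies(qc_matrix, assigned, variant_keys=plp)
        gene_of = annotations["gene"].to_dict()
        exclusions = freqtier.homozygous_proband_parents(matrix, meta, plp, gene_of)
        adjusted = freqtier.carrier_frequencies(
            qc_matrix, assigned, variant_keys=plp, excluded_samples=exclusions
        ) if exclusions else records
        _log(
            log, "parent_removal",
            n_variants_affected=len(exclusions),
            n_parents_removed=sum(len(v) for v in exclusions.values()),
        )
        freq_frame = freqtier.frequency_table(
            adjusted, annotations, tier1_genes=config.tier1_genes,
            strict_tier3=config.strict_tier3,
        )
        freq_frame.to_csv(out / "frequencies.tsv", sep="\t", index=False)
        results["frequencies"] = freq_frame

        # ---- candidate gating -----------------------------------------
        candidates = plp
        if config.existing_panel:
            panel = read_panel(config.existing_panel, "existing", "variant_based")
            candidates = filters.subtract_panel(candidates, panel)
        _log(log, "subtract_panel", n_input=len(plp), n_retained=len(candidates))

        targets = config.target_ancestries
        if targets is None:
            sizes = assigned.value_counts()
            targets = list(sizes.index[:2])
        gate_records = [r for r in adjusted if r.variant_key in set(candidates)]
        gated = filters.frequency_gate(
            gate_records, targets, min_frequency=config.min_target_fraction
        )
        _log(log, "frequency_gate", n_input=len(candidates), n_retained=len(gated),
             target_ancestries=sorted(targets))

        excl = filters.exclusion_filters(
            gated, annotations, af_cutoff=config.af_cutoff, hom_cutoff=config.hom_cutoff
        )
        filters.exclusion_report(excl).to_csv(out / "exclusions.tsv", sep="\t", index=False)
        _log(log, "exclusion_filters", n_input=len(gated),
             n_retained=len(excl.retained), n_removed=len(excl.excluded))
        results["candidates"] = excl.retained

        # ---- curation --------------------------------------------------
        evidence = read_evidence(config.evidence) if config.evidence else []
        by_variant: dict[str, list] = {}
        for item in evidence:
            by_variant.setdefault(item.variant_key, []).append(item)
        decisions = [
            curate_variant(
                key, by_variant.get(key, []),
                severity=str(annotations.loc[key, "severity"]) if key in annotations.index else "",
            )
            for key in excl.retained
        ]
        best_tier: dict[str, int] = {}
        for r in adjusted:
            if r.ancestry in targets and r.group_size > 0 and r.n_carriers > 0:
                t = freqtier.assign_tier(
                    r, str(annotations.loc[r.variant_key, "inheritance"]),
                    config.tier1_genes, gene=gene_of.get(r.variant_key),
                    strict_tier3=config.strict_tier3,
                ).tier
                best_tier[r.variant_key] = min(t, best_tier.get(r.variant_key, 4))
        counts, panel_frame = summarize_curation(decisions, tiers=best_tier, genes=gene_of)
        pd.DataFrame(
            [
                {"variant_key": d.variant_key, "outcome": d.outcome,
                 "supporting_items": ";".join(d.supporting_items),
                 "flagged_for_review": d.flagged_for_review}
                for d in decisions
            ]
        ).to_csv(out / "curation.tsv", sep="\t", index=False)
        panel_frame.to_csv(out / "final_panel.tsv", sep="\t", index=False)
        _log(log, "curation", **{k: int(v) for k, v in sorted(counts.items())},
             n_panel=len(panel_frame))
        results["curation_counts"] = counts
        results["final_panel"] = panel_frame

        # ---- comparison and validation --------------------------------
        if config.compare_panels:
            panels = [read_panel(p.path, p.name, p.kind) for p in config.compare_panels]
            membership = compare_to_panels(
                {k: gene_of.get(k, "") for k in excl.retained}, panels
            )
            membership.to_csv(out / "panel_comparison.tsv", sep="\t", index=False)
            _log(log, "panel_comparison", n_rows=len(membership))
            results["panel_comparison"] = membership
        if config.reference_afs:
            afs = read_reference_afs(config.reference_afs)
            validation = sensitivity_validation(
                afs, set(plp), min_frequency=config.min_target_fraction
            )
            with open(out / "validation.tsv", "w") as fh:
                fh.write("n_reference\tn_recovered\trecall\n")
                recall = validation["recall"]
                fh.write(
                    f"{validation['n_reference']}\t{validation['n_recovered']}\t"
                    + (f"{recall:.6f}" if recall is not None else "undefined")
                    + "\n"
                )
            _log(log, "validation", n_reference=validation["n_reference"],
                 n_recovered=validation["n_recovered"])
            results["validation"] = validation
    return results
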