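"""Synthetic cohort generator: reproducibility, Mendelian transmission,
planted structure, and divergence calibration against an independent
per-variant Hudson Fst estimator."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import chi2_contingency

from carrierpanel import (
    MISSING,
    FounderVariantSpec,
    SimulationConfig,
    plant_affected_family,
    simulate_cohort,
)


def hudson_fst(ac1, n1, ac2, n2):
    """Independent per-variant Hudson Fst oracle (ratio of averages).

    ac = alternate allele count, n = total allele count, per population.
    """
    p1, p2 = ac1 / n1, ac2 / n2
    num = (p1 - p2) ** 2 - p1 * (1 - p1) / (n1 - 1) - p2 * (1 - p2) / (n2 - 1)
    den = p1 * (1 - p2) + p2 * (1 - p1)
    ok = den > 0
    return num[ok].sum() / den[ok].sum()


def test_identical_seed_bit_identical():
    cfg = dict(
        population_sizes=(60, 40), n_background_variants=300,
        n_trios_per_population=3, n_duplicates=2, seed=5,
        founder_variant_specs=(FounderVariantSpec("pop00", 0.05),),
    )
    m1, meta1, ann1 = simulate_cohort(SimulationConfig(**cfg))
    m2, meta2, ann2 = simulate_cohort(SimulationConfig(**cfg))
    assert np.array_equal(m1.dosages, m2.dosages)
    assert m1.sample_ids == m2.sample_ids and m1.variant_keys == m2.variant_keys
    pd.testing.assert_frame_equal(meta1, meta2)
    pd.testing.assert_frame_equal(ann1, ann2)


def test_planted_founder_counts_exact(clean_two_pop):
    matrix, meta, ann = clean_two_pop
    founders = ann[ann["is_founder"]]
    for key, row in founders.iterrows():
        j = matrix.variant_index(key)
        target = row["target_population"]
        expected = round(row["target_carrier_frequency"] * (meta["true_population"] == target).sum())
        for pop, grp in meta.groupby("true_population"):
            rows = [matrix.sample_index(s) for s in grp.index]
            col = matrix.dosages[rows, j]
            carriers = int((col == 1).sum())
            if pop == target:
                assert carriers == expected
                assert not (col == 2).any()
            else:
                assert carriers == 0 and not (col == 2).any()


def test_infeasible_founder_spec_rejected():
    cfg = SimulationConfig(
        population_sizes=(10, 10), n_background_variants=50,
        founder_variant_specs=(FounderVariantSpec("pop00", 0.5),),
        n_trios_per_population=0, n_duplicates=0, seed=0,
    )
    # carrier frequency > 0.5 rejected at spec construction already
    with pytest.raises(ValueError):
        FounderVariantSpec("pop00", 0.6)
    # feasible boundary: round(0.5*10)=5 carriers fits
    simulate_cohort(cfg)


def test_mendelian_consistency(structured_cohort):
    matrix, meta, _ = structured_cohort
    trios = meta[meta["role"] == "proband"]
    for child_id, row in trios.iterrows():
        fam = row["family_id"]
        parents = meta.index[(meta["family_id"] == fam) & (meta["role"] == "parent")]
        assert len(parents) == 2
        c = matrix.dosages[matrix.sample_index(child_id)]
        f = matrix.dosages[matrix.sample_index(parents[0])]
        m = matrix.dosages[matrix.sample_index(parents[1])]
        ok = (c != MISSING) & (f != MISSING) & (m != MISSING)
        # child allele count bounded by what each parent can transmit
        lo = (f[ok] == 2).astype(int) + (m[ok] == 2).astype(int)
        hi = 2 - ((f[ok] == 0).astype(int) + (m[ok] == 0).astype(int))
        assert np.all(c[ok] >= lo) and np.all(c[ok] <= hi)


def test_duplicates_copy_template(structured_cohort):
    matrix, meta, _ = structured_cohort
    dups = meta[meta["role"] == "duplicate"]
    assert len(dups) == 4
    for dup_id, row in dups.iterrows():
        a = matrix.dosages[matrix.sample_index(dup_id)]
        b = matrix.dosages[matrix.sample_index(row["duplicate_of"])]
        ok = (a != MISSING) & (b != MISSING)
        assert np.array_equal(a[ok], b[ok])  # copies differ only in missing pattern


def test_label_error_rate_applied(structured_cohort):
    _, meta, _ = structured_cohort
    err = (meta["reported_population"] != meta["true_population"]).mean()
    assert 0.02 < err < 0.09  # nominal 5%


def test_zero_fst_allele_frequencies_homogeneous():
    cfg = SimulationConfig(
        population_sizes=(400, 400), fst_per_population=0.0,
        n_background_variants=400, ancestral_maf_range=(0.1, 0.5),
        n_trios_per_population=0, n_duplicates=0,
        label_error_rate=0.0, missing_rate=0.0, seed=21,
    )
    matrix, meta, _ = cfg, None, None
    matrix, meta, _ = simulate_cohort(cfg)
    pops = [meta.index[meta["true_population"] == p] for p in ("pop00", "pop01")]
    rows = [[matrix.sample_index(s) for s in ids] for ids in pops]
    n_sig = 0
    for j in range(matrix.n_variants):
        table = []
        for r in rows:
            col = matrix.dosages[r, j]
            alt = int(col.sum())
            table.append([alt, 2 * len(r) - alt])
        _, p, *_ = chi2_contingency(np.array(table))
        n_sig += p < 0.01
    assert n_sig / matrix.n_variants <= 0.05


def test_fst_calibration_against_hudson_oracle():
    cfg = SimulationConfig(
        population_sizes=(500, 500), fst_per_population=0.05,
        n_background_variants=5000, n_trios_per_population=0, n_duplicates=0,
        label_error_rate=0.0, missing_rate=0.0, seed=1,
        ancestral_maf_range=(0.05, 0.5),
    )
    matrix, meta, _ = simulate_cohort(cfg)
    g1 = matrix.dosages[:500, :].astype(float)
    g2 = matrix.dosages[500:, :].astype(float)
    fst = hudson_fst(g1.sum(axis=0), 1000.0, g2.sum(axis=0), 1000.0)
    assert 0.03 <= fst <= 0.07


def test_plant_affected_family_homozygous(clean_two_pop):
    matrix, meta, ann = clean_two_pop
    key = ann.index[ann["is_founder"]][0]
    m2, meta2 = plant_affected_family(matrix, meta, ann, key, "ashkenazi", "homozygous")
    fam = meta2[meta2["role"] == "proband"]
    child = fam.index[-1]
    parents = meta2.index[
        (meta2["family_id"] == meta2.loc[child, "family_id"]) & (meta2["role"] == "parent")
    ]
    j = m2.variant_index(key)
    assert m2.dosages[m2.sample_index(child), j] == 2
    for p in parents:
        assert m2.dosages[m2.sample_index(p), j] == 1
    assert meta2.loc[child, "affected"]


def test_plant_affected_family_compound_het(clean_two_pop):
    matrix, meta, ann = clean_two_pop
    # two variants in the same gene: duplicate a founder annotation row
    key = ann.index[ann["is_founder"]][0]
    gene = ann.loc[key, "gene"]
    partner = ann.index[~ann["is_founder"]][0]
    ann2 = ann.copy()
    ann2.loc[partner, "gene"] = gene
    m2, meta2 = plant_affected_family(
        matrix, meta, ann2, key, "ashkenazi", "compound_het"
    )
    child = meta2.index[-1]
    j1, j2 = m2.variant_index(key), m2.variant_index(partner)
    assert m2.dosages[m2.sample_index(child), j1] == 1
    assert m2.dosages[m2.sample_index(child), j2] == 1
    parents = meta2.index[
        (meta2["family_id"] == meta2.loc[child, "family_id"]) & (meta2["role"] == "parent")
    ]
    carries = [
        (m2.dosages[m2.sample_index(p), j1] >= 1, m2.dosages[m2.sample_index(p), j2] >= 1)
        for p in parents
    ]
    # each parent carries exactly one of the two variants
    for c1, c2 in carries:
        assert int(c1) + int(c2) == 1


def test_plant_affected_family_no_capacity():
    cfg = SimulationConfig(
        population_sizes=(2, 50), n_background_variants=50,
        founder_variant_specs=(FounderVariantSpec("pop00", 0.5),),
        n_trios_per_population=1, n_duplicates=0, seed=0,
        label_error_rate=0.0, missing_rate=0.0,
    )
    matrix, meta, ann = simulate_cohort(cfg)
    key = ann.index[ann["is_founder"]][0]
    # both pop00 samples already consumed as trio parents
    with pytest.raises(ValueError, match="unused"):
        plant_affected_family(matrix, meta, ann, key, "pop00", "homozygous")
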