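"""Ancestry inference: common-variant selection, PCA projection,
label-outlier cleaning, classification and its invariances."""

import numpy as np
import pandas as pd
import pytest

from carrierpanel import (
    MISSING,
    AncestryModel,
    SimulationConfig,
    fit_pca,
    predict_ancestry,
    remove_label_outliers,
    select_common_variants,
    simulate_cohort,
    train_classifier,
)


@pytest.fixture(scope="module")
def two_pop():
    cfg = SimulationConfig(
        population_sizes=(200, 200), fst_per_population=0.1,
        n_background_variants=2000, n_trios_per_population=0,
        n_duplicates=0, label_error_rate=0.0, missing_rate=0.01, seed=31,
    )
    return simulate_cohort(cfg)


@pytest.fixture(scope="module")
def fitted(two_pop):
    matrix, meta, ann = two_pop
    subset = select_common_variants(matrix, ann)
    model = fit_pca(matrix, subset)
    scores = model.transform(matrix)
    labels = meta["reported_population"].to_numpy()
    train_classifier(scores, labels, model)
    return model, scores, labels


def test_common_variant_selection_matches_brute_force(two_pop):
    matrix, _, ann = two_pop
    subset = set(select_common_variants(matrix, ann, maf_min=0.05, call_rate_min=0.95))
    expected = set()
    for j, key in enumerate(matrix.variant_keys):
        col = matrix.dosages[:, j]
        called = col != MISSING
        if called.sum() / len(col) < 0.95:
            continue
        af = col[called].sum() / (2 * called.sum())
        if min(af, 1 - af) < 0.05:
            continue
        if str(ann.loc[key, "chrom"]) == "X":
            continue
        expected.add(key)
    assert subset == expected


def test_rare_variant_excluded_common_included():
    from carrierpanel import GenotypeMatrix

    n = 1000
    d = np.zeros((n, 2), dtype=np.int8)
    d[:3, 0] = 1       # 3 carriers of 1000: MAF 0.0015
    d[: n // 2, 1] = 1  # AF 0.25
    matrix = GenotypeMatrix(d, [f"s{i}" for i in range(n)], ["1:1:A:G", "1:2:A:G"])
    ann = pd.DataFrame({"chrom": ["1", "1"]}, index=matrix.variant_keys)
    assert select_common_variants(matrix, ann) == ["1:2:A:G"]
    with pytest.raises(ValueError, match="no variant"):
        select_common_variants(matrix.subset_variants(["1:1:A:G"]), ann)


def test_pc1_separates_populations(two_pop, fitted):
    matrix, meta, _ = two_pop
    _, scores, _ = fitted
    truth = (meta["true_population"] == "pop01").to_numpy()
    side = scores[:, 0] > np.median(scores[:, 0])
    acc = max(np.mean(side == truth), np.mean(side == ~truth))
    assert acc >= 0.99


def test_explained_variance_non_increasing(fitted):
    model, _, _ = fitted
    evr = model.explained_variance_ratio
    assert np.all(np.diff(evr) <= 1e-12)
    assert evr.sum() <= 1.0 + 1e-9


def test_loadings_orthonormal(fitted):
    model, _, _ = fitted
    gram = model.loadings.T @ model.loadings
    assert np.allclose(gram, np.eye(gram.shape[0]), atol=1e-8)


def test_duplicate_samples_identical_scores(two_pop):
    matrix, _, ann = two_pop
    subset = select_common_variants(matrix, ann)
    model = fit_pca(matrix, subset)
    scores = model.transform(matrix)
    dup = matrix.subset_samples([matrix.sample_ids[0]])
    s2 = model.transform(dup)
    assert np.allclose(scores[0], s2[0])


def test_too_few_samples_rejected(two_pop):
    matrix, _, ann = two_pop
    subset = select_common_variants(matrix, ann)
    with pytest.raises(ValueError, match="samples"):
        fit_pca(matrix.subset_samples(matrix.sample_ids[:5]), subset)


def test_outlier_rule_removes_mislabeled_keeps_calibration(two_pop, fitted):
    _, scores, labels = fitted
    # plant 5% label swaps
    rng = np.random.default_rng(3)
    corrupted = labels.copy()
    swap = rng.choice(len(labels), size=20, replace=False)
    corrupted[swap] = np.where(corrupted[swap] == "pop00", "pop01", "pop00")
    keep = remove_label_outliers(scores, corrupted)
    assert (~keep[swap]).mean() >= 0.95
    clean_removed = (~keep[np.setdiff1d(np.arange(len(labels)), swap)]).mean()
    assert clean_removed <= 0.03  # ~1% expected under the null


def test_small_label_group_passes_with_warning(fitted):
    _, scores, labels = fitted
    tiny = labels.copy()
    tiny[:5] = "rare_group"
    with pytest.warns(UserWarning, match="outlier filter skipped"):
        keep = remove_label_outliers(scores[:50], tiny[:50])
    assert keep[:5].all()


def test_single_label_training_rejected(fitted):
    model, scores, _ = fitted
    with pytest.raises(ValueError, match="2 ancestry labels"):
        train_classifier(scores[:20], np.array(["x"] * 20), model)


def test_training_accuracy_and_probabilities(two_pop, fitted):
    matrix, meta, _ = two_pop
    model, scores, labels = fitted
    proba = model.classifier.predict_proba(scores)
    assert np.allclose(proba.sum(axis=1), 1.0, atol=1e-9)
    pred = predict_ancestry(model, matrix)
    assigned = pred["ancestry"] != "unassigned"
    acc = np.mean(pred.loc[assigned, "ancestry"].to_numpy() == labels[assigned.to_numpy()])
    assert acc >= 0.99


def test_prediction_idempotent(two_pop, fitted):
    matrix, _, _ = two_pop
    model, _, _ = fitted
    p1 = predict_ancestry(model, matrix)
    p2 = predict_ancestry(model, matrix)
    pd.testing.assert_frame_equal(p1, p2)


def test_label_permutation_equivariance(two_pop):
    matrix, meta, ann = two_pop
    subset = select_common_variants(matrix, ann)
    model_a = fit_pca(matrix, subset)
    scores = model_a.transform(matrix)
    labels = meta["reported_population"].to_numpy()
    renamed = np.where(labels == "pop00", "zeta", "alpha")
    train_classifier(scores, labels, model_a)
    model_b = fit_pca(matrix, subset)
    train_classifier(scores, renamed, model_b)
    pa = predict_ancestry(model_a, matrix)["ancestry"].to_numpy()
    pb = predict_ancestry(model_b, matrix)["ancestry"].to_numpy()
    mapping = {"pop00": "zeta", "pop01": "alpha", "unassigned": "unassigned"}
    assert all(mapping[a] == b for a, b in zip(pa, pb))


def test_held_out_population_mostly_unassigned():
    cfg = SimulationConfig(
        population_sizes=(150, 150, 150), fst_per_population=0.1,
        n_background_variants=2000, n_trios_per_population=0, n_duplicates=0,
        label_error_rate=0.0, missing_rate=0.0, seed=41,
    )
    matrix, meta, ann = simulate_cohort(cfg)
    train_ids = meta.index[meta["true_population"] != "pop02"]
    held = meta.index[meta["true_population"] == "pop02"]
    sub = matrix.subset_samples(list(train_ids))
    subset = select_common_variants(sub, ann)
    model = fit_pca(sub, subset)
    scores = model.transform(sub)
    train_classifier(scores, meta.loc[train_ids, "reported_population"].to_numpy(), model)
    pred = predict_ancestry(model, matrix.subset_samples(list(held)))
    assert (pred["ancestry"] == "unassigned").mean() >= 0.8


def test_missing_model_variants_reported(two_pop, fitted):
    matrix, _, _ = two_pop
    model, _, _ = fitted
    truncated = matrix.subset_variants(matrix.variant_keys[: len(model.variant_subset) // 2])
    with pytest.raises(KeyError, match="absent"):
        model.transform(truncated)


def test_model_round_trip(tmp_path, two_pop, fitted):
    matrix, _, _ = two_pop
    model, _, _ = fitted
    path = tmp_path / "model.npz"
    model.save(path)
    loaded = AncestryModel.load(path)
    p1 = predict_ancestry(model, matrix)
    p2 = predict_ancestry(loaded, matrix)
    pd.testing.assert_frame_equal(p1, p2)


def test_accuracy_monotone_in_fst():
    accs = []
    for fst in (0.01, 0.05, 0.1):
        cfg = SimulationConfig(
            population_sizes=(120, 120), fst_per_population=fst,
            n_background_variants=1500, n_trios_per_population=0, n_duplicates=0,
            label_error_rate=0.0, missing_rate=0.0, seed=51,
        )
        matrix, meta, ann = simulate_cohort(cfg)
        subset = select_common_variants(matrix, ann)
        model = fit_pca(matrix, subset)
        scores = model.transform(matrix)
        labels = meta["true_population"].to_numpy()
        train = np.r_[0:60, 120:180]
        test = np.setdiff1d(np.arange(240), train)
        train_classifier(scores[train], labels[train], model)
        proba = model.classifier.predict_proba(scores[test])
        pred = np.asarray(model.classifier.classes_)[np.argmax(proba, axis=1)]
        accs.append(np.mean(pred == labels[test]))
    assert accs[0] <= accs[1] + 1e-9 <= accs[2] + 2e-9
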