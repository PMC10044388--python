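"""Infer sample ancestries: PCA on common variants + logistic regression.

Thirteen ancestries at Fst 0.05 with 5% wrong self-reports.  The
outlier rule cleans the training labels, the classifier is trained on
31 samples per label, and every sample is then assigned its most
probable ancestry (low-confidence calls become "unassigned").
"""

import numpy as np

from carrierpanel import (
    SimulationConfig,
    fit_pca,
    predict_ancestry,
    remove_label_outliers,
    select_common_variants,
    simulate_cohort,
    train_classifier,
)

config = SimulationConfig(
    population_sizes=(75,) * 13,
    fst_per_population=0.05,
    n_background_variants=3000,
    n_trios_per_population=0,
    n_duplicates=0,
    label_error_rate=0.05,
    seed=3,
)
matrix, meta, annotations = simulate_cohort(config)

subset = select_common_variants(matrix, annotations)
print(f"common variants for PCA: {len(subset)} of {matrix.n_variants}")
model = fit_pca(matrix, subset)
scores = model.transform(matrix)

reported = meta["reported_population"].to_numpy()
true = meta["true_population"].to_numpy()
keep = remove_label_outliers(scores, reported)
mislabeled = reported != true
print(f"outlier rule removed {int((~keep & mislabeled).sum())} of "
      f"{int(mislabeled.sum())} mislabeled training samples "
      f"(and {int((~keep & ~mislabeled).sum())} correct ones)")

train = np.concatenate([
    np.flatnonzero((reported == lab) & keep)[:31] for lab in np.unique(reported)
])
train_classifier(scores[train], reported[train], model)
pred = predict_ancestry(model, matrix)
test = np.setdiff1d(np.arange(matrix.n_samples), train)
acc = np.mean(pred["ancestry"].to_numpy()[test] == true[test])
print(f"held-out accuracy vs true ancestry: {acc:.3f} "
      f"({pred['ancestry'].nunique()} distinct labels assigned)")
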