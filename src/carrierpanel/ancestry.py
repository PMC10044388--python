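"""PCA-based ancestry inference with a classifier over ten components.

The workflow mirrors standard cohort practice: restrict to common,
well-called autosomal variants; run a centered, scaled PCA keeping the
first ten components; clean the self-reported training labels by
removing samples that do not cluster with their reported ancestry
(squared Mahalanobis distance to the label centroid beyond the
chi-square(10) 99% quantile); fit a multinomial logistic regression on
the ten scores; and predict every sample's most probable ancestry,
flagging low-confidence calls as unassigned so they never enter
ancestry-specific frequency denominators.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import chi2
from sklearn.decomposition import PCA
from sklearn.linear_model import LogisticRegression

from .containers import MISSING, GenotypeMatrix

N_COMPONENTS = 10

_AUTOSOMES = {str(c) for c in range(1, 23)}


@dataclass
class AncestryModel:
    """Frozen projection + classifier: variant subset, centering stats,
    loadings (variants x 10), logistic-regression weights and labels."""

    variant_subset: list[str]
    means: np.ndarray
    scales: np.ndarray
    loadings: np.ndarray  # (n_variants, N_COMPONENTS)
    classifier: LogisticRegression | None = None
    label_set: list[str] = field(default_factory=list)
    confidence_threshold: float = 0.8
    explained_variance_ratio: np.ndarray | None = None

    def transform(self, matrix: GenotypeMatrix) -> np.ndarray:
        """Project samples onto the stored components (no refit).

        Missing dosages are imputed at the stored per-variant mean.
        """
        missing_keys = [k for k in self.variant_subset if k not in set(matrix.variant_keys)]
        if missing_keys:
            shown = ", ".join(missing_keys[:5])
            raise KeyError(
                f"{len(missing_keys)} model variants absent from input matrix: {shown} ..."
            )
        sub = matrix.subset_variants(self.variant_subset)
        x = sub.dosages.astype(np.float64)
        miss = sub.dosages == MISSING
        x[miss] = np.broadcast_to(self.means, x.shape)[miss]
        x = (x - self.means) / self.scales
        return x @ self.loadings

    def save(self, path: str | Path) -> None:
        path = Path(path)
        clf = self.classifier
        np.savez(
            path,
            format_version=np.array([1]),
            means=self.means,
            scales=self.scales,
            loadings=self.loadings,
            explained_variance_ratio=(
                self.explained_variance_ratio
                if self.explained_variance_ratio is not None
                else np.zeros(0)
            ),
            coef=clf.coef_ if clf is not None else np.zeros((0, 0)),
            intercept=clf.intercept_ if clf is not None else np.zeros(0),
            classes=np.array(clf.classes_, dtype=object) if clf is not None else np.zeros(0),
            meta=np.array(
                [
                    json.dumps(
                        {
                            "variant_subset": self.variant_subset,
                            "label_set": self.label_set,
                            "confidence_threshold": self.confidence_threshold,
                        }
                    )
                ],
                dtype=object,
            ),
        )

    @classmethod
    def load(cls, path: str | Path) -> "AncestryModel":
        with np.load(path, allow_pickle=True) as z:
            meta = json.loads(str(z["meta"][0]))
            model = cls(
                variant_subset=meta["variant_subset"],
                means=z["means"],
                scales=z["scales"],
                loadings=z["loadings"],
                label_set=meta["label_set"],
                confidence_threshold=meta["confidence_threshold"],
                explained_variance_ratio=(
                    z["explained_variance_ratio"]
                    if z["explained_variance_ratio"].size
                    else None
                ),
            )
            if z["coef"].size:
                clf = LogisticRegression()
                clf.coef_ = z["coef"]
                clf.intercept_ = z["intercept"]
                clf.classes_ = z["classes"]
                model.classifier = clf
        return model


def select_common_variants(
    matrix: GenotypeMatrix,
    annotations: pd.DataFrame,
    maf_min: float = 0.05,
    call_rate_min: float = 0.95,
) -> list[str]:
    """Autosomal variants with cohort MAF >= maf_min and call rate >= call_rate_min."""
    if matrix.n_samples == 0 or matrix.n_variants == 0:
        raise ValueError("empty genotype matrix")
    d = matrix.dosages
    called = d != MISSING
    n_called = called.sum(axis=0)
    call_rate = n_called / matrix.n_samples
    with np.errstate(divide="ignore", invalid="ignore"):
        af = np.where(n_called > 0, np.where(called, d, 0).sum(axis=0) / (2.0 * n_called), 0.0)
    maf = np.minimum(af, 1.0 - af)
    autosomal = np.array(
        [str(annotations.loc[k, "chrom"]) in _AUTOSOMES for k in matrix.variant_keys]
    )
    keep = autosomal & (maf >= maf_min) & (call_rate >= call_rate_min)
    subset = [k for k, ok in zip(matrix.variant_keys, keep) if ok]
    if not subset:
        raise ValueError(
            "no variant passes the common-variant filter; PCA impossible "
            f"(maf_min={maf_min}, call_rate_min={call_rate_min})"
        )
    return subset


def fit_pca(
    matrix: GenotypeMatrix,
    variant_subset: list[str],
    n_components: int = N_COMPONENTS,
    confidence_threshold: float = 0.8,
) -> AncestryModel:
    """Centered, variance-scaled PCA on the common-variant submatrix.

    Missing dosages are mean-imputed per variant.  Component signs are
    fixed so each column's largest-magnitude loading is positive,
    making the projection reproducible across runs.
    """
    if matrix.n_samples < n_components + 1:
        raise ValueError(
            f"need at least {n_components + 1} samples for {n_components} components, "
            f"got {matrix.n_samples}"
        )
    sub = matrix.subset_variants(variant_subset)
    x = sub.dosages.astype(np.float64)
    miss = sub.dosages == MISSING
    means = np.where(miss, np.nan, x).astype(np.float64)
    means = np.nanmean(means, axis=0)
    x[miss] = np.broadcast_to(means, x.shape)[miss]
    scales = x.std(axis=0, ddof=0)
    scales[scales == 0] = 1.0
    xs = (x - means) / scales

    pca = PCA(n_components=n_components, svd_solver="full", random_state=0)
    pca.fit(xs)
    loadings = pca.components_.T.copy()  # (n_variants, n_components)
    # deterministic sign: largest-magnitude loading positive per component
    for c in range(loadings.shape[1]):
        col = loadings[:, c]
        if col[np.argmax(np.abs(col))] < 0:
            loadings[:, c] = -col
    return AncestryModel(
        variant_subset=list(variant_subset),
        means=means,
        scales=scales,
        loadings=loadings,
        confidence_threshold=confidence_threshold,
        explained_variance_ratio=pca.explained_variance_ratio_.copy(),
    )


def remove_label_outliers(
    scores: np.ndarray,
    reported_labels: pd.Series | np.ndarray,
    distance_quantile: float = 0.99,
    ridge: float = 1e-3,
    min_group: int = 11,
) -> np.ndarray:
    """Boolean mask of training samples that cluster with their reported label.

    A sample is dropped when its squared Mahalanobis distance to its
    own label's centroid exceeds the chi-square(d) ``distance_quantile``
    quantile.  The centroid and covariance are re-estimated on the
    retained samples only, iterating to a fixed point: a plain one-shot
    estimate would let mislabeled samples inflate their reported
    group's covariance and mask themselves.  Labels with fewer than
    ``min_group`` samples pass through unfiltered with a warning.
    """
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(reported_labels)
    n, d = scores.shape
    cutoff = chi2.ppf(distance_quantile, df=d)
    keep = np.ones(n, dtype=bool)
    for label in pd.unique(labels):
        idx = np.flatnonzero(labels == label)
        if len(idx) < min_group:
            warnings.warn(
                f"label {label!r} has only {len(idx)} samples; outlier filter skipped",
                stacklevel=2,
            )
            continue
        pts = scores[idx]
        inlier = np.ones(len(idx), dtype=bool)
        for _ in range(20):  # converges in a handful of iterations
            if inlier.sum() <= d + 1:
                break
            centroid = pts[inlier].mean(axis=0)
            cov = np.cov(pts[inlier], rowvar=False)
            cov = cov + ridge * np.trace(cov) / d * np.eye(d)
            centered = pts - centroid
            d2 = np.einsum("ij,jk,ik->i", centered, np.linalg.inv(cov), centered)
            new_inlier = d2 <= cutoff
            if np.array_equal(new_inlier, inlier):
                break
            inlier = new_inlier
        keep[idx[~inlier]] = False
    return keep


def train_classifier(
    scores: np.ndarray,
    labels: pd.Series | np.ndarray,
    model: AncestryModel,
    c: float = 1.0,
) -> AncestryModel:
    """Fit the multinomial logistic-regression head on retained training scores."""
    labels = np.asarray(labels)
    label_set = sorted(pd.unique(labels))
    if len(label_set) < 2:
        raise ValueError("classifier needs at least 2 ancestry labels")
    clf = LogisticRegression(
        C=c,
        max_iter=2000,
        solver="lbfgs",
        random_state=0,
    )
    clf.fit(np.asarray(scores, dtype=np.float64), labels)
    model.classifier = clf
    model.label_set = label_set
    return model


def predict_ancestry(
    model: AncestryModel,
    matrix: GenotypeMatrix,
) -> pd.DataFrame:
    """Most probable ancestry per sample, with its probability as confidence.

    Samples whose top-class probability falls below the model's
    confidence threshold are labelled ``unassigned`` (and should be
    excluded from per-ancestry denominators downstream).
    """
    if model.classifier is None:
        raise ValueError("model has no trained classifier")
    scores = model.transform(matrix)
    proba = model.classifier.predict_proba(scores)
    top = np.argmax(proba, axis=1)
    confidence = proba[np.arange(len(top)), top]
    labels = np.asarray(model.classifier.classes_)[top].astype(object)
    labels[confidence < model.confidence_threshold] = "unassigned"
    return pd.DataFrame(
        {"ancestry": labels, "confidence": confidence},
        index=pd.Index(matrix.sample_ids, name="sample_id"),
    )
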