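"""Core in-memory containers shared across the pipeline stages.

The cohort substrate is a samples x variants matrix of diploid
alternate-allele dosages (0, 1, 2) with -1 marking a missing call,
wrapped together with its sample and variant identifiers.  Sample
metadata and variant annotations travel as pandas DataFrames indexed
by sample id and canonical variant key respectively.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

MISSING = -1

#: columns every sample-metadata frame carries
SAMPLE_META_COLUMNS = [
    "true_population",
    "reported_population",
    "family_id",
    "role",
    "affected",
    "duplicate_of",
]

#: columns every variant-annotation frame carries
VARIANT_ANNOTATION_COLUMNS = [
    "chrom",
    "pos",
    "ref",
    "alt",
    "gene",
    "classifications",
    "inheritance",
    "condition",
    "severity",
    "reference_overall_af",
    "reference_homozygote_count",
]


@dataclass
class GenotypeMatrix:
    """Samples x variants alternate-allele dosage matrix.

    Attributes
    ----------
    dosages:
        int8 array of shape (n_samples, n_variants); entries in
        {0, 1, 2} or :data:`MISSING` (-1).
    sample_ids:
        sample identifiers, row order.
    variant_keys:
        canonical ``chrom:pos:ref:alt`` keys, column order.
    """

    dosages: np.ndarray
    sample_ids: list[str]
    variant_keys: list[str]

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=np.int8)
        if self.dosages.ndim != 2:
            raise ValueError("dosages must be a 2-D array")
        if self.dosages.shape != (len(self.sample_ids), len(self.variant_keys)):
            raise ValueError(
                f"dosage shape {self.dosages.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.variant_keys)} variants"
            )
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("duplicate sample ids")
        if len(set(self.variant_keys)) != len(self.variant_keys):
            raise ValueError("duplicate variant keys")

    @property
    def n_samples(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_variants(self) -> int:
        return self.dosages.shape[1]

    def sample_index(self, sample_id: str) -> int:
        try:
            return self._sample_lookup[sample_id]
        except AttributeError:
            self._sample_lookup = {s: i for i, s in enumerate(self.sample_ids)}
            return self._sample_lookup[sample_id]

    def variant_index(self, key: str) -> int:
        try:
            return self._variant_lookup[key]
        except AttributeError:
            self._variant_lookup = {k: j for j, k in enumerate(self.variant_keys)}
            return self._variant_lookup[key]

    def subset_samples(self, sample_ids: list[str]) -> "GenotypeMatrix":
        idx = [self.sample_index(s) for s in sample_ids]
        return GenotypeMatrix(self.dosages[idx, :].copy(), list(sample_ids), list(self.variant_keys))

    def subset_variants(self, keys: list[str]) -> "GenotypeMatrix":
        idx = [self.variant_index(k) for k in keys]
        return GenotypeMatrix(self.dosages[:, idx].copy(), list(self.sample_ids), list(keys))

    def copy(self) -> "GenotypeMatrix":
        return GenotypeMatrix(self.dosages.copy(), list(self.sample_ids), list(self.variant_keys))


def empty_sample_meta() -> pd.DataFrame:
    df = pd.DataFrame(columns=SAMPLE_META_COLUMNS)
    df.index.name = "sample_id"
    return df


def validate_sample_meta(meta: pd.DataFrame) -> None:
    missing = [c for c in SAMPLE_META_COLUMNS if c not in meta.columns]
    if missing:
        raise ValueError(f"sample metadata missing columns: {missing}")


def validate_variant_annotation(ann: pd.DataFrame) -> None:
    missing = [c for c in VARIANT_ANNOTATION_COLUMNS if c not in ann.columns]
    if missing:
        raise ValueError(f"variant annotation missing columns: {missing}")
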