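"""Relatedness QC: kinship estimation and cohort pruning.

Pairwise kinship is estimated with the KING-robust between-family
estimator, which needs no allele-frequency estimates and stays unbiased
under population structure — essential in a multi-ethnic cohort:

    phi_hat = (N_het,het - 2 N_opp,hom) / (N_het,i + N_het,j)

over sites called in both samples, where N_het,het counts sites
heterozygous in both, N_opp,hom counts opposite homozygotes (0 vs 2),
and N_het,i / N_het,j are per-sample heterozygote counts.  Expected
values: ~0.5 for duplicates/MZ twins, ~0.25 first degree, ~0.125 second
degree.  Pruning removes affected probands first, then breaks every
remaining pair at or above the second-degree threshold by greedily
deleting the highest-degree vertex of the relatedness graph.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import MISSING, GenotypeMatrix

#: standard kinship thresholds (powers-of-two midpoints): duplicate,
#: first degree, second degree
DUPLICATE_THRESHOLD = 0.354
FIRST_DEGREE_THRESHOLD = 0.177
SECOND_DEGREE_THRESHOLD = 0.0884


@dataclass(frozen=True)
class KinshipEstimate:
    """KING-robust kinship for one sample pair.

    ``phi`` is NaN when the pair has no heterozygous sites (degenerate
    denominator); such pairs are treated as unrelated.
    """

    sample_i: str
    sample_j: str
    phi: float
    n_informative_sites: int

    @property
    def defined(self) -> bool:
        return not math.isnan(self.phi)


def kinship_coefficient(
    genotypes_i: np.ndarray,
    genotypes_j: np.ndarray,
    sample_i: str = "i",
    sample_j: str = "j",
) -> KinshipEstimate:
    """KING-robust kinship between two dosage vectors.

    Sites missing in either sample are excluded.  Returns a flagged
    (NaN) estimate when neither sample is heterozygous at any shared
    site.
    """
    gi = np.asarray(genotypes_i)
    gj = np.asarray(genotypes_j)
    if gi.shape != gj.shape:
        raise ValueError("genotype vectors differ in length")
    ok = (gi != MISSING) & (gj != MISSING)
    gi, gj = gi[ok], gj[ok]
    het_i = gi == 1
    het_j = gj == 1
    n_hh = int(np.sum(het_i & het_j))
    n_opp = int(np.sum(((gi == 0) & (gj == 2)) | ((gi == 2) & (gj == 0))))
    denom = int(het_i.sum()) + int(het_j.sum())
    phi = (n_hh - 2 * n_opp) / denom if denom > 0 else float("nan")
    return KinshipEstimate(sample_i, sample_j, phi, int(ok.sum()))


def kinship_matrix(
    matrix: GenotypeMatrix,
    max_sites: int | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """All-pairs KING-robust kinship, vectorized.

    Returns a square DataFrame indexed by sample id, with NaN on the
    diagonal and wherever the estimator is undefined.  ``max_sites``
    subsamples variant columns (deterministically from ``seed``) for
    very wide matrices.
    """
    d = matrix.dosages
    if max_sites is not None and matrix.n_variants > max_sites:
        rng = np.random.default_rng(seed)
        cols = np.sort(rng.choice(matrix.n_variants, size=max_sites, replace=False))
        d = d[:, cols]
    called = (d != MISSING)
    het = (d == 1) & called
    hom0 = (d == 0) & called
    hom2 = (d == 2) & called

    het_f = het.astype(np.float64)
    called_f = called.astype(np.float64)
    n_hh = het_f @ het_f.T
    n_opp = hom0.astype(np.float64) @ hom2.astype(np.float64).T
    n_opp = n_opp + n_opp.T
    # heterozygote counts restricted to sites called in the partner
    het_given_partner = het_f @ called_f.T
    denom = het_given_partner + het_given_partner.T
    with np.errstate(divide="ignore", invalid="ignore"):
        phi = np.where(denom > 0, (n_hh - 2.0 * n_opp) / denom, np.nan)
    np.fill_diagonal(phi, np.nan)
    return pd.DataFrame(phi, index=matrix.sample_ids, columns=matrix.sample_ids)


def prune_cohort(
    matrix: GenotypeMatrix,
    meta: pd.DataFrame,
    dup_threshold: float = DUPLICATE_THRESHOLD,
    second_degree_threshold: float = SECOND_DEGREE_THRESHOLD,
    max_sites: int | None = None,
    precomputed_kinship: pd.DataFrame | None = None,
) -> list[str]:
    """Retained sample ids after removing probands, duplicates and relatives.

    Affected probands are dropped first (healthy parents are the usable
    samples).  A relatedness graph then connects every pair with
    phi >= ``second_degree_threshold``; vertices are removed greedily in
    descending degree (ties broken by sample id order) until no edge
    remains, maximizing retention.  The ``dup_threshold`` is exposed for
    reporting; duplicate pairs exceed the second-degree cut and are
    broken by the same greedy rule.
    """
    ids = list(matrix.sample_ids)
    affected = set(meta.index[(meta["affected"] == True) & (meta["role"] == "proband")])  # noqa: E712
    keep = [s for s in ids if s not in affected]
    if not keep:
        return []
    if precomputed_kinship is None:
        phi = kinship_matrix(matrix.subset_samples(keep), max_sites=max_sites)
    else:
        phi = precomputed_kinship.loc[keep, keep]

    arr = phi.to_numpy(copy=True)
    np.fill_diagonal(arr, np.nan)
    adj = np.nan_to_num(arr, nan=-1.0) >= second_degree_threshold
    order = {s: i for i, s in enumerate(keep)}
    active = np.ones(len(keep), dtype=bool)
    degree = adj.sum(axis=1)
    while True:
        degree = (adj & active[None, :]).sum(axis=1)
        degree[~active] = 0
        if degree.max(initial=0) == 0:
            break
        # highest degree first; ties by sample id order
        top = int(np.flatnonzero(degree == degree.max())[0])
        active[top] = False
    return [s for s, i in order.items() if active[i]]
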