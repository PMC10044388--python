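"""Synthetic cohort generator with controllable population structure.

Emulates the statistical structure a carrier-screening cohort analysis
assumes: K discrete ancestries diverged from a common ancestral
population under the Balding-Nichols model, trio families with affected
probands, duplicated samples, self-report label errors, uniform missing
calls, and founder variants planted at specified per-ancestry carrier
frequencies.

Under Balding-Nichols, each population's allele frequency at a variant
with ancestral frequency p and divergence F (the Fst parameter) is drawn

    p_k ~ Beta(p (1-F)/F, (1-p)(1-F)/F)

which has mean p and variance F p (1-p); genotypes are then binomial
under Hardy-Weinberg within each population.  F = 0 degenerates to
p_k = p exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import (
    MISSING,
    SAMPLE_META_COLUMNS,
    VARIANT_ANNOTATION_COLUMNS,
    GenotypeMatrix,
)
from .panels import variant_key_str

_AUTOSOMES = [str(c) for c in range(1, 23)]

# Default population layout mirrors a multi-ethnic clinical cohort:
# two large groups (~1000 and ~600) plus eleven smaller ones (25-309),
# thirteen ancestries in all.
_DEFAULT_POPULATION_SIZES = (1011, 613, 309, 275, 240, 205, 170, 140, 110, 80, 60, 40, 25)


@dataclass
class FounderVariantSpec:
    """A pathogenic founder variant planted into one target population."""

    target_population: str
    target_carrier_frequency: float
    inheritance: str = "AR"  # "AR" | "XL"
    gene: str | None = None
    severity: str = "severe"
    classifications: str = "clinvar=P"
    reference_overall_af: float = 0.0005
    reference_homozygote_count: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.target_carrier_frequency <= 0.5:
            raise ValueError(
                f"target carrier frequency {self.target_carrier_frequency} outside (0, 0.5]"
            )
        if self.inheritance not in ("AR", "XL"):
            raise ValueError(f"inheritance must be AR or XL, got {self.inheritance!r}")


@dataclass
class SimulationConfig:
    """Full description of one synthetic cohort.

    Identical configs (including ``seed``) produce bit-identical
    cohorts.  Defaults describe a thirteen-ancestry clinical cohort
    with moderate divergence (Fst 0.05), 5% self-report label errors
    and 2% missing calls.
    """

    population_sizes: tuple[int, ...] = _DEFAULT_POPULATION_SIZES
    population_names: tuple[str, ...] | None = None
    fst_per_population: tuple[float, ...] | float = 0.05
    n_background_variants: int = 5000
    ancestral_maf_range: tuple[float, float] = (0.01, 0.5)
    founder_variant_specs: tuple[FounderVariantSpec, ...] = ()
    n_trios_per_population: int = 5
    n_duplicates: int = 10
    label_error_rate: float = 0.05
    missing_rate: float = 0.02
    binomial_founders: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        self.population_sizes = tuple(int(n) for n in self.population_sizes)
        if not self.population_sizes or any(n < 1 for n in self.population_sizes):
            raise ValueError("population sizes must all be >= 1")
        k = len(self.population_sizes)
        if self.population_names is None:
            self.population_names = tuple(f"pop{i:02d}" for i in range(k))
        else:
            self.population_names = tuple(self.population_names)
        if len(self.population_names) != k:
            raise ValueError("population_names length must match population_sizes")
        if len(set(self.population_names)) != k:
            raise ValueError("population names must be unique")
        if np.isscalar(self.fst_per_population):
            self.fst_per_population = (float(self.fst_per_population),) * k
        else:
            self.fst_per_population = tuple(float(f) for f in self.fst_per_population)
        if len(self.fst_per_population) != k:
            raise ValueError("fst_per_population length must match population_sizes")
        if any(not 0.0 <= f < 1.0 for f in self.fst_per_population):
            raise ValueError("Fst values must lie in [0, 1)")
        lo, hi = self.ancestral_maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValueError("ancestral_maf_range must lie within (0, 0.5]")
        for rate, name in (
            (self.label_error_rate, "label_error_rate"),
            (self.missing_rate, "missing_rate"),
        ):
            if not 0.0 <= rate < 1.0:
                raise ValueError(f"{name} must lie in [0, 1)")
        self.founder_variant_specs = tuple(self.founder_variant_specs)
        for spec in self.founder_variant_specs:
            if spec.target_population not in self.population_names:
                raise ValueError(
                    f"founder variant targets unknown population {spec.target_population!r}"
                )

    @property
    def n_populations(self) -> int:
        return len(self.population_sizes)


def _balding_nichols_afs(
    rng: np.random.Generator,
    ancestral: np.ndarray,
    fst: float,
) -> np.ndarray:
    """Per-population allele frequencies for one population."""
    if fst == 0.0:
        return ancestral.copy()
    scale = (1.0 - fst) / fst
    return rng.beta(ancestral * scale, (1.0 - ancestral) * scale)


def _transmit(rng: np.random.Generator, father: np.ndarray, mother: np.ndarray) -> np.ndarray:
    """Mendelian child dosage from two parental dosage vectors (no missing)."""
    child = np.zeros(father.shape, dtype=np.int8)
    for parent in (father, mother):
        allele = (parent == 2).astype(np.int8)
        het = parent == 1
        allele[het] = rng.integers(0, 2, size=int(het.sum()), dtype=np.int8)
        child += allele
    return child


def simulate_cohort(config: SimulationConfig) -> tuple[GenotypeMatrix, pd.DataFrame, pd.DataFrame]:
    """Generate a cohort (genotypes, sample metadata, variant annotations).

    The matrix rows order founders first (per population), then trio
    probands, then duplicates.  Planted founder variants appear as
    heterozygotes in exactly ``round(cf * N)`` samples of the target
    population (before trios/duplicates) and nowhere else, unless
    ``binomial_founders`` is set.
    """
    rng = np.random.default_rng(config.seed)
    k = config.n_populations
    m_bg = config.n_background_variants
    pops = list(config.population_names)

    # ---- variant annotation table -------------------------------------
    lo, hi = config.ancestral_maf_range
    ancestral = rng.uniform(lo, hi, size=m_bg)

    records = []
    pos_counter = {}
    for j in range(m_bg):
        chrom = _AUTOSOMES[j % len(_AUTOSOMES)]
        pos_counter[chrom] = pos_counter.get(chrom, 0) + 1000
        records.append(
            {
                "chrom": chrom,
                "pos": pos_counter[chrom],
                "ref": "A",
                "alt": "G",
                "gene": f"BG{j // 4:05d}",
                "classifications": "",
                "inheritance": "AR",
                "condition": "",
                "severity": "",
                "reference_overall_af": round(float(ancestral[j]), 6),
                "reference_homozygote_count": 0,
                "is_founder": False,
                "target_population": "",
                "target_carrier_frequency": 0.0,
            }
        )
    for i, spec in enumerate(config.founder_variant_specs):
        chrom = "X" if spec.inheritance == "XL" else _AUTOSOMES[i % len(_AUTOSOMES)]
        pos_counter[chrom] = pos_counter.get(chrom, 0) + 1000
        # offset founder positions well past the background block
        pos = pos_counter[chrom] + 10_000_000
        records.append(
            {
                "chrom": chrom,
                "pos": pos,
                "ref": "C",
                "alt": "T",
                "gene": spec.gene or f"FV{i:03d}",
                "classifications": spec.classifications,
                "inheritance": spec.inheritance,
                "condition": f"condition_{spec.gene or i}",
                "severity": spec.severity,
                "reference_overall_af": spec.reference_overall_af,
                "reference_homozygote_count": spec.reference_homozygote_count,
                "is_founder": True,
                "target_population": spec.target_population,
                "target_carrier_frequency": spec.target_carrier_frequency,
            }
        )
    annotations = pd.DataFrame.from_records(records)
    keys = [
        variant_key_str(r["chrom"], r["pos"], r["ref"], r["alt"])
        for r in records
    ]
    annotations.index = pd.Index(keys, name="variant_key")
    m = len(keys)

    # ---- founder-generation genotypes ---------------------------------
    blocks = []
    meta_rows = []
    sample_counter = 0
    pop_row_ranges: dict[str, tuple[int, int]] = {}
    row_cursor = 0
    for p_idx, (pop, n_pop, fst) in enumerate(
        zip(pops, config.population_sizes, config.fst_per_population)
    ):
        pop_afs = _balding_nichols_afs(rng, ancestral, fst)
        geno = rng.binomial(2, pop_afs[None, :], size=(n_pop, m_bg)).astype(np.int8)
        block = np.zeros((n_pop, m), dtype=np.int8)
        block[:, :m_bg] = geno
        blocks.append(block)
        for _ in range(n_pop):
            meta_rows.append(
                {
                    "sample_id": f"S{sample_counter:05d}",
                    "true_population": pop,
                    "reported_population": pop,  # errors applied later
                    "family_id": "",
                    "role": "unrelated",
                    "affected": False,
                    "duplicate_of": "",
                }
            )
            sample_counter += 1
        pop_row_ranges[pop] = (row_cursor, row_cursor + n_pop)
        row_cursor += n_pop

    dosages = np.vstack(blocks)

    # ---- plant founder variants ---------------------------------------
    for j, spec in zip(
        (idx for idx in range(m) if annotations["is_founder"].iloc[idx]),
        config.founder_variant_specs,
    ):
        lo_row, hi_row = pop_row_ranges[spec.target_population]
        n_pop = hi_row - lo_row
        if config.binomial_founders:
            carriers = np.flatnonzero(
                rng.random(n_pop) < spec.target_carrier_frequency
            )
        else:
            n_car = int(round(spec.target_carrier_frequency * n_pop))
            if n_car > n_pop:
                raise ValueError(
                    f"founder spec infeasible: {n_car} carriers exceed population "
                    f"{spec.target_population} size {n_pop}"
                )
            carriers = rng.choice(n_pop, size=n_car, replace=False)
        dosages[lo_row + carriers, j] = 1

    # ---- trios ----------------------------------------------------------
    family_counter = 0
    trio_rows = []
    for pop in pops:
        lo_row, hi_row = pop_row_ranges[pop]
        n_pop = hi_row - lo_row
        n_trios = min(config.n_trios_per_population, n_pop // 2)
        available = list(range(lo_row, hi_row))
        parent_picks = rng.choice(len(available), size=2 * n_trios, replace=False)
        for t in range(n_trios):
            f_row = available[parent_picks[2 * t]]
            m_row = available[parent_picks[2 * t + 1]]
            fam = f"fam{family_counter:04d}"
            family_counter += 1
            for row in (f_row, m_row):
                meta_rows[row]["family_id"] = fam
                meta_rows[row]["role"] = "parent"
            child = _transmit(rng, dosages[f_row], dosages[m_row])
            trio_rows.append(child)
            meta_rows.append(
                {
                    "sample_id": f"S{sample_counter:05d}",
                    "true_population": pop,
                    "reported_population": pop,
                    "family_id": fam,
                    "role": "proband",
                    "affected": True,
                    "duplicate_of": "",
                }
            )
            sample_counter += 1
    if trio_rows:
        dosages = np.vstack([dosages, np.array(trio_rows, dtype=np.int8)])

    # ---- duplicates -----------------------------------------------------
    n_templates = dosages.shape[0]
    if config.n_duplicates:
        template_rows = rng.choice(n_templates, size=config.n_duplicates, replace=False)
        dup_block = dosages[template_rows, :].copy()
        for row in template_rows:
            meta_rows.append(
                {
                    "sample_id": f"S{sample_counter:05d}",
                    "true_population": meta_rows[row]["true_population"],
                    "reported_population": meta_rows[row]["true_population"],
                    "family_id": meta_rows[row]["family_id"],
                    "role": "duplicate",
                    "affected": meta_rows[row]["affected"],
                    "duplicate_of": meta_rows[row]["sample_id"],
                }
            )
            sample_counter += 1
        dosages = np.vstack([dosages, dup_block])

    # ---- self-report label errors --------------------------------------
    if config.label_error_rate > 0 and k > 1:
        for row in meta_rows:
            if rng.random() < config.label_error_rate:
                others = [p for p in pops if p != row["true_population"]]
                row["reported_population"] = others[rng.integers(0, len(others))]

    # ---- missingness ----------------------------------------------------
    if config.missing_rate > 0:
        mask = rng.random(dosages.shape) < config.missing_rate
        dosages = dosages.copy()
        dosages[mask] = MISSING

    meta = pd.DataFrame(meta_rows).set_index("sample_id")[SAMPLE_META_COLUMNS]
    matrix = GenotypeMatrix(dosages, list(meta.index), keys)
    return matrix, meta, annotations


def plant_affected_family(
    matrix: GenotypeMatrix,
    meta: pd.DataFrame,
    annotations: pd.DataFrame,
    variant_key: str,
    population: str,
    kind: str = "homozygous",
    partner_variant_key: str | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Add a trio whose proband is homozygous (or compound het) for a variant.

    Two unused samples of the population (role ``unrelated``, no family)
    become heterozygous carrier parents; an affected proband is appended
    with dosage 2 at the variant (``homozygous``) or dosage 1 at the
    variant and at ``partner_variant_key`` in the same gene
    (``compound_het``), with remaining genotypes transmitted Mendelian
    from the parents.
    """
    if kind not in ("homozygous", "compound_het"):
        raise ValueError(f"unknown family kind {kind!r}")
    if variant_key not in matrix.variant_keys:
        raise ValueError(f"variant {variant_key} not in matrix")
    j = matrix.variant_index(variant_key)
    j2 = None
    if kind == "compound_het":
        if partner_variant_key is None:
            gene = annotations.loc[variant_key, "gene"]
            partners = [
                key for key in annotations.index[annotations["gene"] == gene]
                if key != variant_key and key in set(matrix.variant_keys)
            ]
            if not partners:
                raise ValueError(f"no gene-matched partner variant for {variant_key}")
            partner_variant_key = partners[0]
        j2 = matrix.variant_index(partner_variant_key)
        if j2 == j:
            raise ValueError("compound het requires two distinct variants")

    unused = meta.index[
        (meta["true_population"] == population)
        & (meta["role"] == "unrelated")
        & (meta["family_id"] == "")
    ].tolist()
    if len(unused) < 2:
        raise ValueError(
            f"population {population!r} has fewer than 2 unused samples to become parents"
        )
    father_id, mother_id = unused[0], unused[1]
    f_row = matrix.sample_index(father_id)
    m_row = matrix.sample_index(mother_id)

    if rng is None:
        rng = np.random.default_rng(0)

    dosages = matrix.dosages.copy()
    if kind == "homozygous":
        dosages[f_row, j] = 1
        dosages[m_row, j] = 1
    else:  # each parent carries exactly one of the two variants
        dosages[f_row, j] = 1
        dosages[f_row, j2] = 0
        dosages[m_row, j] = 0
        dosages[m_row, j2] = 1
    father = np.where(dosages[f_row] == MISSING, 0, dosages[f_row]).astype(np.int8)
    mother = np.where(dosages[m_row] == MISSING, 0, dosages[m_row]).astype(np.int8)
    child = _transmit(rng, father, mother)
    if kind == "homozygous":
        child[j] = 2
    else:
        child[j] = 1
        child[j2] = 1

    fams = [f for f in meta["family_id"] if str(f).startswith("fam")]
    fam = f"fam{len(set(fams)) + 1000:04d}"
    child_id = f"S{matrix.n_samples:05d}"
    while child_id in set(matrix.sample_ids):
        child_id = child_id + "p"

    new_meta = meta.copy()
    new_meta.loc[father_id, ["family_id", "role"]] = [fam, "parent"]
    new_meta.loc[mother_id, ["family_id", "role"]] = [fam, "parent"]
    new_meta.loc[child_id] = {
        "true_population": population,
        "reported_population": population,
        "family_id": fam,
        "role": "proband",
        "affected": True,
        "duplicate_of": "",
    }
    new_matrix = GenotypeMatrix(
        np.vstack([dosages, child[None, :]]),
        list(matrix.sample_ids) + [child_id],
        list(matrix.variant_keys),
    )
    return new_matrix, new_meta
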