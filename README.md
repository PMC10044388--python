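# carrierpanel

Data-driven design of pan-ethnic carrier screening panels from
multi-sample genotype cohorts.

Carrier screening aims to identify couples at risk of having children
affected by severe recessive or X-linked disorders. Pan-ethnic panels
work well for widely shared conditions, but pathogenic *founder
variants* — disease alleles at elevated frequency in one ancestry
because of a shared founder — are easily missed or mis-tiered when a
population is under-represented in reference databases. `carrierpanel`
implements the full analytical path from a clinical genotype cohort to
a curated, tiered panel of founder variants per inferred ancestry:

1. **Relatedness QC** — pairwise kinship with the KING-robust
   between-family estimator,
   φ̂ = (N<sub>het,het</sub> − 2·N<sub>opp,hom</sub>) / (N<sub>het,i</sub> + N<sub>het,j</sub>),
   then greedy pruning of duplicates (φ ≥ 0.354) and first/second-degree
   relatives (φ ≥ 0.0884), with affected probands dropped first so the
   healthy parents are analyzed.
2. **Ancestry inference** — PCA on common autosomal variants
   (MAF ≥ 0.05, call rate ≥ 0.95), ten components, self-reported
   training labels cleaned by a Mahalanobis outlier rule
   (χ²₁₀ 99% cutoff, iteratively trimmed covariance), multinomial
   logistic regression; low-confidence samples are "unassigned" and
   never enter frequency denominators.
3. **Carrier frequencies and ACMG tiers** — per (ancestry, variant)
   carrier counts over non-missing calls, exact-fraction frequencies
   rendered "1/N"; tier 1 via gene list, tier 2 at ≥ 1/100, tier 3 at
   ≥ 1/200 or X-linked, tier 4 below. Parents of probands homozygous
   (or compound heterozygous) for a variant are excluded from that
   variant's numerator and denominator — an ascertainment correction
   specific to trio-rich clinical cohorts.
4. **Candidate filtering** — any-source P/LP selection, subtraction of
   existing panels, a frequency gate in the target ancestries, and an
   order-independent exclusion cascade (reference AF > 0.5%, ≥ 3
   reference homozygotes, mild condition).
5. **Curation** — a precedence rule engine over structured evidence
   (healthy biallelic case ⇒ excluded; mild ⇒ excluded; affected
   concordant biallelic case or causal literature report ⇒ confirmed;
   otherwise uncertain).
6. **Panel comparison and validation** — membership against variant- and
   gene-based commercial panels; sensitivity against a reference panel
   using Hardy–Weinberg carrier frequencies 2p(1−p).

A synthetic-cohort generator (Balding–Nichols population structure,
Mendelian trios, duplicates, label errors, planted founder variants)
makes every stage testable without access to clinical data.

## Worked example

The ascertainment correction that motivates stage 3, reconstructed at
the size it matters in practice (`examples/04_frequencies_and_tiers.py`):
a group of 613 samples contains 8 heterozygous carriers of a recessive
variant, but 4 of them are parents of affected homozygous probands —
they were sampled *because* their children are affected.

```
before correction: 8/613 = 1/77  -> tier 2
after correction:  4/609 = 1/152 -> tier 3
```

Uncorrected, the variant's carrier frequency (1/77 ≥ 1/100) puts it in
tier 2; after removing the four ascertained parents from numerator and
denominator the exact frequency 4/609 falls between 1/200 and 1/100,
i.e. tier 3. The tier decides who is offered screening for it.

End to end (`examples/07_end_to_end.py`), a simulated two-ancestry
cohort with three confirmable planted founder variants and a
mild-condition decoy yields:

```
retained after QC: 753 of 813
curation outcomes: {'confirmed_pfv': 3}
final panel:
   variant_key gene  tier supporting_items
1:10042000:C:T  FVA     2            case0
2:10042000:C:T  FVB     2            case1
3:10042000:C:T  FVC     3            pmid1
```

exactly the planted variants, at the tiers their planted carrier
frequencies imply (0.03 and 0.015 ≥ 1/100 ⇒ tier 2; 0.0075 ⇒ tier 3),
with the mild decoy excluded by the cascade. The other scripts in
`examples/` demonstrate each capability in isolation, and a thin
`carrierpanel` CLI (`simulate`, `qc`, `ancestry-fit`,
`ancestry-predict`, `run-all`, `validate`) wraps the same functions for
shell use.

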