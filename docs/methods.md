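# Methods

## Scope and model

`carrierpanel` turns a multi-sample diploid genotype cohort (biallelic
alternate-allele dosages 0/1/2 with missing calls) plus sample
metadata and variant annotations into a tiered panel of candidate
pathogenic founder variants per inferred ancestry. Upstream read
alignment and variant calling, automated ACMG classification, and the
content of literature curation are out of scope: classifications,
severities and evidence arrive as structured inputs.

## Synthetic cohorts

The generator emulates the statistical structure the analysis relies
on, not sequencing data.

* **Population structure.** K discrete ancestries diverge from a
  common ancestral pool under the Balding–Nichols model: for ancestral
  allele frequency p and divergence F, each population's frequency is
  Beta(p(1−F)/F, (1−p)(1−F)/F), with mean p and variance F·p(1−p);
  genotypes are binomial under Hardy–Weinberg within population. F = 0
  degenerates to identical frequencies. A hand-written per-variant
  Hudson estimator in the test suite confirms that simulated pairs at
  F = 0.05 yield mean Fst within [0.03, 0.07].
* **Families.** Trio parents are drawn from the existing population
  samples; a child is appended per trio with strict Mendelian
  transmission (heterozygous parents transmit either allele with
  probability ½). Probands are marked affected. `plant_affected_family`
  additionally constructs homozygous or compound-heterozygous affected
  trios for a chosen variant, converting two unused samples into
  heterozygous carrier parents.
* **Duplicates** are exact genotype copies of a template, made before
  missingness so the copies differ only in missing pattern.
* **Label errors** replace the reported ancestry with a uniformly
  chosen other label at the configured rate. **Missingness** is uniform
  at random; real missingness is not uniform (capture and coverage
  effects), which is a known simplification.
* **Founder variants** are planted deterministically: exactly
  round(cf·N) heterozygotes in the target population, absent elsewhere,
  so frequency-recovery tests are exact; a binomial mode exists for
  statistical tests. X-linked variants sit on chromosome "X" but all
  samples are treated as diploid — male hemizygosity is not modeled.

Defaults describe a thirteen-ancestry clinical cohort (two large
groups of 1011 and 613 plus eleven of 25–309 samples, F = 0.05 per
population, 5% label errors, 2% missing calls, ancestral MAF uniform
on (0.01, 0.5)); tests and examples typically override the sizes
downward. Passing tests on these cohorts show the pipeline's logic is
correct under its own assumptions (discrete ancestries, linkage
equilibrium, random missingness); they do not certify behaviour under
admixture, LD, or structured missingness.

## Relatedness QC

The KING-robust between-family kinship estimator is used because it
needs no allele-frequency estimates and remains unbiased under
population structure — the cohort is multi-ethnic by construction.
Pairs with no heterozygous site in either sample have an undefined
estimate, are flagged, and are treated as unrelated. Thresholds are
the standard powers-of-two midpoints: 0.354 (duplicate/MZ), 0.177
(first degree), 0.0884 (second degree). Pruning removes affected
probands first, then greedily deletes the highest-degree vertex of the
φ ≥ 0.0884 graph (ties by sample id order) until no edge remains;
greedy max-degree removal retains more samples than removing both
members of each pair and is deterministic. The all-pairs computation
is three boolean matrix products; a `max_sites` option subsamples
variant columns for very wide matrices.

## Ancestry inference

Common-variant selection (autosomal, MAF ≥ 0.05, call rate ≥ 0.95) and
the ten-component PCA are conventional; missing dosages are mean-imputed
per variant, columns are centered and variance-scaled, and component
signs are fixed (largest-magnitude loading positive) so projections are
reproducible. New samples are always projected with the stored
centering and loadings, never refitted.

Self-reported labels are cleaned before training: a sample is removed
when its squared Mahalanobis distance to its reported label's centroid
exceeds the χ²(10) 99% quantile. Centroid and covariance are
re-estimated on retained samples only, iterated to a fixed point, with
a small ridge term (10⁻³·tr(Σ)/d on the diagonal). The iteration
matters: a one-shot covariance is inflated by the mislabeled samples
themselves, which masks them (observed directly with two populations,
where all outliers lie on one axis). A minimum-covariance-determinant
estimate was considered and rejected: its distances are strongly
inflated at group sizes near 75 in ten dimensions, removing ~15% of
correctly labelled samples where the trimmed iteration removes <1%.
Labels with fewer than 11 samples pass through with a warning.

The classifier is multinomial logistic regression (L2, lbfgs, fixed
settings) on the ten scores: deterministic, probabilistic — the top
class probability is the confidence, and samples below the 0.8 default
threshold are "unassigned" and excluded from every per-ancestry
denominator downstream.

## Carrier frequencies, correction, tiers

A carrier is any sample with dosage ≥ 1 (homozygotes included — this
matches the usual carrier-rate definition and the 4-in-301 ⇒ 1/75
arithmetic). The denominator is the number of ancestry-group samples
with a non-missing call at that variant. Frequencies are stored as
exact `Fraction`s; the "1/N" rendering uses round-half-away-from-zero
of group_size/carriers and is presentation only — published renderings
of the same counts differ by rounding convention, so tier comparisons
never use it.

Because clinical cohorts enroll affected families, parents of a
proband homozygous — or compound heterozygous, detected via a second
heterozygous call in the same gene — for a variant are removed from
that variant's numerator and denominator only. The adjusted record is
an exact recount over the reduced sample set, asserted as such in the
tests.

Tiers: explicit gene list ⇒ tier 1; carrier frequency ≥ 1/100 ⇒ tier 2;
≥ 1/200 or X-linked ⇒ tier 3; else tier 4. Boundaries are inclusive by
default (the recommendation wording is "≥"); `strict_tier3` switches
to a strict comparison. The HWE-based sensitivity validation uses a
strict ">" independently, matching the convention of validating
against an external frequency resource.

## Candidate filtering and curation

P/LP selection is any-source: one P or LP call among a variant's
classification records suffices. The exclusion cascade (reference
AF > 0.5%, ≥ 3 reference homozygotes, mild condition) is a conjunction
of independent predicates, hence order-independent, and every
exclusion carries its triggering rules. Variants with missing
annotation fields are retained with a "not evaluable" warning —
a manual-review-forward posture rather than silent dropping. The
homozygote rule reads the *reference-database* count; cohort-internal
homozygotes are the business of the parent correction.

Curation precedence is: benign evidence (biallelic case in a healthy
individual, or one with no associated phenotype) > mild condition >
confirmation (biallelic affected-concordant case or causal literature
report) > uncertain. The decision is a pure function of the evidence
multiset and severity; contradictory evidence resolves to exclusion
and is flagged for review. Confirmation requires at least one
supporting source.

## Variant keys and panels

All cross-panel matching uses one canonical key: alleles uppercased,
shared suffix then prefix trimmed (keeping one anchor base), and
indels left-aligned against a reference sequence when one is provided.
Normalization is idempotent (fuzz-tested). Variant-based panels match
on the key, gene-based panels on the symbol, and both levels are
reported per (variant, panel).

## Numerical and determinism choices

All randomness flows from explicit integer seeds through
`numpy.random.default_rng`; the classifier and PCA use fixed solver
settings. Rerunning the pipeline with one config and seed produces
byte-identical artifacts (hash-asserted in tests). TSV is used for
every inter-stage artifact so stages are independently inspectable.
Degenerate inputs are explicit: empty common-variant subsets, single
training labels, empty reference sets (recall reported as undefined),
zero-carrier records (frequency 0, no "1/N"), and kinship pairs with
empty denominators are all handled and tested.

## Problem sizes

The test and acceptance workloads use desk-scale cohorts chosen to
exercise each property with comfortable statistical margins: 13 × 75
samples with 3000 background variants for ancestry accuracy and
label-error removal, 2 × 1000 with 5000 variants for frequency
recovery and Fst calibration, and 2 × 400 with ~900 variants for the
end-to-end runs.

## Known limitations

Admixed individuals are not modeled or handled — each sample gets one
most-probable ancestry. No LD, no sex-aware X hemizygosity, no
haplotype phasing (compound heterozygosity is inferred from two
heterozygous calls in one gene, which cannot distinguish cis from
trans). Carrier-frequency confidence intervals (Wilson) are available
for reporting but deliberately unused in tiering.
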