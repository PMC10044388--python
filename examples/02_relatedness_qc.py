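"""Kinship-based QC: find duplicates and relatives, keep a maximal
unrelated subset.

The KING-robust estimator puts duplicates near phi = 0.5 and
parent-child pairs near 0.25; pruning removes affected probands first,
then breaks every pair at or above the second-degree cutoff (0.0884).
"""

import numpy as np

from carrierpanel import (
    SECOND_DEGREE_THRESHOLD,
    SimulationConfig,
    kinship_matrix,
    prune_cohort,
    simulate_cohort,
)

config = SimulationConfig(
    population_sizes=(250,),
    n_background_variants=4000,
    n_trios_per_population=8,
    n_duplicates=3,
    seed=7,
)
matrix, meta, _ = simulate_cohort(config)
phi = kinship_matrix(matrix)

dup = meta.index[meta["role"] == "duplicate"][0]
template = meta.loc[dup, "duplicate_of"]
print(f"duplicate pair phi:     {phi.loc[dup, template]:.3f}  (expected ~0.5)")
child = meta.index[meta["role"] == "proband"][0]
parent = meta.index[(meta["family_id"] == meta.loc[child, "family_id"])
                    & (meta["role"] == "parent")][0]
print(f"parent-child pair phi:  {phi.loc[parent, child]:.3f}  (expected ~0.25)")

retained = prune_cohort(matrix, meta)
post = kinship_matrix(matrix.subset_samples(retained))
print(f"retained {len(retained)} of {matrix.n_samples} samples")
print(f"max kinship after pruning: {np.nanmax(post.to_numpy()):.3f} "
      f"(< {SECOND_DEGREE_THRESHOLD})")
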