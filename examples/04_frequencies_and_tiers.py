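"""Carrier frequencies, the proband-parent correction, and ACMG tiers.

Reconstructs the canonical correction scenario: a group of 613 samples
with 8 heterozygous carriers of a recessive variant, 4 of whom are
parents of probands homozygous for it.  Including those parents the
variant looks like tier 2 (>= 1/100); after the correction it is
tier 3 (>= 1/200).
"""

import numpy as np
import pandas as pd

from carrierpanel import (
    GenotypeMatrix,
    assign_tier,
    carrier_frequencies,
    remove_homozygous_proband_parents,
)
from carrierpanel.containers import SAMPLE_META_COLUMNS

n_group, key = 613, "1:100:C:T"
ids = [f"G{i:04d}" for i in range(n_group)] + ["P0", "P1"]
dosages = np.zeros((len(ids), 1), dtype=np.int8)
dosages[[0, 1, 2, 3], 0] = 1          # 4 carrier parents (2 families)
dosages[[10, 20, 30, 40], 0] = 1      # 4 unrelated carriers
dosages[[n_group, n_group + 1], 0] = 2  # homozygous affected probands

rows = []
for i in range(n_group):
    fam = f"fam{i // 2}" if i < 4 else ""
    role = "parent" if i < 4 else "unrelated"
    rows.append((ids[i], "popA", "popA", fam, role, False, ""))
rows.append(("P0", "popA", "popA", "fam0", "proband", True, ""))
rows.append(("P1", "popA", "popA", "fam1", "proband", True, ""))
meta = pd.DataFrame(rows, columns=["sample_id"] + SAMPLE_META_COLUMNS).set_index("sample_id")

matrix = GenotypeMatrix(dosages, ids, [key])
labels = meta.loc[meta["role"] != "proband", "true_population"]
group = matrix.subset_samples(list(labels.index))

(before,) = carrier_frequencies(group, labels, [key])
print(f"before correction: {before.n_carriers}/{before.group_size} "
      f"= {before.one_in_n}  -> tier {assign_tier(before, 'AR').tier}")

(after,) = remove_homozygous_proband_parents([before], matrix, meta, [key], labels)
print(f"after correction:  {after.n_carriers}/{after.group_size} "
      f"= {after.one_in_n}  -> tier {assign_tier(after, 'AR').tier}")
# The 4 parents were sampled because their children are affected, not
# at random; removing them from numerator and denominator corrects the
# ascertainment bias and demotes the variant from tier 2 to tier 3.
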