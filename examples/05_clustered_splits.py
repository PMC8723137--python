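"""Leakage-free cross-validation splits from CDR sequence clusters.

Antibodies are clustered greedily at 90% CDR identity (CD-HIT style) and
whole clusters are assigned to folds, so near-identical antibodies never
straddle train/validation/test.  Each fold carries two disjoint validation
carvings, supporting a 2-architecture x 2-validation-set ensemble.
"""

import numpy as np

from voxscreen import cluster_cdr_sequences, make_folds, sample_decoys
from voxscreen.synthetic import make_decoy_pool

rng = np.random.default_rng(21)
cognate = "GFTFSSYAMSWIRQAPGKGLEWV"[:24].ljust(24, "A")
pool = make_decoy_pool(cognate, n_families=5, family_size=12, rng=rng)

clusters = cluster_cdr_sequences(pool, cutoff=0.9)
print(f"pool: {len(pool)} antibodies in {clusters.n_clusters} clusters "
      f"(5 planted families)")

plan = make_folds(clusters, k=5, rng=rng)
plan.check()  # raises if any cluster straddles a partition
for fold in range(2):
    test = plan.antibodies_in(plan.test_clusters(fold))
    val0 = plan.antibodies_in(plan.validation_sets[fold][0])
    trn = plan.antibodies_in(plan.train_clusters(fold, validation_set=0))
    print(f"fold {fold}: train {len(trn):>2}, validation {len(val0):>2}, "
          f"test {len(test):>2}  (disjoint by construction)")

decoys = sample_decoys("ag1", "cognate", cognate, pool, n=20, rng=rng)
print(f"decoy draw: {len(decoys)} ids, all < 90% CDR identity to the cognate")
print(f"first five: {decoys[:5]}")
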