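"""Hypergeometric overrepresentation baseline on binary labels.

Labels the entities with the most extreme constraint-1 weights as
"significant" (a stand-in for an upstream differential-expression call) and
tests the same planted catalog with the classical one-sided hypergeometric
test, illustrating what a counting test sees and what it misses.
"""

import numpy as np

from tmea import (
    LabeledBackground,
    decompose,
    log_transform,
    make_truth,
    plant_catalog,
    run_hypgsea,
    synthesize_matrix,
)

truth = make_truth(seed=1)
matrix = synthesize_matrix(truth, seed=2)
decomp = decompose(log_transform(matrix, pseudocount=0.0))

catalog = plant_catalog(
    truth,
    n_null_sets=30,
    archetype_params=[
        {"archetype": "shift", "constraint": 1, "size": 30},
        {"archetype": "single", "constraint": 1, "size": 15, "n_extreme": 3,
         "tail_quantile": 0.99},
    ],
    seed=3,
)

# label the top 10% |weight| entities of constraint 1 as significant
w = np.abs(decomp.weights[:, 1])
threshold = np.quantile(w, 0.9)
background = LabeledBackground(decomp.entity_ids, (w > threshold).tolist())

records = run_hypgsea(background, catalog, background_mode="all_measured")
print("fas_id                   N     K    n   k       p        q")
for r in records[:6]:
    print(f"{r.fas_id:21s} {r.N:5d} {r.K:5d} {r.n:4d} {r.k:3d} "
          f"{r.p:9.2e} {r.q_bh:9.2e}")

# Interpretation: the shifted set overlaps the labelled tail broadly and is
# found by counting; the single-extreme set overlaps in only ~3 members, so
# its hypergeometric evidence is far weaker than its weight-sum evidence —
# the complementary case the weight-sum statistic exists for.
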