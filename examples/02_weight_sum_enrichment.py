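"""Run the directional weight-sum Monte Carlo enrichment test.

Plants three annotation archetypes in a synthetic catalog — a shifted set
(majority vote), a single-extreme set and a tail subgroup — alongside 30
random null sets, then tests every set against constraint 1 in both
directions and prints the significant records.
"""

from tmea import (
    decompose,
    free_energy,
    log_transform,
    make_truth,
    plant_catalog,
    run_tmea,
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
        {"archetype": "subgroup", "constraint": 1, "direction": "negative",
         "size": 25, "tail_quantile": 0.95},
    ],
    seed=3,
)

records = run_tmea(decomp, catalog, constraint_indices=[1], b=10_000, seed=4)
print("fas_id                constraint dir       s   s+/-   w_hat      p        q")
for r in records:
    if r.q_bh < 0.05:
        print(f"{r.fas_id:21s} {r.constraint:^10d} {r.direction:8s} "
              f"{r.set_size:3d} {r.subset_size:4d}  {r.weight_sum:+8.4f} "
              f"{r.p_empirical:8.5f} {r.q_bh:8.5f}")

energies = free_energy(decomp, matrix, [1])
print("\nconstraint-1 potential lambda_1(t) and free energy F_1(t):")
print("lambda:  " + "  ".join(f"{v:9.3g}" for v in decomp.potentials[1]))
print("F:       " + "  ".join(f"{f:9.3g}" for f in energies.per_constraint[0]))

# Interpretation: only the three planted sets reach q < 0.05 — the shifted
# and single-extreme sets in the positive direction, the subgroup in the
# negative — while the 30 random sets stay non-significant. Sign changes of
# the potential mark state transitions; the free energy is the
# abundance-weighted work of the constraint, so its magnitude is dominated
# by the most abundant entities.
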