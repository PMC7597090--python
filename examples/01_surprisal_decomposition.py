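"""Decompose a synthetic abundance time course into baseline + constraints.

Builds a low-rank log-linear matrix (1,000 entities, 11 time points, 3
constraints), decomposes its log by SVD and prints the singular spectrum,
the importance losses and the fraction of the data recovered by the
baseline plus the first k constraints.
"""

from tmea import (
    decompose,
    importance_spectrum,
    log_transform,
    make_truth,
    recovery_fraction,
    suggest_n_constraints,
    synthesize_matrix,
)

truth = make_truth(n_entities=1000, n_conditions=11, rank=3, noise_sd=0.2, seed=1)
matrix = synthesize_matrix(truth, seed=2)
decomp = decompose(log_transform(matrix, pseudocount=0.0))

spectrum = importance_spectrum(decomp)
print("component  sigma      relative_loss")
for a in range(6):
    loss = spectrum.relative_losses[a] if a < len(spectrum.relative_losses) else float("nan")
    print(f"{a:9d}  {decomp.singular_values[a]:9.2f}  {loss:.3f}")
print(f"suggested number of constraints: {suggest_n_constraints(decomp)}")
for k in (0, 1, 2, 3):
    print(f"recovery with baseline + constraints 1..{k}: "
          f"{recovery_fraction(decomp, k):.4f}")

# Interpretation: the spectrum drops steeply over the four planted
# components and flattens into noise; the recovery fraction shows the
# baseline alone explains most of the log-signal mass and three constraints
# recover essentially all of it.
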