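"""Quantify how much of the weight-sum signal member counting explains.

Computes weight ratios (WR) and count ratios (CR) for every set at each
percentile threshold of the constraint weight pools, regresses WR on CR per
threshold, and prints the 15% trimmed mean of R² per direction.
"""

from tmea import (
    decompose,
    log_transform,
    make_truth,
    plant_catalog,
    synthesize_matrix,
    wrcr_profile,
)

truth = make_truth(seed=1)
matrix = synthesize_matrix(truth, seed=2)
decomp = decompose(log_transform(matrix, pseudocount=0.0))
catalog = plant_catalog(truth, n_null_sets=150, set_size_range=(10, 50), seed=3)

profile = wrcr_profile(decomp, catalog, constraint_indices=[1, 2, 3])
print("quantile   R2(positive)   R2(negative)")
for q in (0.10, 0.25, 0.50, 0.75, 0.90):
    i = list(profile.quantiles).index(q)
    print(f"{q:8.2f}   {profile.r2_positive[i]:12.3f}   {profile.r2_negative[i]:12.3f}")
print(f"\n15% trimmed mean R2, positive direction: "
      f"{profile.trimmed_mean_r2_positive:.3f}")
print(f"15% trimmed mean R2, negative direction: "
      f"{profile.trimmed_mean_r2_negative:.3f}")

# Interpretation: for random (exchangeable) sets, counts explain roughly
# two thirds of the variance in weight mass — substantial, but the
# unexplained remainder is carried by the weights themselves, which is why
# the enrichment statistic sums weights instead of counting members.
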