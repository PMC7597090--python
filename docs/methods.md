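# Methods

## Model

Surprisal analysis treats a measured abundance time course as a system held
away from a maximum-entropy steady state by a small number of constraints.
For entity *i* (transcript, protein, metabolite) at time *t*, the
log-abundance is modelled as

    ln X_i(t) = G_i0 λ₀(t) + Σ_{α≥1} G_iα λ_α(t),

where the first term is the baseline (steady-state) contribution and each
constraint α contributes a time-invariant per-entity weight G_iα modulated
by a time-dependent potential (Lagrange multiplier) λ_α(t). The surprisal
of an observation is the negated deviation from the baseline,
−Σ_{α≥1} G_iα λ_α(t). Free energy attributable to constraint α at time *t*
is

    F_α(t) = −λ_α(t) · Σ_i X_i(t) G_iα,

and total work is the sum over constraints α ≥ 1; the baseline is excluded
by definition (it is the minimum-free-energy reference). Free energies are
reported in the same arbitrary units as the log-abundance input; no
thermodynamic unit conversion is attempted.

The decomposition is realised by the thin SVD `L = U S Vᵀ` of the
log matrix: weights `G = U`, potentials `λ_α(t) = σ_α V_tα`. All
min(entities, conditions) components are retained; truncation is a
downstream choice. Key properties relied on throughout: the weight columns
are orthonormal, the squared singular values partition the squared
Frobenius norm of `L` (so the recovery fraction of a truncation at
component *k* is Σ_{α≤k} σ_α² / Σ σ_α²), and the truncation residual equals
the discarded spectrum (Eckart–Young).

### Sign convention

SVD leaves the sign of each (Uα, Vα) pair arbitrary, which would make
enrichment directions irreproducible. The convention adopted: for the
baseline (α = 0) flip so that the weight column sums to ≥ 0 (baseline
weights predominantly positive, as befits a state population); for α ≥ 1
flip so that the potential's first nonzero value over time is ≥ 0. This
makes the decomposition a deterministic function of its input — verified
bitwise in tests.

### Choosing the number of constraints

The importance spectrum reports the relative loss
(σ_α − σ_{α+1})/σ_α between consecutive singular values; where σ_α = 0 the
loss is defined as 0 so the spectrum stays total. `suggest_n_constraints`
names the constraint with the largest relative loss after the baseline, but
the cut is deliberately left a user choice: with near-geometric spectra the
relative losses of true components are nearly equal and no automatic rule
is trustworthy.

## Directional weight-sum enrichment (the core test)

For one functionally annotated set (FAS) and one constraint, members with
strictly positive and strictly negative weights are tested separately
(zero weights belong to neither subset). The statistic is the directional
weight sum ŵ± = Σ E±. The null resamples b subsets of the same cardinality
s± from the constraint's full same-sign weight pool over all measured
entities and counts resamples at least as extreme (ties inclusive):

    p± = #{W_i ≥ ŵ⁺ (resp. ≤ ŵ⁻)} / b.

Design choices, with defaults:

* **Sampling without replacement** within each resample (a permutation
  null over subsets of the observed pool). A bootstrap
  (with-replacement) mode exists behind `sampling_mode="bootstrap"`; its
  null support differs (it can repeat the most extreme weight), so the two
  modes are not interchangeable.
* **Pool = all same-sign weights of the constraint**, members included —
  the test asks whether the set's weight mass is surprising for its size
  given the whole constraint, not versus the complement.
* **b = 10,000 by default.** The smallest attainable nonzero p is 1/b;
  each result carries that resolution alongside p, and an add-one
  estimator (n+1)/(b+1) is available for conservative FDR work. The plain
  estimator is the default and can return exactly 0.
* **BH family = one family per (constraint, direction)** — the narrowest
  defensible grouping, since the two directions are reported as separate
  functional descriptors per constraint. Per-constraint and global
  families are configurable.
* **Minimum measured set size 5 (inclusive)**, counted after intersecting
  the FAS with the measured entities; unmeasured annotation members are
  dropped with a logged count so the test is conditional on the measured
  background.
* **Determinism**: each (FAS, constraint, direction) test draws its RNG
  from a seed sequence keyed by (run seed, constraint, direction,
  CRC-32 of the FAS id), so results are independent of catalog iteration
  order and reproducible bit-for-bit.

Numerical note: resampling is vectorised by drawing uniform keys per pool
element and taking the s smallest (argpartition), chunked to at most ~4M
materialised elements; this is exact uniform subset sampling, not an
approximation.

## Hypergeometric baseline (hypGSEA)

The classical comparison: entities carry a binary significance label
produced upstream (e.g. a differential-expression call; computing such
labels is out of scope here), and each FAS is scored by the one-sided
upper tail P(X ≥ k) of Hypergeometric(N, K, n), BH-corrected across all
tested FASs in a single family. No mid-p correction is applied: at small
set sizes the discreteness of the distribution makes the test conservative,
and mid-p risks exceeding the nominal level; an expert flag exposes it for
comparison experiments. The background N defaults to labelled entities
carrying at least one annotation (`background_mode="annotated"`, the common
convention); `"all_measured"` uses every labelled entity. The choice
changes N and hence every p-value, so it is surfaced prominently rather
than buried.

## WR/CR diagnostics

To quantify how much of the weight-sum signal mere counting of extreme
members would capture: for each percentile threshold q ∈ {1%, …, 99%} of a
constraint's directional weight pool, each FAS yields a weight ratio
WR (fraction of its directional weight mass beyond the threshold) and a
count ratio CR (fraction of its members beyond it). WR is regressed on CR
across all (FAS, constraint) combinations per quantile, and the 99 R²
values per direction are summarised by a 15% trimmed mean (dropping
⌊0.15·n⌋ values from each end). High R² means counts explain weight mass
(the majority-vote regime); sets driven by one or a few extreme-weight
members appear as high-WR/low-CR outliers and depress R².

Conventions that had to be pinned:

* Denominators are **within-set** (the set's own weight mass and member
  count), so ratios are comparable across sets of different sizes; a
  global-denominator variant (pool mass/count) is available behind a flag.
* For the negative direction the threshold is the (1 − q) pool quantile
  with strict `<`, so a given q selects equally extreme tails in both
  directions; ratios use absolute values and stay in [0, 1].
* Empirical quantiles use linear interpolation between order statistics
  (type 7), and thresholding is strict, mirroring the strict inequalities
  that define the directional subsets.
* Quantile thresholds are taken per constraint by default; a pooled mode
  (thresholds from the requested constraints' weights pooled together)
  exists behind a flag.

## Synthetic data

The generator emulates a desk-scale bulk transcriptomics time course.
Defaults: 1,000 entities, 11 time points, 3 constraints beyond the
baseline, singular values decaying geometrically (ratio 0.3) from
`baseline_log_level · sqrt(entities · conditions)` with
`baseline_log_level = 6` (mean abundance ≈ e⁶ ≈ 400), and Gaussian noise of
sd 0.2 on the log scale (multiplicative ~20% noise on abundances). The
baseline component is built on near-constant entity and time vectors;
constraint weight vectors are drawn from a Laplace distribution before
orthonormalisation because real constraint weights are heavy-tailed — a few
strongly responding entities dominate each pattern — and heavy tails are
what gives the single-extreme archetype meaning. A negative-binomial count
mode (dispersion 0.1) produces integer matrices with zeros for testing
pseudocount handling; the default pseudocount is 1 for count data and 0
otherwise (strict positivity is enforced).

Planted annotation archetypes (alongside uniform-random null sets):

* **shift** — members sampled with probability ∝ rank^strength of the
  directional weight (default strength 8, at which a 30-member set is
  detected essentially always); strength 0 reduces to a null set.
* **single** — the most extreme 1–2 pool entities (default 2) plus random
  members: the case a counting test cannot see.
* **subgroup** — a random block from the directional tail (default 6
  members beyond the 97th percentile) plus random members.

What the generator does **not** emulate: realistic transcriptome
correlation structure beyond low rank, count overdispersion varying by
abundance, batch effects, or annotation bias. Passing tests demonstrate
correctness of the machinery and calibration/power under the low-rank
log-linear model — not performance guarantees on any particular real
dataset.

Validation problem sizes: the power experiments use 20 independent
generator seeds with 30 null sets per catalog and b = 5,000 (b = 2,000 for
the effect-size sweep); at 1,000 entities the planted single-extreme effect
size is stated as 3 tail entities in a 15-member set, because the two most
extreme pool weights at this pool size sit near the null's ~5·10⁻⁴
quantile, which a BH family of ~30 turns into a borderline q — three
extremes is the desk-scale analogue of a two-extreme set in a
20,000-entity transcriptome, where pool-overlap in resampling is
negligible. Null calibration uses 2,000 random sets at b = 2,000, where the
Kolmogorov–Smirnov distance of the p-value families from uniform is
consistent with pure sampling noise (expected D ≈ 0.87/√2000 ≈ 0.019).

## Degenerate inputs and tie-breaking

* Zero matrix: valid; all singular values 0, recovery fraction defined
  as 1.
* Zero singular values: importance losses defined as 0.
* Exact-zero weights: excluded from both directional subsets and pools
  (the defining inequalities are strict).
* Ties in resampled sums count as extreme (inclusive ≥/≤); note that
  comparing sums of the same subset computed by different summation orders
  can differ in the last ulp, so knife-edge equalities between observed and
  resampled sums are only meaningful to ~1e-15 relative.
* Sign-convention ties (potential exactly 0 at the first condition) fall
  through to the next condition.
* R² is flagged missing (NaN) with fewer than 3 (CR, WR) pairs or zero CR
  variance; a constant WR gives R² = 0.

## Replicates and normalisation

Replicate sample columns are aggregated to one column per condition before
the log transform — mean on the raw abundance scale by default, median
optionally. Aggregation-before-decomposition is a deliberate choice: the
decomposition operates on one profile per time point. An optional
per-column scaling to the mean column total (library-size style) is
available but off by default, since the method as formulated acts on
absolute log abundances. The free-energy sums Σ_i X_i(t) G_iα use the same
abundance matrix (same aggregation/normalisation state) that produced the
decomposed log matrix.

## Known limitations

* The enrichment null conditions on the observed weight pool; it does not
  model between-replicate uncertainty in the weights themselves.
* Empirical p-values of exactly 0 occur whenever ŵ± exceeds every
  resample; downstream consumers should floor them at the stored 1/b
  resolution when ranking across different b.
* Hierarchy-aware testing of nested annotation bins is not attempted; each
  ontology path is a distinct test unit (ancestor propagation of members
  is off by default and available as a flag).
* MapMan parsing assumes the documented five-column layout; other ontology
  formats should be converted to GMT.
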