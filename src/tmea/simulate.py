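"""Synthetic abundance matrices with known low-rank log-linear structure.

The generator builds a ground-truth decomposition (orthonormal entity
weights, orthogonal time potentials with geometrically decaying scales, a
dominant near-constant baseline), exponentiates the noisy log matrix into
strictly positive abundances, and plants annotation sets exhibiting the
three weight-distribution archetypes that drive enrichment calls:

* ``shift`` — the whole member weight distribution is shifted towards
  extreme values (the majority-vote case a counting test also detects);
* ``single`` — one or two members carry pool-extreme weights while the rest
  are unremarkable (detectable by a weight sum, invisible to counting);
* ``subgroup`` — a block of members is skewed to one tail.

Constraint weights are drawn from a Laplace distribution before
orthonormalisation: real constraint weights are heavy-tailed, with a few
strongly responding entities dominating each pattern, and heavy tails are
what makes the ``single`` archetype meaningful.

Defaults emulate a desk-scale bulk transcriptomics time course: 1,000
entities, 11 time points, 3 constraints beyond the baseline, multiplicative
(log-additive Gaussian) noise with sd 0.2.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np

from tmea.io import AbundanceMatrix, AnnotationCatalog
from tmea.surprisal import _apply_sign_convention


@dataclass
class PlantedTruth:
    """Ground-truth weights, potentials and planted-set bookkeeping."""

    true_weights: np.ndarray
    true_potentials: np.ndarray
    singular_values: np.ndarray
    noise_sd: float
    entity_ids: list[str]
    condition_labels: list[str]
    planted_sets: list[tuple[str, int, str, str]] = field(default_factory=list)

    @property
    def rank(self) -> int:
        """Number of constraints beyond the baseline."""
        return self.true_weights.shape[1] - 1

    def noiseless_log_matrix(self) -> np.ndarray:
        return self.true_weights @ self.true_potentials


def make_truth(
    n_entities: int = 1000,
    n_conditions: int = 11,
    rank: int = 3,
    singular_value_decay: float = 0.3,
    baseline_log_level: float = 6.0,
    noise_sd: float = 0.2,
    seed: int = 0,
) -> PlantedTruth:
    """Construct a ground-truth decomposition with a geometric singular spectrum.

    The baseline component is built on near-constant entity weights and time
    potentials (every entity populates the steady state), constraints on
    heavy-tailed (Laplace) weight vectors orthonormalised against it.
    Singular values decay geometrically from
    ``baseline_log_level * sqrt(n_entities * n_conditions)`` (which puts the
    mean log abundance near ``baseline_log_level``), so the spectrum has an
    unambiguous elbow after the last true constraint. Deterministic per seed.
    """
    if rank + 1 > min(n_entities, n_conditions):
        raise ValueError(
            f"rank {rank} too large for {n_entities} entities x {n_conditions} conditions"
        )
    if not 0 < singular_value_decay < 1:
        raise ValueError("singular_value_decay must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    # entity weights: ones column (baseline) then Laplace-tailed constraint columns
    raw_g = np.empty((n_entities, rank + 1))
    raw_g[:, 0] = 1.0
    if rank:
        raw_g[:, 1:] = rng.laplace(size=(n_entities, rank))
    g, _ = np.linalg.qr(raw_g)
    # time potentials: ones column then smooth random profiles
    raw_v = np.empty((n_conditions, rank + 1))
    raw_v[:, 0] = 1.0
    if rank:
        raw_v[:, 1:] = rng.normal(size=(n_conditions, rank))
    v, _ = np.linalg.qr(raw_v)
    sigma = baseline_log_level * np.sqrt(n_entities * n_conditions) * (
        singular_value_decay ** np.arange(rank + 1)
    )
    g, vt = _apply_sign_convention(g, v.T)
    potentials = sigma[:, None] * vt
    return PlantedTruth(
        true_weights=g,
        true_potentials=potentials,
        singular_values=sigma,
        noise_sd=noise_sd,
        entity_ids=[f"G{i:05d}" for i in range(n_entities)],
        condition_labels=[f"t{j:02d}" for j in range(n_conditions)],
    )


def synthesize_matrix(
    truth: PlantedTruth,
    seed: int = 0,
    mode: Literal["lognormal", "negative_binomial"] = "lognormal",
    nb_dispersion: float = 0.1,
) -> AbundanceMatrix:
    """Exponentiate the noisy log matrix into a strictly positive abundance matrix.

    ``lognormal`` adds Gaussian noise (sd ``truth.noise_sd``) on the log
    scale — multiplicative noise on abundances. ``negative_binomial`` draws
    integer counts with mean ``exp(L*)`` and the given dispersion, for
    testing pseudocount handling on count matrices (counts of zero are
    possible there).
    """
    rng = np.random.default_rng(seed)
    log_mean = truth.noiseless_log_matrix()
    if mode == "lognormal":
        values = np.exp(log_mean + rng.normal(scale=truth.noise_sd, size=log_mean.shape))
    elif mode == "negative_binomial":
        mu = np.exp(log_mean)
        r = 1.0 / nb_dispersion
        values = rng.negative_binomial(r, r / (r + mu)).astype(float)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return AbundanceMatrix(
        list(truth.entity_ids), list(truth.condition_labels), values
    )


def _directional_values(truth: PlantedTruth, constraint: int, direction: str) -> np.ndarray:
    if not 1 <= constraint <= truth.rank:
        raise ValueError(f"constraint {constraint} out of range 1..{truth.rank}")
    w = truth.true_weights[:, constraint]
    if direction == "positive":
        return w
    if direction == "negative":
        return -w
    raise ValueError(f"unknown direction {direction!r}")


def plant_catalog(
    truth: PlantedTruth,
    n_null_sets: int = 100,
    set_size_range: tuple[int, int] = (10, 40),
    archetype_params: Sequence[dict] | None = None,
    seed: int = 0,
) -> AnnotationCatalog:
    """Annotation catalog of random null sets plus planted enrichment archetypes.

    Null sets are uniform random entity draws. Each entry of
    ``archetype_params`` plants one set, keyed by::

        archetype:     'shift' | 'single' | 'subgroup'
        constraint:    alpha >= 1 (default 1)
        direction:     'positive' | 'negative' (default 'positive')
        size:          total member count (default 20; must be >= 5)
        strength:      shift only — exponent of the rank-proportional
                       sampling probability (default 8.0; 0 = null)
        n_extreme:     single/subgroup — members taken from the extreme
                       tail (default 2 for single, 6 for subgroup)
        tail_quantile: single/subgroup — tail start (default 0.995 single,
                       0.97 subgroup)

    Planted assignments are appended to ``truth.planted_sets`` for later
    truth evaluation. Deterministic per seed.
    """
    rng = np.random.default_rng(seed)
    n = len(truth.entity_ids)
    lo, hi = set_size_range
    if lo < 5:
        raise ValueError("set sizes below 5 fall under the default size filter")
    sets: dict[str, set[str]] = {}
    ids = np.asarray(truth.entity_ids)
    for j in range(n_null_sets):
        size = int(rng.integers(lo, hi + 1))
        members = rng.choice(n, size=size, replace=False)
        sets[f"null_{j:04d}"] = set(ids[members])

    for j, params in enumerate(archetype_params or []):
        params = dict(params)
        archetype = params.pop("archetype")
        constraint = int(params.pop("constraint", 1))
        direction = params.pop("direction", "positive")
        size = int(params.pop("size", 20))
        if size < 5:
            raise ValueError("planted set size must be >= 5")
        d = _directional_values(truth, constraint, direction)
        order = np.argsort(d)  # ascending; extreme tail at the end
        if archetype == "shift":
            strength = float(params.pop("strength", 8.0))
            ranks = np.empty(n)
            ranks[order] = np.arange(1, n + 1)
            probs = ranks**strength
            probs /= probs.sum()
            members = rng.choice(n, size=size, replace=False, p=probs)
        elif archetype in ("single", "subgroup"):
            n_extreme = int(params.pop("n_extreme", 2 if archetype == "single" else 6))
            tail_quantile = float(
                params.pop("tail_quantile", 0.995 if archetype == "single" else 0.97)
            )
            tail = order[int(np.ceil(tail_quantile * n)) :]
            if len(tail) < n_extreme:
                raise ValueError(
                    f"tail beyond quantile {tail_quantile} holds {len(tail)} entities, "
                    f"need {n_extreme}"
                )
            if n_extreme > size:
                raise ValueError("n_extreme exceeds the requested set size")
            # 'single' takes the most extreme entities; 'subgroup' a random tail block
            if archetype == "single":
                extreme = tail[-n_extreme:]
            else:
                extreme = rng.choice(tail, size=n_extreme, replace=False)
            rest = np.setdiff1d(np.arange(n), extreme)
            members = np.concatenate(
                [extreme, rng.choice(rest, size=size - n_extreme, replace=False)]
            )
        else:
            raise ValueError(f"unknown archetype {archetype!r}")
        if params:
            raise ValueError(f"unknown archetype parameter(s) {sorted(params)}")
        fas_id = f"planted_{archetype}_{j}"
        sets[fas_id] = set(ids[members])
        truth.planted_sets.append((fas_id, constraint, direction, archetype))
    return AnnotationCatalog(sets)
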