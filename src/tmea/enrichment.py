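"""Directional weight-sum enrichment testing with a Monte Carlo permutation null.

For a functionally annotated set E and one constraint alpha, the members with
strictly positive weights E+ = {w in E : w > 0} and strictly negative weights
E- = {w in E : w < 0} are tested separately. The test statistic is the
directional weight sum w_hat+ = sum(E+) (resp. w_hat-), and the null asks how
likely a random subset of the constraint's same-sign weight pool, of the same
cardinality s+/s-, is to reach a sum at least as extreme:

    p+ = P(W+ >= w_hat+),   p- = P(W- <= w_hat-),

estimated empirically from b resampled subsets as the fraction of resamples
at least as extreme (ties inclusive). Resampling is without replacement by
default (a permutation null over subsets of the observed pool); a bootstrap
mode resamples with replacement. The smallest attainable p is 1/b, so b
should be large; an add-one estimator (n_extreme + 1)/(b + 1) is offered for
conservative FDR work. Per constraint the procedure yields two functional
descriptors: one for positively and one for inversely contributing entities.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np
from statsmodels.stats.multitest import multipletests

from tmea.io import AnnotationCatalog
from tmea.surprisal import SurprisalDecomposition

logger = logging.getLogger(__name__)

Direction = Literal["positive", "negative"]

# cap on elements materialised per sampling chunk (memory/speed tradeoff)
_CHUNK_ELEMENTS = 4_000_000


@dataclass
class DirectionalSplit:
    """Directional partition of one FAS's weights in one constraint.

    Zero weights belong to neither subset (the defining inequalities are
    strict), so ``s_plus + s_minus`` can be smaller than the measured set
    size.
    """

    fas_id: str
    constraint: int
    positive_members: list[tuple[str, float]]
    negative_members: list[tuple[str, float]]

    @property
    def s_plus(self) -> int:
        return len(self.positive_members)

    @property
    def s_minus(self) -> int:
        return len(self.negative_members)

    @property
    def w_hat_plus(self) -> float:
        return float(sum(w for _, w in self.positive_members))

    @property
    def w_hat_minus(self) -> float:
        return float(sum(w for _, w in self.negative_members))


@dataclass
class EmpiricalPValue:
    """Empirical tail probability from b Monte Carlo resamples.

    ``p = n_extreme / b`` (plain estimator); ``resolution = 1/b`` is the
    smallest nonzero attainable value, reported so that a p of exactly 0 can
    be floored downstream if desired.
    """

    p: float
    b: int
    n_extreme: int
    direction: Direction

    @property
    def resolution(self) -> float:
        return 1.0 / self.b


@dataclass
class EnrichmentRecord:
    """One (FAS, constraint, direction) enrichment test result."""

    fas_id: str
    constraint: int
    direction: Direction
    set_size: int
    subset_size: int
    weight_sum: float
    p_empirical: float
    q_bh: float = float("nan")
    p_resolution: float | None = None


def split_directional(
    weights: Mapping[str, float],
    members: Iterable[str],
    fas_id: str,
    constraint: int,
) -> DirectionalSplit:
    """Partition a FAS's member weights into positive and negative subsets.

    Members absent from the weight map (unmeasured entities) are dropped with
    a logged count; exact-zero weights are excluded from both subsets.
    """
    members = sorted(set(members))
    if not members:
        raise ValueError(f"FAS {fas_id!r}: empty member set")
    measured = [m for m in members if m in weights]
    n_dropped = len(members) - len(measured)
    if n_dropped:
        logger.info("FAS %s: dropped %d unmeasured member(s)", fas_id, n_dropped)
    positive = [(m, float(weights[m])) for m in measured if weights[m] > 0]
    negative = [(m, float(weights[m])) for m in measured if weights[m] < 0]
    return DirectionalSplit(fas_id, constraint, positive, negative)


def _resample_sums(
    pool: np.ndarray,
    subset_size: int,
    b: int,
    rng: np.random.Generator,
    replace: bool,
) -> np.ndarray:
    """Sums of b random size-s subsets of the pool, vectorised in chunks."""
    P = len(pool)
    sums = np.empty(b)
    chunk = max(1, _CHUNK_ELEMENTS // P)
    done = 0
    while done < b:
        cb = min(chunk, b - done)
        if replace:
            idx = rng.integers(0, P, size=(cb, subset_size))
        elif subset_size == P:
            sums[done : done + cb] = pool.sum()
            done += cb
            continue
        else:
            # uniform random s-subset per row: smallest s of i.i.d. uniform keys
            keys = rng.random((cb, P))
            idx = np.argpartition(keys, subset_size - 1, axis=1)[:, :subset_size]
        sums[done : done + cb] = pool[idx].sum(axis=1)
        done += cb
    return sums


def monte_carlo_pvalue(
    pool: Sequence[float] | np.ndarray,
    subset_size: int,
    observed_sum: float,
    b: int,
    direction: Direction,
    seed: int | np.random.SeedSequence | np.random.Generator,
    replace: bool = False,
    estimator: Literal["plain", "add_one"] = "plain",
) -> EmpiricalPValue:
    """Empirical p-value of a directional weight sum against resampled subsets.

    Draws ``b`` subsets of ``subset_size`` from ``pool`` (without replacement
    within each subset by default), sums each, and counts resamples at least
    as extreme as ``observed_sum`` — ``>=`` for the positive direction,
    ``<=`` for the negative one. Deterministic given (seed, b, pool order).
    """
    pool = np.asarray(pool, dtype=float)
    if direction not in ("positive", "negative"):
        raise ValueError(f"unknown direction {direction!r}")
    if b < 1:
        raise ValueError("b must be >= 1")
    if subset_size < 1:
        raise ValueError("subset_size must be >= 1")
    if len(pool) < subset_size:
        raise ValueError(
            f"pool of size {len(pool)} cannot supply subsets of size {subset_size}"
        )
    if direction == "positive" and np.any(pool <= 0):
        raise ValueError("positive-direction pool must contain strictly positive weights")
    if direction == "negative" and np.any(pool >= 0):
        raise ValueError("negative-direction pool must contain strictly negative weights")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    sums = _resample_sums(pool, subset_size, b, rng, replace)
    if direction == "positive":
        n_extreme = int(np.count_nonzero(sums >= observed_sum))
    else:
        n_extreme = int(np.count_nonzero(sums <= observed_sum))
    if estimator == "plain":
        p = n_extreme / b
    elif estimator == "add_one":
        p = (n_extreme + 1) / (b + 1)
    else:
        raise ValueError(f"unknown estimator {estimator!r}")
    return EmpiricalPValue(p=p, b=b, n_extreme=n_extreme, direction=direction)


def exact_permutation_pvalue(
    pool: Sequence[float] | np.ndarray,
    subset_size: int,
    observed_sum: float,
    direction: Direction,
) -> float:
    """Exact tail probability by exhaustive enumeration of all C(P, s) subsets.

    Feasible only for small pools; used as the ground truth the Monte Carlo
    estimator converges to.
    """
    pool = np.asarray(pool, dtype=float)
    if subset_size < 1 or subset_size > len(pool):
        raise ValueError("subset_size out of range")
    n_extreme = 0
    n_total = 0
    for combo in combinations(pool.tolist(), subset_size):
        s = sum(combo)
        if direction == "positive":
            n_extreme += s >= observed_sum
        else:
            n_extreme += s <= observed_sum
        n_total += 1
    return n_extreme / n_total


def bh_adjust(p_values: Sequence[float]) -> list[float]:
    """Benjamini-Hochberg step-up FDR adjustment, preserving input order."""
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return []
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1].tolist()


def _substream(seed: int, constraint: int, direction: Direction, fas_id: str) -> np.random.SeedSequence:
    """Deterministic per-test RNG substream, independent of iteration order."""
    dcode = 1 if direction == "positive" else 2
    return np.random.SeedSequence(
        [int(seed), int(constraint), dcode, zlib.crc32(fas_id.encode("utf-8"))]
    )


def run_tmea(
    decomp: SurprisalDecomposition,
    catalog: AnnotationCatalog,
    constraint_indices: Sequence[int],
    b: int = 10_000,
    min_set_size: int = 5,
    seed: int = 0,
    sampling_mode: Literal["permutation", "bootstrap"] = "permutation",
    bh_family: Literal[
        "per_constraint_direction", "per_constraint", "global"
    ] = "per_constraint_direction",
    p_estimator: Literal["plain", "add_one"] = "plain",
) -> list[EnrichmentRecord]:
    """Run the directional weight-sum enrichment test for every FAS and constraint.

    For each requested constraint alpha >= 1 and each FAS with at least
    ``min_set_size`` measured members, both directions are tested against the
    full same-sign weight pools of that constraint (restricted to measured
    entities); a direction with no members is skipped. BH correction is
    applied within each (constraint, direction) family by default.
    """
    if sampling_mode not in ("permutation", "bootstrap"):
        raise ValueError(f"unknown sampling_mode {sampling_mode!r}")
    if bh_family not in ("per_constraint_direction", "per_constraint", "global"):
        raise ValueError(f"unknown bh_family {bh_family!r}")
    replace = sampling_mode == "bootstrap"
    measured = set(decomp.entity_ids)
    if not any(members & measured for members in catalog.sets.values()):
        raise ValueError("no catalog member is present among the measured entities")

    records: list[EnrichmentRecord] = []
    n_small = 0
    for alpha in sorted(int(a) for a in constraint_indices):
        if alpha < 1:
            raise ValueError("constraints for enrichment testing start at alpha = 1")
        decomp._check_component(alpha)
        col = decomp.weights[:, alpha]
        weight_map = dict(zip(decomp.entity_ids, col.tolist()))
        pos_pool = col[col > 0]
        neg_pool = col[col < 0]
        for fas_id in sorted(catalog.sets):
            members = catalog.sets[fas_id] & measured
            s = len(members)
            if s < min_set_size:
                n_small += 1
                continue
            split = split_directional(weight_map, members, fas_id, alpha)
            for direction, pool, subset_size, w_hat in (
                ("positive", pos_pool, split.s_plus, split.w_hat_plus),
                ("negative", neg_pool, split.s_minus, split.w_hat_minus),
            ):
                if subset_size == 0:
                    continue
                result = monte_carlo_pvalue(
                    pool,
                    subset_size,
                    w_hat,
                    b,
                    direction,
                    _substream(seed, alpha, direction, fas_id),
                    replace=replace,
                    estimator=p_estimator,
                )
                records.append(
                    EnrichmentRecord(
                        fas_id=fas_id,
                        constraint=alpha,
                        direction=direction,
                        set_size=s,
                        subset_size=subset_size,
                        weight_sum=w_hat,
                        p_empirical=result.p,
                        p_resolution=result.resolution,
                    )
                )
    if not records:
        logger.warning(
            "no FAS passed min_set_size=%d (%d too small); empty result", min_set_size, n_small
        )
        return []

    def family_key(r: EnrichmentRecord):
        if bh_family == "per_constraint_direction":
            return (r.constraint, r.direction)
        if bh_family == "per_constraint":
            return (r.constraint,)
        return ()

    families: dict[tuple, list[EnrichmentRecord]] = {}
    for r in records:
        families.setdefault(family_key(r), []).append(r)
    for fam in families.values():
        qs = bh_adjust([r.p_empirical for r in fam])
        for r, q in zip(fam, qs):
            r.q_bh = q
    records.sort(key=lambda r: (r.constraint, r.direction, r.q_bh, r.fas_id))
    return records
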