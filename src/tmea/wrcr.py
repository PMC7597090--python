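"""Weight-ratio / count-ratio diagnostics for the weight-sum test statistic.

For a quantile threshold on a constraint's directional weight pool, each FAS
yields a weight ratio WR (fraction of its directional weight mass beyond the
threshold) and a count ratio CR (fraction of its members beyond it). If
counting extreme members carried the same information as summing weights,
WR would be a linear function of CR across sets. Regressing WR on CR at
every percentile threshold and summarising the R-squared values by a 15%
trimmed mean quantifies how much of the weight-sum signal mere counting
explains — the unexplained remainder is the motivation for using weight
sums, which can flag sets driven by one or a few extreme-weight members
that counting at any threshold would miss.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
from scipy.stats import trim_mean

from tmea.io import AnnotationCatalog
from tmea.surprisal import SurprisalDecomposition

DEFAULT_QUANTILES = np.arange(1, 100) / 100.0


@dataclass
class WrCrProfile:
    """Per-quantile regression quality of WR on CR, per direction."""

    quantiles: np.ndarray
    r2_positive: np.ndarray
    r2_negative: np.ndarray
    trimmed_mean_r2_positive: float
    trimmed_mean_r2_negative: float


def wrcr_for_set(
    weights: Sequence[float] | np.ndarray,
    pool: Sequence[float] | np.ndarray,
    quantile: float,
) -> tuple[float, float]:
    """Weight ratio and count ratio of one set at one pool-quantile threshold.

    ``weights`` are the set's directional member weights and ``pool`` the
    constraint's full same-sign weight pool; both must share one sign, which
    determines the direction. For positive weights the threshold is the
    ``quantile`` of the pool and membership beyond it is strict ``>``; for
    negative weights the threshold is the ``1 - quantile`` pool quantile with
    strict ``<``, so a given quantile selects equally extreme tails in both
    directions. Ratios use absolute values, hence lie in [0, 1]. The
    empirical quantile uses linear interpolation between order statistics
    (the type-7 convention).
    """
    weights = np.asarray(weights, dtype=float)
    pool = np.asarray(pool, dtype=float)
    if weights.size == 0:
        raise ValueError("empty member weight set")
    if pool.size == 0:
        raise ValueError("empty weight pool")
    if not 0 < quantile < 1:
        raise ValueError("quantile must lie in (0, 1)")
    if np.all(pool > 0):
        if np.any(weights <= 0):
            raise ValueError("member weights must share the pool's (positive) sign")
        threshold = float(np.quantile(pool, quantile))
        beyond = weights > threshold
    elif np.all(pool < 0):
        if np.any(weights >= 0):
            raise ValueError("member weights must share the pool's (negative) sign")
        threshold = float(np.quantile(pool, 1.0 - quantile))
        beyond = weights < threshold
    else:
        raise ValueError("pool must be strictly one-signed")
    abs_w = np.abs(weights)
    wr = float(abs_w[beyond].sum() / abs_w.sum())
    cr = float(np.count_nonzero(beyond) / weights.size)
    return wr, cr


def linear_r2(pairs: Sequence[tuple[float, float]]) -> float:
    """R-squared of the ordinary least squares fit WR ~ intercept + slope * CR.

    Returns NaN (flagged missing) with fewer than 3 pairs or zero CR
    variance; a constant WR yields 0 (no variance to explain linearly).
    """
    arr = np.asarray(list(pairs), dtype=float)
    if arr.ndim != 2 or arr.shape[0] < 3:
        return float("nan")
    cr, wr = arr[:, 0], arr[:, 1]
    if np.var(cr) == 0:
        return float("nan")
    if np.var(wr) == 0:
        return 0.0
    r = np.corrcoef(cr, wr)[0, 1]
    return float(r * r)


def trimmed_mean(values: Sequence[float] | np.ndarray, fraction: float) -> float:
    """Mean after dropping floor(fraction * n) values from each end."""
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("empty value list")
    if not 0 <= fraction < 0.5:
        raise ValueError("trim fraction must lie in [0, 0.5)")
    return float(trim_mean(values, fraction))


def wrcr_profile(
    decomp: SurprisalDecomposition,
    catalog: AnnotationCatalog,
    constraint_indices: Sequence[int],
    min_set_size: int = 5,
    quantiles: np.ndarray | None = None,
    trim_fraction: float = 0.15,
    denominator: Literal["within_set", "global"] = "within_set",
    pool_mode: Literal["per_constraint", "pooled"] = "per_constraint",
) -> WrCrProfile:
    """WR-vs-CR regression quality across all FASs, per quantile and direction.

    For every percentile threshold (1%..99% by default) and each direction,
    (CR, WR) pairs are collected over every (FAS, constraint) combination
    with enough measured members, pooled across the requested constraints,
    and the per-quantile R-squared values are summarised by their 15%
    trimmed mean. ``denominator='global'`` normalises by the pool's weight
    mass and count instead of the set's own; ``pool_mode='pooled'`` takes
    quantile thresholds from the constraints' weights pooled together.
    """
    if quantiles is None:
        quantiles = DEFAULT_QUANTILES
    quantiles = np.asarray(quantiles, dtype=float)
    if denominator not in ("within_set", "global"):
        raise ValueError(f"unknown denominator mode {denominator!r}")
    measured = set(decomp.entity_ids)
    row_of = {e: i for i, e in enumerate(decomp.entity_ids)}

    # member weights per (constraint, FAS), plus directional pools
    per_constraint: list[tuple[np.ndarray, np.ndarray, list[np.ndarray]]] = []
    indices = sorted(int(a) for a in constraint_indices)
    pooled_cols = []
    for alpha in indices:
        if alpha < 1:
            raise ValueError("constraints for WR/CR diagnostics start at alpha = 1")
        decomp._check_component(alpha)
        pooled_cols.append(decomp.weights[:, alpha])
    pooled = np.concatenate(pooled_cols) if pooled_cols else np.array([])

    sets_members = {
        fas_id: sorted(members & measured)
        for fas_id, members in catalog.sets.items()
        if len(members & measured) >= min_set_size
    }

    n_q = len(quantiles)
    r2 = {"positive": np.full(n_q, np.nan), "negative": np.full(n_q, np.nan)}
    for qi, q in enumerate(quantiles):
        pairs: dict[str, list[tuple[float, float]]] = {"positive": [], "negative": []}
        for alpha in indices:
            col = decomp.weights[:, alpha]
            source = pooled if pool_mode == "pooled" else col
            pools = {"positive": source[source > 0], "negative": source[source < 0]}
            for fas_id, members in sets_members.items():
                w = col[[row_of[m] for m in members]]
                for direction, sel in (("positive", w > 0), ("negative", w < 0)):
                    mw = w[sel]
                    pool = pools[direction]
                    if mw.size == 0 or pool.size == 0:
                        continue
                    wr, cr = wrcr_for_set(mw, pool, q)
                    if denominator == "global":
                        abs_mw = np.abs(mw)
                        abs_pool = np.abs(pool)
                        wr = float(wr * abs_mw.sum() / abs_pool.sum())
                        cr = float(cr * mw.size / pool.size)
                    pairs[direction].append((cr, wr))
        for direction in ("positive", "negative"):
            r2[direction][qi] = linear_r2(pairs[direction])

    def summarise(vals: np.ndarray) -> float:
        finite = vals[np.isfinite(vals)]
        return trimmed_mean(finite, trim_fraction) if finite.size else float("nan")

    return WrCrProfile(
        quantiles=quantiles,
        r2_positive=r2["positive"],
        r2_negative=r2["negative"],
        trimmed_mean_r2_positive=summarise(r2["positive"]),
        trimmed_mean_r2_negative=summarise(r2["negative"]),
    )
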