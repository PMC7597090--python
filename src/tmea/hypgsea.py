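"""One-sided hypergeometric overrepresentation baseline (hypGSEA).

The classical comparison method: entities carry a binary significance label
(e.g. a differential-expression flag computed upstream), and each FAS is
tested for overrepresentation of labelled entities by the upper tail of the
hypergeometric distribution. No mid-p correction is applied — at the small
set sizes typical of functional annotations the discrete distribution makes
the test conservative, and mid-p would risk exceeding the nominal level; an
expert flag exposes it for comparison experiments only.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
from scipy.stats import hypergeom

from tmea.io import AnnotationCatalog
from tmea.enrichment import bh_adjust

logger = logging.getLogger(__name__)


@dataclass
class LabeledBackground:
    """Measured entities with a binary significance label each."""

    entity_ids: list[str]
    is_significant: list[bool]

    def __post_init__(self) -> None:
        if len(self.entity_ids) != len(self.is_significant):
            raise ValueError("labels and entity IDs differ in length")
        if len(set(self.entity_ids)) != len(self.entity_ids):
            raise ValueError("duplicate entity IDs in labeled background")


@dataclass
class HypgseaRecord:
    """One FAS overrepresentation test: overlap k of n members among K labelled in N."""

    fas_id: str
    N: int
    K: int
    n: int
    k: int
    p: float
    q_bh: float = float("nan")


def hypergeom_upper_tail(k: int, N: int, K: int, n: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N, K, n), without mid-p correction.

    N: background size; K: labelled entities; n: set size; k: observed
    overlap. Computed via the survival function, which works in log space
    and is stable for extreme tails.
    """
    if not (0 <= K <= N and 0 <= n <= N):
        raise ValueError(f"invalid hypergeometric parameters N={N}, K={K}, n={n}")
    if not 0 <= k <= min(K, n):
        raise ValueError(f"overlap k={k} outside [0, min(K={K}, n={n})]")
    return float(hypergeom.sf(k - 1, N, K, n))


def run_hypgsea(
    background: LabeledBackground,
    catalog: AnnotationCatalog,
    min_set_size: int = 5,
    background_mode: Literal["annotated", "all_measured"] = "annotated",
    mid_p: bool = False,
) -> list[HypgseaRecord]:
    """One-sided hypergeometric test per FAS, BH-corrected across all tested FASs.

    ``background_mode='annotated'`` (default) restricts the universe N to
    labelled entities carrying at least one annotation, the common GSEA
    convention; ``'all_measured'`` uses every labelled entity. FASs with
    fewer than ``min_set_size`` measured members are excluded. Results are
    sorted by (q, fas_id).
    """
    labels = dict(zip(background.entity_ids, background.is_significant))
    if background_mode == "annotated":
        annotated = set().union(*catalog.sets.values()) if catalog.sets else set()
        universe = [e for e in background.entity_ids if e in annotated]
    elif background_mode == "all_measured":
        universe = list(background.entity_ids)
    else:
        raise ValueError(f"unknown background_mode {background_mode!r}")
    universe_set = set(universe)
    if not universe_set:
        raise ValueError("no catalog member is present in the labeled background")
    N = len(universe)
    K = sum(labels[e] for e in universe)
    if K == 0:
        logger.warning("no significant entity in the background; all p-values are 1")

    records: list[HypgseaRecord] = []
    for fas_id in sorted(catalog.sets):
        members = catalog.sets[fas_id] & universe_set
        n = len(members)
        if n < min_set_size:
            continue
        k = sum(labels[m] for m in members)
        p = hypergeom_upper_tail(k, N, K, n)
        if mid_p:
            p -= 0.5 * float(hypergeom.pmf(k, N, K, n))
        records.append(HypgseaRecord(fas_id=fas_id, N=N, K=K, n=n, k=k, p=p))
    if not records:
        logger.warning("no FAS passed min_set_size=%d", min_set_size)
        return []
    qs = bh_adjust([r.p for r in records])
    for r, q in zip(records, qs):
        r.q_bh = q
    records.sort(key=lambda r: (r.q_bh, r.fas_id))
    return records
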