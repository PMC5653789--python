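"""Directional overlap of two DEG callings with hypergeometric significance.

Two case/control studies are compared on the intersection of their tested
gene universes: how many genes up-regulated in study A are also up-regulated
in study B (and likewise down/down), and how surprising that count is under
a hypergeometric null in which B's set is a uniform random draw from the
shared universe.  The shared-universe size is the single largest hidden
determinant of the p-value, so it is carried in the result and logged.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats
from scipy.special import logsumexp

from .differential import DEGSets
from .errors import ValidationError

logger = logging.getLogger(__name__)

__all__ = ["hypergeom_upper_tail", "directional_overlap", "OverlapResult"]


@dataclass
class OverlapResult:
    """Directional concordance counts and their hypergeometric p-value."""

    direction: str            # "up" or "down"
    n_universe: int           # N, size of the shared tested universe
    n_set_a: int              # |A| after restriction to the universe
    n_set_b: int              # |B| after restriction
    n_overlap: int            # k = |A & B|
    pct_of_a: float           # 100 * k / |A| (0 when A is empty)
    p_value: float            # P[X >= k], X ~ Hypergeom(N, |A|, |B|)


def hypergeom_upper_tail(N: int, K: int, n: int, k: int) -> float:
    """Upper-tail hypergeometric probability ``P[X >= k]``.

    ``X`` counts the marked items in a size-``n`` draw without replacement
    from ``N`` items of which ``K`` are marked.  The tail is accumulated in
    log space so that extreme enrichments do not underflow prematurely.
    """
    for name, value in (("N", N), ("K", K), ("n", n), ("k", k)):
        if int(value) != value or value < 0:
            raise ValidationError(f"{name} must be a non-negative integer, got {value}")
    if K > N:
        raise ValidationError(f"K <= N violated: K={K}, N={N}")
    if n > N:
        raise ValidationError(f"n <= N violated: n={n}, N={N}")
    if k > min(n, K):
        raise ValidationError(f"k <= min(n, K) violated: k={k}, n={n}, K={K}")
    if k == 0:
        return 1.0
    ks = np.arange(k, min(n, K) + 1)
    log_tail = logsumexp(stats.hypergeom.logpmf(ks, N, K, n))
    return float(np.clip(np.exp(log_tail), np.finfo(float).tiny, 1.0))


def _one_direction(direction: str, a: set[str], b: set[str],
                   universe: set[str]) -> tuple[OverlapResult, set[str]]:
    shared = a & b
    k = len(shared)
    pct = 100.0 * k / len(a) if a else 0.0
    p = hypergeom_upper_tail(len(universe), len(a), len(b), k)
    result = OverlapResult(
        direction=direction,
        n_universe=len(universe),
        n_set_a=len(a),
        n_set_b=len(b),
        n_overlap=k,
        pct_of_a=pct,
        p_value=p,
    )
    return result, shared


def directional_overlap(
    degs_a: DEGSets, degs_b: DEGSets
) -> tuple[OverlapResult, OverlapResult, set[str], set[str]]:
    """Up/up and down/down concordance of two DEG callings.

    Both sets are first restricted to the intersection of the two tested
    universes; percentages are relative to the restricted A sets (matching
    the asymmetric phrasing "x% of study-A genes were also changed in B").

    Returns
    -------
    (up_result, down_result, shared_up, shared_down)
    """
    if not degs_a.universe or not degs_b.universe:
        raise ValidationError("both DEG callings need a non-empty universe")
    universe = degs_a.universe & degs_b.universe
    if not universe:
        raise ValidationError("tested universes of the two studies do not intersect")
    logger.info(
        "concordance universe: %d genes (A tested %d, B tested %d)",
        len(universe), len(degs_a.universe), len(degs_b.universe),
    )
    up_res, shared_up = _one_direction(
        "up", degs_a.up & universe, degs_b.up & universe, universe
    )
    down_res, shared_down = _one_direction(
        "down", degs_a.down & universe, degs_b.down & universe, universe
    )
    return up_res, down_res, shared_up, shared_down
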