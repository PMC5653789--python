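"""Per-gene case-vs-control statistics and threshold DEG calling.

The contrast is a per-gene two-sided t test on log2 expression (Welch by
default, pooled-variance optional), with Benjamini-Hochberg q-values across
all tested genes.  Differentially expressed genes (DEGs) are then the genes
whose estimated linear fold change strictly exceeds a threshold (default 2)
at a q-value strictly below an FDR threshold (default 0.05); both thresholds
are strict inequalities, so boundary genes are excluded.

Fold change is defined as the difference of group means on the log2 scale,
i.e. the ratio of geometric means on the linear scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ValidationError
from .io import ExpressionMatrix

__all__ = ["welch_contrast", "bh_adjust", "call_degs", "DEGSets"]

_TINY = np.finfo(float).tiny


@dataclass
class DEGSets:
    """Thresholded up/down gene sets plus the universe they were called in."""

    up: set[str]
    down: set[str]
    universe: set[str]
    fc_threshold: float = 2.0
    fdr_threshold: float = 0.05

    def __post_init__(self) -> None:
        if self.fc_threshold <= 0 or self.fdr_threshold <= 0:
            raise ValidationError("thresholds must be positive")
        if self.up & self.down:
            raise ValidationError("up and down sets overlap")
        if not (self.up | self.down) <= self.universe:
            raise ValidationError("DEG sets extend outside the universe")


def welch_contrast(matrix: ExpressionMatrix, equal_var: bool = False) -> pd.DataFrame:
    """Per-gene case-vs-control t statistics on a log2 matrix.

    Parameters
    ----------
    matrix : ExpressionMatrix
        Log2 expression with case/control sample groups, >=2 samples each.
    equal_var : bool
        If True use the pooled-variance (Student) t; default is Welch with
        Satterthwaite degrees of freedom.

    Returns
    -------
    pandas.DataFrame
        Indexed by gene, columns ``log2fc`` (case minus control mean),
        ``t``, ``p`` (two-sided) and ``q`` (Benjamini-Hochberg).

    Notes
    -----
    Degenerate genes with zero variance in both groups get ``p = 1`` when
    the group means coincide and the smallest positive ``p`` otherwise.
    """
    case = matrix.group_values("case")
    control = matrix.group_values("control")
    if case.shape[1] < 2 or control.shape[1] < 2:
        raise ValidationError(
            f"need >=2 samples per group, got case={case.shape[1]}, "
            f"control={control.shape[1]}"
        )
    log2fc = case.mean(axis=1) - control.mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t_stat, p = stats.ttest_ind(case, control, axis=1, equal_var=equal_var)
    t_stat = np.asarray(t_stat, dtype=float)
    p = np.asarray(p, dtype=float)
    # zero variance in both groups: t is 0/0
    degenerate = ~np.isfinite(t_stat)
    if degenerate.any():
        same = degenerate & (log2fc == 0)
        diff = degenerate & (log2fc != 0)
        t_stat[same], p[same] = 0.0, 1.0
        t_stat[diff] = np.sign(log2fc[diff]) * np.inf
        p[diff] = _TINY
    p = np.clip(p, _TINY, 1.0)
    q = bh_adjust(p)
    return pd.DataFrame(
        {"log2fc": log2fc, "t": t_stat, "p": p, "q": q},
        index=pd.Index(matrix.gene_ids, name="gene"),
    )


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values.

    Implements ``q_(i) = min_{j>=i} p_(j) * m / j`` capped at 1, returned in
    the input order.  All p must lie in (0, 1].
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise ValidationError("p_values must be a non-empty 1-D sequence")
    if np.any(~np.isfinite(p)) or np.any(p <= 0) or np.any(p > 1):
        raise ValidationError("p-values must lie in (0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)
    q = np.empty_like(q_sorted)
    q[order] = q_sorted
    return q


def call_degs(
    contrast: pd.DataFrame,
    fc_threshold: float = 2.0,
    fdr_threshold: float = 0.05,
) -> DEGSets:
    """Threshold a contrast table into up/down DEG sets.

    ``up`` holds genes with ``log2fc > log2(fc_threshold)`` and
    ``q < fdr_threshold``; ``down`` mirrors it with the sign flipped.  The
    inequalities are strict: a gene sitting exactly on either threshold is
    not called.
    """
    if fc_threshold <= 0 or fdr_threshold <= 0:
        raise ValidationError("thresholds must be positive")
    lfc_cut = np.log2(fc_threshold)
    sig = contrast["q"] < fdr_threshold
    up = set(contrast.index[sig & (contrast["log2fc"] > lfc_cut)])
    down = set(contrast.index[sig & (contrast["log2fc"] < -lfc_cut)])
    return DEGSets(
        up=up,
        down=down,
        universe=set(contrast.index),
        fc_threshold=fc_threshold,
        fdr_threshold=fdr_threshold,
    )
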