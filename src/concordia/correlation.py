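"""Spearman correlation of two fold-change profiles.

Compares a disease fold-change profile (e.g. patient vs control PBMCs)
against a stimulation fold-change profile (e.g. cytokine-treated vs
untreated cells) over their shared genes.  Rank correlation is deliberately
insensitive to the scale and any monotone distortion of either profile,
which differ between platforms.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ValidationError
from .io import ExpressionMatrix

__all__ = ["FoldChangeProfile", "SpearmanResult", "fold_change_profile",
           "spearman_correlation", "read_profile", "write_profile"]

_TINY = np.finfo(float).tiny


@dataclass
class FoldChangeProfile:
    """Per-gene log2 fold changes with a source label."""

    values: pd.Series  # indexed by gene ID
    source_label: str = ""

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates:
            dups = self.values.index[self.values.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate genes in profile: {dups}")
        vals = self.values.to_numpy(dtype=float)
        if not np.all(np.isfinite(vals)):
            raise ValidationError("profile contains non-finite values")


@dataclass
class SpearmanResult:
    rho: float
    n_genes: int
    p_value: float


def fold_change_profile(matrix: ExpressionMatrix, label: str = "") -> FoldChangeProfile:
    """Case-minus-control mean difference per gene on the log2 scale."""
    case = matrix.group_values("case")
    control = matrix.group_values("control")
    if case.shape[1] < 2 or control.shape[1] < 2:
        raise ValidationError(
            f"need >=2 samples per group, got case={case.shape[1]}, "
            f"control={control.shape[1]}"
        )
    lfc = pd.Series(case.mean(axis=1) - control.mean(axis=1),
                    index=matrix.values.index, name="log2fc")
    return FoldChangeProfile(values=lfc, source_label=label)


def _exact_p(x: np.ndarray, y: np.ndarray, rho_obs: float) -> float:
    """Two-sided exact permutation p for |rho| under independent rankings."""
    n = len(x)
    rx = stats.rankdata(x)
    count = total = 0
    for perm in itertools.permutations(stats.rankdata(y)):
        r = stats.pearsonr(rx, np.asarray(perm)).statistic
        total += 1
        if abs(r) >= abs(rho_obs) - 1e-12:
            count += 1
    return count / total


def spearman_correlation(
    a: FoldChangeProfile, b: FoldChangeProfile, method: str = "t"
) -> SpearmanResult:
    """Spearman rho between two profiles over their shared genes.

    Ties receive mid-ranks.  The p-value uses the two-sided t approximation
    ``t = rho * sqrt((n-2) / (1-rho^2))`` (inaccurate below n ~ 10); pass
    ``method="exact"`` for an exact permutation p, available for n <= 8.
    ``rho = +/-1`` maps to the smallest positive float rather than 0.
    """
    shared = a.values.index.intersection(b.values.index)
    n = len(shared)
    if n < 4:
        raise ValidationError(f"need >=4 shared genes, got {n}")
    x = a.values.loc[shared].to_numpy(dtype=float)
    y = b.values.loc[shared].to_numpy(dtype=float)
    rx, ry = stats.rankdata(x), stats.rankdata(y)
    # identical / exactly reversed rankings: return +/-1 without float fuzz
    if np.array_equal(rx, ry):
        rho = 1.0
    elif np.array_equal(rx, len(rx) + 1.0 - ry):
        rho = -1.0
    else:
        rho = float(np.clip(stats.spearmanr(x, y).statistic, -1.0, 1.0))
    if method == "exact":
        if n > 8:
            raise ValidationError("exact permutation p limited to n <= 8")
        p = _exact_p(x, y, rho)
    elif method == "t":
        if abs(rho) >= 1.0:
            p = _TINY
        else:
            t = rho * np.sqrt((n - 2) / (1.0 - rho * rho))
            p = float(2.0 * stats.t.sf(abs(t), df=n - 2))
    else:
        raise ValidationError(f"unknown method {method!r}")
    return SpearmanResult(rho=rho, n_genes=n, p_value=float(np.clip(p, _TINY, 1.0)))


def read_profile(path, label: str = "") -> FoldChangeProfile:
    """Read a 2-column TSV (gene, log2fc) profile."""
    df = pd.read_csv(path, sep="\t", header=None, names=["gene", "log2fc"],
                     dtype={"gene": str})
    return FoldChangeProfile(
        values=pd.Series(df["log2fc"].to_numpy(dtype=float), index=df["gene"]),
        source_label=label or str(path),
    )


def write_profile(profile: FoldChangeProfile, path) -> None:
    profile.values.to_csv(path, sep="\t", header=False,
                          float_format="%.6f", lineterminator="\n")
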