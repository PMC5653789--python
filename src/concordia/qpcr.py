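"""Relative quantification of qPCR Ct tables and cytokine synergy scoring.

Fold changes use the classic 2^-ddCt method with a fixed amplification
efficiency of 2: the target Ct is normalised to a reference gene within each
condition (dCt), then to a control condition (ddCt), and the fold change is
2^-ddCt.  Replicates are aggregated as the arithmetic mean of ddCt, i.e. the
geometric mean of replicate folds, because fold changes live on a log scale.

Synergy between two single-agent treatments and their combination is scored
against an explicit null model of no interaction:

* ``bliss_multiplicative`` (default) — expected combination fold is the
  product of the single-agent folds; on the log2 scale the effects add.
* ``additive_hsa`` — highest-single-agent: expected fold is
  ``max(fold_a, fold_b)``.

The synergy index is observed/expected; an index above 1 is synergistic.
No significance test is attached to the index; a bootstrap CI over
replicate folds is offered as a descriptive adjunct.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ValidationError

__all__ = ["FoldChangeSet", "SynergyResult", "ddct_fold", "synergy_index",
           "bootstrap_fold_ci", "SYNERGY_MODELS"]

SYNERGY_MODELS = ("bliss_multiplicative", "additive_hsa")
_ADDITIVE_TOL = 1e-9


@dataclass
class FoldChangeSet:
    """Linear fold change of one condition vs control, with replicate folds."""

    condition: str
    fold: float
    replicate_folds: list[float] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.fold <= 0:
            raise ValidationError(f"fold must be positive, got {self.fold}")


@dataclass
class SynergyResult:
    fold_a: float
    fold_b: float
    fold_combo: float
    model: str
    expected: float
    index: float
    classification: str


def _mean_ct(table: pd.DataFrame, condition: str, gene: str) -> pd.Series:
    sub = table[(table["condition"] == condition) & (table["gene"] == gene)]
    if sub.empty:
        raise ValidationError(
            f"no Ct rows for gene {gene!r} in condition {condition!r}"
        )
    return sub.set_index("replicate")["ct"]


def ddct_fold(
    ct: pd.DataFrame,
    target_gene: str,
    reference_gene: str,
    condition: str,
    control_condition: str,
) -> FoldChangeSet:
    """2^-ddCt fold change of a target gene in one condition vs control.

    When target and reference share the same replicate indices in both
    conditions, per-replicate ddCt values give replicate folds whose
    geometric mean is the reported fold; otherwise the fold is computed from
    condition means only and ``replicate_folds`` holds that single value.
    """
    per_cond: dict[str, pd.Series | float] = {}
    aligned = True
    for cond in (condition, control_condition):
        tgt = _mean_ct(ct, cond, target_gene)
        ref = _mean_ct(ct, cond, reference_gene)
        if set(tgt.index) == set(ref.index):
            per_cond[cond] = (tgt - ref.reindex(tgt.index)).sort_index()
        else:
            aligned = False
            per_cond[cond] = float(tgt.mean() - ref.mean())
    if aligned:
        d_treat, d_ctrl = per_cond[condition], per_cond[control_condition]
        aligned = set(d_treat.index) == set(d_ctrl.index)
    if aligned:
        ddct = (d_treat - d_ctrl.reindex(d_treat.index)).to_numpy(dtype=float)
        replicate_folds = [float(f) for f in 2.0 ** (-ddct)]
        fold = float(2.0 ** (-ddct.mean()))
    else:
        dct = {
            c: float(v.mean()) if isinstance(v, pd.Series) else v
            for c, v in per_cond.items()
        }
        fold = float(2.0 ** (-(dct[condition] - dct[control_condition])))
        replicate_folds = [fold]
    return FoldChangeSet(condition=condition, fold=fold,
                         replicate_folds=replicate_folds)


def synergy_index(
    fold_a: float,
    fold_b: float,
    fold_combo: float,
    model: str = "bliss_multiplicative",
) -> SynergyResult:
    """Score a two-agent combination against a no-interaction null model."""
    for name, f in (("fold_a", fold_a), ("fold_b", fold_b),
                    ("fold_combo", fold_combo)):
        if not f > 0:
            raise ValidationError(f"{name} must be positive, got {f}")
    if model == "bliss_multiplicative":
        expected = fold_a * fold_b
    elif model == "additive_hsa":
        expected = max(fold_a, fold_b)
    else:
        raise ValidationError(f"unknown synergy model {model!r}; use {SYNERGY_MODELS}")
    index = fold_combo / expected
    if abs(index - 1.0) <= _ADDITIVE_TOL:
        classification = "additive"
    elif index > 1.0:
        classification = "synergistic"
    else:
        classification = "sub-additive"
    return SynergyResult(
        fold_a=fold_a, fold_b=fold_b, fold_combo=fold_combo,
        model=model, expected=expected, index=index,
        classification=classification,
    )


def bootstrap_fold_ci(
    replicate_folds, n_boot: int = 2000, alpha: float = 0.05, seed: int = 0
) -> tuple[float, float]:
    """Percentile bootstrap CI for the geometric-mean fold over replicates."""
    folds = np.asarray(replicate_folds, dtype=float)
    if folds.size == 0 or np.any(folds <= 0):
        raise ValidationError("replicate folds must be positive and non-empty")
    rng = np.random.default_rng(seed)
    logs = np.log2(folds)
    draws = rng.choice(logs, size=(n_boot, logs.size), replace=True).mean(axis=1)
    lo, hi = np.quantile(2.0 ** draws, [alpha / 2, 1 - alpha / 2])
    return float(lo), float(hi)
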