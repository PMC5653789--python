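"""Functional-term enrichment and signed cytokine-signature attribution.

Two gene-set questions about the shared (concordant) gene set:

1. Which functional terms from a flat gene->term annotation are
   over-represented in it (upper-tail hypergeometric test per term, flagged
   at a raw p threshold, default 0.001)?

2. Which stimulation signature from a treatment compendium best explains it?
   Each treatment contributes an induced and a repressed gene set; the
   shared set is tested against both, and the result is summarised as a
   signed statistic: ``sign * -log10(min(p_induced, p_repressed))`` with a
   positive sign when the induced side is the stronger match.  The two-sided
   p-value is the Bonferroni-doubled minimum, and treatments are ranked by
   Benjamini-Hochberg q across the compendium.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .concordance import hypergeom_upper_tail
from .differential import bh_adjust
from .errors import ValidationError
from .io import SignatureCompendium, SignatureEntry

__all__ = [
    "TermEnrichment",
    "SignedEnrichment",
    "enrich_terms",
    "signed_signature_stat",
    "rank_treatments",
]


@dataclass
class TermEnrichment:
    term_id: str
    n_annotated_in_universe: int
    n_annotated_in_set: int
    p_value: float
    enriched: bool


@dataclass
class SignedEnrichment:
    """Attribution of a gene set to one treatment's signature.

    ``statistic`` is ``-log10(min(p_induced, p_repressed))`` signed positive
    when the induced-side p is at most the repressed-side p (ties induced).
    ``q_value`` is filled in by :func:`rank_treatments`.
    """

    treatment_id: str
    p_induced: float
    p_repressed: float
    statistic: float
    p_two: float
    q_value: float | None = None
    degenerate: bool = False


def enrich_terms(
    gene_set: set[str],
    universe: set[str],
    annotation: pd.DataFrame,
    p_threshold: float = 0.001,
) -> list[TermEnrichment]:
    """Hypergeometric over-representation of annotation terms in a gene set.

    Parameters
    ----------
    gene_set, universe : set of str
        The tested set and the background it was drawn from; the set must be
        contained in the universe.
    annotation : pandas.DataFrame
        Columns ``gene`` and ``term``; genes may carry any number of terms.
    p_threshold : float
        Raw (uncorrected) p below which a term is flagged ``enriched``.

    Returns one result per term with at least one annotated gene in the
    universe, sorted by ascending p (term ID breaks ties).
    """
    if not gene_set <= universe:
        extra = sorted(gene_set - universe)[:5]
        raise ValidationError(f"gene_set not contained in universe (e.g. {extra})")
    N, n = len(universe), len(gene_set)
    results = []
    for term, genes in annotation.groupby("term")["gene"]:
        annotated = set(genes) & universe
        K = len(annotated)
        if K == 0:
            continue
        k = len(annotated & gene_set)
        p = hypergeom_upper_tail(N, K, n, k)
        results.append(
            TermEnrichment(
                term_id=str(term),
                n_annotated_in_universe=K,
                n_annotated_in_set=k,
                p_value=p,
                enriched=p < p_threshold,
            )
        )
    results.sort(key=lambda r: (r.p_value, r.term_id))
    return results


def signed_signature_stat(
    shared_set: set[str], universe: set[str], signature_entry: SignatureEntry
) -> SignedEnrichment:
    """Signed enrichment of a gene set against one treatment's signature.

    Both signature directions are intersected with the universe before
    testing.  If both are empty after restriction the result is flagged
    degenerate with statistic 0 and p_two 1.
    """
    if not shared_set <= universe:
        extra = sorted(shared_set - universe)[:5]
        raise ValidationError(f"shared_set not contained in universe (e.g. {extra})")
    N, n = len(universe), len(shared_set)
    induced = signature_entry.induced & universe
    repressed = signature_entry.repressed & universe
    if not induced and not repressed:
        return SignedEnrichment(
            treatment_id=signature_entry.treatment_id,
            p_induced=1.0, p_repressed=1.0,
            statistic=0.0, p_two=1.0, degenerate=True,
        )
    p_ind = (
        hypergeom_upper_tail(N, len(induced), n, len(induced & shared_set))
        if induced else 1.0
    )
    p_rep = (
        hypergeom_upper_tail(N, len(repressed), n, len(repressed & shared_set))
        if repressed else 1.0
    )
    sign = 1.0 if p_ind <= p_rep else -1.0
    stat = sign * -np.log10(min(p_ind, p_rep))
    # -log10(1.0) is -0.0; normalise so sign(statistic) semantics stay clean
    if stat == 0:
        stat = 0.0
    return SignedEnrichment(
        treatment_id=signature_entry.treatment_id,
        p_induced=p_ind,
        p_repressed=p_rep,
        statistic=float(stat),
        p_two=min(1.0, 2.0 * min(p_ind, p_rep)),
    )


def attribute_signatures(
    shared_set: set[str], universe: set[str], compendium: SignatureCompendium
) -> list[SignedEnrichment]:
    """Signed statistics for every treatment, ranked with BH q-values."""
    results = [signed_signature_stat(shared_set, universe, e) for e in compendium]
    return rank_treatments(results)


def rank_treatments(results: list[SignedEnrichment]) -> list[SignedEnrichment]:
    """BH-adjust the two-sided p across treatments and sort deterministically.

    Order: ascending q, then ascending p_two, then descending |statistic|,
    then treatment ID — a total order independent of input order.
    """
    if not results:
        raise ValidationError("need at least one treatment result")
    q = bh_adjust([r.p_two for r in results])
    ranked = [
        SignedEnrichment(
            treatment_id=r.treatment_id,
            p_induced=r.p_induced,
            p_repressed=r.p_repressed,
            statistic=r.statistic,
            p_two=r.p_two,
            q_value=float(qi),
            degenerate=r.degenerate,
        )
        for r, qi in zip(results, q)
    ]
    ranked.sort(
        key=lambda r: (r.q_value, r.p_two, -abs(r.statistic), r.treatment_id)
    )
    return ranked
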