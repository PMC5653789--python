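# concordia

Cross-disease transcriptome concordance analysis with cytokine signature
attribution, response correlation, and qPCR synergy quantification.

## The problem

Chronic inflammatory diseases can share downstream transcriptional programs
even when they affect different tissues — inflamed skin and atherosclerotic
arteries being the motivating pair. The analytical questions this package
answers are:

1. **Concordance.** Do the genes up-regulated in disease A overlap the genes
   up-regulated in disease B far beyond chance, on the universe of genes
   testable in both studies?
2. **Attribution.** Given a compendium of stimulation signatures (gene sets
   induced and repressed by individual cytokine treatments of cultured
   cells), which upstream treatments best explain the shared gene set?
3. **Response correlation.** Does a patient-vs-control fold-change profile
   (e.g. from PBMCs) rank-correlate with a cytokine-stimulation profile?
4. **Synergy.** In follow-up qPCR experiments, does a two-cytokine
   combination exceed the no-interaction expectation built from the
   single-agent fold changes?

## The statistics

* Per-gene differential expression: two-sided Welch *t* on log2 expression,
  Benjamini–Hochberg q-values, DEG calling at strict thresholds
  FC > 2 and FDR < 0.05 (both configurable).
* Directional overlap: for up-sets A and B in a shared universe of N genes,
  the overlap k is tested with the upper-tail hypergeometric probability
  P[X ≥ k], X ~ Hypergeom(N, |A|, |B|), accumulated in log space.
* Signature attribution: each treatment contributes an induced and a
  repressed set; the shared gene set is tested against both and summarised
  as the signed statistic sign · (−log10 min(p_induced, p_repressed)),
  positive when the induced side matches. Two-sidedness is
  2·min(p), BH-corrected across treatments.
* Term enrichment against a flat gene→term annotation, flagged at raw
  p < 0.001.
* Response correlation: Spearman rho (mid-ranks) with a two-sided *t*
  approximation for p, or an exact permutation p for n ≤ 8.
* qPCR: fold = 2^−ΔΔCt with ΔCt = Ct(target) − Ct(reference); synergy
  index = fold_combo / expected with a multiplicative (Bliss-style) or
  highest-single-agent expectation.

A synthetic-study generator (`concordia.simulate`) plants all of this with
known ground truth — driver treatments, signed per-gene effects, a qPCR
interaction term — so the full pipeline is testable without any downloads.

## Worked example

```sh
concordia simulate --seed 1 --out study/
concordia run-all --config pipeline.yaml --out study/results
```

with `pipeline.yaml` pointing at the bundle files (see
`concordia run-all --help`). The same analysis from Python:

```python
from concordia import (SimulationConfig, generate_two_tissue_study,
                       welch_contrast, call_degs, directional_overlap,
                       attribute_signatures)

study = generate_two_tissue_study(SimulationConfig(seed=1))
degs1 = call_degs(welch_contrast(study.tissue1))
degs2 = call_degs(welch_contrast(study.tissue2))
up, down, shared_up, _ = directional_overlap(degs1, degs2)
print(f"up/up: {up.n_overlap} genes ({up.pct_of_a:.1f}%, p={up.p_value:.3g})")
ranked = attribute_signatures(shared_up, degs1.universe & degs2.universe,
                              study.compendium)
print([(r.treatment_id, round(r.statistic, 1)) for r in ranked[:3]])
```

prints

```
up/up: 138 genes (76.2%, p=6.92e-134)
[('IFN-g', 90.1), ('TNF-a', 83.9), ('GM-CSF', -1.3)]
```

— of the 181 genes up-called in tissue 1, 138 (76.2%) are also up in
tissue 2, overwhelmingly beyond the hypergeometric null, and the signed
attribution ranks the two planted driver cytokines first with large
positive (induced-side) statistics; the third-ranked treatment is already
at noise level.

For the synergy arm, single-agent inductions of 600× and 60× with a
combination of 95 000× give a multiplicative expectation of 36 000× and a
synergy index of 95 000/36 000 ≈ 2.64 — the combination is 2.6-fold above
what independent action predicts:

```python
from concordia import synergy_index
synergy_index(600, 60, 95000)
# SynergyResult(... expected=36000, index=2.639, classification='synergistic')
```

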