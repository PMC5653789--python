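# Methods

## Overview

`concordia` implements a cross-disease concordance analysis as a chain of
exact set statistics over thresholded differential-expression calls, plus
two satellite analyses (rank correlation of fold-change profiles; ΔΔCt
quantification with synergy scoring). This note documents the models, their
assumptions, the defaults and why they were chosen, and what the synthetic
data do and do not establish.

## Differential expression

Input matrices are gene-level log2 expression (microarray log-intensities or
log2 FPKM); this is a documented precondition — the package performs no
normalisation or probe collapsing. Per gene, a two-sided Welch *t* test
(Satterthwaite degrees of freedom) compares case vs control; fold change is
the difference of group means on the log2 scale, i.e. the ratio of geometric
means. Welch rather than pooled variance is the default because equal group
variances cannot be assumed across disease states; a pooled switch
(`equal_var=True`) is provided. q-values are Benjamini–Hochberg step-up,
q₍ᵢ₎ = min₍ⱼ≥ᵢ₎ p₍ⱼ₎·m/j capped at 1; BH is the field-standard FDR control
for exchangeable gene-level tests. No empirical-Bayes variance moderation is
applied — moderation changes DEG counts invisibly and the downstream set
statistics are deliberately a pure function of the printed thresholds.

DEG calling uses strict inequalities, FC > 2 and FDR < 0.05 by default: a
gene exactly on either boundary is excluded. Degenerate genes (zero variance
in both groups) get p = 1 when the group means coincide and the smallest
positive double otherwise.

## Directional concordance

The analysis universe is the intersection of the genes tested in both
studies; both DEG sets are restricted to it before counting. This choice is
the single largest hidden determinant of the p-value, so the universe size
is logged and carried in every result. The up/up (and down/down) overlap k
is scored by the upper-tail hypergeometric probability P[X ≥ k] with
X ~ Hypergeom(N, |A|, |B|) — equivalently a one-sided Fisher exact test.
The tail is summed from log-pmf values via log-sum-exp, so p-values down to
the smallest positive double (~1e-308) are representable; smaller tails are
clamped to that bound rather than underflowing to 0. The reported
percentage is k/|A| (restricted), intentionally asymmetric in the two
studies; k itself is symmetric. No cross-direction (up/down) discordance
test is computed.

## Term enrichment and signature attribution

Term enrichment tests the shared up-set against a flat gene→term table with
the same hypergeometric upper tail, one test per term with ≥1 annotated gene
in the universe, flagged at raw p < 0.001 with no multiple-testing
correction (configurable). The annotation is deliberately flat: no ontology
graph propagation is performed, keeping the statistic exact; users of real
GO should pre-propagate annotations.

Attribution tests the shared set against each treatment's induced and
repressed signature sets (each first intersected with the universe). The
summary statistic is signed: |s| = −log10 min(p_induced, p_repressed), with
s > 0 when p_induced ≤ p_repressed (ties break to the induced side). The
statistic is isolated in one function so an alternative magnitude (e.g. a
signed z) can be swapped in. The per-treatment two-sided p is the Bonferroni
doubling min(1, 2·min(p)), because each treatment is tested in two
directions; BH runs across treatments on these doubled p-values. Ranking is
a deterministic total order: q, then p_two, then |statistic| descending,
then treatment ID. Enrichment is computed on the shared **up** set by
default — the attribution question concerns genes increased in both
diseases — with `enrich_direction: down` available.

## Response correlation

Profiles are per-gene mean log2 differences (case − control). Spearman rho
uses mid-ranks for ties; exactly concordant or exactly reversed rankings
return ±1.0 without floating-point fuzz. The p-value uses the two-sided *t*
approximation t = rho·√((n−2)/(1−rho²)), accurate for the intended use
(thousands of genes) and documented as inaccurate below n ≈ 10; an exact
permutation p is available for n ≤ 8. rho = ±1 maps p to the smallest
positive double. All shared genes enter by default (no responsive-gene
filter), since any such filter is an analysis choice that should be explicit.

## qPCR quantification and synergy

Fold changes use 2^−ΔΔCt with amplification efficiency fixed at 2
(efficiency-corrected Pfaffl quantification is out of scope). ΔCt is
Ct(target) − Ct(reference) within a condition; ΔΔCt subtracts the control
condition. Replicates aggregate as the arithmetic mean of ΔΔCt — the
geometric mean of folds — because folds are log-scale quantities; replicate
folds are computed per replicate when target/reference/control replicate
indices align, otherwise from condition means. By construction the fold is
invariant to any per-condition Ct shift applied equally to target and
reference (the normalisation contract).

Synergy is scored against an explicit null model: multiplicative
(Bliss-style independence on fold changes, expected = fold_a·fold_b; effects
add on the log2 scale) by default, or highest-single-agent
(expected = max(fold_a, fold_b)). Index = observed/expected; > 1 is
synergistic, with an absolute tolerance of 1e-9 around 1 for the "additive"
label. No significance test is attached to the index; a percentile
bootstrap CI over replicate folds is offered as a descriptive adjunct.

## Synthetic data: what it emulates

The generator produces, from one integer seed expanded into independent
substreams per component:

* a treatment compendium (default 42 treatments, 100 genes each, split 70%
  induced / 30% repressed — the split is unspecified territory and is
  configurable). Signatures are sampled independently per treatment and may
  overlap, as real cytokine signatures do (a disjoint switch exists);
* two case/control cohorts in which the signature genes of the first
  `n_driver_treatments` treatments (default: "IFN-g" and "TNF-a") are
  shifted by ±`shared_effect_lfc` in the case arms of **both** tissues, a
  `background_de_rate` fraction of the remaining genes gets tissue-private
  shifts of the same magnitude, and everything else is i.i.d. Gaussian
  noise around a Gaussian log2 baseline (log-normal linear baseline);
* a flat annotation containing one planted term covering the planted
  induced genes plus random terms;
* stimulation fold-change profiles for the drivers (signature effect +
  noise), emulating stimulated-vs-unstimulated PBMC profiles;
* tidy Ct tables for {control, A, B, A+B} in which the target gene's Ct
  drops by planted ΔCt shifts and the combination carries an extra
  `interaction_dct`, so the Bliss index recovered downstream is exactly
  2^interaction_dct at zero replicate noise.

Default study conditions: 2000 genes; 42 treatments with 2 drivers; shared
linear fold change 3 (log2 ≈ 1.585); log2 noise SD 0.5; 13 and 16 samples
per arm in tissues 1 and 2 (early/advanced-plaque-sized cohorts); 5%
background DE; Ct defaults planting ~600× and ~60× single-agent inductions
with a combination ~2.64× above multiplicative, 3 replicates, 0.15-cycle
technical noise. At these settings per-gene power is essentially 1, so
driver recovery failures indicate implementation faults, not sampling luck.

What the generator does **not** emulate: probe-level effects, platform
differences between the two cohorts, RNA-seq count noise (negative
binomial), batch effects, correlated genes, or signature misannotation.
Passing tests therefore establish the correctness of the statistics and the
pipeline plumbing under the stated model — not robustness to the
platform artefacts of real cross-study data, where the universe choice and
normalisation dominate.

## Numerical choices and degenerate inputs

* Hypergeometric tails in log space (log-sum-exp of logpmf); k = 0 returns
  exactly 1.
* BH implemented as a reverse cumulative minimum over mergesort-ranked
  p-values (stable ties); validated against the direct quadratic formula.
* Empty DEG sets: concordance with k = 0 gives p = 1; a pipeline run whose
  thresholds call no DEGs skips concordance with a logged reason.
* A treatment whose both signature sets vanish after universe restriction
  yields a degenerate result (statistic 0, p_two 1, flagged) rather than an
  error, so one bad compendium entry cannot abort an attribution.
* p-values are clamped to the smallest positive double; they are never 0.

## Test and verification sizes

The fast unit suite runs a scaled-down study (400 genes, 8 treatments, 8
samples per arm). The acceptance suite verifies the hypergeometric
implementation exhaustively for all N ≤ 12, BH on 1000 random vectors, null
calibration and driver recovery on the full default study over 100 and 50
seeds respectively, and Spearman properties on 1000 cases — sizes chosen so
the complete suite finishes in well under a minute while leaving the
statistical assertions sharp.

## Known limitations

* The concordance p-value is only as meaningful as the declared universe;
  cross-platform universes must be constructed by the caller.
* Strict-threshold DEG sets discard effect-size information; no rank-based
  (threshold-free) concordance is provided.
* The signed attribution statistic is a p-value transform, not an effect
  size; compendium treatments with very different signature sizes are
  comparable in significance but not in magnitude of effect.
* ΔΔCt assumes perfect (2×) amplification efficiency and an unregulated
  reference gene.
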