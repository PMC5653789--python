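"""Synthetic study generator with planted ground truth.

Emulates the data shapes of a cross-disease concordance study: two
case/control expression cohorts (e.g. inflamed skin and atherosclerotic
plaque) whose shared differential signal was injected by a small number of
"driver" treatments from a stimulation-signature compendium, plus a flat
functional annotation, stimulation fold-change profiles, and qPCR Ct tables
carrying a super-multiplicative two-cytokine interaction.

The expression model is intentionally simple: each gene has a Gaussian
log2 baseline (log-normal on the linear scale) shared by all samples of a
tissue; case samples of both tissues are shifted by the planted log2 effect
of driver-signature genes (positive for induced, negative for repressed
membership); a configurable fraction of the remaining genes receives
tissue-private shifts; everything else is i.i.d. Gaussian noise.  Under this
model Welch-t/BH assumptions hold exactly, so recovery by the downstream
pipeline is provable rather than merely plausible.

A single integer seed is expanded into independent per-component substreams
(compendium, each tissue, annotation, profiles, Ct) so that each stage is
individually reproducible.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .correlation import FoldChangeProfile, write_profile
from .errors import ValidationError
from .io import (
    ExpressionMatrix,
    SignatureCompendium,
    SignatureEntry,
    validate_ct,
    write_annotation,
    write_ct,
    write_expression,
    write_gmt,
)

__all__ = [
    "SimulationConfig",
    "CtSimConfig",
    "SyntheticStudy",
    "generate_compendium",
    "generate_two_tissue_study",
    "generate_ct_experiment",
    "write_bundle",
    "TREATMENT_NAMES",
]

# Cytokine-style labels for the stimulation compendium; the first entries
# double as the default planted drivers.
TREATMENT_NAMES = [
    "IFN-g", "TNF-a", "IL-17A", "IL-1b", "IL-19", "IL-20", "IL-24",
    "IL-36g", "IFN-a", "IL-4", "IL-13", "IL-6", "OSM", "IL-22", "TGF-b",
    "IL-21", "IL-23", "IL-12", "IL-18", "IL-33", "TSLP", "GM-CSF", "IL-2",
    "IL-15", "IL-27", "IL-10", "IL-5", "IL-9", "IL-25", "IFN-b", "LT-a",
    "TRAIL", "CD40L", "IL-26", "IL-28A", "IL-29", "IL-31", "IL-32",
    "IL-34", "IL-37", "EGF", "KGF",
]

_SUBSTREAMS = ("compendium", "tissue1", "tissue2", "annotation", "profiles", "ct")


def _substreams(seed: int) -> dict[str, np.random.Generator]:
    children = np.random.SeedSequence(seed).spawn(len(_SUBSTREAMS))
    return {name: np.random.default_rng(c) for name, c in zip(_SUBSTREAMS, children)}


@dataclass
class SimulationConfig:
    """Parameters of the two-tissue synthetic study.

    Defaults encode the study conditions the pipeline is exercised under: a
    42-treatment compendium with 2 planted drivers, 2000 genes, a shared
    linear fold change of 3 (log2 ~ 1.585) on driver-signature genes,
    residual log2 SD 0.5, and group sizes of 13 (tissue 1) and 16 (tissue 2)
    per arm, mirroring early/advanced plaque cohort sizes.
    """

    n_genes: int = 2000
    n_treatments: int = 42
    n_driver_treatments: int = 2
    module_size: int = 100
    shared_effect_lfc: float = math.log2(3.0)
    noise_sd: float = 0.5
    n_samples_per_group_tissue1: int = 13
    n_samples_per_group_tissue2: int = 16
    background_de_rate: float = 0.05
    induced_fraction: float = 0.7
    disjoint_signatures: bool = False
    baseline_mean: float = 7.0
    baseline_sd: float = 1.5
    n_annotation_terms: int = 50
    annotation_term_size: int = 50
    seed: int = 0

    def validate(self) -> None:
        counts = {
            "n_genes": self.n_genes,
            "n_treatments": self.n_treatments,
            "n_driver_treatments": self.n_driver_treatments,
            "module_size": self.module_size,
            "n_samples_per_group_tissue1": self.n_samples_per_group_tissue1,
            "n_samples_per_group_tissue2": self.n_samples_per_group_tissue2,
        }
        for name, value in counts.items():
            if int(value) != value or value < 1:
                raise ValidationError(f"{name} must be an integer >= 1, got {value}")
        if self.module_size > self.n_genes:
            raise ValidationError("module_size cannot exceed n_genes")
        if self.disjoint_signatures and self.module_size * self.n_treatments > self.n_genes:
            raise ValidationError(
                "disjoint signatures need module_size * n_treatments <= n_genes"
            )
        if self.n_driver_treatments > self.n_treatments:
            raise ValidationError("n_driver_treatments cannot exceed n_treatments")
        if not self.noise_sd > 0:
            raise ValidationError("noise_sd must be positive")
        if not 0 <= self.background_de_rate < 1:
            raise ValidationError("background_de_rate must lie in [0, 1)")
        if not 0 <= self.induced_fraction <= 1:
            raise ValidationError("induced_fraction must lie in [0, 1]")

    @property
    def gene_ids(self) -> list[str]:
        width = len(str(self.n_genes))
        return [f"G{i:0{width}d}" for i in range(1, self.n_genes + 1)]

    @property
    def treatment_ids(self) -> list[str]:
        names = list(TREATMENT_NAMES[: self.n_treatments])
        names += [f"treatment_{i:02d}" for i in range(len(names) + 1, self.n_treatments + 1)]
        return names

    @property
    def driver_ids(self) -> list[str]:
        return self.treatment_ids[: self.n_driver_treatments]


@dataclass
class CtSimConfig:
    """Parameters of the simulated qPCR experiment.

    Defaults plant single-agent fold inductions of ~600x (condition A) and
    ~60x (condition B) with a combination exceeding the multiplicative
    expectation by ~2.64x — the magnitude regime of a strongly synergistic
    chemokine induction — measured over 3 replicates with 0.15-cycle
    technical noise.
    """

    base_ct: float = 28.0
    ref_ct: float = 18.0
    effect_a_dct: float = math.log2(600.0)
    effect_b_dct: float = math.log2(60.0)
    interaction_dct: float = math.log2(95_000.0 / 36_000.0)
    replicate_sd: float = 0.15
    n_replicates: int = 3
    target_gene: str = "CXCL10"
    reference_gene: str = "RPLP0"
    condition_a: str = "IFN-g"
    condition_b: str = "TNF-a"
    control_condition: str = "control"
    seed: int = 0

    def validate(self) -> None:
        if self.n_replicates < 2:
            raise ValidationError("n_replicates must be >= 2")
        if self.replicate_sd < 0:
            raise ValidationError("replicate_sd must be >= 0")

    @property
    def combo_condition(self) -> str:
        return f"{self.condition_a}+{self.condition_b}"


@dataclass
class SyntheticStudy:
    """A generated study bundle with its planted ground truth."""

    tissue1: ExpressionMatrix
    tissue2: ExpressionMatrix
    compendium: SignatureCompendium
    annotation: pd.DataFrame
    truth: dict
    stimulation_profiles: dict[str, FoldChangeProfile] = field(default_factory=dict)


def generate_compendium(
    cfg: SimulationConfig, rng: np.random.Generator | None = None
) -> SignatureCompendium:
    """Draw per-treatment induced/repressed gene sets from the gene universe.

    Each treatment samples ``module_size`` genes without replacement and
    splits them ``induced_fraction`` induced / remainder repressed.  By
    default treatments sample independently, so signatures may overlap
    (as real cytokine signatures do); ``disjoint_signatures`` partitions the
    universe instead.
    """
    cfg.validate()
    if rng is None:
        rng = _substreams(cfg.seed)["compendium"]
    genes = np.array(cfg.gene_ids)
    n_induced = round(cfg.induced_fraction * cfg.module_size)
    entries = []
    if cfg.disjoint_signatures:
        pool = rng.permutation(genes)
    for i, tid in enumerate(cfg.treatment_ids):
        if cfg.disjoint_signatures:
            members = pool[i * cfg.module_size : (i + 1) * cfg.module_size]
        else:
            members = rng.choice(genes, size=cfg.module_size, replace=False)
        entries.append(
            SignatureEntry(
                treatment_id=tid,
                induced=set(members[:n_induced]),
                repressed=set(members[n_induced:]),
            )
        )
    return SignatureCompendium(entries)


def _planted_directions(cfg: SimulationConfig,
                        compendium: SignatureCompendium) -> dict[str, int]:
    """Signed direction per driver-signature gene; first driver wins conflicts."""
    directions: dict[str, int] = {}
    for driver in cfg.driver_ids:
        entry = compendium.get(driver)
        for gene in sorted(entry.induced):
            directions.setdefault(gene, +1)
        for gene in sorted(entry.repressed):
            directions.setdefault(gene, -1)
    return directions


def _tissue_matrix(
    cfg: SimulationConfig,
    rng: np.random.Generator,
    tissue_label: str,
    n_per_group: int,
    planted: dict[str, int],
) -> tuple[ExpressionMatrix, dict[str, float]]:
    genes = cfg.gene_ids
    gene_index = {g: i for i, g in enumerate(genes)}
    baseline = rng.normal(cfg.baseline_mean, cfg.baseline_sd, size=cfg.n_genes)

    effects = np.zeros(cfg.n_genes)
    for gene, direction in planted.items():
        effects[gene_index[gene]] = direction * cfg.shared_effect_lfc
    non_planted = np.array([g for g in genes if g not in planted])
    n_background = round(cfg.background_de_rate * len(non_planted))
    background: dict[str, float] = {}
    if n_background:
        chosen = rng.choice(non_planted, size=n_background, replace=False)
        signs = rng.choice([-1.0, 1.0], size=n_background)
        for gene, sign in zip(chosen, signs):
            lfc = sign * cfg.shared_effect_lfc
            effects[gene_index[gene]] = lfc
            background[str(gene)] = float(lfc)

    case_ids = [f"{tissue_label}_case_{i:02d}" for i in range(1, n_per_group + 1)]
    ctrl_ids = [f"{tissue_label}_control_{i:02d}" for i in range(1, n_per_group + 1)]
    noise = rng.normal(0.0, cfg.noise_sd, size=(cfg.n_genes, 2 * n_per_group))
    values = baseline[:, None] + noise
    values[:, :n_per_group] += effects[:, None]
    df = pd.DataFrame(values, index=pd.Index(genes, name="gene"),
                      columns=case_ids + ctrl_ids)
    groups = pd.Series(
        ["case"] * n_per_group + ["control"] * n_per_group,
        index=case_ids + ctrl_ids, name="group",
    )
    return ExpressionMatrix(values=df, groups=groups), background


def _annotation_table(
    cfg: SimulationConfig, rng: np.random.Generator, planted: dict[str, int]
) -> pd.DataFrame:
    """Flat gene->term annotation with one planted term over the induced genes."""
    rows: list[tuple[str, str]] = []
    planted_up = sorted(g for g, d in planted.items() if d > 0)
    rows += [(g, "shared_inflammatory_response") for g in planted_up]
    genes = np.array(cfg.gene_ids)
    width = len(str(cfg.n_annotation_terms))
    for i in range(1, cfg.n_annotation_terms + 1):
        size = min(cfg.annotation_term_size, cfg.n_genes)
        members = rng.choice(genes, size=size, replace=False)
        rows += [(str(g), f"term_{i:0{width}d}") for g in sorted(members)]
    return pd.DataFrame(rows, columns=["gene", "term"])


def _stimulation_profiles(
    cfg: SimulationConfig, rng: np.random.Generator,
    compendium: SignatureCompendium,
) -> dict[str, FoldChangeProfile]:
    """Per-driver stimulation fold-change profiles (signature effect + noise)."""
    profiles = {}
    genes = cfg.gene_ids
    gene_index = {g: i for i, g in enumerate(genes)}
    for driver in cfg.driver_ids:
        entry = compendium.get(driver)
        lfc = rng.normal(0.0, cfg.noise_sd, size=cfg.n_genes)
        for g in entry.induced:
            lfc[gene_index[g]] += cfg.shared_effect_lfc
        for g in entry.repressed:
            lfc[gene_index[g]] -= cfg.shared_effect_lfc
        profiles[driver] = FoldChangeProfile(
            values=pd.Series(lfc, index=pd.Index(genes, name="gene")),
            source_label=f"stimulation:{driver}",
        )
    return profiles


def generate_two_tissue_study(cfg: SimulationConfig) -> SyntheticStudy:
    """Generate the full two-cohort study with planted concordant signal.

    Driver-signature genes are shifted by ``shared_effect_lfc`` (signed by
    membership direction) in the case arms of BOTH tissues; a
    ``background_de_rate`` fraction of the remaining genes receives
    tissue-private shifts of the same magnitude; all else is noise.  The
    returned ``truth`` record carries driver IDs, planted directions, and
    the complete per-tissue true effect maps.
    """
    cfg.validate()
    streams = _substreams(cfg.seed)
    compendium = generate_compendium(cfg, rng=streams["compendium"])
    planted = _planted_directions(cfg, compendium)

    tissue1, bg1 = _tissue_matrix(
        cfg, streams["tissue1"], "T1", cfg.n_samples_per_group_tissue1, planted
    )
    tissue2, bg2 = _tissue_matrix(
        cfg, streams["tissue2"], "T2", cfg.n_samples_per_group_tissue2, planted
    )
    annotation = _annotation_table(cfg, streams["annotation"], planted)
    profiles = _stimulation_profiles(cfg, streams["profiles"], compendium)

    shared = {g: d * cfg.shared_effect_lfc for g, d in planted.items()}
    truth = {
        "driver_ids": list(cfg.driver_ids),
        "planted_genes": {g: int(d) for g, d in sorted(planted.items())},
        "shared_effect_lfc": cfg.shared_effect_lfc,
        "true_effects": {
            "tissue1": {**shared, **bg1},
            "tissue2": {**shared, **bg2},
        },
        "config": asdict(cfg),
    }
    return SyntheticStudy(
        tissue1=tissue1, tissue2=tissue2, compendium=compendium,
        annotation=annotation, truth=truth, stimulation_profiles=profiles,
    )


def generate_ct_experiment(cfg: CtSimConfig) -> pd.DataFrame:
    """Tidy Ct table for conditions {control, A, B, A+B}.

    The target gene's Ct drops by the planted dCt shifts (``effect_a_dct``
    under A, ``effect_b_dct`` under B, their sum plus ``interaction_dct``
    under the combination) while the reference gene stays flat, so with
    ``replicate_sd = 0`` the downstream 2^-ddCt fold of condition A vs
    control is exactly ``2**effect_a_dct`` and the Bliss synergy index is
    exactly ``2**interaction_dct``.
    """
    cfg.validate()
    rng = _substreams(cfg.seed)["ct"]
    shifts = {
        cfg.control_condition: 0.0,
        cfg.condition_a: cfg.effect_a_dct,
        cfg.condition_b: cfg.effect_b_dct,
        cfg.combo_condition: cfg.effect_a_dct + cfg.effect_b_dct + cfg.interaction_dct,
    }
    rows = []
    for condition, shift in shifts.items():
        for rep in range(1, cfg.n_replicates + 1):
            for gene, center in ((cfg.target_gene, cfg.base_ct - shift),
                                 (cfg.reference_gene, cfg.ref_ct)):
                ct = center + (rng.normal(0.0, cfg.replicate_sd)
                               if cfg.replicate_sd > 0 else 0.0)
                rows.append((condition, gene, rep, ct))
    table = pd.DataFrame(rows, columns=["condition", "gene", "replicate", "ct"])
    return validate_ct(table, cfg.reference_gene)


def write_bundle(
    study: SyntheticStudy,
    outdir: str | Path,
    ct_table: pd.DataFrame | None = None,
    force: bool = False,
) -> Path:
    """Write a study (and optional Ct table) as a flat-file bundle directory."""
    outdir = Path(outdir)
    if outdir.exists() and any(outdir.iterdir()) and not force:
        raise ValidationError(
            f"output directory {outdir} is not empty (pass force=True to overwrite)"
        )
    outdir.mkdir(parents=True, exist_ok=True)
    write_expression(study.tissue1, outdir / "tissue1.tsv", outdir / "tissue1_groups.tsv")
    write_expression(study.tissue2, outdir / "tissue2.tsv", outdir / "tissue2_groups.tsv")
    write_gmt(study.compendium, outdir / "compendium.gmt")
    write_annotation(study.annotation, outdir / "annotation.tsv")
    with open(outdir / "truth.json", "w", encoding="utf-8") as fh:
        json.dump(study.truth, fh, indent=2, sort_keys=True)
        fh.write("\n")
    if study.stimulation_profiles:
        profile_dir = outdir / "profiles"
        profile_dir.mkdir(exist_ok=True)
        for tid, profile in study.stimulation_profiles.items():
            write_profile(profile, profile_dir / f"{tid}.tsv")
    if ct_table is not None:
        write_ct(ct_table, outdir / "ct.tsv")
    return outdir
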