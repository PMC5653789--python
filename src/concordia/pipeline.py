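"""End-to-end orchestration: differential -> concordance -> enrichment ->
attribution, plus the optional response-correlation and qPCR-synergy stages,
driven by a single config and emitting a machine-readable report.

The report is a pure function of the inputs: every number in it can be
recomputed by calling the stage functions directly on the same files, and
two runs on identical inputs produce identical reports apart from the
``generated_at`` timestamp.
"""

from __future__ import annotations

import dataclasses
import datetime
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .concordance import directional_overlap
from .correlation import fold_change_profile, read_profile, spearman_correlation
from .differential import call_degs, welch_contrast
from .enrichment import attribute_signatures, enrich_terms
from .errors import ValidationError
from .io import (
    read_annotation,
    read_ct,
    read_expression,
    read_gmt,
    write_deg_gmt,
)
from .qpcr import ddct_fold, synergy_index

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_all"]


@dataclass
class PipelineConfig:
    """Paths and thresholds for a full pipeline run."""

    tissue1: Path
    tissue1_groups: Path
    tissue2: Path
    tissue2_groups: Path
    compendium: Path
    annotation: Path
    outdir: Path
    profiles: list[Path] = field(default_factory=list)
    ct: Path | None = None
    fc_threshold: float = 2.0
    fdr_threshold: float = 0.05
    term_p_threshold: float = 0.001
    treatment_q_threshold: float = 0.05
    enrich_direction: str = "up"  # "up" or "down": which shared set to enrich
    ct_target_gene: str = "CXCL10"
    ct_reference_gene: str = "RPLP0"
    ct_condition_a: str = "IFN-g"
    ct_condition_b: str = "TNF-a"
    ct_combo_condition: str = "IFN-g+TNF-a"
    ct_control_condition: str = "control"
    seed: int = 0

    def validate(self) -> None:
        for name in ("tissue1", "tissue1_groups", "tissue2", "tissue2_groups",
                     "compendium", "annotation"):
            path = getattr(self, name)
            if not Path(path).exists():
                raise ValidationError(f"{name} path does not exist: {path}")
        for p in self.profiles:
            if not Path(p).exists():
                raise ValidationError(f"profile path does not exist: {p}")
        if self.ct is not None and not Path(self.ct).exists():
            raise ValidationError(f"ct path does not exist: {self.ct}")
        for name in ("fc_threshold", "fdr_threshold", "term_p_threshold",
                     "treatment_q_threshold"):
            if not getattr(self, name) > 0:
                raise ValidationError(f"{name} must be positive")
        if self.enrich_direction not in ("up", "down"):
            raise ValidationError("enrich_direction must be 'up' or 'down'")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "PipelineConfig":
        """Load a config file; keyword overrides win over file values.

        Relative paths in the file are resolved against its directory.
        """
        path = Path(path)
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        raw.update({k: v for k, v in overrides.items() if v is not None})
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        base = path.parent
        path_keys = ("tissue1", "tissue1_groups", "tissue2", "tissue2_groups",
                     "compendium", "annotation", "ct", "outdir")
        for key in path_keys:
            if key in raw and raw[key] is not None:
                raw[key] = base / raw[key] if not Path(raw[key]).is_absolute() else Path(raw[key])
        if "profiles" in raw:
            raw["profiles"] = [
                base / p if not Path(p).is_absolute() else Path(p)
                for p in raw["profiles"]
            ]
        return cls(**raw)


def _jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return _jsonable(dataclasses.asdict(obj))
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (set, frozenset)):
        return sorted(obj)
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, Path):
        return str(obj)
    if hasattr(obj, "item"):  # numpy scalars
        return obj.item()
    return obj


def run_all(config: PipelineConfig) -> dict:
    """Execute every configured stage and write report.json plus per-stage TSVs."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict = {
        "config": _jsonable(dataclasses.asdict(config)),
        "seed": config.seed,
        "version": __version__,
    }

    try:
        report.update(_core_stages(config, outdir))
        if config.profiles:
            report["correlation"] = _correlation_stage(config)
        if config.ct is not None:
            report["synergy"] = _synergy_stage(config, outdir)
    finally:
        # flush whatever was computed, even on a failed later stage
        report["generated_at"] = datetime.datetime.now(
            datetime.timezone.utc
        ).isoformat()
        with open(outdir / "report.json", "w", encoding="utf-8") as fh:
            json.dump(_jsonable(report), fh, indent=2, sort_keys=True)
            fh.write("\n")
    return report


def _core_stages(config: PipelineConfig, outdir: Path) -> dict:
    out: dict = {}
    matrices = {
        "tissue1": read_expression(config.tissue1, config.tissue1_groups),
        "tissue2": read_expression(config.tissue2, config.tissue2_groups),
    }
    degs = {}
    out["differential"] = {}
    for name, matrix in matrices.items():
        contrast = welch_contrast(matrix)
        contrast.to_csv(outdir / f"contrast_{name}.tsv", sep="\t",
                        float_format="%.6g", lineterminator="\n")
        called = call_degs(contrast, config.fc_threshold, config.fdr_threshold)
        write_deg_gmt(name, called.up, called.down, outdir / f"degs_{name}.gmt")
        degs[name] = called
        out["differential"][name] = {
            "n_genes_tested": len(called.universe),
            "n_up": len(called.up),
            "n_down": len(called.down),
        }
        logger.info("%s: %d genes tested, %d up, %d down",
                    name, len(called.universe), len(called.up), len(called.down))

    if not (degs["tissue1"].up | degs["tissue1"].down):
        out["concordance"] = {"skipped": "no DEGs called in tissue1 at the "
                                         "configured thresholds"}
        return out
    if not (degs["tissue2"].up | degs["tissue2"].down):
        out["concordance"] = {"skipped": "no DEGs called in tissue2 at the "
                                         "configured thresholds"}
        return out

    up_res, down_res, shared_up, shared_down = directional_overlap(
        degs["tissue1"], degs["tissue2"]
    )
    universe = degs["tissue1"].universe & degs["tissue2"].universe
    out["concordance"] = {"up": _jsonable(up_res), "down": _jsonable(down_res)}
    write_deg_gmt("shared", shared_up, shared_down, outdir / "shared_sets.gmt")

    shared = shared_up if config.enrich_direction == "up" else shared_down
    if not shared:
        out["enrichment"] = {"skipped": f"shared {config.enrich_direction} set empty"}
        return out

    annotation = read_annotation(config.annotation)
    terms = enrich_terms(shared, universe, annotation, config.term_p_threshold)
    pd.DataFrame([dataclasses.asdict(t) for t in terms]).to_csv(
        outdir / "term_enrichment.tsv", sep="\t", index=False, lineterminator="\n"
    )
    out["enrichment"] = {
        "direction": config.enrich_direction,
        "n_terms_tested": len(terms),
        "n_enriched": sum(t.enriched for t in terms),
        "enriched_terms": [t.term_id for t in terms if t.enriched],
    }

    compendium = read_gmt(config.compendium)
    ranked = attribute_signatures(shared, universe, compendium)
    pd.DataFrame([dataclasses.asdict(r) for r in ranked]).to_csv(
        outdir / "attribution.tsv", sep="\t", index=False, lineterminator="\n"
    )
    out["attribution"] = {
        "n_treatments": len(ranked),
        "n_significant": sum(r.q_value < config.treatment_q_threshold for r in ranked),
        "ranking": [
            {"treatment_id": r.treatment_id, "statistic": r.statistic,
             "p_two": r.p_two, "q_value": r.q_value}
            for r in ranked
        ],
    }
    return out


def _correlation_stage(config: PipelineConfig) -> dict:
    matrix = read_expression(config.tissue1, config.tissue1_groups)
    disease = fold_change_profile(matrix, label="tissue1")
    results = {}
    for path in config.profiles:
        stim = read_profile(path, label=Path(path).stem)
        res = spearman_correlation(disease, stim)
        results[stim.source_label] = {
            "rho": res.rho, "n_genes": res.n_genes, "p_value": res.p_value,
        }
    return results


def _synergy_stage(config: PipelineConfig, outdir: Path) -> dict:
    ct = read_ct(config.ct, config.ct_reference_gene)
    folds = {}
    for cond in (config.ct_condition_a, config.ct_condition_b,
                 config.ct_combo_condition):
        folds[cond] = ddct_fold(
            ct, config.ct_target_gene, config.ct_reference_gene,
            cond, config.ct_control_condition,
        )
    result = synergy_index(
        folds[config.ct_condition_a].fold,
        folds[config.ct_condition_b].fold,
        folds[config.ct_combo_condition].fold,
    )
    rows = [{"condition": f.condition, "fold": f.fold,
             "n_replicates": len(f.replicate_folds)} for f in folds.values()]
    pd.DataFrame(rows).to_csv(outdir / "synergy_folds.tsv", sep="\t",
                              index=False, lineterminator="\n")
    return {
        "target_gene": config.ct_target_gene,
        "folds": {c: f.fold for c, f in folds.items()},
        "synergy": _jsonable(result),
    }
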