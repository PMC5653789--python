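"""Readers and writers for the flat file formats the pipeline touches.

All formats are UTF-8, tab-delimited, LF-terminated text:

* expression matrix — TSV, first column ``gene``, header row of sample IDs,
  values on the log2 scale;
* group map — 2-column TSV ``sample<TAB>group`` with groups ``case`` /
  ``control``;
* signature compendium — standard GMT, two lines per treatment named
  ``<treatment>_induced`` and ``<treatment>_repressed``;
* annotation — 2-column TSV ``gene<TAB>term`` (flat, no ontology structure);
* Ct table — tidy TSV with columns ``condition, gene, replicate, ct``.

Gene identifiers are matched by exact, case-sensitive string equality
everywhere; no alias resolution is attempted.  Inputs are expected to be
gene-level already (probe collapsing is a documented precondition, not a
feature).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ValidationError

logger = logging.getLogger(__name__)

GROUP_LABELS = ("case", "control")
CT_MIN, CT_MAX = 0.0, 45.0

__all__ = [
    "ExpressionMatrix",
    "SignatureCompendium",
    "SignatureEntry",
    "read_expression",
    "write_expression",
    "read_gmt",
    "write_gmt",
    "read_annotation",
    "write_annotation",
    "read_ct",
    "write_ct",
    "validate_ct",
]


@dataclass
class ExpressionMatrix:
    """A genes x samples log2 expression table with a case/control labelling.

    Attributes
    ----------
    values : pandas.DataFrame
        Rows indexed by unique gene IDs, columns by unique sample IDs.
    groups : pandas.Series
        Maps every sample ID to ``"case"`` or ``"control"``.
    """

    values: pd.DataFrame
    groups: pd.Series

    def __post_init__(self) -> None:
        idx = self.values.index
        cols = self.values.columns
        if idx.has_duplicates:
            dups = idx[idx.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate gene IDs: {dups}")
        if cols.has_duplicates:
            dups = cols[cols.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate sample IDs: {dups}")
        missing = [s for s in cols if s not in self.groups.index]
        if missing:
            raise ValidationError(f"samples missing from group map: {missing}")
        self.groups = self.groups.reindex(cols)
        bad = sorted(set(self.groups.unique()) - set(GROUP_LABELS))
        if bad:
            raise ValidationError(
                f"unknown group labels {bad}; expected one of {GROUP_LABELS}"
            )
        if self.values.isna().any().any():
            raise ValidationError("expression matrix contains missing values")

    @property
    def gene_ids(self) -> list[str]:
        return self.values.index.tolist()

    @property
    def sample_ids(self) -> list[str]:
        return self.values.columns.tolist()

    def samples_in(self, group: str) -> list[str]:
        return self.groups.index[self.groups == group].tolist()

    def group_values(self, group: str) -> np.ndarray:
        """Genes x samples array restricted to one group."""
        return self.values[self.samples_in(group)].to_numpy(dtype=float)


@dataclass
class SignatureEntry:
    treatment_id: str
    induced: set[str] = field(default_factory=set)
    repressed: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        both = self.induced & self.repressed
        if both:
            raise ValidationError(
                f"genes {sorted(both)} appear in both induced and repressed "
                f"sets of treatment {self.treatment_id!r}"
            )
        if not self.induced and not self.repressed:
            raise ValidationError(
                f"treatment {self.treatment_id!r} has no genes in either set"
            )


@dataclass
class SignatureCompendium:
    """Per-treatment induced/repressed gene sets (stimulation signatures)."""

    entries: list[SignatureEntry]

    def __post_init__(self) -> None:
        ids = [e.treatment_id for e in self.entries]
        if len(set(ids)) != len(ids):
            dups = sorted({t for t in ids if ids.count(t) > 1})
            raise ValidationError(f"duplicate treatment IDs: {dups}")

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)

    @property
    def treatment_ids(self) -> list[str]:
        return [e.treatment_id for e in self.entries]

    def get(self, treatment_id: str) -> SignatureEntry:
        for e in self.entries:
            if e.treatment_id == treatment_id:
                return e
        raise KeyError(treatment_id)


# ---------------------------------------------------------------------------
# expression matrix


def read_expression(path: str | Path, group_map_path: str | Path) -> ExpressionMatrix:
    """Load a log2 expression TSV plus its sample->group map.

    Genes with any missing value are dropped (with a logged count) rather
    than imputed.  Duplicate gene IDs and samples absent from the group map
    are hard errors.
    """
    df = pd.read_csv(path, sep="\t", index_col=0, dtype={0: str})
    df.index = df.index.astype(str)
    if df.index.has_duplicates:
        dups = df.index[df.index.duplicated()].unique().tolist()
        raise ValidationError(f"duplicate gene IDs in {path}: {dups}")
    n_missing = int(df.isna().any(axis=1).sum())
    if n_missing:
        logger.warning("dropping %d gene(s) with missing values from %s", n_missing, path)
        df = df.dropna(axis=0)
    groups = read_group_map(group_map_path)
    missing = [s for s in df.columns if s not in groups.index]
    if missing:
        raise ValidationError(
            f"samples {missing} in {path} are absent from group map {group_map_path}"
        )
    return ExpressionMatrix(values=df.astype(float), groups=groups)


def read_group_map(path: str | Path) -> pd.Series:
    gm = pd.read_csv(path, sep="\t", header=None, names=["sample", "group"], dtype=str)
    if gm["sample"].duplicated().any():
        dups = gm.loc[gm["sample"].duplicated(), "sample"].tolist()
        raise ValidationError(f"duplicate samples in group map {path}: {dups}")
    return pd.Series(gm["group"].to_numpy(), index=gm["sample"], name="group")


def write_expression(matrix: ExpressionMatrix, path: str | Path,
                     group_map_path: str | Path | None = None) -> None:
    df = matrix.values.copy()
    df.index.name = "gene"
    df.to_csv(path, sep="\t", float_format="%.6f", lineterminator="\n")
    if group_map_path is not None:
        matrix.groups.to_csv(group_map_path, sep="\t", header=False, lineterminator="\n")


# ---------------------------------------------------------------------------
# GMT

_SUFFIXES = ("_induced", "_repressed")


def read_gmt(path: str | Path) -> SignatureCompendium:
    """Parse a GMT file into a compendium.

    Set names must end in ``_induced`` or ``_repressed``; the two directions
    of a treatment are merged by the shared name stem.  A treatment with only
    one direction present gets an empty set for the other.
    """
    induced: dict[str, set[str]] = {}
    repressed: dict[str, set[str]] = {}
    order: list[str] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise ValidationError(
                    f"{path}:{lineno}: GMT line has {len(fields)} field(s); "
                    "need at least name and description"
                )
            name = fields[0]
            genes = {g for g in fields[2:] if g}
            for suffix, store in ((_SUFFIXES[0], induced), (_SUFFIXES[1], repressed)):
                if name.endswith(suffix):
                    stem = name[: -len(suffix)]
                    if stem not in induced and stem not in repressed:
                        order.append(stem)
                    store[stem] = store.get(stem, set()) | genes
                    break
            else:
                raise ValidationError(
                    f"{path}:{lineno}: set name {name!r} lacks an "
                    f"'_induced'/'_repressed' suffix"
                )
    entries = [
        SignatureEntry(t, induced.get(t, set()), repressed.get(t, set()))
        for t in order
    ]
    return SignatureCompendium(entries)


def write_gmt(compendium: SignatureCompendium, path: str | Path,
              description: str = "na") -> None:
    """Serialize a compendium as GMT (two lines per treatment, members sorted)."""
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for entry in compendium:
            for suffix, genes in ((_SUFFIXES[0], entry.induced),
                                  (_SUFFIXES[1], entry.repressed)):
                members = "\t".join(sorted(genes))
                line = f"{entry.treatment_id}{suffix}\t{description}"
                fh.write(line + ("\t" + members if members else "") + "\n")


def write_deg_gmt(label: str, up: set[str], down: set[str], path: str | Path) -> None:
    """Write a pair of DEG sets as GMT lines ``<label>_up`` / ``<label>_down``."""
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for suffix, genes in (("_up", up), ("_down", down)):
            members = "\t".join(sorted(genes))
            fh.write(f"{label}{suffix}\tna" + ("\t" + members if members else "") + "\n")


# ---------------------------------------------------------------------------
# annotation


def read_annotation(path: str | Path) -> pd.DataFrame:
    """Read a flat 2-column gene->term table (no header)."""
    ann = pd.read_csv(path, sep="\t", header=None, names=["gene", "term"], dtype=str)
    if ann.isna().any().any():
        raise ValidationError(f"annotation {path} has incomplete rows")
    return ann


def write_annotation(annotation: pd.DataFrame, path: str | Path) -> None:
    annotation[["gene", "term"]].to_csv(
        path, sep="\t", header=False, index=False, lineterminator="\n"
    )


# ---------------------------------------------------------------------------
# Ct tables

CT_COLUMNS = ["condition", "gene", "replicate", "ct"]


def validate_ct(table: pd.DataFrame, reference_gene: str) -> pd.DataFrame:
    missing_cols = [c for c in CT_COLUMNS if c not in table.columns]
    if missing_cols:
        raise ValidationError(f"Ct table lacks column(s) {missing_cols}")
    table = table[CT_COLUMNS].copy()
    table["ct"] = table["ct"].astype(float)
    table["replicate"] = table["replicate"].astype(int)
    out_of_range = table[(table["ct"] <= CT_MIN) | (table["ct"] >= CT_MAX)]
    if len(out_of_range):
        row = out_of_range.iloc[0]
        raise ValidationError(
            f"Ct value {row['ct']} for gene {row['gene']!r} in condition "
            f"{row['condition']!r} outside ({CT_MIN}, {CT_MAX})"
        )
    for cond, sub in table.groupby("condition", sort=False):
        if reference_gene not in set(sub["gene"]):
            raise ValidationError(
                f"reference gene {reference_gene!r} absent in condition {cond!r}"
            )
    return table


def read_ct(path: str | Path, reference_gene: str) -> pd.DataFrame:
    """Load and validate a tidy Ct table (columns condition, gene, replicate, ct)."""
    table = pd.read_csv(path, sep="\t", dtype={"condition": str, "gene": str})
    return validate_ct(table, reference_gene)


def write_ct(table: pd.DataFrame, path: str | Path) -> None:
    table[CT_COLUMNS].to_csv(path, sep="\t", index=False,
                             float_format="%.6f", lineterminator="\n")
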