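"""Readers and writers for the pipeline's on-disk artifacts.

Expression matrices travel as plain TSV (genes in rows, first column the gene
identifier) or GCT 1.2; gene sets as GMT; clinical data as TSV with one row
per sample.  In memory an expression matrix is a ``pandas.DataFrame`` with a
unique gene index and unique sample columns, log2-scale float values, and
``NaN`` marking missing measurements.  Gene identifiers are matched
case-sensitively after whitespace trimming.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "FormatError",
    "GeneSet",
    "GeneSetCollection",
    "read_expression",
    "write_expression",
    "collapse_duplicate_genes",
    "read_gmt",
    "write_gmt",
    "read_clinical",
    "write_clinical",
    "CLINICAL_REQUIRED",
    "CLINICAL_BINARY",
]


class FormatError(ValueError):
    """A file violates its declared format contract."""


# ---------------------------------------------------------------------------
# expression matrices


def _validate_matrix(df: pd.DataFrame, source: str) -> pd.DataFrame:
    df.index.name = None
    df.columns.name = None
    if df.index.duplicated().any():
        dups = df.index[df.index.duplicated()].unique().tolist()[:5]
        raise FormatError(
            f"{source}: duplicate gene ids after loading: {dups}; "
            "run collapse_duplicate_genes on the raw table first"
        )
    if df.columns.duplicated().any():
        dups = df.columns[df.columns.duplicated()].unique().tolist()[:5]
        raise FormatError(f"{source}: duplicate sample ids: {dups}")
    return df


def _coerce_numeric(df: pd.DataFrame) -> pd.DataFrame:
    out = df.apply(pd.to_numeric, errors="coerce")
    n_bad = int(out.isna().sum().sum() - df.isna().sum().sum())
    if n_bad:
        logger.info("coerced %d non-numeric expression cells to missing", n_bad)
    return out.astype(float)


def read_expression(path: str | Path, format: str | None = None) -> pd.DataFrame:
    """Load a genes x samples expression matrix from TSV or GCT 1.2.

    ``format`` is ``"tsv"`` or ``"gct"``; if None it is inferred from the
    file suffix (``.gct`` -> GCT, anything else TSV).  Non-numeric cells
    become NaN.  Gene ids are loaded verbatim apart from whitespace trimming
    and may be duplicated in the raw file only for TSV input followed by
    :func:`collapse_duplicate_genes`; this reader rejects duplicates.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format is None:
        format = "gct" if path.suffix.lower() == ".gct" else "tsv"
    if format == "tsv":
        _check_header_unique(path, str(path))
        df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
        df.index = df.index.astype(str).str.strip()
        df.columns = df.columns.astype(str).str.strip()
        return _validate_matrix(_coerce_numeric(df), str(path))
    if format == "gct":
        return _read_gct(path)
    raise ValueError(f"unknown expression format {format!r}")


def _check_header_unique(fh_or_path, source: str, skip: int = 0) -> None:
    """pandas mangles duplicate header fields; detect them on the raw line."""
    with open(fh_or_path, encoding="utf-8") as fh:
        for _ in range(skip):
            fh.readline()
        fields = [f.strip() for f in fh.readline().rstrip("\n").split("\t")[1:]]
    dups = sorted({f for f in fields if fields.count(f) > 1})
    if dups:
        raise FormatError(f"{source}: duplicate sample ids: {dups[:5]}")


def _read_gct(path: Path) -> pd.DataFrame:
    _check_header_unique(path, str(path), skip=2)
    with open(path, encoding="utf-8") as fh:
        version = fh.readline().strip()
        if version != "#1.2":
            raise FormatError(f"{path}: expected GCT version line '#1.2', got {version!r}")
        dims = fh.readline().split("\t")
        try:
            n_genes, n_samples = int(dims[0]), int(dims[1])
        except (IndexError, ValueError) as exc:
            raise FormatError(f"{path}: malformed GCT dimension line") from exc
        df = pd.read_csv(fh, sep="\t", index_col=0, dtype=str)
    if df.shape[0] != n_genes:
        raise FormatError(
            f"{path}: GCT header declares {n_genes} genes but file has {df.shape[0]} rows"
        )
    # first data column is the Description field
    desc_dropped = df.iloc[:, 1:]
    if desc_dropped.shape[1] != n_samples:
        raise FormatError(
            f"{path}: GCT header declares {n_samples} samples "
            f"but file has {desc_dropped.shape[1]} sample columns"
        )
    desc_dropped.index = desc_dropped.index.astype(str).str.strip()
    desc_dropped.columns = desc_dropped.columns.astype(str).str.strip()
    return _validate_matrix(_coerce_numeric(desc_dropped), str(path))


def write_expression(df: pd.DataFrame, path: str | Path, format: str | None = None) -> None:
    """Write an expression matrix as TSV or GCT 1.2 (UTF-8, LF endings)."""
    path = Path(path)
    if format is None:
        format = "gct" if path.suffix.lower() == ".gct" else "tsv"
    if format == "tsv":
        out = df.copy()
        out.index.name = out.index.name or "gene"
        out.to_csv(path, sep="\t", lineterminator="\n", float_format="%.10g")
    elif format == "gct":
        with open(path, "w", encoding="utf-8", newline="\n") as fh:
            fh.write("#1.2\n")
            fh.write(f"{df.shape[0]}\t{df.shape[1]}\n")
            fh.write("NAME\tDescription\t" + "\t".join(map(str, df.columns)) + "\n")
            for gene, row in zip(df.index, np.asarray(df, dtype=float)):
                cells = "\t".join("" if np.isnan(v) else f"{v:.10g}" for v in row)
                fh.write(f"{gene}\tna\t{cells}\n")
    else:
        raise ValueError(f"unknown expression format {format!r}")


def collapse_duplicate_genes(df: pd.DataFrame) -> pd.DataFrame:
    """Average rows that share a gene id into a single row per gene.

    The per-sample arithmetic mean ignores missing cells, so a pair
    ``[1, NaN]`` / ``[3, 7]`` collapses to ``[2, 7]``.  Output order is first
    occurrence.  This mirrors the probe-summarisation step applied to
    microarray data before correlation analysis.
    """
    if not df.index.duplicated().any():
        return df
    order = df.index[~df.index.duplicated()]
    collapsed = df.groupby(level=0, sort=False).mean()
    return collapsed.loc[order]


# ---------------------------------------------------------------------------
# gene sets (GMT)


@dataclass
class GeneSet:
    name: str
    description: str
    genes: list[str]

    def __post_init__(self) -> None:
        if not self.genes:
            raise FormatError(f"gene set {self.name!r} is empty")


@dataclass
class GeneSetCollection:
    """Named gene sets; a thin mapping over :class:`GeneSet` entries."""

    sets: dict[str, GeneSet] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets.values())

    def __getitem__(self, name: str) -> GeneSet:
        return self.sets[name]

    def __contains__(self, name: str) -> bool:
        return name in self.sets

    def add(self, gs: GeneSet) -> None:
        if gs.name in self.sets:
            raise FormatError(f"duplicate gene-set name {gs.name!r}")
        self.sets[gs.name] = gs

    @classmethod
    def from_dict(cls, d: Mapping[str, Iterable[str]]) -> "GeneSetCollection":
        coll = cls()
        for name, genes in d.items():
            coll.add(GeneSet(name, "", list(dict.fromkeys(genes))))
        return coll


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Parse a GMT file: name, description, then one gene per field.

    Genes repeated within a set are deduplicated (first occurrence kept) with
    a logged warning; a line with fewer than three fields is a format error.
    """
    coll = GeneSetCollection()
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = [f.strip() for f in line.split("\t")]
            if len(fields) < 3:
                raise FormatError(f"{path}:{lineno}: GMT line has fewer than 3 fields")
            name, desc, genes = fields[0], fields[1], [g for g in fields[2:] if g]
            unique = list(dict.fromkeys(genes))
            if len(unique) < len(genes):
                logger.warning(
                    "gene set %r: %d duplicate gene(s) removed", name, len(genes) - len(unique)
                )
            coll.add(GeneSet(name, desc, unique))
    return coll


def write_gmt(coll: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for gs in coll:
            fh.write("\t".join([gs.name, gs.description or "na", *gs.genes]) + "\n")


# ---------------------------------------------------------------------------
# clinical tables

CLINICAL_REQUIRED = ("sample", "time", "event")
CLINICAL_BINARY = ("event", "gcimp", "radiotherapy", "temozolomide")


def read_clinical(path: str | Path) -> pd.DataFrame:
    """Load a clinical TSV into a typed survival table indexed by sample id.

    Required columns: ``sample``, ``time`` (days), ``event`` (0/1).  Optional:
    ``age``, ``gcimp``, ``radiotherapy``, ``temozolomide`` (0/1, missing
    allowed for gcimp), ``subtype``.  Rows with missing time or event are
    dropped with a logged count; a negative time or a non-binary flag is a
    format error naming the sample.
    """
    raw = pd.read_csv(path, sep="\t", dtype=str)
    raw.columns = [c.strip().lower() for c in raw.columns]
    missing_cols = [c for c in CLINICAL_REQUIRED if c not in raw.columns]
    if missing_cols:
        raise FormatError(f"{path}: missing required column(s) {missing_cols}")
    raw["sample"] = raw["sample"].astype(str).str.strip()
    if raw["sample"].duplicated().any():
        dups = raw.loc[raw["sample"].duplicated(), "sample"].tolist()[:5]
        raise FormatError(f"{path}: duplicate sample ids {dups}")

    table = raw.set_index("sample")
    for col in table.columns:
        if col != "subtype":
            table[col] = pd.to_numeric(table[col], errors="coerce")

    incomplete = table["time"].isna() | table["event"].isna()
    if incomplete.any():
        logger.info("dropped %d sample(s) missing time or event", int(incomplete.sum()))
        table = table.loc[~incomplete]

    bad_time = table.index[table["time"] < 0].tolist()
    if bad_time:
        raise FormatError(f"{path}: negative survival time for sample(s) {bad_time[:5]}")
    for col in CLINICAL_BINARY:
        if col in table.columns:
            vals = table[col].dropna()
            if not vals.isin([0, 1]).all():
                bad = table.index[~table[col].isin([0, 1]) & table[col].notna()].tolist()
                raise FormatError(f"{path}: column {col!r} not binary for sample(s) {bad[:5]}")
    return table


def write_clinical(table: pd.DataFrame, path: str | Path) -> None:
    out = table.copy()
    out.index.name = "sample"
    out.to_csv(path, sep="\t", lineterminator="\n", float_format="%.10g")
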