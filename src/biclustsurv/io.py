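"""Readers and writers for the package's tab-separated table formats.

Every table is TSV, UTF-8, '.' decimal. Expression files have genes in rows:
a header line of sample ids and a first column of gene symbols. Gene symbols
are case-preserved but matched case-insensitively (a case conflict warns).
Duplicated symbols keep the first occurrence with a logged warning.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ParseError

__all__ = [
    "ReadReport",
    "read_expression",
    "write_expression",
    "read_clinical",
    "write_clinical",
    "read_gene_list",
    "read_sample_labels",
    "write_panel",
]

log = logging.getLogger(__name__)

CLINICAL_REQUIRED = ("sample_id", "os_months", "os_event")


@dataclass
class ReadReport:
    """What a reader had to tolerate: duplicates dropped, missing cells."""

    n_genes: int = 0
    n_samples: int = 0
    n_duplicates_dropped: int = 0
    genes_with_missing: list[str] = field(default_factory=list)

    @property
    def n_missing_genes(self) -> int:
        return len(self.genes_with_missing)


def read_expression(path) -> tuple[pd.DataFrame, ReadReport]:
    """Read a genes x samples expression TSV.

    Returns the matrix (index = gene symbols, columns = sample ids) and a
    :class:`ReadReport`. Missing cells stay as NaN and the affected genes are
    listed in the report so downstream selection can exclude them with a
    logged count. Non-numeric cells raise :class:`ParseError` with the
    offending line number.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")
    except pd.errors.ParserError as exc:
        line = getattr(exc, "lineno", None)
        raise ParseError(f"cannot parse {path}: {exc}", line=line) from exc

    numeric = pd.DataFrame(index=df.index, columns=df.columns, dtype=float)
    for col in df.columns:
        series = df[col]
        if series.dtype == object:  # a non-numeric cell forced object dtype
            coerced = pd.to_numeric(series, errors="coerce")
            bad = coerced.isna() & series.notna() & (series.astype(str).str.strip() != "")
            if bad.any():
                row_pos = int(np.argmax(bad.to_numpy()))
                raise ParseError(
                    f"non-numeric cell {series.iloc[row_pos]!r} in column {col!r}",
                    line=row_pos + 2,  # +1 header, +1 one-based
                )
        numeric[col] = series.astype(float)

    dup = numeric.index.duplicated(keep="first")
    n_dup = int(dup.sum())
    if n_dup:
        log.warning("%s: dropped %d duplicated gene symbol(s), first occurrence kept",
                    path.name, n_dup)
        numeric = numeric.loc[~dup]

    lowered = numeric.index.str.lower()
    if lowered.duplicated().any():
        log.warning("%s: gene symbols differing only by case present", path.name)

    missing = numeric.isna().any(axis=1)
    report = ReadReport(
        n_genes=numeric.shape[0],
        n_samples=numeric.shape[1],
        n_duplicates_dropped=n_dup,
        genes_with_missing=list(numeric.index[missing]),
    )
    numeric.index.name = "gene"
    return numeric, report


def write_expression(expr: pd.DataFrame, path) -> None:
    """Write a genes x samples matrix as TSV (first column = gene symbol)."""
    out = expr.copy()
    out.index.name = "gene"
    out.to_csv(path, sep="\t")


def read_clinical(path) -> pd.DataFrame:
    """Read a clinical TSV; requires sample_id, os_months, os_event columns."""
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in CLINICAL_REQUIRED if c not in df.columns]
    if missing:
        raise ParseError(f"clinical table missing required column(s): {missing}")
    if not df["os_event"].isin((0, 1)).all():
        raise ParseError("os_event must be coded 0/1")
    return df


def write_clinical(clinical: pd.DataFrame, path) -> None:
    clinical.to_csv(path, sep="\t", index=False)


def read_gene_list(path) -> list[str]:
    """One gene symbol per line; blank lines and '#' comments ignored."""
    symbols: list[str] = []
    seen: set[str] = set()
    for raw in Path(path).read_text(encoding="utf-8").splitlines():
        sym = raw.strip()
        if not sym or sym.startswith("#"):
            continue
        if sym.lower() in seen:
            log.warning("duplicate gene symbol in list: %s", sym)
            continue
        seen.add(sym.lower())
        symbols.append(sym)
    return symbols


def read_sample_labels(path) -> pd.Series:
    """Two-column TSV: sample id, label (e.g. tumor type)."""
    df = pd.read_csv(path, sep="\t")
    if df.shape[1] < 2:
        raise ParseError("expected two columns: sample id and label")
    return pd.Series(df.iloc[:, 1].to_numpy(), index=df.iloc[:, 0], name="label")


def write_panel(panel, path) -> None:
    """Write a GenePanel's statistics table with the gene symbol first."""
    table = panel.stats.reset_index()
    if table.columns[0] != "gene":
        table = table.rename(columns={table.columns[0]: "gene"})
    table.to_csv(path, sep="\t", index=False)
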