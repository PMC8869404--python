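"""Readers and writers for the pipeline's text formats.

Feature tables, count matrices and group maps are tab-separated with a
header row and a leading versioned comment line (``# mglia <kind> v1``);
gene sets are read from GMT or from two-column CSV (symbol, direction).
"""

from __future__ import annotations

import csv
from pathlib import Path

import pandas as pd

from .features import ALL_FEATURES
from .gene_sets import GeneSet

FORMAT_VERSION = "v1"


def _write_tsv(df: pd.DataFrame, path: str | Path, kind: str, index: bool = False) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"# mglia {kind} {FORMAT_VERSION}\n")
        df.to_csv(fh, sep="\t", index=index)


def write_feature_table(table: pd.DataFrame, path: str | Path) -> None:
    missing = [f for f in ALL_FEATURES if f not in table.columns]
    if missing:
        raise ValueError(f"feature table lacks columns: {missing}")
    _write_tsv(table, path, "feature-table")


def read_feature_table(path: str | Path) -> pd.DataFrame:
    table = pd.read_csv(path, sep="\t", comment="#")
    missing = [f for f in ALL_FEATURES if f not in table.columns]
    if missing:
        raise ValueError(f"feature table {path} lacks columns: {missing}")
    return table


def write_counts(counts: pd.DataFrame, path: str | Path) -> None:
    _write_tsv(counts.rename_axis("gene"), path, "count-matrix", index=True)


def read_counts(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", index_col=0)


def write_groups(groups: pd.DataFrame | pd.Series, path: str | Path) -> None:
    if isinstance(groups, pd.Series):
        groups = groups.to_frame()
    _write_tsv(groups.rename_axis("sample"), path, "group-map", index=True)


def read_groups(path: str | Path) -> pd.Series:
    df = pd.read_csv(path, sep="\t", comment="#", index_col=0)
    return df.iloc[:, 0]


def write_table(df: pd.DataFrame, path: str | Path, kind: str, index: bool = False) -> None:
    _write_tsv(df, path, kind, index=index)


def read_gene_set(path: str | Path, name: str | None = None) -> list[GeneSet]:
    """Read gene sets from GMT (possibly several, undirected) or from a
    two-column CSV ``symbol,direction`` (one directed set named after the
    file)."""
    path = Path(path)
    text = path.read_text().strip()
    if not text:
        raise ValueError(f"gene set file {path} is empty")
    if path.suffix.lower() == ".gmt":
        sets = []
        for line in text.splitlines():
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                raise ValueError(f"malformed GMT line in {path}: {line!r}")
            sets.append(GeneSet(parts[0], tuple(parts[2:])))
        return sets
    rows = list(csv.reader(text.splitlines()))
    if rows and rows[0][0].strip().lower() in ("symbol", "gene"):
        rows = rows[1:]
    genes, dirs = [], {}
    for row in rows:
        if not row or not row[0].strip():
            continue
        genes.append(row[0].strip())
        if len(row) > 1 and row[1].strip():
            dirs[row[0].strip()] = row[1].strip().lower()
    if not genes:
        raise ValueError(f"gene set file {path} contains no genes")
    return [GeneSet(name or path.stem, tuple(genes), dirs if dirs else None)]
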