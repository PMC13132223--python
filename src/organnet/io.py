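"""Readers and writers for the package's plain-text formats.

Canonical tabular dialect: tab-delimited UTF-8 with '.' decimal separator.
Expression matrices are genes x samples, first column gene ids, header row
sample ids. Nested reports are JSON.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import DataError

# float format used for every TSV we write; fixed so reruns are byte-identical
FLOAT_FORMAT = "%.10g"


def read_expression(path: str | Path) -> pd.DataFrame:
    """Read a log2 expression matrix (genes x samples) from TSV.

    Raises :class:`DataError` on duplicate gene or sample ids, and on any
    non-numeric or missing cell, naming the offending row/column.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    if df.shape[0] == 0 or df.shape[1] == 0:
        raise DataError(f"{path}: empty expression matrix")
    if df.index.duplicated().any():
        dup = df.index[df.index.duplicated()][0]
        raise DataError(f"{path}: duplicated gene id {dup!r}")
    if df.columns.duplicated().any():
        dup = df.columns[df.columns.duplicated()][0]
        raise DataError(f"{path}: duplicated sample id {dup!r}")
    values = np.empty(df.shape, dtype=float)
    for j, col in enumerate(df.columns):
        converted = pd.to_numeric(df[col], errors="coerce")
        bad = np.nonzero(converted.isna().to_numpy())[0]
        if bad.size:
            gene = df.index[bad[0]]
            raise DataError(
                f"{path}: non-numeric or missing value at gene {gene!r}, "
                f"sample {col!r}"
            )
        values[:, j] = converted.to_numpy()
    if not np.isfinite(values).all():
        i, j = np.argwhere(~np.isfinite(values))[0]
        raise DataError(
            f"{path}: non-finite value at gene {df.index[i]!r}, "
            f"sample {df.columns[j]!r}"
        )
    out = pd.DataFrame(values, index=df.index, columns=df.columns)
    out.index.name = "gene_id"
    return out


def write_expression(expr: pd.DataFrame, path: str | Path) -> None:
    expr = expr.copy()
    expr.index.name = "gene_id"
    expr.to_csv(path, sep="\t", float_format=FLOAT_FORMAT)


def read_sample_table(path: str | Path) -> pd.DataFrame:
    """Read a sample annotation table (sample_id, organ, phenotype, label)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"sample_id", "organ", "phenotype", "label"}
    missing = required - set(df.columns)
    if missing:
        raise DataError(f"{path}: missing columns {sorted(missing)}")
    bad = set(df["label"]) - {"normal", "pathological"}
    if bad:
        raise DataError(f"{path}: unknown labels {sorted(bad)}")
    return df


def write_sample_table(samples: pd.DataFrame, path: str | Path) -> None:
    samples.to_csv(path, sep="\t", index=False)


def read_gene_list(path: str | Path) -> list[str]:
    """Read a plain-text gene panel, one gene id per line; '#' comments."""
    genes: list[str] = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            genes.append(line)
    if len(set(genes)) != len(genes):
        raise DataError(f"{path}: duplicate gene ids in panel")
    return genes


def write_edge_list(edges: pd.DataFrame, path: str | Path) -> None:
    edges.to_csv(path, sep="\t", index=False, float_format=FLOAT_FORMAT)


def read_edge_list(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    required = {"gene_a", "gene_b", "rho", "q"}
    if not required <= set(df.columns):
        raise DataError(f"{path}: edge list must have columns {sorted(required)}")
    return df


def write_module_table(assignments: pd.DataFrame, path: str | Path) -> None:
    assignments.to_csv(path, sep="\t", index=False)


def read_module_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str, "organ": str})
    required = {"gene_id", "organ", "module_id"}
    if not required <= set(df.columns):
        raise DataError(f"{path}: module table must have columns {sorted(required)}")
    return df


def write_json(obj, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def read_json(path: str | Path):
    return json.loads(Path(path).read_text())
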