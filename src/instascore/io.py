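"""Readers and writers for the pipeline's plain-text interchange formats.

Expression matrices travel as TSV with genes in rows (first column ``gene``),
sample annotation and follow-up tables as TSV with a ``sample_id`` column,
gene-set signatures as GMT (set name, description, then one gene symbol per
tab-separated field), and fitted score models as JSON.  Every writer/reader
pair round-trips values at full precision (floats are serialized with
``repr``-level precision) and identifiers exactly.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Mapping

import pandas as pd

__all__ = [
    "read_expression",
    "write_expression",
    "read_samples",
    "write_samples",
    "read_followup",
    "write_followup",
    "read_gmt",
    "write_gmt",
]

#: float format guaranteeing exact binary round-trip through decimal text
_FLOAT_FMT = "%.17g"


def read_expression(path: str | Path) -> pd.DataFrame:
    """Read a genes-by-samples log2 expression matrix from TSV.

    The first column must be named ``gene`` and hold unique gene symbols;
    all remaining columns are samples and must be numeric.

    Raises
    ------
    ValueError
        On duplicate gene symbols, duplicate sample ids, or non-numeric
        cells (with the offending coordinates).
    """
    df = pd.read_csv(path, sep="\t", dtype={0: str}, float_precision="round_trip")
    if df.columns[0] != "gene":
        raise ValueError(f"{path}: first column must be 'gene', got {df.columns[0]!r}")
    dup_samples = df.columns[1:][df.columns[1:].duplicated()]
    if len(dup_samples):
        raise ValueError(f"{path}: duplicate sample ids: {sorted(set(dup_samples))}")
    genes = df["gene"]
    dup = genes[genes.duplicated()]
    if len(dup):
        raise ValueError(f"{path}: duplicate gene symbols: {sorted(set(dup))}")
    X = df.set_index("gene")
    for col in X.columns:
        if not pd.api.types.is_numeric_dtype(X[col]):
            bad = X.index[pd.to_numeric(X[col], errors="coerce").isna()][:5]
            raise ValueError(
                f"{path}: non-numeric values in sample column {col!r}, e.g. rows {list(bad)}"
            )
    if X.isna().any().any():
        rows = X.index[X.isna().any(axis=1)][:5]
        raise ValueError(f"{path}: missing values, e.g. in rows {list(rows)}")
    return X


def write_expression(X: pd.DataFrame, path: str | Path) -> None:
    """Write a genes-by-samples matrix as TSV with a leading ``gene`` column."""
    out = X.copy()
    out.index.name = "gene"
    out.to_csv(path, sep="\t", float_format=_FLOAT_FMT)


def read_samples(path: str | Path) -> pd.DataFrame:
    """Read a sample annotation table (``sample_id`` indexed) from TSV."""
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str}, float_precision="round_trip")
    if "sample_id" not in df.columns:
        raise ValueError(f"{path}: missing 'sample_id' column")
    dup = df["sample_id"][df["sample_id"].duplicated()]
    if len(dup):
        raise ValueError(f"{path}: duplicate sample ids: {sorted(set(dup))}")
    return df.set_index("sample_id")


def write_samples(samples: pd.DataFrame, path: str | Path) -> None:
    out = samples.copy()
    out.index.name = "sample_id"
    out.to_csv(path, sep="\t", float_format=_FLOAT_FMT)


def read_followup(path: str | Path) -> pd.DataFrame:
    """Read a clinical follow-up table (delta eGFR, graft loss) from TSV."""
    df = read_samples(path)
    for col in ("delta_egfr", "graft_loss"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing {col!r} column")
    if df["delta_egfr"].isna().any():
        raise ValueError(f"{path}: non-finite delta_egfr values")
    return df


write_followup = write_samples


def read_gmt(path: str | Path) -> dict[str, list[str]]:
    """Read gene-set signatures from a GMT file.

    Each line is ``name<TAB>description<TAB>gene1<TAB>gene2...``; lines with
    fewer than three fields are rejected with their line number.
    """
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(
                    f"{path}:{lineno}: GMT line needs >=3 tab-separated fields, got {len(fields)}"
                )
            name = fields[0]
            if name in sets:
                raise ValueError(f"{path}:{lineno}: duplicate set name {name!r}")
            genes = [g for g in fields[2:] if g]
            if not genes:
                raise ValueError(f"{path}:{lineno}: set {name!r} is empty")
            sets[name] = genes
    if not sets:
        raise ValueError(f"{path}: no gene sets found")
    return sets


def write_gmt(sets: Mapping[str, list[str]], path: str | Path, description: str = "na") -> None:
    with open(path, "w") as fh:
        for name, genes in sets.items():
            fh.write("\t".join([name, description, *genes]) + "\n")


def write_json(obj, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_json(path: str | Path):
    with open(path) as fh:
        return json.load(fh)
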