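"""Readers and writers for the plain-text table formats used throughout.

Evidence tables can be read either in the internal long format
(``peptide_id / protein_id / sample_id / intensity``) or in a minimal
MaxQuant ``evidence.txt`` dialect (``Sequence / Proteins / Raw file /
Intensity``); the column mapping is configurable.
"""
from __future__ import annotations

import hashlib
from pathlib import Path

import pandas as pd

#: default mapping from MaxQuant evidence columns to internal names
MAXQUANT_COLUMNS = {
    "Sequence": "peptide_id",
    "Proteins": "protein_id",
    "Raw file": "sample_id",
    "Intensity": "intensity",
}

INTERNAL_EVIDENCE_COLUMNS = ["peptide_id", "protein_id", "sample_id", "intensity"]


def read_evidence(path, column_map: dict[str, str] | None = None) -> pd.DataFrame:
    """Read an evidence TSV, auto-detecting the MaxQuant dialect."""
    df = pd.read_csv(path, sep="\t")
    if column_map is None:
        if set(INTERNAL_EVIDENCE_COLUMNS).issubset(df.columns):
            column_map = {}
        elif set(MAXQUANT_COLUMNS).issubset(df.columns):
            column_map = MAXQUANT_COLUMNS
        else:
            raise ValueError(
                f"unrecognized evidence columns {list(df.columns)}; "
                "pass an explicit column_map"
            )
    df = df.rename(columns=column_map)
    missing = set(INTERNAL_EVIDENCE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"evidence table lacks columns {sorted(missing)}")
    return df[INTERNAL_EVIDENCE_COLUMNS].copy()


def write_evidence(evidence: pd.DataFrame, path, dialect: str = "maxquant") -> None:
    """Write evidence as TSV, by default in the MaxQuant column dialect."""
    if dialect == "maxquant":
        inv = {v: k for k, v in MAXQUANT_COLUMNS.items()}
        evidence.rename(columns=inv).to_csv(path, sep="\t", index=False)
    elif dialect == "internal":
        evidence.to_csv(path, sep="\t", index=False)
    else:
        raise ValueError(f"unknown evidence dialect {dialect!r}")


def read_design(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    required = {"sample_id", "genotype", "fraction", "replicate"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"design table lacks columns {sorted(missing)}")
    return df


def write_table(df: pd.DataFrame, path, index: bool = False) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=index)


def read_table(path, index_col=None) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=index_col)


def read_lipid_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    if "lipid_id" not in df.columns:
        raise ValueError("lipid table lacks a lipid_id column")
    return df


def read_library(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    required = {"name", "mz", "rt"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"lipid library lacks columns {sorted(missing)}")
    return df


def sha256_file(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()
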