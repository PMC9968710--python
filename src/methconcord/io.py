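"""TSV readers/writers for every artifact the pipeline exchanges.

Dialect is fixed: tab-separated, UTF-8, '.' decimal, ``NA`` for missing,
mandatory header row.  Matrices carry the probe id in the first column
(header ``probe_id``) and one column per subject.
"""

from __future__ import annotations

import os
from typing import Dict, Iterable, Optional

import pandas as pd

NA_REP = "NA"
FLOAT_FMT = "%.10g"

ANNOTATION_COLUMNS = ["probe_id", "chrom", "pos", "snp_distance_bp", "context"]


def write_matrix(df: pd.DataFrame, path: str) -> None:
    """Write a probes x subjects matrix (beta or detection-p)."""
    df.to_csv(path, sep="\t", na_rep=NA_REP, float_format=FLOAT_FMT,
              index_label="probe_id")


def read_matrix(path: str) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col="probe_id", na_values=[NA_REP],
                     keep_default_na=False, dtype=None)
    df.index = df.index.astype(str)
    return df.astype(float)


def write_annotation(annotation: pd.DataFrame, path: str) -> None:
    cols = [c for c in ANNOTATION_COLUMNS if c in annotation.columns]
    annotation.to_csv(path, sep="\t", na_rep=NA_REP, columns=cols, index=False)


def read_annotation(path: str) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", na_values=[NA_REP], keep_default_na=False)
    if "probe_id" not in df.columns:
        raise ValueError(f"annotation file {path} lacks a probe_id column")
    df["probe_id"] = df["probe_id"].astype(str)
    if "snp_distance_bp" in df.columns:
        df["snp_distance_bp"] = pd.to_numeric(df["snp_distance_bp"], errors="coerce")
    return df


def write_proportions(props: Dict[str, pd.DataFrame], path: str) -> None:
    """Long-format proportions: tissue, subject_id, one column per cell type.

    Cell types absent for a tissue are written as NA.
    """
    frames = []
    for tissue, table in props.items():
        frame = table.copy()
        frame.insert(0, "subject_id", frame.index.astype(str))
        frame.insert(0, "tissue", tissue)
        frames.append(frame.reset_index(drop=True))
    combined = pd.concat(frames, ignore_index=True)
    combined.to_csv(path, sep="\t", na_rep=NA_REP, float_format=FLOAT_FMT, index=False)


def read_proportions(path: str) -> Dict[str, pd.DataFrame]:
    df = pd.read_csv(path, sep="\t", na_values=[NA_REP], keep_default_na=False)
    out: Dict[str, pd.DataFrame] = {}
    for tissue, group in df.groupby("tissue", sort=False):
        table = group.set_index(group["subject_id"].astype(str))
        table = table.drop(columns=["tissue", "subject_id"])
        table = table.dropna(axis=1, how="all").astype(float)
        table.index.name = "subject_id"
        out[str(tissue)] = table
    return out


def write_table(df: pd.DataFrame, path: str, index: bool = False) -> None:
    """Generic record table (correlation records, flags, reports...)."""
    df.to_csv(path, sep="\t", na_rep=NA_REP, float_format=FLOAT_FMT, index=index)


def read_table(path: str, **kwargs) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", na_values=[NA_REP], keep_default_na=False,
                       **kwargs)


def read_correlation_table(path: str) -> pd.DataFrame:
    """Read an external per-CpG correlation table.

    Requires columns ``probe_id``, ``tissue_pair``, ``rho``; extra columns
    are carried through untouched.
    """
    df = read_table(path)
    missing = {"probe_id", "tissue_pair", "rho"} - set(df.columns)
    if missing:
        raise ValueError(f"correlation table {path} lacks columns: {sorted(missing)}")
    df["probe_id"] = df["probe_id"].astype(str)
    df["rho"] = pd.to_numeric(df["rho"], errors="coerce")
    return df


def read_probe_list(path: str) -> pd.DataFrame:
    """Probe-id list with an optional p column (e.g. an mQTL list)."""
    df = read_table(path)
    if "probe_id" not in df.columns:
        # headerless single-column fallback
        df = pd.read_csv(path, sep="\t", header=None, names=["probe_id"])
    df["probe_id"] = df["probe_id"].astype(str)
    if "p" in df.columns:
        df["p"] = pd.to_numeric(df["p"], errors="coerce")
    return df


def ensure_dir(path: str) -> str:
    os.makedirs(path, exist_ok=True)
    return path
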