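"""Readers and writers for the pipeline's tabular interchange formats.

Count matrices are TSV files with the gene identifier in the first column
and one column per sample (integer cells).  Sample metadata is a TSV with a
``sample_id`` column, a ``group`` column in {tumor, normal} and optional
label columns used for classifier training.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .errors import FormatError, InvalidInputError

VALID_GROUPS = frozenset({"tumor", "normal"})


def read_counts(path) -> pd.DataFrame:
    """Read a genes x samples count matrix from TSV.

    Returns a DataFrame indexed by gene identifier with one integer column
    per sample.  Duplicate gene or sample identifiers and negative or
    non-integer cells are rejected.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.shape[1] == 0:
        raise FormatError(f"{path}: no sample columns found")
    if df.index.duplicated().any():
        dups = df.index[df.index.duplicated()].unique().tolist()
        raise InvalidInputError(f"duplicate gene identifiers: {dups[:5]}")
    if df.columns.duplicated().any():
        raise InvalidInputError("duplicate sample identifiers")
    try:
        values = df.to_numpy(dtype=np.int64)
    except (ValueError, TypeError) as exc:
        raise InvalidInputError(f"{path}: non-integer count cells") from exc
    if (values < 0).any():
        raise InvalidInputError(f"{path}: negative counts")
    out = pd.DataFrame(values, index=df.index.astype(str), columns=df.columns.astype(str))
    out.index.name = "gene_id"
    return out


def write_counts(df: pd.DataFrame, path) -> None:
    df = df.copy()
    df.index.name = "gene_id"
    df.to_csv(path, sep="\t")


def read_sample_metadata(path) -> pd.DataFrame:
    """Read sample metadata TSV; index sample_id, requires a ``group`` column."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("sample_id", "group"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing required column {col!r}")
    if df["sample_id"].duplicated().any():
        raise InvalidInputError(f"{path}: duplicate sample identifiers")
    bad = set(df["group"]) - VALID_GROUPS
    if bad:
        raise InvalidInputError(f"{path}: invalid group values {sorted(bad)}")
    return df.set_index("sample_id")


def read_patient_counts(path) -> pd.Series:
    """Read a single-sample count TSV (same dialect, exactly one sample column)."""
    df = read_counts(path)
    if df.shape[1] != 1:
        raise FormatError(
            f"{path}: expected exactly one sample column, found {df.shape[1]}"
        )
    series = df.iloc[:, 0]
    series.name = df.columns[0]
    return series
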