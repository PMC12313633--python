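"""Phenotype table I/O with schema validation.

The canonical exchange format is a long CSV with header
``environment,block,genotype,is_check,trait,value`` (UTF-8, "." decimal,
empty value field = missing).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["REQUIRED_COLUMNS", "read_phenotypes", "write_phenotypes"]

REQUIRED_COLUMNS = ["environment", "block", "genotype", "is_check", "trait", "value"]

_TRUE = {"true", "1", "t", "yes"}
_FALSE = {"false", "0", "f", "no"}


def _rows(mask: pd.Series | np.ndarray) -> list[int]:
    # +2: header line plus 1-based numbering
    return (np.flatnonzero(np.asarray(mask)) + 2).tolist()


def read_phenotypes(path) -> pd.DataFrame:
    """Read and validate a plot-level phenotype CSV.

    Raises ValueError (with file row numbers) on missing columns, duplicate
    (environment, block, genotype, trait) rows, non-integer blocks or
    non-numeric values.  Missing values stay as NaN.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"missing required column(s): {missing}")
    df = df[REQUIRED_COLUMNS].copy()

    block = pd.to_numeric(df["block"], errors="coerce")
    bad = block.isna() | (block != block.round())
    if bad.any():
        raise ValueError(f"non-integer block values at row(s) {_rows(bad)}")
    df["block"] = block.astype(int)

    flags = df["is_check"].str.strip().str.lower()
    bad = ~flags.isin(_TRUE | _FALSE)
    if bad.any():
        raise ValueError(f"unparseable is_check values at row(s) {_rows(bad)}")
    df["is_check"] = flags.isin(_TRUE)

    raw = df["value"].str.strip()
    value = pd.to_numeric(raw.replace({"": None, "NA": None, "NaN": None}), errors="coerce")
    bad = value.isna() & ~raw.isin(["", "NA", "NaN", "nan"])
    if bad.any():
        raise ValueError(f"non-numeric value entries at row(s) {_rows(bad)}")
    df["value"] = value.astype(float)

    dup = df.duplicated(subset=["environment", "block", "genotype", "trait"], keep=False)
    if dup.any():
        raise ValueError(
            f"duplicate (environment, block, genotype, trait) rows at row(s) {_rows(dup)}"
        )
    return df


def write_phenotypes(records: pd.DataFrame, path) -> None:
    """Write records in the canonical column order (round-trips with
    :func:`read_phenotypes`)."""
    missing = [c for c in REQUIRED_COLUMNS if c not in records.columns]
    if missing:
        raise ValueError(f"records missing column(s): {missing}")
    records[REQUIRED_COLUMNS].to_csv(path, index=False)
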