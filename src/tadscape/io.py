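"""Readers and writers for the plain-text formats the pipeline exchanges.

Dialects:

* BED — tab-separated, 0-based half-open; optional name/score/strand columns.
* COO — ``chrom  bin1  bin2  count`` with 0-based bin indices; written in
  upper-triangle order, duplicates merged (summed) on read with a warning.
* count tables — tidy TSV with header
  ``site_id  chrom  start  end  condition  replicate  count``.

Parsers reject malformed rows with the file name and 1-based line number
rather than coercing them.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .intervals import validate_intervals


class ParseError(ValueError):
    """Malformed input row; message carries file and line number."""


def _fail(path, lineno, msg):
    raise ParseError(f"{path}:{lineno}: {msg}")


BED_EXTRA = ["name", "score", "strand"]


def read_bed(path) -> pd.DataFrame:
    """Read BED3-BED6 into a DataFrame (chrom, start, end[, name, score, strand])."""
    path = Path(path)
    rows = []
    ncols = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                _fail(path, lineno, f"expected >=3 tab-separated fields, got {len(parts)}")
            if ncols is None:
                ncols = len(parts)
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError:
                _fail(path, lineno, f"non-integer coordinates {parts[1]!r}/{parts[2]!r}")
            if end <= start:
                _fail(path, lineno, f"end {end} <= start {start}")
            if start < 0:
                _fail(path, lineno, f"negative start {start}")
            rows.append([parts[0], start, end] + parts[3:6])
    cols = ["chrom", "start", "end"] + BED_EXTRA[: (ncols or 3) - 3]
    df = pd.DataFrame(rows, columns=cols)
    df["start"] = df["start"].astype(np.int64)
    df["end"] = df["end"].astype(np.int64)
    if "score" in df.columns:
        df["score"] = pd.to_numeric(df["score"], errors="coerce")
    return df


def write_bed(df: pd.DataFrame, path) -> None:
    validate_intervals(df)
    cols = ["chrom", "start", "end"] + [c for c in BED_EXTRA if c in df.columns]
    df[cols].to_csv(path, sep="\t", header=False, index=False)


def read_coo(path) -> pd.DataFrame:
    """Read contact triples; (j,i)/(i,j) duplicates are summed with a warning."""
    path = Path(path)
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) != 4:
                _fail(path, lineno, f"expected 4 fields (chrom bin1 bin2 count), got {len(parts)}")
            try:
                b1, b2, count = int(parts[1]), int(parts[2]), float(parts[3])
            except ValueError:
                _fail(path, lineno, "non-numeric bin index or count")
            if b1 < 0 or b2 < 0:
                _fail(path, lineno, "negative bin index")
            if count < 0:
                _fail(path, lineno, f"negative count {count}")
            lo, hi = (b1, b2) if b1 <= b2 else (b2, b1)
            rows.append((parts[0], lo, hi, count))
    df = pd.DataFrame(rows, columns=["chrom", "bin1", "bin2", "count"])
    dup = df.duplicated(subset=["chrom", "bin1", "bin2"], keep=False)
    if dup.any():
        warnings.warn(f"{path}: {int(dup.sum())} duplicate bin pairs merged by summation")
        df = df.groupby(["chrom", "bin1", "bin2"], as_index=False)["count"].sum()
    return df.sort_values(["chrom", "bin1", "bin2"]).reset_index(drop=True)


def write_coo(df: pd.DataFrame, path) -> None:
    """Write contact triples in strict upper-triangle (bin1 <= bin2) order."""
    out = df.copy()
    b1 = np.minimum(out["bin1"], out["bin2"])
    b2 = np.maximum(out["bin1"], out["bin2"])
    out["bin1"], out["bin2"] = b1, b2
    out = out.groupby(["chrom", "bin1", "bin2"], as_index=False)["count"].sum()
    out = out.sort_values(["chrom", "bin1", "bin2"])
    out.to_csv(path, sep="\t", header=False, index=False)


COUNT_COLS = ["site_id", "chrom", "start", "end", "condition", "replicate", "count"]


def read_counts(path) -> pd.DataFrame:
    path = Path(path)
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in COUNT_COLS if c not in df.columns]
    if missing:
        raise ParseError(f"{path}:1: missing columns {missing}")
    if (df["count"] < 0).any():
        lineno = int(df.index[df["count"] < 0][0]) + 2  # header + 1-based
        _fail(path, lineno, "negative count")
    if (df["end"] <= df["start"]).any():
        lineno = int(df.index[df["end"] <= df["start"]][0]) + 2
        _fail(path, lineno, "end <= start")
    return df


def write_counts(df: pd.DataFrame, path) -> None:
    df[COUNT_COLS].to_csv(path, sep="\t", index=False)
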