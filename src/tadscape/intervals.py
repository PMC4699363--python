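"""Genomic interval primitives.

All coordinates are 0-based half-open [start, end). Interval tables are
pandas DataFrames with at least ``chrom``, ``start``, ``end`` columns;
functions here never mutate their inputs.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

INTERVAL_COLS = ["chrom", "start", "end"]


def validate_intervals(df: pd.DataFrame, name: str = "intervals") -> pd.DataFrame:
    """Check interval-table schema and coordinate sanity; return the input."""
    for col in INTERVAL_COLS:
        if col not in df.columns:
            raise ValueError(f"{name}: missing column {col!r}")
    if len(df) and (df["end"] <= df["start"]).any():
        bad = df.index[(df["end"] <= df["start"])][0]
        raise ValueError(f"{name}: empty or inverted interval at row {bad}")
    if len(df) and (df["start"] < 0).any():
        raise ValueError(f"{name}: negative start coordinate")
    return df


def midpoints(df: pd.DataFrame) -> np.ndarray:
    """Integer midpoint of each interval (floor of the mean)."""
    return ((df["start"].to_numpy() + df["end"].to_numpy()) // 2).astype(np.int64)


def merge_intervals(df: pd.DataFrame) -> pd.DataFrame:
    """Union of intervals: sorted, overlap-free per chromosome.

    Touching intervals ([0,5) and [5,9)) are kept separate; only true
    overlaps are merged, so membership semantics (>=1 bp) are preserved.
    """
    validate_intervals(df)
    out = []
    for chrom, grp in df.sort_values(["chrom", "start", "end"]).groupby("chrom", sort=True):
        starts = grp["start"].to_numpy()
        ends = grp["end"].to_numpy()
        cur_s, cur_e = starts[0], ends[0]
        for s, e in zip(starts[1:], ends[1:]):
            if s < cur_e:  # strict overlap
                cur_e = max(cur_e, e)
            else:
                out.append((chrom, cur_s, cur_e))
                cur_s, cur_e = s, e
        out.append((chrom, cur_s, cur_e))
    return pd.DataFrame(out, columns=INTERVAL_COLS)


def _per_chrom_sorted(df: pd.DataFrame) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    out = {}
    for chrom, grp in df.groupby("chrom", sort=False):
        grp = grp.sort_values("start")
        out[chrom] = (grp["start"].to_numpy(np.int64), grp["end"].to_numpy(np.int64))
    return out


def assign_points(points_chrom: np.ndarray, points_pos: np.ndarray,
                  subjects: pd.DataFrame) -> np.ndarray:
    """Index of the subject interval containing each point, -1 if none.

    Subjects must be non-overlapping within a chromosome (merge first if
    unsure). Containment follows the half-open convention: a point on a
    subject's start is inside, on its end is outside.
    """
    validate_intervals(subjects, "subjects")
    sub = subjects.reset_index(drop=True)
    order = {}
    for chrom, grp in sub.groupby("chrom", sort=False):
        grp = grp.sort_values("start")
        order[chrom] = (grp["start"].to_numpy(np.int64),
                        grp["end"].to_numpy(np.int64),
                        grp.index.to_numpy())
    result = np.full(len(points_pos), -1, dtype=np.int64)
    pc = np.asarray(points_chrom)
    pp = np.asarray(points_pos, dtype=np.int64)
    for chrom, (starts, ends, idx) in order.items():
        m = pc == chrom
        if not m.any():
            continue
        pos = pp[m]
        i = np.searchsorted(starts, pos, side="right") - 1
        inside = (i >= 0) & (pos < ends[np.clip(i, 0, None)])
        res = np.full(pos.shape, -1, dtype=np.int64)
        res[inside] = idx[i[inside]]
        result[m] = res
    return result


def overlaps_any(query: pd.DataFrame, subjects: pd.DataFrame) -> np.ndarray:
    """Boolean per query interval: does it overlap >=1 bp of any subject?"""
    validate_intervals(query, "query")
    merged = merge_intervals(subjects) if len(subjects) else subjects
    per_chrom = _per_chrom_sorted(merged) if len(merged) else {}
    hit = np.zeros(len(query), dtype=bool)
    qc = query["chrom"].to_numpy()
    qs = query["start"].to_numpy(np.int64)
    qe = query["end"].to_numpy(np.int64)
    for chrom, (starts, ends) in per_chrom.items():
        m = qc == chrom
        if not m.any():
            continue
        # rightmost subject starting before the query end
        i = np.searchsorted(starts, qe[m], side="left") - 1
        ok = (i >= 0) & (ends[np.clip(i, 0, None)] > qs[m])
        hit[m] = ok
    return hit
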