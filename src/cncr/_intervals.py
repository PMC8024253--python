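"""Shared half-open interval helpers (pyranges-backed).

All coordinates are 0-based half-open. DataFrames use the columns
``chrom``, ``start``, ``end``; conversion to pyranges' column naming is
internal to this module.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pyranges as pr

INTERVAL_COLS = ["chrom", "start", "end"]


def _to_pyranges(df: pd.DataFrame, extra_cols: list[str] | None = None) -> pr.PyRanges:
    cols = {"Chromosome": df["chrom"], "Start": df["start"], "End": df["end"]}
    for c in extra_cols or []:
        cols[c] = df[c]
    return pr.PyRanges(pd.DataFrame(cols))


def _from_pyranges(g: pr.PyRanges) -> pd.DataFrame:
    df = g.df
    if df.empty:
        return empty_intervals()
    out = df.rename(columns={"Chromosome": "chrom", "Start": "start", "End": "end"})
    out["chrom"] = out["chrom"].astype(str)
    return out.reset_index(drop=True)


def empty_intervals() -> pd.DataFrame:
    return pd.DataFrame({"chrom": pd.Series(dtype=str),
                         "start": pd.Series(dtype=np.int64),
                         "end": pd.Series(dtype=np.int64)})


def merge_intervals(df: pd.DataFrame, chrom_order: list[str] | None = None) -> pd.DataFrame:
    """Union of possibly overlapping intervals, sorted deterministically."""
    if len(df) == 0:
        return empty_intervals()
    merged = _from_pyranges(_to_pyranges(df).merge())
    return sort_intervals(merged, chrom_order)


def sort_intervals(df: pd.DataFrame, chrom_order: list[str] | None = None) -> pd.DataFrame:
    if len(df) == 0:
        return df.reset_index(drop=True)
    if chrom_order is None:
        key = df["chrom"]
    else:
        rank = {c: i for i, c in enumerate(chrom_order)}
        key = df["chrom"].map(rank)
        if key.isna().any():
            bad = sorted(df.loc[key.isna(), "chrom"].unique())
            raise ValueError(f"intervals on chromosomes not in layout: {bad}")
    order = np.lexsort((df["start"].to_numpy(), key.to_numpy()))
    return df.iloc[order].reset_index(drop=True)


def flag_overlaps(query: pd.DataFrame, subject: pd.DataFrame) -> np.ndarray:
    """Boolean array: does each query interval overlap the subject set by >=1 bp?"""
    flags = np.zeros(len(query), dtype=bool)
    if len(query) == 0 or len(subject) == 0:
        return flags
    q = query[INTERVAL_COLS].copy()
    q["_idx"] = np.arange(len(q))
    hit = _to_pyranges(q, ["_idx"]).overlap(_to_pyranges(subject))
    if len(hit) > 0:
        flags[hit.df["_idx"].to_numpy()] = True
    return flags


def overlap_bp(query: pd.DataFrame, subject: pd.DataFrame, by: str) -> pd.Series:
    """Total bp of intersection between each query interval (keyed by column
    `by`) and the union of the subject set. Subject is merged internally so
    overlapping subject intervals are not double counted."""
    out = pd.Series(0, index=query[by], dtype=np.int64)
    if len(query) == 0 or len(subject) == 0:
        return out
    merged = merge_intervals(subject)
    pieces = _to_pyranges(query, [by]).intersect(_to_pyranges(merged))
    if len(pieces) > 0:
        df = pieces.df
        lengths = (df["End"] - df["Start"]).groupby(df[by]).sum()
        out.loc[lengths.index] += lengths
    return out


def points_in_intervals(chroms: np.ndarray, pos: np.ndarray, intervals: pd.DataFrame) -> np.ndarray:
    """Membership of 0-based points in a merged, disjoint interval set."""
    flags = np.zeros(len(pos), dtype=bool)
    if len(intervals) == 0 or len(pos) == 0:
        return flags
    for chrom, sub in intervals.groupby("chrom", sort=False):
        sel = chroms == chrom
        if not sel.any():
            continue
        starts = np.sort(sub["start"].to_numpy())
        ends = np.sort(sub["end"].to_numpy())
        p = pos[sel]
        i = np.searchsorted(starts, p, side="right")
        inside = (i > 0) & (p < ends[np.clip(i - 1, 0, None)])
        flags[np.flatnonzero(sel)] = inside
    return flags


def merge_adjacent_bins(chroms: np.ndarray, starts: np.ndarray, ends: np.ndarray,
                        chrom_order: list[str]) -> pd.DataFrame:
    """Merge a set of bins into maximal intervals, joining bins only when they
    abut exactly (end == next start on the same chromosome)."""
    if len(starts) == 0:
        return empty_intervals()
    rank = {c: i for i, c in enumerate(chrom_order)}
    key = np.array([rank[c] for c in chroms])
    order = np.lexsort((starts, key))
    c, s, e = chroms[order], starts[order], ends[order]
    new_run = np.ones(len(s), dtype=bool)
    new_run[1:] = (c[1:] != c[:-1]) | (s[1:] != e[:-1])
    run_id = np.cumsum(new_run) - 1
    first = np.flatnonzero(new_run)
    out_start = s[first]
    out_end = np.full(first.shape, -1, dtype=e.dtype)
    np.maximum.at(out_end, run_id, e)
    return pd.DataFrame({"chrom": c[first], "start": out_start, "end": out_end})
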