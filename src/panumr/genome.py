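"""Genomic interval arithmetic on sorted numpy arrays.

All coordinates in this package are 0-based half-open. Interval tables are
pandas DataFrames with at least ``chrom``, ``start`` and ``end`` columns.
The helpers here assume nothing about overlap unless stated.
"""

from __future__ import annotations

from typing import Mapping

import numpy as np
import pandas as pd

INTERVAL_COLS = ["chrom", "start", "end"]


def tile_bins(chrom_sizes: Mapping[str, int], bin_size: int = 100) -> pd.DataFrame:
    """Tile each chromosome with fixed-size bins anchored at 0.

    The final bin of a chromosome may be ragged (shorter than ``bin_size``).
    """
    frames = []
    for chrom, size in chrom_sizes.items():
        starts = np.arange(0, size, bin_size, dtype=np.int64)
        ends = np.minimum(starts + bin_size, size)
        frames.append(pd.DataFrame({"chrom": chrom, "start": starts, "end": ends}))
    if not frames:
        return pd.DataFrame(columns=INTERVAL_COLS)
    return pd.concat(frames, ignore_index=True)


def sort_intervals(df: pd.DataFrame) -> pd.DataFrame:
    return df.sort_values(["chrom", "start", "end"], kind="mergesort").reset_index(drop=True)


def merge_intervals(df: pd.DataFrame, max_gap: int = 0) -> pd.DataFrame:
    """Union of intervals, joining neighbours separated by <= max_gap bp."""
    if df.empty:
        return df[INTERVAL_COLS].copy()
    out = []
    for chrom, grp in sort_intervals(df).groupby("chrom", sort=True):
        starts = grp["start"].to_numpy()
        ends = grp["end"].to_numpy()
        cur_s, cur_e = starts[0], ends[0]
        for s, e in zip(starts[1:], ends[1:]):
            if s - cur_e <= max_gap:
                cur_e = max(cur_e, e)
            else:
                out.append((chrom, cur_s, cur_e))
                cur_s, cur_e = s, e
        out.append((chrom, cur_s, cur_e))
    return pd.DataFrame(out, columns=INTERVAL_COLS)


def subtract_intervals(df: pd.DataFrame, blacklist: pd.DataFrame) -> pd.DataFrame:
    """Remove blacklist bp from each interval, keeping leftover pieces."""
    if df.empty or blacklist is None or blacklist.empty:
        return df.copy()
    bl = merge_intervals(blacklist)
    pieces = []
    for _, row in df.iterrows():
        cuts = bl[(bl["chrom"] == row["chrom"])
                  & (bl["start"] < row["end"]) & (bl["end"] > row["start"])]
        pos = row["start"]
        extra = {k: row[k] for k in df.columns if k not in INTERVAL_COLS}
        for _, c in cuts.sort_values("start").iterrows():
            if c["start"] > pos:
                pieces.append({"chrom": row["chrom"], "start": pos, "end": c["start"], **extra})
            pos = max(pos, c["end"])
        if pos < row["end"]:
            pieces.append({"chrom": row["chrom"], "start": pos, "end": row["end"], **extra})
    return pd.DataFrame(pieces, columns=list(df.columns))


def _per_chrom_subject(subject: pd.DataFrame):
    """Precompute per-chromosome sorted starts and running-max ends."""
    index = {}
    for chrom, grp in subject.groupby("chrom", sort=False):
        grp = grp.sort_values("start")
        starts = grp["start"].to_numpy(dtype=np.int64)
        ends = grp["end"].to_numpy(dtype=np.int64)
        index[chrom] = (starts, np.maximum.accumulate(ends), ends)
    return index


def overlaps_any(query: pd.DataFrame, subject: pd.DataFrame) -> np.ndarray:
    """Boolean per query row: does it overlap any subject interval (>=1 bp)?

    Subject intervals may overlap each other (e.g. gene annotations).
    """
    result = np.zeros(len(query), dtype=bool)
    if query.empty or subject.empty:
        return result
    index = _per_chrom_subject(subject)
    chroms = query["chrom"].to_numpy()
    for chrom in pd.unique(chroms):
        if chrom not in index:
            continue
        pos = np.flatnonzero(chroms == chrom)
        starts, cummax_ends, _ = index[chrom]
        qs = query["start"].to_numpy(dtype=np.int64)[pos]
        qe = query["end"].to_numpy(dtype=np.int64)[pos]
        # candidate: last subject with start < query end
        idx = np.searchsorted(starts, qe, side="left")
        hit = (idx > 0) & (np.where(idx > 0, cummax_ends[np.maximum(idx - 1, 0)], 0) > qs)
        result[pos] = hit
    return result


def gap_to_nearest(query: pd.DataFrame, subject: pd.DataFrame) -> np.ndarray:
    """Distance in bp from each query interval to the nearest subject interval.

    0 when they overlap or abut; ``np.inf`` when the subject set is empty on
    that chromosome. Distance between [a,b) and a downstream [c,d) is c - b.
    """
    result = np.full(len(query), np.inf)
    if query.empty or subject.empty:
        return result
    chroms = query["chrom"].to_numpy()
    for chrom in pd.unique(chroms):
        sub = subject[subject["chrom"] == chrom]
        if sub.empty:
            continue
        pos = np.flatnonzero(chroms == chrom)
        sub_starts = np.sort(sub["start"].to_numpy(dtype=np.int64))
        sub_ends = np.sort(sub["end"].to_numpy(dtype=np.int64))
        qs = query["start"].to_numpy(dtype=np.int64)[pos]
        qe = query["end"].to_numpy(dtype=np.int64)[pos]
        ov = overlaps_any(query.iloc[pos][INTERVAL_COLS], sub)
        # nearest subject start at/after query end
        i = np.searchsorted(sub_starts, qe, side="left")
        right = np.where(i < len(sub_starts), sub_starts[np.minimum(i, len(sub_starts) - 1)] - qe, np.inf)
        # nearest subject end at/before query start
        j = np.searchsorted(sub_ends, qs, side="right")
        left = np.where(j > 0, qs - sub_ends[np.maximum(j - 1, 0)], np.inf)
        d = np.minimum(np.maximum(right, 0), np.maximum(left, 0))
        d[ov] = 0
        result[pos] = d
    return result


def interval_bp(df: pd.DataFrame) -> int:
    if df.empty:
        return 0
    return int((df["end"] - df["start"]).sum())


def validate_tiling(track: pd.DataFrame, bin_size: int = 100) -> None:
    """Hard-error when bins are unsorted, overlapping, or off-grid."""
    for chrom, grp in track.groupby("chrom", sort=False):
        starts = grp["start"].to_numpy()
        ends = grp["end"].to_numpy()
        if np.any(np.diff(starts) <= 0):
            raise ValueError(f"{chrom}: bins are not sorted/unique by start")
        if np.any(starts[1:] < ends[:-1]):
            raise ValueError(f"{chrom}: bins overlap")
        if np.any(starts % bin_size != 0):
            raise ValueError(f"{chrom}: bin starts are not multiples of {bin_size}")
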