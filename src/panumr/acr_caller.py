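"""Post-process candidate accessible regions into high-confidence ACRs.

Candidate regions (e.g. MACS2 peaks) are split into 50-bp windows with
25-bp steps; per-window Tn5 integration frequency is normalised to the
genome-average per-bp insertion rate; windows above a fold threshold are
merged (tolerating 150-bp gaps); merged regions must exceed 50 bp; an
optional blacklist (organelle-homologous intervals) is subtracted. The
position of maximal windowed insertion frequency within each ACR is its
summit.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .config import ThresholdConfig
from .genome import overlaps_any, sort_intervals, subtract_intervals

ACR_COLUMNS = ["chrom", "start", "end", "max_norm_freq", "summit", "summit_flagged"]


def _insertion_index(insertions: pd.DataFrame) -> dict[str, np.ndarray]:
    return {
        chrom: np.sort(grp["pos"].to_numpy(dtype=np.int64))
        for chrom, grp in insertions.groupby("chrom", sort=False)
    }


def window_normalized_frequency(
    insertions: pd.DataFrame,
    candidate_regions: pd.DataFrame,
    genome_bp: int,
    win: int = 50,
    step: int = 25,
) -> pd.DataFrame:
    """Per-window Tn5 insertion counts, normalised to the genome average.

    ``normalized = (count / window_len) / (total_insertions / genome_bp)``.
    Windows tile each candidate region from its start; the last window is
    clipped to the region end. Duplicate windows arising from overlapping
    candidate regions are collapsed.
    """
    if genome_bp <= 0:
        raise ValueError("genome_bp must be positive")
    total = len(insertions)
    if total == 0:
        raise ValueError("no Tn5 insertions genome-wide: normalization undefined")
    rate = total / genome_bp

    index = _insertion_index(insertions)
    frames = []
    for _, region in sort_intervals(candidate_regions).iterrows():
        starts = np.arange(region["start"], region["end"], step, dtype=np.int64)
        ends = np.minimum(starts + win, region["end"])
        pos = index.get(region["chrom"], np.empty(0, dtype=np.int64))
        counts = np.searchsorted(pos, ends) - np.searchsorted(pos, starts)
        frames.append(
            pd.DataFrame(
                {
                    "chrom": region["chrom"],
                    "start": starts,
                    "end": ends,
                    "count": counts,
                    "norm": (counts / (ends - starts)) / rate,
                }
            )
        )
    if not frames:
        return pd.DataFrame(columns=["chrom", "start", "end", "count", "norm"])
    out = pd.concat(frames, ignore_index=True)
    out = out.drop_duplicates(["chrom", "start", "end"])
    return sort_intervals(out)


def merge_acr_windows(
    windows: pd.DataFrame,
    thr: float = 25.0,
    max_gap: int = 150,
    min_len: int = 50,
    blacklist: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Merge qualifying windows (norm > thr) into ACR intervals.

    Successive qualifying windows join one region while the gap between
    their edges is <= ``max_gap``; regions with span <= ``min_len`` are
    dropped; blacklist intervals are removed by subtraction (pieces are
    re-checked against ``min_len``).
    """
    qual = sort_intervals(windows[windows["norm"] > thr])
    records = []
    for chrom, grp in qual.groupby("chrom", sort=True):
        starts = grp["start"].to_numpy()
        ends = grp["end"].to_numpy()
        norms = grp["norm"].to_numpy()
        cur_s, cur_e, cur_m = starts[0], ends[0], norms[0]
        for s, e, m in zip(starts[1:], ends[1:], norms[1:]):
            if s - cur_e <= max_gap:
                cur_e = max(cur_e, e)
                cur_m = max(cur_m, m)
            else:
                records.append((chrom, cur_s, cur_e, cur_m))
                cur_s, cur_e, cur_m = s, e, m
        records.append((chrom, cur_s, cur_e, cur_m))
    acrs = pd.DataFrame(records, columns=["chrom", "start", "end", "max_norm_freq"])
    acrs = acrs[(acrs["end"] - acrs["start"]) > min_len]
    if blacklist is not None and not blacklist.empty:
        acrs = subtract_intervals(acrs, blacklist)
        acrs = acrs[(acrs["end"] - acrs["start"]) > min_len]
    return acrs.reset_index(drop=True)


def find_summit(
    chrom: str,
    start: int,
    end: int,
    insertions: pd.DataFrame,
    win: int = 50,
    step: int = 25,
) -> tuple[int, bool]:
    """Summit of one ACR: midpoint of the window with the most insertions.

    Ties resolve to the leftmost window. An ACR containing zero insertions
    gets its interval midpoint, flagged.
    """
    pos = np.sort(
        insertions.loc[insertions["chrom"] == chrom, "pos"].to_numpy(dtype=np.int64)
    )
    starts = np.arange(start, end, step, dtype=np.int64)
    ends = np.minimum(starts + win, end)
    counts = np.searchsorted(pos, ends) - np.searchsorted(pos, starts)
    if counts.max(initial=0) == 0:
        return int((start + end) // 2), True
    best = int(np.argmax(counts))  # argmax returns the leftmost maximum
    return int((starts[best] + ends[best]) // 2), False


def add_summits(
    acrs: pd.DataFrame,
    insertions: pd.DataFrame,
    win: int = 50,
    step: int = 25,
) -> pd.DataFrame:
    out = acrs.copy()
    summits, flags = [], []
    for _, row in acrs.iterrows():
        s, f = find_summit(row["chrom"], row["start"], row["end"], insertions, win, step)
        summits.append(s)
        flags.append(f)
    out["summit"] = pd.Series(summits, index=acrs.index, dtype=np.int64)
    out["summit_flagged"] = pd.Series(flags, index=acrs.index, dtype=bool)
    return out


def call_acrs(
    insertions: pd.DataFrame,
    candidate_regions: pd.DataFrame,
    genome_bp: int,
    cfg: ThresholdConfig | None = None,
    blacklist: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Full ACR post-processing: windows -> merge -> blacklist -> summits."""
    cfg = cfg or ThresholdConfig()
    windows = window_normalized_frequency(
        insertions, candidate_regions, genome_bp, cfg.acr_window, cfg.acr_step
    )
    acrs = merge_acr_windows(
        windows, cfg.acr_fold, cfg.acr_max_gap, cfg.acr_min_len, blacklist
    )
    return add_summits(acrs, insertions, cfg.acr_window, cfg.acr_step)


def classify_umr_accessibility(umrs: pd.DataFrame, acrs: pd.DataFrame) -> pd.DataFrame:
    """Label UMRs as aUMR (>=1 bp ACR overlap) or iUMR.

    Also reports, per UMR, whether any overlapping ACR is fully contained
    within the UMR interval.
    """
    out = umrs.copy()
    if umrs.empty:
        out["accessibility"] = pd.Series(dtype=object)
        out["acr_contained"] = pd.Series(dtype=bool)
        return out
    if acrs is None or acrs.empty:
        out["accessibility"] = "iUMR"
        out["acr_contained"] = False
        return out
    hit = overlaps_any(umrs, acrs)
    contained = np.zeros(len(umrs), dtype=bool)
    for chrom, grp in umrs.groupby("chrom", sort=False):
        sub = acrs[acrs["chrom"] == chrom]
        if sub.empty:
            continue
        for idx, row in grp.iterrows():
            inside = (sub["start"] >= row["start"]) & (sub["end"] <= row["end"])
            overlap = (sub["start"] < row["end"]) & (sub["end"] > row["start"])
            contained[umrs.index.get_loc(idx)] = bool((inside & overlap).any())
    out["accessibility"] = np.where(hit, "aUMR", "iUMR")
    out["acr_contained"] = contained
    return out


def acr_bp_in_umrs(acrs: pd.DataFrame, umrs: pd.DataFrame) -> float:
    """Fraction of total ACR bp falling inside UMR intervals."""
    total = int((acrs["end"] - acrs["start"]).sum()) if not acrs.empty else 0
    if total == 0:
        return float("nan")
    outside = subtract_intervals(acrs, umrs)
    out_bp = int((outside["end"] - outside["start"]).sum()) if not outside.empty else 0
    return 1.0 - out_bp / total
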