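"""Identify identical-by-state (IBS) megabase blocks from SNP density.

SNP density per 1-Mb window is the SNP count divided by the number of
syntenic-alignment bp in the window; maximal runs of consecutive windows
with density strictly below 0.0005 that span at least 5 Mb are IBS regions.
Windows without any syntenic alignment have undefined density and terminate
runs — absence of alignment is not evidence of identity.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .crossmap import SyntenyMap

WINDOW_COLS = ["chrom", "start", "end", "n_snps", "syntenic_bp", "density", "defined"]
IBS_COLS = ["chrom", "start", "end", "span", "n_snps", "syntenic_bp", "density"]


def snp_density_windows(
    snps: pd.DataFrame,
    synteny: SyntenyMap,
    chrom_sizes: dict[str, int],
    win: int = 1_000_000,
) -> pd.DataFrame:
    """Per-window SNP density over syntenic bp on the source genome.

    ``snps`` needs columns chrom, pos. Windows with zero syntenic bp get
    density NaN and defined=False.
    """
    seg = synteny.segments
    frames = []
    for chrom, size in chrom_sizes.items():
        starts = np.arange(0, size, win, dtype=np.int64)
        ends = np.minimum(starts + win, size)
        sub = seg[seg["src_chrom"] == chrom]
        syn = np.zeros(len(starts), dtype=np.int64)
        if not sub.empty:
            ss = sub["src_start"].to_numpy()
            se = sub["src_end"].to_numpy()
            for i, (ws, we) in enumerate(zip(starts, ends)):
                syn[i] = np.maximum(
                    0, np.minimum(se, we) - np.maximum(ss, ws)
                ).sum()
        pos = np.sort(snps.loc[snps["chrom"] == chrom, "pos"].to_numpy(dtype=np.int64))
        counts = np.searchsorted(pos, ends) - np.searchsorted(pos, starts)
        with np.errstate(invalid="ignore", divide="ignore"):
            density = np.where(syn > 0, counts / np.maximum(syn, 1), np.nan)
        frames.append(
            pd.DataFrame(
                {
                    "chrom": chrom, "start": starts, "end": ends,
                    "n_snps": counts, "syntenic_bp": syn,
                    "density": density, "defined": syn > 0,
                }
            )
        )
    if not frames:
        return pd.DataFrame(columns=WINDOW_COLS)
    return pd.concat(frames, ignore_index=True)


def call_ibs(
    windows: pd.DataFrame,
    max_density: float = 0.0005,
    min_span: int = 5_000_000,
) -> pd.DataFrame:
    """Maximal runs of consecutive windows with density strictly below the
    threshold; runs spanning >= min_span are emitted as IBS regions."""
    records = []
    for chrom, grp in windows.groupby("chrom", sort=True):
        grp = grp.sort_values("start")
        qual = (grp["defined"] & (grp["density"] < max_density)).to_numpy()
        starts = grp["start"].to_numpy()
        ends = grp["end"].to_numpy()
        n_snps = grp["n_snps"].to_numpy()
        syn = grp["syntenic_bp"].to_numpy()
        i = 0
        n = len(grp)
        while i < n:
            if not qual[i]:
                i += 1
                continue
            j = i
            while j < n and qual[j]:
                j += 1
            span = int(ends[j - 1] - starts[i])
            if span >= min_span:
                tot_snps = int(n_snps[i:j].sum())
                tot_syn = int(syn[i:j].sum())
                records.append(
                    (chrom, int(starts[i]), int(ends[j - 1]), span, tot_snps,
                     tot_syn, tot_snps / tot_syn)
                )
            i = j
    return pd.DataFrame(records, columns=IBS_COLS)
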