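"""Call differentially methylated 100-bp tiles (DMTs) between two genotypes.

The definition is purely threshold-based, per sequence context:

* CG / CHG: |level_A - level_B| >= 0.40 AND min(A, B) < 0.10 AND
  max(A, B) > 0.40
* CHH: min(A, B) < 0.05 AND max(A, B) > 0.25 (no explicit difference
  clause; the two bounds already force a gap > 0.20)

Calls are restricted to tiles in shared space with adequate coverage in
both genotypes; direction names the hypomethylated genotype.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .config import CONTEXTS, SHARED_STATUSES, ThresholdConfig

DMT_COLS = ["chrom", "start", "end", "context", "level_a", "level_b", "direction"]


def call_dmt(
    level_a: float,
    level_b: float,
    context: str,
    coverage_ok_a: bool = True,
    coverage_ok_b: bool = True,
    mapping_status: str = "shared_exact",
    cfg: ThresholdConfig | None = None,
) -> str | None:
    """Evaluate the DMT predicate for one tile.

    Returns 'hypo_in_A', 'hypo_in_B' or None (no call). Tiles outside
    shared space or failing coverage in either genotype are never called.
    """
    cfg = cfg or ThresholdConfig()
    if context not in CONTEXTS:
        raise ValueError(f"unknown context {context!r}")
    for lv in (level_a, level_b):
        if not np.isnan(lv) and not 0.0 <= lv <= 1.0:
            raise ValueError("methylation levels must lie in [0, 1]")
    if mapping_status not in SHARED_STATUSES or not (coverage_ok_a and coverage_ok_b):
        return None
    if np.isnan(level_a) or np.isnan(level_b):
        return None
    lo, hi = min(level_a, level_b), max(level_a, level_b)
    if context == "CHH":
        called = lo < cfg.dmt_chh_low and hi > cfg.dmt_chh_high
    else:
        called = (hi - lo) >= cfg.dmt_diff and lo < cfg.dmt_low and hi > cfg.dmt_high
    if not called:
        return None
    return "hypo_in_A" if level_a < level_b else "hypo_in_B"


def call_dmts(tiles: pd.DataFrame, cfg: ThresholdConfig | None = None) -> pd.DataFrame:
    """Vectorised DMT calling over a tile table.

    ``tiles`` columns: chrom, start, end, context, level_a, level_b,
    coverage_ok_a, coverage_ok_b, status. Returns the subset of called
    tiles with a ``direction`` column.
    """
    cfg = cfg or ThresholdConfig()
    la = tiles["level_a"].to_numpy(dtype=float)
    lb = tiles["level_b"].to_numpy(dtype=float)
    for arr in (la, lb):
        finite = arr[~np.isnan(arr)]
        if finite.size and (finite.min() < 0 or finite.max() > 1):
            raise ValueError("methylation levels must lie in [0, 1]")
    eligible = (
        tiles["status"].isin(SHARED_STATUSES).to_numpy()
        & tiles["coverage_ok_a"].to_numpy(dtype=bool)
        & tiles["coverage_ok_b"].to_numpy(dtype=bool)
        & ~np.isnan(la)
        & ~np.isnan(lb)
    )
    lo = np.fmin(la, lb)
    hi = np.fmax(la, lb)
    is_chh = (tiles["context"] == "CHH").to_numpy()
    called_chh = (lo < cfg.dmt_chh_low) & (hi > cfg.dmt_chh_high)
    called_cgchg = ((hi - lo) >= cfg.dmt_diff) & (lo < cfg.dmt_low) & (hi > cfg.dmt_high)
    called = eligible & np.where(is_chh, called_chh, called_cgchg)
    out = tiles.loc[called, ["chrom", "start", "end", "context", "level_a", "level_b"]].copy()
    out["direction"] = np.where(la[called] < lb[called], "hypo_in_A", "hypo_in_B")
    return out.reset_index(drop=True)


def make_dmt_tiles(
    bin_stats_a: pd.DataFrame,
    track_a: pd.DataFrame,
    bin_stats_b: pd.DataFrame,
    track_b: pd.DataFrame,
    mappings: pd.DataFrame,
    bin_size: int = 100,
) -> pd.DataFrame:
    """Build the per-(source tile, context) table consumed by call_dmts.

    Target levels come from the target bin with maximal overlap of each
    source bin's projected interval; coverage gates reuse the missing-data
    classification of the two domain tracks.
    """
    from .crossmap import target_bin_of  # local import to avoid cycle

    cov_a = {(r.chrom, r.start): r.label != "missing_data"
             for r in track_a.itertuples(index=False)}
    cov_b = {(r.chrom, r.start): r.label != "missing_data"
             for r in track_b.itertuples(index=False)}
    lvl_a = {
        (r.chrom, r.start, r.context): r.level
        for r in bin_stats_a.itertuples(index=False)
    }
    lvl_b = {
        (r.chrom, r.start, r.context): r.level
        for r in bin_stats_b.itertuples(index=False)
    }
    rows = []
    for m in mappings.itertuples(index=False):
        if m.status not in SHARED_STATUSES:
            continue
        tbin = target_bin_of(m.tgt_start, m.tgt_end, bin_size)
        ok_a = cov_a.get((m.chrom, m.start), False)
        ok_b = cov_b.get((m.tgt_chrom, tbin), False)
        for ctx in CONTEXTS:
            rows.append(
                (
                    m.chrom, m.start, m.end, ctx,
                    lvl_a.get((m.chrom, m.start, ctx), np.nan),
                    lvl_b.get((m.tgt_chrom, tbin, ctx), np.nan),
                    ok_a, ok_b, m.status,
                )
            )
    return pd.DataFrame(
        rows,
        columns=["chrom", "start", "end", "context", "level_a", "level_b",
                 "coverage_ok_a", "coverage_ok_b", "status"],
    )
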