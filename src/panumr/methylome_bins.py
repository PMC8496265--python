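"""Summarise per-cytosine methylation calls into 100-bp bins and classify
each bin into one of six methylation domains.

The domain classifier applies a strict hierarchy: bins with too few
cytosines or too little read coverage are ``missing_data``; then, in order,
RdDM (CHH-driven), heterochromatin (CG and CHG), CG-only, unmethylated
(all contexts low) and intermediate. Edge semantics follow the original
wording exactly: strictly greater-than for RdDM and CG-only, >= for
heterochromatin, strictly less-than for unmethylated.

Bin methylation level is read-weighted (sum of methylated reads over sum of
total reads), not the mean of per-site ratios; this matches the
"CT / number of sites" coverage bookkeeping and is robust at low coverage.
Counts from both strands are pooled. A context with zero sites contributes
level 0 to the classification comparisons, so absent CHH sites cannot veto
an unmethylated call.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .config import CONTEXTS, DOMAIN_LABELS, ThresholdConfig
from .genome import tile_bins

logger = logging.getLogger(__name__)

CALL_COLUMNS = ["chrom", "pos", "strand", "context", "meth_reads", "total_reads"]


@dataclass(frozen=True)
class BinContextStats:
    """Per-bin, per-context summary (site count, reads/site, weighted level)."""

    n_sites: int
    coverage: float          # total reads / n_sites
    level: float | None      # None/NaN when no reads

    @property
    def total_reads(self) -> float:
        return self.coverage * self.n_sites

    @property
    def meth_reads(self) -> float:
        if self.level is None or np.isnan(self.level):
            return 0.0
        return self.level * self.total_reads


def summarize_bins(
    calls: pd.DataFrame,
    chrom_sizes: Mapping[str, int],
    bin_size: int = 100,
) -> pd.DataFrame:
    """Aggregate per-cytosine calls into per-(bin, context) statistics.

    Parameters
    ----------
    calls
        DataFrame with columns chrom, pos, strand, context, meth_reads,
        total_reads. Row order is irrelevant; counts are summed.
    chrom_sizes
        Mapping chromosome -> length in bp. Every bin x context combination
        is emitted, including empty ones (n_sites=0, level NaN).

    Returns
    -------
    DataFrame with columns chrom, start, end, context, n_sites, coverage,
    level, meth_reads, total_reads, one row per (bin, context).
    """
    missing = [c for c in CALL_COLUMNS if c not in calls.columns and c != "strand"]
    if missing:
        raise ValueError(f"calls table lacks columns: {missing}")
    bad_ctx = set(calls["context"].unique()) - set(CONTEXTS)
    if bad_ctx:
        raise ValueError(f"unknown cytosine contexts: {sorted(bad_ctx)}")
    if (calls["meth_reads"] < 0).any() or (calls["total_reads"] < 0).any():
        raise ValueError("negative read counts")
    if (calls["meth_reads"] > calls["total_reads"]).any():
        raise ValueError("meth_reads exceeds total_reads for some sites")

    sizes = calls["chrom"].map(dict(chrom_sizes))
    if sizes.isna().any():
        raise ValueError(
            f"calls on chromosomes absent from chrom_sizes: "
            f"{sorted(calls.loc[sizes.isna(), 'chrom'].unique())}"
        )
    in_range = (calls["pos"] >= 0) & (calls["pos"] < sizes)
    n_bad = int((~in_range).sum())
    if n_bad:
        logger.warning("dropping %d cytosine calls beyond chromosome ends", n_bad)
        calls = calls[in_range]

    df = calls.assign(start=(calls["pos"] // bin_size) * bin_size)
    agg = (
        df.groupby(["chrom", "start", "context"], sort=False, observed=True)
        .agg(
            n_sites=("pos", "size"),
            meth_reads=("meth_reads", "sum"),
            total_reads=("total_reads", "sum"),
        )
        .reset_index()
    )

    grid = tile_bins(chrom_sizes, bin_size)
    grid = grid.merge(pd.DataFrame({"context": list(CONTEXTS)}), how="cross")
    out = grid.merge(agg, on=["chrom", "start", "context"], how="left")
    out[["n_sites", "meth_reads", "total_reads"]] = (
        out[["n_sites", "meth_reads", "total_reads"]].fillna(0).astype(np.int64)
    )
    with np.errstate(invalid="ignore", divide="ignore"):
        out["coverage"] = np.where(
            out["n_sites"] > 0, out["total_reads"] / out["n_sites"].clip(lower=1), 0.0
        )
        out["level"] = np.where(
            out["total_reads"] > 0,
            out["meth_reads"] / out["total_reads"].clip(lower=1),
            np.nan,
        )
    cols = ["chrom", "start", "end", "context", "n_sites", "coverage", "level",
            "meth_reads", "total_reads"]
    return out.sort_values(["chrom", "start", "context"], kind="mergesort")[cols].reset_index(drop=True)


def _classify_arrays(
    cg: np.ndarray,
    chg: np.ndarray,
    chh: np.ndarray,
    total_sites: np.ndarray,
    pooled_coverage: np.ndarray,
    cfg: ThresholdConfig,
) -> np.ndarray:
    """Vectorised six-rule hierarchy; NaN levels are treated as 0."""
    for name, arr in (("CG", cg), ("CHG", chg), ("CHH", chh)):
        if np.nanmin(arr, initial=0.0) < 0:
            raise ValueError(f"negative {name} methylation level")
    cg = np.nan_to_num(cg)
    chg = np.nan_to_num(chg)
    chh = np.nan_to_num(chh)
    conditions = [
        (total_sites < cfg.min_sites) | (pooled_coverage < cfg.min_coverage),
        chh > cfg.chh_rddm,
        (cg >= cfg.cg_chg_het) & (chg >= cfg.cg_chg_het),
        cg > cfg.cg_only,
        (cg < cfg.unmethylated_max) & (chg < cfg.unmethylated_max) & (chh < cfg.unmethylated_max),
    ]
    labels = DOMAIN_LABELS[:5]
    return np.select(conditions, labels, default="intermediate")


def classify_bin(
    cg: BinContextStats,
    chg: BinContextStats,
    chh: BinContextStats,
    cfg: ThresholdConfig | None = None,
) -> str:
    """Classify a single bin from its three per-context summaries.

    The missing-data gate uses cytosine count and coverage pooled across all
    three contexts (see docs/methods.md for why the pooled reading was
    chosen over a per-context one).
    """
    cfg = cfg or ThresholdConfig()
    total_sites = cg.n_sites + chg.n_sites + chh.n_sites
    total_reads = cg.total_reads + chg.total_reads + chh.total_reads
    pooled_cov = total_reads / total_sites if total_sites else 0.0

    def _lvl(s: BinContextStats) -> float:
        return np.nan if s.level is None else s.level

    return str(
        _classify_arrays(
            np.array([_lvl(cg)]),
            np.array([_lvl(chg)]),
            np.array([_lvl(chh)]),
            np.array([total_sites]),
            np.array([pooled_cov]),
            cfg,
        )[0]
    )


def classify_bins(bin_stats: pd.DataFrame, cfg: ThresholdConfig | None = None) -> pd.DataFrame:
    """Classify every bin of a summarize_bins table into a domain track.

    Returns a DataFrame with columns chrom, start, end, label — one row per
    bin, labels drawn from :data:`panumr.config.DOMAIN_LABELS`.
    """
    cfg = cfg or ThresholdConfig()
    wide = bin_stats.pivot_table(
        index=["chrom", "start", "end"],
        columns="context",
        values=["level", "n_sites", "total_reads"],
        aggfunc="first",
        observed=True,
    )
    levels = {c: wide["level"].get(c, pd.Series(np.nan, index=wide.index)).to_numpy()
              for c in CONTEXTS}
    n_sites = sum(
        wide["n_sites"].get(c, pd.Series(0, index=wide.index)).fillna(0).to_numpy()
        for c in CONTEXTS
    )
    total_reads = sum(
        wide["total_reads"].get(c, pd.Series(0, index=wide.index)).fillna(0).to_numpy()
        for c in CONTEXTS
    )
    with np.errstate(invalid="ignore", divide="ignore"):
        pooled_cov = np.where(n_sites > 0, total_reads / np.maximum(n_sites, 1), 0.0)
    labels = _classify_arrays(
        levels["CG"], levels["CHG"], levels["CHH"], n_sites, pooled_cov, cfg
    )
    track = wide.index.to_frame(index=False)
    track["label"] = labels
    return track.sort_values(["chrom", "start"], kind="mergesort").reset_index(drop=True)
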