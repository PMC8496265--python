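"""Call unmethylated regions (UMRs) from a methylation-domain track.

A UMR is a maximal run of 100-bp bins labelled unmethylated, tolerant of
interspersed missing-data bins as long as those stay below one third of the
run. Candidates are trimmed so they start and end on unmethylated bins;
candidates violating the missing-data ceiling are split at their longest
internal missing run and both sides are re-evaluated recursively (the
constraint itself is fixed by the method definition, the split strategy is
this package's deterministic resolution of it). Surviving regions shorter
than 300 bp are removed.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .config import ThresholdConfig
from .genome import gap_to_nearest, overlaps_any, validate_tiling

UMR_COLUMNS = ["chrom", "start", "end", "n_bins", "n_missing", "missing_fraction"]


def _longest_missing_run(is_missing: np.ndarray, i: int, j: int) -> tuple[int, int]:
    """Longest run of True within [i, j); leftmost on ties."""
    best_len, best_a, best_b = 0, i, i
    a = None
    for k in range(i, j + 1):
        inside = k < j and is_missing[k]
        if inside and a is None:
            a = k
        elif not inside and a is not None:
            if k - a > best_len:
                best_len, best_a, best_b = k - a, a, k
            a = None
    return best_a, best_b


def _resolve(is_missing: np.ndarray, i: int, j: int, max_missing: float, out: list) -> None:
    # trim missing bins from both ends
    while i < j and is_missing[i]:
        i += 1
    while j > i and is_missing[j - 1]:
        j -= 1
    if i >= j:
        return
    n_miss = int(is_missing[i:j].sum())
    if n_miss / (j - i) >= max_missing:
        a, b = _longest_missing_run(is_missing, i, j)
        _resolve(is_missing, i, a, max_missing, out)
        _resolve(is_missing, b, j, max_missing, out)
    else:
        out.append((i, j, n_miss))


def call_umrs(
    track: pd.DataFrame,
    cfg: ThresholdConfig | None = None,
) -> pd.DataFrame:
    """Group unmethylated/missing bins of a domain track into UMRs.

    Parameters
    ----------
    track
        Domain track (chrom, start, end, label) as produced by
        :func:`panumr.methylome_bins.classify_bins`. Bins must tile each
        chromosome without overlap; a ragged final bin is ignored for UMR
        membership.

    Returns
    -------
    Sorted, non-overlapping UMR table with columns chrom, start, end,
    n_bins, n_missing, missing_fraction.
    """
    cfg = cfg or ThresholdConfig()
    bs = cfg.bin_size
    validate_tiling(track, bs)

    records = []
    for chrom, grp in track.groupby("chrom", sort=True):
        full = grp[(grp["end"] - grp["start"]) == bs].sort_values("start")
        starts = full["start"].to_numpy()
        labels = full["label"].to_numpy()
        in_run = np.isin(labels, ("unmethylated", "missing_data"))
        is_missing = labels == "missing_data"
        # maximal runs of candidate bins
        k = 0
        n = len(labels)
        pieces: list[tuple[int, int, int]] = []
        while k < n:
            if not in_run[k]:
                k += 1
                continue
            j = k
            while j < n and in_run[j] and (j == k or starts[j] == starts[j - 1] + bs):
                j += 1
            _resolve(is_missing, k, j, cfg.umr_max_missing, pieces)
            k = j
        for i, j, n_miss in pieces:
            span = (j - i) * bs
            if span < cfg.umr_min_len:
                continue
            records.append(
                (chrom, int(starts[i]), int(starts[j - 1]) + bs, j - i, n_miss,
                 n_miss / (j - i))
            )
    return pd.DataFrame(records, columns=UMR_COLUMNS)


def classify_umr_location(
    umrs: pd.DataFrame,
    genes: pd.DataFrame,
    proximal_bp: int = 2000,
) -> pd.DataFrame:
    """Annotate UMRs as genic / proximal / intergenic relative to gene bodies.

    Genic means >=1 bp overlap with any gene body; proximal means within
    ``proximal_bp`` of the nearest gene-body edge (inclusive at exactly that
    distance); everything else is intergenic. An empty gene set makes every
    UMR intergenic.
    """
    out = umrs.copy()
    if umrs.empty:
        out["location"] = pd.Series(dtype=object)
        return out
    if genes is None or genes.empty:
        out["location"] = "intergenic"
        return out
    genic = overlaps_any(umrs, genes)
    gap = gap_to_nearest(umrs, genes)
    out["location"] = np.where(
        genic, "genic", np.where(gap <= proximal_bp, "proximal", "intergenic")
    )
    return out
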