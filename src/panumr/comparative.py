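"""Classify UMR stability across genotypes and its downstream summaries.

Each source UMR is compared against a second genotype through the bin-level
synteny mapping:

* nonshared — any member bin is unmapped or excluded by the indel filters;
* missing_data — shared, but more than half of the projected target bins
  lack methylation data;
* polymorphic — more than half of the target bins with data are methylated
  (RdDM, heterochromatin or CG-only); typed by the dominant methylated
  domain in the fixed order CHH -> CG/CHG -> CG-only;
* identical — the projected bin set equals the bin set of the overlapping
  target UMR(s);
* partial — overlapping target UMR(s) exist but the bin boundaries differ
  (containment or shifted edges).

The categories are mutually exclusive and exhaustive over source UMRs.
"""

from __future__ import annotations

from collections import Counter

import numpy as np
import pandas as pd

from .config import METHYLATED_LABELS, SHARED_STATUSES, ThresholdConfig
from .crossmap import target_bin_of

COMPARISON_COLS = [
    "chrom", "start", "end", "n_bins", "category", "methylated_bin_fraction",
    "polymorphic_type", "no_target_umr", "acr_only_in_target", "acr_class",
    "tgt_chrom", "tgt_start", "tgt_end",
]

CATEGORIES = ("nonshared", "missing_data", "identical", "partial", "polymorphic")


def classify_polymorphic_type(methylated_label_counts: Counter | dict) -> str:
    """Dominant methylated-domain type of a polymorphic UMR.

    Applied in the fixed hierarchy CHH (RdDM) -> CG/CHG (heterochromatin)
    -> CG-only; a class wins outright with >50% of the methylated bins;
    when no class reaches a majority the largest class wins, ties resolved
    by the same hierarchy order.
    """
    order = (("rddm", "chh"), ("heterochromatin", "cg_chg"), ("cg_only", "cg_only"))
    total = sum(methylated_label_counts.get(lbl, 0) for lbl, _ in order)
    if total == 0:
        raise ValueError("polymorphic UMR without methylated target bins")
    for lbl, name in order:
        if methylated_label_counts.get(lbl, 0) / total > 0.5:
            return name
    best = max(order, key=lambda p: methylated_label_counts.get(p[0], 0))
    return best[1]


def classify_overlap_boundary(
    projected_bins: set[tuple[str, int]],
    target_umr_bins: list[set[tuple[str, int]]],
) -> tuple[str, bool]:
    """Refine an overlapping UMR into identical / partial.

    ``projected_bins`` is the target-bin set of the source UMR;
    ``target_umr_bins`` are the bin sets of target UMRs that touch it.
    Returns (category, no_target_umr_flag). Without any overlapping target
    UMR the comparison is flagged and reported as partial.
    """
    touching = [b for b in target_umr_bins if b & projected_bins]
    if not touching:
        return "partial", True
    union: set[tuple[str, int]] = set().union(*touching)
    return ("identical" if union == projected_bins else "partial"), False


def _umr_member_bins(start: int, end: int, bin_size: int) -> list[int]:
    return list(range(start, end, bin_size))


def classify_umr_stability(
    umr_row,
    mapping_by_bin: dict,
    target_label: dict,
    cfg: ThresholdConfig,
) -> dict:
    """Stability call for a single source UMR (see module docstring).

    ``mapping_by_bin`` maps (chrom, bin_start) -> mapping record;
    ``target_label`` maps (tgt_chrom, tgt_bin_start) -> domain label.
    Returns a dict with category, methylated fraction, projected bins and
    target span; boundary refinement of overlapping UMRs happens separately.
    """
    bins = _umr_member_bins(umr_row["start"], umr_row["end"], cfg.bin_size)
    if not bins:
        raise ValueError("UMR without member bins")
    records = [mapping_by_bin.get((umr_row["chrom"], b)) for b in bins]
    base = {
        "methylated_bin_fraction": np.nan,
        "projected_bins": set(),
        "tgt_chrom": None, "tgt_start": -1, "tgt_end": -1,
        "meth_counts": Counter(),
    }
    if any(r is None or r.status not in SHARED_STATUSES for r in records):
        return {**base, "category": "nonshared"}

    projected = []
    labels = []
    for r in records:
        tbin = target_bin_of(r.tgt_start, r.tgt_end, cfg.bin_size)
        projected.append((r.tgt_chrom, tbin))
        labels.append(target_label.get((r.tgt_chrom, tbin), "missing_data"))
    tgt_chrom = records[0].tgt_chrom
    tgt_start = min(r.tgt_start for r in records)
    tgt_end = max(r.tgt_end for r in records)
    base.update(
        projected_bins=set(projected), tgt_chrom=tgt_chrom,
        tgt_start=int(tgt_start), tgt_end=int(tgt_end),
    )

    with_data = [lbl for lbl in labels if lbl != "missing_data"]
    frac_missing = 1.0 - len(with_data) / len(labels)
    if not with_data or frac_missing > cfg.missing_target_max:
        return {**base, "category": "missing_data"}

    meth = [lbl for lbl in with_data if lbl in METHYLATED_LABELS]
    frac = len(meth) / len(with_data)
    base["methylated_bin_fraction"] = frac
    base["meth_counts"] = Counter(meth)
    if frac > cfg.polymorphic_min_frac:
        return {**base, "category": "polymorphic"}
    return {**base, "category": "overlapping"}


def classify_acr_variability(
    source_overlaps_acr: bool,
    target_overlaps_acr: bool,
) -> str:
    """ACR-variability class of a UMR given accessibility in each genotype."""
    if source_overlaps_acr and target_overlaps_acr:
        return "stable_acr"
    if source_overlaps_acr:
        return "source_only_acr"
    if target_overlaps_acr:
        return "target_only_acr"
    return "no_acr"


def _overlaps_sorted(intervals: pd.DataFrame, chrom: str, start: int, end: int) -> bool:
    sub = intervals[intervals["chrom"] == chrom]
    if sub.empty:
        return False
    return bool(((sub["start"] < end) & (sub["end"] > start)).any())


def compare_umrs(
    source_umrs: pd.DataFrame,
    mappings: pd.DataFrame,
    target_track: pd.DataFrame,
    target_umrs: pd.DataFrame,
    cfg: ThresholdConfig | None = None,
    source_acrs: pd.DataFrame | None = None,
    target_acrs: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Classify every source UMR against one contrast genotype.

    Returns one row per source UMR (columns in :data:`COMPARISON_COLS`);
    categories partition the UMR set. ACR variability columns are filled
    when ACR tables for both genotypes are supplied. The flag
    ``acr_only_in_target`` marks polymorphic UMRs that are nonetheless
    accessible in the target genotype (accessible-but-methylated regions);
    it is a flag, not a separate category.
    """
    cfg = cfg or ThresholdConfig()
    mapping_by_bin = {
        (r.chrom, r.start): r for r in mappings.itertuples(index=False)
    }
    target_label = {
        (r.chrom, r.start): r.label for r in target_track.itertuples(index=False)
    }
    tgt_umr_bins: dict[tuple[str, int], int] = {}
    tgt_umr_sets: list[set[tuple[str, int]]] = []
    for i, r in enumerate(target_umrs.itertuples(index=False)):
        bins = {(r.chrom, b) for b in _umr_member_bins(r.start, r.end, cfg.bin_size)}
        tgt_umr_sets.append(bins)
        for key in bins:
            tgt_umr_bins[key] = i

    rows = []
    for _, umr in source_umrs.iterrows():
        res = classify_umr_stability(umr, mapping_by_bin, target_label, cfg)
        category = res["category"]
        poly_type = "unset"
        no_tgt = False
        if category == "polymorphic":
            poly_type = classify_polymorphic_type(res["meth_counts"])
        elif category == "overlapping":
            touched = {
                tgt_umr_bins[b] for b in res["projected_bins"] if b in tgt_umr_bins
            }
            category, no_tgt = classify_overlap_boundary(
                res["projected_bins"], [tgt_umr_sets[i] for i in sorted(touched)]
            )
        acr_class = "unset"
        acr_only = False
        if source_acrs is not None and target_acrs is not None:
            src_hit = _overlaps_sorted(source_acrs, umr["chrom"], umr["start"], umr["end"])
            tgt_hit = False
            if res["tgt_chrom"] is not None and res["tgt_start"] >= 0:
                tgt_hit = _overlaps_sorted(
                    target_acrs, res["tgt_chrom"], res["tgt_start"], res["tgt_end"]
                )
            acr_class = classify_acr_variability(src_hit, tgt_hit)
            acr_only = category == "polymorphic" and tgt_hit
        rows.append(
            (
                umr["chrom"], umr["start"], umr["end"],
                len(_umr_member_bins(umr["start"], umr["end"], cfg.bin_size)),
                category, res["methylated_bin_fraction"], poly_type, no_tgt,
                acr_only, acr_class, res["tgt_chrom"], res["tgt_start"], res["tgt_end"],
            )
        )
    return pd.DataFrame(rows, columns=COMPARISON_COLS)


def attribute_dmts(dmts: pd.DataFrame, comparisons: pd.DataFrame) -> pd.Series:
    """Fraction of hypomethylated-in-source DMT bins inside polymorphic
    UMRs, inside partial UMRs, or elsewhere ('other': sub-UMR-size patches
    and single-bin differences).

    Bins are deduplicated across contexts; fractions sum to 1.
    """
    hypo = dmts[dmts["direction"] == "hypo_in_A"]
    bins = hypo[["chrom", "start"]].drop_duplicates()
    total = len(bins)
    if total == 0:
        return pd.Series({"polymorphic": np.nan, "partial": np.nan, "other": np.nan})

    def _membership(category: str) -> set[tuple[str, int]]:
        sub = comparisons[comparisons["category"] == category]
        keys: set[tuple[str, int]] = set()
        for r in sub.itertuples(index=False):
            keys.update((r.chrom, b) for b in range(r.start, r.end, 100))
        return keys

    poly = _membership("polymorphic")
    part = _membership("partial")
    n_poly = n_part = 0
    for r in bins.itertuples(index=False):
        key = (r.chrom, r.start)
        if key in poly:
            n_poly += 1
        elif key in part:
            n_part += 1
    return pd.Series(
        {
            "polymorphic": n_poly / total,
            "partial": n_part / total,
            "other": (total - n_poly - n_part) / total,
        }
    )


def classify_expression(
    expression: pd.DataFrame,
    cfg: ThresholdConfig | None = None,
) -> pd.Series:
    """Per-gene expression class from the supplied DE summary table.

    silent — both means below the expression floor; de_higher_A /
    de_higher_B — |log2FC| above the fold cutoff at significant p (log2FC
    is A over B); expressed_not_de otherwise.
    """
    cfg = cfg or ThresholdConfig()
    silent = (expression["mean_a"] < cfg.expr_floor) & (expression["mean_b"] < cfg.expr_floor)
    de = (expression["log2fc"].abs() > cfg.de_lfc) & (expression["p_value"] < cfg.de_p)
    return pd.Series(
        np.where(
            silent, "silent",
            np.where(
                de & (expression["log2fc"] > 0), "de_higher_A",
                np.where(de, "de_higher_B", "expressed_not_de"),
            ),
        ),
        index=expression.index,
    )


def link_expression(
    comparisons: pd.DataFrame,
    genes: pd.DataFrame,
    expression: pd.DataFrame,
    cfg: ThresholdConfig | None = None,
) -> pd.DataFrame:
    """Cross-tabulate UMR stability against expression class of TSS-linked genes.

    A gene links to a UMR when its TSS lies within ``cfg.tss_window`` bp of
    the UMR interval (upstream or downstream; overlap counts as distance
    0). Only UMRs classified identical / partial / polymorphic participate.
    Genes without an expression record are excluded. Returns a long table
    (umr category, polymorphic_type, gene, expression class), one row per
    link; use ``pd.crosstab`` on it for figure-style proportions.
    """
    cfg = cfg or ThresholdConfig()
    expr = expression.set_index("gene_id")
    classes = classify_expression(expr.reset_index(), cfg)
    classes.index = expr.index
    rows = []
    usable = comparisons[comparisons["category"].isin(("identical", "partial", "polymorphic"))]
    for g in genes.itertuples(index=False):
        if g.gene_id not in classes.index:
            continue
        sub = usable[usable["chrom"] == g.chrom]
        if sub.empty:
            continue
        tss = g.tss
        dist = np.maximum.reduce(
            [sub["start"].to_numpy() - tss, tss - (sub["end"].to_numpy() - 1),
             np.zeros(len(sub), dtype=np.int64)]
        )
        for _, umr in sub[dist <= cfg.tss_window].iterrows():
            rows.append(
                (
                    umr["chrom"], umr["start"], umr["end"], umr["category"],
                    umr["polymorphic_type"], g.gene_id, classes.loc[g.gene_id],
                )
            )
    return pd.DataFrame(
        rows,
        columns=["chrom", "start", "end", "category", "polymorphic_type",
                 "gene_id", "expression_class"],
    )
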