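"""Project 100-bp bins between two genome assemblies via a synteny map.

The synteny map is a single-coverage set of alignment chains, each made of
ungapped segments; gaps between consecutive segments of a chain are indels
(source-side gap = deletion in the target, target-side gap = insertion).
A bin is mappable when it lies entirely within one chain's source span
(block-internal indels allowed); its target interval spans the projections
of its first and last aligned bases. Variant counts (SNPs, indels) per bin
come from an external variant table, and shared-space filtering keeps bins
with at most 4 indel events of at most 20 bp each.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import SHARED_STATUSES, ThresholdConfig
from .genome import tile_bins

SEGMENT_COLS = [
    "chain_id", "src_chrom", "src_start", "src_end",
    "tgt_chrom", "tgt_start", "tgt_end", "strand",
]

MAPPING_COLS = [
    "chrom", "start", "end", "tgt_chrom", "tgt_start", "tgt_end", "reverse",
    "n_snps", "n_indels", "max_indel_len", "status",
]


@dataclass
class SyntenyMap:
    """Ordered ungapped alignment segments grouped into chains.

    ``segments`` columns: chain_id, src_chrom, src_start, src_end,
    tgt_chrom, tgt_start, tgt_end, strand. Target coordinates are always on
    the forward strand; strand '-' means the alignment is reverse-
    complemented (source order maps to descending target order).
    """

    segments: pd.DataFrame
    _chains: pd.DataFrame = field(init=False, repr=False)

    def __post_init__(self) -> None:
        seg = self.segments.reset_index(drop=True)
        if seg.empty:
            seg = pd.DataFrame(columns=SEGMENT_COLS)
        lengths_src = seg["src_end"] - seg["src_start"]
        lengths_tgt = seg["tgt_end"] - seg["tgt_start"]
        if not (lengths_src == lengths_tgt).all():
            raise ValueError("ungapped segments must have equal source/target length")
        if (lengths_src <= 0).any():
            raise ValueError("segments must have positive length")
        self._check_single_coverage(seg, "src")
        self._check_single_coverage(seg, "tgt")
        for cid, grp in seg.groupby("chain_id", sort=False):
            if grp["src_chrom"].nunique() > 1 or grp["tgt_chrom"].nunique() > 1:
                raise ValueError(f"chain {cid} spans multiple chromosomes")
            if grp["strand"].nunique() > 1:
                raise ValueError(f"chain {cid} mixes strands")
        self.segments = seg.sort_values(["src_chrom", "src_start"], kind="mergesort").reset_index(drop=True)
        self._chains = (
            self.segments.groupby("chain_id", sort=False)
            .agg(
                src_chrom=("src_chrom", "first"),
                src_start=("src_start", "min"),
                src_end=("src_end", "max"),
                tgt_chrom=("tgt_chrom", "first"),
                tgt_start=("tgt_start", "min"),
                tgt_end=("tgt_end", "max"),
                strand=("strand", "first"),
            )
            .reset_index()
        )
        # single coverage must also hold at chain-span level on the source
        self._check_single_coverage(
            self._chains.rename(columns={"src_start": "src_start", "src_end": "src_end"}),
            "src",
        )

    @staticmethod
    def _check_single_coverage(seg: pd.DataFrame, side: str) -> None:
        for _, grp in seg.groupby(f"{side}_chrom", sort=False):
            s = grp.sort_values(f"{side}_start")
            if (s[f"{side}_start"].to_numpy()[1:] < s[f"{side}_end"].to_numpy()[:-1]).any():
                raise ValueError(f"overlapping synteny blocks on {side} genome")

    @property
    def chains(self) -> pd.DataFrame:
        return self._chains

    def invert(self) -> "SyntenyMap":
        """Swap source and target genomes (exact inverse mapping)."""
        seg = self.segments.rename(
            columns={
                "src_chrom": "tgt_chrom", "src_start": "tgt_start", "src_end": "tgt_end",
                "tgt_chrom": "src_chrom", "tgt_start": "src_start", "tgt_end": "src_end",
            }
        )
        return SyntenyMap(seg[SEGMENT_COLS])

    def source_bp(self) -> int:
        return int((self.segments["src_end"] - self.segments["src_start"]).sum())

    # -- projection ---------------------------------------------------------
    def project_interval(self, chrom: str, start: int, end: int):
        """Project a source interval to target coordinates.

        Returns (tgt_chrom, tgt_start, tgt_end, reverse) or None when the
        interval is not fully covered by a single chain's source span, or
        falls entirely inside a deletion.
        """
        ch = self._chains
        cand = ch[(ch["src_chrom"] == chrom) & (ch["src_start"] <= start) & (ch["src_end"] >= end)]
        if cand.empty:
            return None
        chain = cand.iloc[0]
        seg = self.segments[self.segments["chain_id"] == chain["chain_id"]]
        hit = seg[(seg["src_start"] < end) & (seg["src_end"] > start)]
        if hit.empty:
            return None
        lo, hi = None, None
        for _, s in hit.iterrows():
            a = max(start, s["src_start"])
            b = min(end, s["src_end"])
            if s["strand"] == "+":
                ta = s["tgt_start"] + (a - s["src_start"])
                tb = s["tgt_start"] + (b - s["src_start"])
            else:
                ta = s["tgt_end"] - (b - s["src_start"])
                tb = s["tgt_end"] - (a - s["src_start"])
            lo = ta if lo is None else min(lo, ta)
            hi = tb if hi is None else max(hi, tb)
        return str(chain["tgt_chrom"]), int(lo), int(hi), chain["strand"] == "-"


def target_bin_of(tgt_start: int, tgt_end: int, bin_size: int = 100) -> int:
    """Target bin (start coordinate) with maximal overlap; leftmost on ties."""
    best_bin, best_ov = None, -1
    b = (tgt_start // bin_size) * bin_size
    while b < tgt_end:
        ov = min(tgt_end, b + bin_size) - max(tgt_start, b)
        if ov > best_ov:
            best_bin, best_ov = b, ov
        b += bin_size
    return int(best_bin)


def _count_variants_per_bin(
    bins: pd.DataFrame, variants: pd.DataFrame, bin_size: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    n = len(bins)
    n_snps = np.zeros(n, dtype=np.int64)
    n_indels = np.zeros(n, dtype=np.int64)
    max_len = np.zeros(n, dtype=np.int64)
    if variants is None or variants.empty:
        return n_snps, n_indels, max_len
    bin_index = {
        (row.chrom, row.start): i for i, row in enumerate(bins.itertuples(index=False))
    }
    for kind, grp in variants.groupby(variants["kind"].eq("snp"), sort=False):
        for row in grp.itertuples(index=False):
            key = (row.chrom, (row.pos // bin_size) * bin_size)
            i = bin_index.get(key)
            if i is None:
                continue
            if kind:  # SNP
                n_snps[i] += 1
            else:
                n_indels[i] += 1
                max_len[i] = max(max_len[i], int(row.length))
    return n_snps, n_indels, max_len


def map_bins(
    chrom_sizes: dict[str, int],
    synteny: SyntenyMap,
    variants: pd.DataFrame | None = None,
    bin_size: int = 100,
) -> pd.DataFrame:
    """Map every source bin to target coordinates and count its variants.

    Returns one row per source bin with columns
    chrom, start, end, tgt_chrom, tgt_start, tgt_end, reverse, n_snps,
    n_indels, max_indel_len, status. Status is provisional here
    (unmapped / shared_exact / shared_snp / shared_indel); apply
    :func:`filter_shared` to finalise shared space.
    """
    bins = tile_bins(chrom_sizes, bin_size)
    n = len(bins)
    tgt_chrom = np.full(n, None, dtype=object)
    tgt_start = np.full(n, -1, dtype=np.int64)
    tgt_end = np.full(n, -1, dtype=np.int64)
    reverse = np.zeros(n, dtype=bool)
    mapped = np.zeros(n, dtype=bool)

    chains = synteny.chains
    for chrom, grp in bins.groupby("chrom", sort=False):
        ch = chains[chains["src_chrom"] == chrom].sort_values("src_start")
        seg = synteny.segments[synteny.segments["src_chrom"] == chrom]
        if ch.empty or seg.empty:
            continue
        ss = seg["src_start"].to_numpy()
        se = seg["src_end"].to_numpy()
        ts = seg["tgt_start"].to_numpy()
        te = seg["tgt_end"].to_numpy()
        neg = (seg["strand"] == "-").to_numpy()
        tchrom = seg["tgt_chrom"].to_numpy()

        c_starts = ch["src_start"].to_numpy()
        c_ends = ch["src_end"].to_numpy()
        b_starts = grp["start"].to_numpy()
        b_ends = grp["end"].to_numpy()
        rows = grp.index.to_numpy()
        # bin fully inside one chain's source span?
        idx = np.searchsorted(c_starts, b_starts, side="right") - 1
        in_chain = (idx >= 0) & (b_ends <= np.where(idx >= 0, c_ends[np.maximum(idx, 0)], -1))
        # overlapping segment range [i0, i1) per bin (segments sorted, disjoint)
        i0 = np.searchsorted(se, b_starts, side="right")
        i1 = np.searchsorted(ss, b_ends, side="left")
        has_seg = in_chain & (i1 > i0)
        single = has_seg & (i1 - i0 == 1)

        # fast path: bin within exactly one ungapped segment
        k = np.where(single, i0, 0)
        a = np.maximum(b_starts, ss[k])
        b = np.minimum(b_ends, se[k])
        fw_lo = ts[k] + (a - ss[k])
        fw_hi = ts[k] + (b - ss[k])
        rv_lo = te[k] - (b - ss[k])
        rv_hi = te[k] - (a - ss[k])
        lo = np.where(neg[k], rv_lo, fw_lo)
        hi = np.where(neg[k], rv_hi, fw_hi)
        sel = rows[single]
        tgt_chrom[sel] = tchrom[k[single]]
        tgt_start[sel] = lo[single]
        tgt_end[sel] = hi[single]
        reverse[sel] = neg[k[single]]
        mapped[sel] = True

        # slow path: bins spanning indel gaps (few)
        for pos in np.nonzero(has_seg & ~single)[0]:
            s, e = int(b_starts[pos]), int(b_ends[pos])
            los, his = [], []
            for j in range(i0[pos], i1[pos]):
                a_, b_ = max(s, ss[j]), min(e, se[j])
                if neg[j]:
                    los.append(te[j] - (b_ - ss[j]))
                    his.append(te[j] - (a_ - ss[j]))
                else:
                    los.append(ts[j] + (a_ - ss[j]))
                    his.append(ts[j] + (b_ - ss[j]))
            i = rows[pos]
            tgt_chrom[i] = tchrom[i0[pos]]
            tgt_start[i], tgt_end[i] = min(los), max(his)
            reverse[i] = bool(neg[i0[pos]])
            mapped[i] = True

    n_snps, n_indels, max_len = _count_variants_per_bin(bins, variants, bin_size)
    status = np.where(
        ~mapped,
        "unmapped",
        np.where(
            (n_snps == 0) & (n_indels == 0),
            "shared_exact",
            np.where(n_indels == 0, "shared_snp", "shared_indel"),
        ),
    )
    out = bins.copy()
    out["tgt_chrom"] = tgt_chrom
    out["tgt_start"] = tgt_start
    out["tgt_end"] = tgt_end
    out["reverse"] = reverse
    out["n_snps"] = n_snps
    out["n_indels"] = n_indels
    out["max_indel_len"] = max_len
    out["status"] = status
    out.loc[~mapped, ["tgt_chrom"]] = None
    return out[MAPPING_COLS]


def filter_shared(
    mappings: pd.DataFrame,
    max_indels: int = 4,
    max_indel_len: int = 20,
) -> pd.DataFrame:
    """Finalise shared space: mapped bins exceeding the indel limits are
    marked excluded (at most ``max_indels`` events, each <= ``max_indel_len``
    bp)."""
    out = mappings.copy()
    mapped = out["status"] != "unmapped"
    bad = mapped & (
        (out["n_indels"] > max_indels) | (out["max_indel_len"] > max_indel_len)
    )
    out.loc[bad, "status"] = "excluded"
    return out


def shared_space_summary(
    mappings_by_contrast: dict[str, pd.DataFrame],
    chrom_sizes: dict[str, int],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-bin shared-genotype counts and per-contrast shared/nonshared bp.

    All contrasts must use the same source-bin tiling. Returns
    ``(per_bin, per_contrast)`` where per_bin carries an integer 0..k count
    of contrasts sharing each bin, and per_contrast carries shared_bp,
    nonshared_bp and genome_bp (which sum exactly).
    """
    genome_bp = int(sum(chrom_sizes.values()))
    items = list(mappings_by_contrast.items())
    if not items:
        raise ValueError("no contrasts provided")
    base = items[0][1][["chrom", "start", "end"]]
    counts = np.zeros(len(base), dtype=np.int64)
    rows = []
    for name, mp in items:
        if len(mp) != len(base) or not (
            mp["chrom"].to_numpy() == base["chrom"].to_numpy()
        ).all() or not (mp["start"].to_numpy() == base["start"].to_numpy()).all():
            raise ValueError(f"contrast {name} uses a different source tiling")
        shared = mp["status"].isin(SHARED_STATUSES).to_numpy()
        counts += shared
        shared_bp = int((mp.loc[shared, "end"] - mp.loc[shared, "start"]).sum())
        rows.append((name, shared_bp, genome_bp - shared_bp, genome_bp))
    per_bin = base.copy()
    per_bin["n_shared_genotypes"] = counts
    per_contrast = pd.DataFrame(
        rows, columns=["contrast", "shared_bp", "nonshared_bp", "genome_bp"]
    )
    return per_bin, per_contrast
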