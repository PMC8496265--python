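"""Generate paired synthetic genomes with planted epigenomic truth.

The generator emulates a pair of inbred genome assemblies (a "source" and a
"target" genotype) with:

* shared and nonshared sequence space (alternating syntenic chains and
  genotype-specific blocks, with small indels inside shared chains);
* a methylation-domain mosaic (heterochromatin background with RdDM,
  CG-only and intermediate patches) realised as per-cytosine beta-binomial
  read counts at configurable coverage and dispersion;
* planted UMRs of each stability class — identical, partial (boundaries
  shifted by 1-5 bins) and polymorphic with a designated methylated domain
  (CHH/RdDM, CG+CHG heterochromatin, or CG-only);
* Tn5 insertion pileups (discretised Gaussians) inside a subset of planted
  UMRs, plus uniform background insertions and MACS2-like candidate peaks;
* SNP/indel fields with optional near-zero-SNP IBS blocks;
* genes whose TSS sits next to planted UMRs, with an expression summary
  table drawn per designated expression class.

Every planted feature is recorded in a machine-readable truth table so the
full pipeline can be scored against it.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from . import io as pio
from .config import CONTEXTS, ThresholdConfig
from .crossmap import SEGMENT_COLS, SyntenyMap, target_bin_of

BIN = 100

#: Mean methylation level per (domain, context); fractions in [0, 1].
DEFAULT_DOMAIN_LEVELS: dict[str, tuple[float, float, float]] = {
    # (CG, CHG, CHH)
    "heterochromatin": (0.90, 0.85, 0.05),
    "rddm": (0.80, 0.70, 0.25),
    "cg_only": (0.80, 0.03, 0.03),
    "unmethylated": (0.02, 0.02, 0.02),
    "intermediate": (0.25, 0.20, 0.05),
}

#: Cytosine sites per bp per context, both strands pooled (CG/CHG sparse,
#: CHH dense, roughly maize-like).
DEFAULT_SITE_DENSITY: dict[str, float] = {"CG": 0.08, "CHG": 0.08, "CHH": 0.20}

DEFAULT_BACKGROUND_WEIGHTS: dict[str, float] = {
    "heterochromatin": 0.70, "rddm": 0.10, "cg_only": 0.10, "intermediate": 0.10,
}

DEFAULT_EXPRESSION_PROBS: dict[str, float] = {
    "de_higher_A": 0.20, "de_higher_B": 0.20,
    "expressed_not_de": 0.40, "silent": 0.20,
}

TRUTH_COLS = [
    "feature_id", "chrom", "start", "end", "tgt_chrom", "tgt_start", "tgt_end",
    "category", "polymorphic_type", "acr_status", "gene_id", "expression_class",
]


@dataclass
class SimConfig:
    """Study conditions for one synthetic genome pair.

    Defaults describe two 5-Mb chromosomes with 100 planted UMRs across the
    five stability classes, 20x mean coverage and beta-binomial dispersion
    0.02. ``dispersion=0`` switches to fully deterministic expected counts
    (the zero-noise fixed point).
    """

    seed: int = 0
    n_chroms: int = 2
    chrom_bp: int = 5_000_000
    shared_fraction: float = 0.8
    # planted UMR counts per stability class
    n_identical: int = 30
    n_partial: int = 30
    n_polymorphic_chh: int = 14
    n_polymorphic_cg_chg: int = 13
    n_polymorphic_cg_only: int = 13
    umr_bins_min: int = 4
    umr_bins_max: int = 12
    partial_shift_max: int = 5
    # read model
    coverage_mean: float = 20.0
    dispersion: float = 0.02
    site_density: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_SITE_DENSITY))
    domain_levels: Mapping[str, tuple[float, float, float]] = field(
        default_factory=lambda: dict(DEFAULT_DOMAIN_LEVELS))
    background_weights: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_BACKGROUND_WEIGHTS))
    patch_mean_bins: float = 10.0
    # variants
    snp_rate: float = 5e-3          # per bp, outside IBS blocks
    ibs_snp_rate: float = 5e-5      # per bp inside IBS blocks
    indel_rate: float = 2e-4        # events per bp inside shared chains
    indel_len_mean: float = 4.0     # geometric mean length, capped at 20
    long_indel_fraction: float = 0.03  # events drawn 21-60 bp instead
    ibs_blocks: tuple[tuple[int, int, int], ...] = ()  # (chrom idx, start, end)
    # ATAC
    acr_fraction: float = 0.4       # planted UMRs carrying a source pileup
    stable_acr_fraction: float = 0.8  # of those, fraction also accessible in target
    target_only_acr_fraction: float = 0.1  # of non-accessible UMRs
    atac_background_rate: float = 0.01  # insertions per bp
    atac_pileup_n: int = 300
    atac_pileup_sd: float = 50.0
    # genes / expression
    background_genes_per_chrom: int = 10
    expression_class_probs: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_EXPRESSION_PROBS))
    genotypes: tuple[str, str] = ("A", "B")

    def planted_counts(self) -> dict[str, int]:
        return {
            "identical": self.n_identical,
            "partial": self.n_partial,
            "polymorphic:chh": self.n_polymorphic_chh,
            "polymorphic:cg_chg": self.n_polymorphic_cg_chg,
            "polymorphic:cg_only": self.n_polymorphic_cg_only,
        }

    def validate(self) -> None:
        if self.chrom_bp % BIN:
            raise ValueError("chrom_bp must be a multiple of the bin size")
        if not 0 < self.shared_fraction <= 1:
            raise ValueError("shared_fraction must be in (0, 1]")
        if self.umr_bins_min < 3:
            raise ValueError("planted UMRs must span >= 3 bins (>= 300 bp)")
        total = sum(self.planted_counts().values())
        footprint = total * (self.umr_bins_max * BIN + 6000)
        usable = self.n_chroms * self.chrom_bp * self.shared_fraction
        if footprint > 0.6 * usable:
            raise ValueError(
                f"infeasible config: {total} planted UMRs need about "
                f"{footprint/1e6:.1f} Mb of shared space but only "
                f"{usable/1e6:.1f} Mb is available"
            )


@dataclass
class SimBundle:
    """In-memory result of :func:`generate_pair` (all pipeline inputs)."""

    config: SimConfig
    chrom_sizes: dict[str, dict[str, int]]      # genotype -> chrom -> bp
    cytosines: dict[str, pd.DataFrame]          # genotype -> call table
    insertions: dict[str, pd.DataFrame]         # genotype -> Tn5 positions
    candidates: dict[str, pd.DataFrame]         # genotype -> candidate peaks
    genes: dict[str, pd.DataFrame]              # genotype -> gene models
    synteny: SyntenyMap                         # source -> target
    variants: pd.DataFrame                      # source coordinates
    expression: pd.DataFrame
    truth: pd.DataFrame


# --------------------------------------------------------------------------
# structure: shared chains, nonshared blocks, indels, SNPs
# --------------------------------------------------------------------------

def _plan_chromosome_structure(cfg: SimConfig, rng: np.random.Generator,
                               chrom_idx: int) -> dict:
    """Lay out nonshared blocks and shared stretches for one chromosome."""
    L = cfg.chrom_bp
    nonshared_bp = int(round((1 - cfg.shared_fraction) * L))
    blocks = []
    if nonshared_bp > 0:
        k = max(1, int(round(nonshared_bp / 250_000)))
        weights = rng.dirichlet(np.full(k, 5.0))
        sizes = np.maximum((weights * nonshared_bp // BIN).astype(int) * BIN, 10 * BIN)
        sector = L // (k + 1)
        prev_end = 0
        for i, size in enumerate(sizes):
            lo = (i + 1) * sector - size // 2
            start = (max(BIN, lo, prev_end + 20 * BIN) // BIN) * BIN
            end = min(start + int(size), L - BIN)
            if end > start:
                blocks.append((start, end))
                prev_end = end
    # shared stretches between nonshared blocks
    stretches = []
    pos = 0
    for bs, be in blocks:
        if bs - pos >= 20 * BIN:
            stretches.append((pos, bs))
        pos = be
    if L - pos >= 20 * BIN:
        stretches.append((pos, L))
    return {"A_only": blocks, "stretches": stretches}


def _draw_indels(cfg: SimConfig, rng: np.random.Generator, start: int, end: int,
                 forbidden: list[tuple[int, int]]) -> list[tuple[int, str, int]]:
    """Indel events (pos, kind, length) inside [start, end), avoiding
    forbidden intervals (planted-UMR footprints)."""
    n = rng.poisson(cfg.indel_rate * (end - start))
    events = []
    for _ in range(n):
        pos = int(rng.integers(start + BIN, max(start + BIN + 1, end - 100 - BIN)))
        if any(a <= pos < b for a, b in forbidden):
            continue
        if rng.random() < cfg.long_indel_fraction:
            length = int(rng.integers(21, 61))
        else:
            length = int(np.clip(rng.geometric(1.0 / cfg.indel_len_mean), 1, 20))
        kind = "ins" if rng.random() < 0.5 else "del"
        events.append((pos, kind, length))
    events.sort()
    # drop events too close together for clean segment construction
    cleaned = []
    last = -10_000
    for pos, kind, length in events:
        if pos - last < 200:
            continue
        cleaned.append((pos, kind, length))
        last = pos + (length if kind == "del" else 0)
    return cleaned


def _build_synteny(cfg: SimConfig, rng: np.random.Generator, chrom: str,
                   structure: dict, forbidden: list[tuple[int, int]]):
    """Build segments, variants and the target chromosome length."""
    segments = []
    variants = []
    b_cursor = 0
    b_only: list[tuple[int, int]] = []
    chain_n = 0
    pieces = sorted(
        [(s, e, "shared") for s, e in structure["stretches"]]
        + [(s, e, "A_only") for s, e in structure["A_only"]]
    )
    for s, e, kind in pieces:
        if kind == "A_only":
            if rng.random() < 0.5:  # matching target-only insertion
                ins = int(rng.integers(50_000, 200_000) // BIN) * BIN
                b_only.append((b_cursor, b_cursor + ins))
                b_cursor += ins
            continue
        chain_n += 1
        cid = f"{chrom}_c{chain_n}"
        indels = _draw_indels(cfg, rng, s, e, forbidden)
        a_pos = s
        for pos, ikind, length in indels:
            if pos <= a_pos or pos + length >= e:
                continue
            seg_len = pos - a_pos
            segments.append((cid, chrom, a_pos, pos, chrom, b_cursor,
                             b_cursor + seg_len, "+"))
            b_cursor += seg_len
            variants.append((chrom, pos, ikind, length))
            if ikind == "del":
                a_pos = pos + length
            else:
                a_pos = pos
                b_cursor += length
        if e > a_pos:
            segments.append((cid, chrom, a_pos, e, chrom, b_cursor,
                             b_cursor + (e - a_pos), "+"))
            b_cursor += e - a_pos
    return segments, variants, b_cursor, b_only


def _draw_snps(cfg: SimConfig, rng: np.random.Generator, chrom: str,
               chrom_idx: int, segments: list) -> list[tuple[str, int, str, int]]:
    """SNPs inside syntenic segments; rate drops inside IBS blocks."""
    ibs = [(s, e) for ci, s, e in cfg.ibs_blocks if ci == chrom_idx]
    snps = []
    for seg in segments:
        _, _, a0, a1 = seg[0], seg[1], seg[2], seg[3]
        cut = [a0]
        for s, e in ibs:
            lo, hi = max(a0, s), min(a1, e)
            if lo < hi:
                cut += [lo, hi]
        cut.append(a1)
        cut = sorted(set(cut))
        for lo, hi in zip(cut[:-1], cut[1:]):
            mid = (lo + hi) // 2
            in_ibs = any(s <= mid < e for s, e in ibs)
            rate = cfg.ibs_snp_rate if in_ibs else cfg.snp_rate
            n = rng.poisson(rate * (hi - lo))
            if n:
                pos = np.unique(rng.integers(lo, hi, size=n))
                snps.extend((chrom, int(p), "snp", 1) for p in pos)
    return snps


# --------------------------------------------------------------------------
# methylation mosaic and planted UMRs
# --------------------------------------------------------------------------

def _background_mosaic(cfg: SimConfig, rng: np.random.Generator, n_bins: int) -> np.ndarray:
    labels = list(cfg.background_weights)
    probs = np.array([cfg.background_weights[k] for k in labels], dtype=float)
    probs /= probs.sum()
    out = np.empty(n_bins, dtype=object)
    i = 0
    while i < n_bins:
        lbl = labels[int(rng.choice(len(labels), p=probs))]
        run = int(rng.geometric(1.0 / cfg.patch_mean_bins))
        out[i: i + run] = lbl
        i += run
    return out


def _place_planted(cfg: SimConfig, rng: np.random.Generator,
                   structures: dict[str, dict]) -> list[dict]:
    """Choose coordinates and classes for all planted UMRs."""
    classes = []
    for cls, n in cfg.planted_counts().items():
        classes += [cls] * n
    rng.shuffle(classes)
    chrom_names = list(structures)
    placements: list[dict] = []
    occupied: dict[str, list[tuple[int, int]]] = {c: [] for c in chrom_names}
    margin = 2000   # from shared-stretch edges
    spacing = 3000  # between planted features
    for idx, cls in enumerate(classes):
        n_bins = int(rng.integers(cfg.umr_bins_min, cfg.umr_bins_max + 1))
        span = n_bins * BIN
        for _ in range(500):
            chrom = chrom_names[int(rng.integers(len(chrom_names)))]
            stretches = structures[chrom]["stretches"]
            s0, s1 = stretches[int(rng.integers(len(stretches)))]
            lo, hi = s0 + margin, s1 - margin - span
            if hi <= lo:
                continue
            start = int(rng.integers(lo, hi) // BIN) * BIN
            end = start + span
            if any(a - spacing < end and start < b + spacing
                   for a, b in occupied[chrom]):
                continue
            occupied[chrom].append((start, end))
            placements.append(
                {"feature_id": f"umr_{idx:04d}", "chrom": chrom,
                 "start": start, "end": end, "class": cls}
            )
            break
        else:
            raise ValueError(
                "infeasible config: could not place all planted UMRs "
                "(genome too small for the requested counts and spacing)"
            )
    return placements


def _project_bins(synteny: SyntenyMap, chrom: str, start: int, end: int) -> list[int]:
    """Target bins (max-overlap rule) of each source bin in [start, end)."""
    bins = []
    for b in range(start, end, BIN):
        proj = synteny.project_interval(chrom, b, b + BIN)
        if proj is None:
            raise RuntimeError("planted UMR fell outside synteny; placement bug")
        _, t0, t1, _ = proj
        bins.append(target_bin_of(t0, t1, BIN))
    return bins


# --------------------------------------------------------------------------
# read-count realisation
# --------------------------------------------------------------------------

def _simulate_cytosines(cfg: SimConfig, rng: np.random.Generator,
                        chrom: str, length: int, labels: np.ndarray) -> pd.DataFrame:
    """Per-cytosine beta-binomial counts from a per-bin domain label array."""
    level_table = {
        lbl: dict(zip(CONTEXTS, lv)) for lbl, lv in cfg.domain_levels.items()
    }
    label_codes, uniq = pd.factorize(labels)
    frames = []
    for ctx in CONTEXTS:
        density = cfg.site_density[ctx]
        pos = np.nonzero(rng.random(length) < density)[0].astype(np.int64)
        if pos.size == 0:
            continue
        means = np.array([level_table[lbl][ctx] for lbl in uniq])
        p_mean = means[label_codes[np.minimum(pos // BIN, len(labels) - 1)]]
        if cfg.dispersion > 0:
            rho = cfg.dispersion
            a = p_mean * (1 - rho) / rho
            b = (1 - p_mean) * (1 - rho) / rho
            p = rng.beta(np.maximum(a, 1e-6), np.maximum(b, 1e-6))
            total = rng.poisson(cfg.coverage_mean, size=pos.size)
            meth = rng.binomial(total, p)
        else:
            total = np.full(pos.size, int(round(cfg.coverage_mean)), dtype=np.int64)
            meth = np.rint(total * p_mean).astype(np.int64)
        frames.append(
            pd.DataFrame(
                {
                    "chrom": chrom, "pos": pos,
                    "strand": np.where(pos % 2 == 0, "+", "-"),
                    "context": ctx, "meth_reads": meth, "total_reads": total,
                }
            )
        )
    if not frames:
        return pd.DataFrame(
            columns=["chrom", "pos", "strand", "context", "meth_reads", "total_reads"]
        )
    out = pd.concat(frames, ignore_index=True)
    return out.sort_values(["pos", "context"], kind="mergesort").reset_index(drop=True)


# --------------------------------------------------------------------------
# generate_pair
# --------------------------------------------------------------------------

def generate_pair(cfg: SimConfig) -> SimBundle:
    """Generate one synthetic genome pair with planted truth.

    Deterministic under a fixed ``cfg.seed``; see the module docstring for
    what is emulated.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    g_src, g_tgt = cfg.genotypes
    chrom_names = [f"chr{i + 1}" for i in range(cfg.n_chroms)]

    # 1) structure per chromosome
    structures = {
        chrom: _plan_chromosome_structure(cfg, rng, i)
        for i, chrom in enumerate(chrom_names)
    }

    # 2) planted UMR placement (before indels so footprints stay indel-free)
    placements = _place_planted(cfg, rng, structures)
    forbidden = {
        chrom: [(p["start"] - 500, p["end"] + 500)
                for p in placements if p["chrom"] == chrom]
        for chrom in chrom_names
    }

    # 3) synteny + variants
    all_segments, all_variants = [], []
    tgt_sizes: dict[str, int] = {}
    b_only_by_chrom: dict[str, list[tuple[int, int]]] = {}
    for i, chrom in enumerate(chrom_names):
        segs, indels, b_len, b_only = _build_synteny(
            cfg, rng, chrom, structures[chrom], forbidden[chrom]
        )
        snps = _draw_snps(cfg, rng, chrom, i, segs)
        all_segments += segs
        all_variants += indels
        all_variants += snps
        tgt_sizes[chrom] = b_len
        b_only_by_chrom[chrom] = b_only
    synteny = SyntenyMap(pd.DataFrame(all_segments, columns=SEGMENT_COLS))
    variants = pd.DataFrame(all_variants, columns=["chrom", "pos", "kind", "length"])
    variants = variants.sort_values(["chrom", "pos"], kind="mergesort").reset_index(drop=True)

    src_sizes = {chrom: cfg.chrom_bp for chrom in chrom_names}

    # 4) source domain mosaic + planted UMRs
    src_labels: dict[str, np.ndarray] = {}
    for chrom in chrom_names:
        arr = _background_mosaic(cfg, rng, cfg.chrom_bp // BIN)
        src_labels[chrom] = arr
    for p in placements:
        arr = src_labels[p["chrom"]]
        arr[p["start"] // BIN: p["end"] // BIN] = "unmethylated"
        # planted UMRs abut dense methylation so their boundaries are crisp
        for b in range(p["start"] // BIN - 2, p["start"] // BIN):
            if b >= 0:
                arr[b] = "heterochromatin"
        for b in range(p["end"] // BIN, p["end"] // BIN + 2):
            if b < len(arr):
                arr[b] = "heterochromatin"

    # 5) target mosaic: back-project source labels, then apply class edits
    tgt_labels: dict[str, np.ndarray] = {}
    inv = synteny.invert()
    for chrom in chrom_names:
        n_bins = max(1, tgt_sizes[chrom] // BIN + (1 if tgt_sizes[chrom] % BIN else 0))
        arr = np.empty(n_bins, dtype=object)
        arr[:] = None
        seg = inv.segments[inv.segments["src_chrom"] == chrom]
        src_arr = src_labels[chrom]
        for s in seg.itertuples(index=False):
            b0 = s.src_start // BIN
            b1 = (s.src_end - 1) // BIN + 1
            for b in range(b0, min(b1, n_bins)):
                mid = b * BIN + BIN // 2
                if not (s.src_start <= mid < s.src_end):
                    continue
                if s.strand == "+":
                    a_pos = s.tgt_start + (mid - s.src_start)
                else:
                    a_pos = s.tgt_end - 1 - (mid - s.src_start)
                arr[b] = src_arr[min(a_pos // BIN, len(src_arr) - 1)]
        # genotype-specific insertions get their own mosaic
        for b0_bp, b1_bp in b_only_by_chrom[chrom]:
            lo, hi = b0_bp // BIN, min(b1_bp // BIN, n_bins)
            arr[lo:hi] = _background_mosaic(cfg, rng, hi - lo)
        # fill unassigned bins (small insertion gaps) from the left neighbour
        last = "heterochromatin"
        for b in range(n_bins):
            if arr[b] is None:
                arr[b] = last
            else:
                last = arr[b]
        tgt_labels[chrom] = arr

    truth_rows = []
    for p in placements:
        chrom = p["chrom"]
        proj = _project_bins(synteny, chrom, p["start"], p["end"])
        arr = tgt_labels[chrom]
        proj_set = sorted(set(proj))
        t_lo, t_hi = proj_set[0], proj_set[-1] + BIN
        cls = p["class"]
        n = len(proj_set)
        if cls == "identical":
            for b in proj_set:
                arr[b // BIN] = "unmethylated"
            b_start, b_end = t_lo, t_hi
        elif cls == "partial":
            max_c = min(cfg.partial_shift_max, (n - 1) // 2)
            while True:
                if max_c >= 1 and rng.random() < 0.4:
                    dl = -int(rng.integers(1, max_c + 1))  # contract left
                    dr = 0
                else:
                    dl = 0
                    dr = int(rng.integers(1, cfg.partial_shift_max + 1))  # extend right
                    if rng.random() < 0.5:
                        dl, dr = dr, dl  # extend left instead
                nb_lo = t_lo - dl * BIN  # dl>0 extends left, dl<0 contracts
                nb_hi = t_hi + dr * BIN
                if (nb_hi - nb_lo) // BIN >= 3 and (nb_lo, nb_hi) != (t_lo, t_hi):
                    break
            for b in range(nb_lo, nb_hi, BIN):
                if 0 <= b // BIN < len(arr):
                    arr[b // BIN] = "unmethylated"
            for b in proj_set:  # contracted bins revert to methylated
                if not (nb_lo <= b < nb_hi):
                    arr[b // BIN] = "heterochromatin"
            b_start, b_end = nb_lo, nb_hi
        else:  # polymorphic:<type>
            ptype = cls.split(":")[1]
            domain = {"chh": "rddm", "cg_chg": "heterochromatin",
                      "cg_only": "cg_only"}[ptype]
            k = max(int(np.floor(0.85 * n)), n // 2 + 1)
            chosen = rng.choice(n, size=k, replace=False)
            for j, b in enumerate(proj_set):
                arr[b // BIN] = domain if j in set(chosen.tolist()) else "unmethylated"
            b_start, b_end = t_lo, t_hi
        # guard: bins flanking the planted target feature stay densely
        # methylated so called boundaries match the planted ones
        for b in (b_start - 2 * BIN, b_start - BIN, b_end, b_end + BIN):
            j = b // BIN
            if 0 <= j < len(arr):
                arr[j] = "heterochromatin"
        p["tgt_start"], p["tgt_end"] = int(b_start), int(b_end)
        p["proj_lo"], p["proj_hi"] = int(t_lo), int(t_hi)

    # 6) ATAC insertions, candidates, truth ACR status
    insertions = {g: [] for g in cfg.genotypes}
    candidates = {g: [] for g in cfg.genotypes}
    for g, sizes in ((g_src, src_sizes), (g_tgt, tgt_sizes)):
        for chrom, L in sizes.items():
            n_bg = rng.poisson(cfg.atac_background_rate * L)
            pos = rng.integers(0, L, size=n_bg)
            insertions[g].append(pd.DataFrame({"chrom": chrom, "pos": pos}))

    def _pileup(g: str, chrom: str, center: int, L: int) -> None:
        pos = np.clip(
            np.rint(rng.normal(center, cfg.atac_pileup_sd, cfg.atac_pileup_n)),
            0, L - 1,
        ).astype(np.int64)
        insertions[g].append(pd.DataFrame({"chrom": chrom, "pos": pos}))
        candidates[g].append(
            (chrom, max(0, center - 750), min(L, center + 750))
        )

    for p in placements:
        chrom = p["chrom"]
        src_mid = (p["start"] + p["end"]) // 2
        tgt_mid = (p["tgt_start"] + p["tgt_end"]) // 2
        polymorphic = p["class"].startswith("polymorphic")
        if rng.random() < cfg.acr_fraction:
            _pileup(g_src, chrom, src_mid, src_sizes[chrom])
            if not polymorphic and rng.random() < cfg.stable_acr_fraction:
                _pileup(g_tgt, chrom, tgt_mid, tgt_sizes[chrom])
                p["acr_status"] = "stable_acr"
            else:
                p["acr_status"] = "source_only_acr"
        elif not polymorphic and rng.random() < cfg.target_only_acr_fraction:
            _pileup(g_tgt, chrom, tgt_mid, tgt_sizes[chrom])
            p["acr_status"] = "target_only_acr"
        else:
            p["acr_status"] = "no_acr"

    # a few signal-free background candidates exercise the ACR filters
    for g, sizes in ((g_src, src_sizes), (g_tgt, tgt_sizes)):
        for chrom, L in sizes.items():
            for _ in range(3):
                c = int(rng.integers(1000, L - 1000))
                candidates[g].append((chrom, c - 500, c + 500))

    insertions = {
        g: pd.concat(v, ignore_index=True).sort_values(["chrom", "pos"]).reset_index(drop=True)
        for g, v in insertions.items()
    }
    candidates = {
        g: pd.DataFrame(v, columns=["chrom", "start", "end"])
        .sort_values(["chrom", "start"]).reset_index(drop=True)
        for g, v in candidates.items()
    }

    # 7) genes + expression
    gene_rows = {g: [] for g in cfg.genotypes}
    expr_rows = []
    classes = list(cfg.expression_class_probs)
    probs = np.array([cfg.expression_class_probs[c] for c in classes], dtype=float)
    probs /= probs.sum()
    for p in placements:
        chrom = p["chrom"]
        gid = f"gene_{p['feature_id']}"
        offset = int(rng.integers(0, 150))
        a_start = p["end"] + offset
        a_end = a_start + int(rng.integers(2000, 4000))
        gene_rows[g_src].append((gid, chrom, a_start, min(a_end, src_sizes[chrom]),
                                 "+", a_start))
        proj = synteny.project_interval(chrom, a_start, min(a_end, src_sizes[chrom]))
        if proj is not None:
            _, t0, t1, _ = proj
            gene_rows[g_tgt].append((gid, chrom, t0, t1, "+", t0))
        ecls = classes[int(rng.choice(len(classes), p=probs))]
        expr_rows.append(_draw_expression(rng, gid, ecls))
        p["gene_id"], p["expression_class"] = gid, ecls
    for g, sizes in ((g_src, src_sizes), (g_tgt, tgt_sizes)):
        for chrom, L in sizes.items():
            for j in range(cfg.background_genes_per_chrom):
                s = int(rng.integers(0, L - 5000))
                e = s + int(rng.integers(1500, 4000))
                strand = "+" if rng.random() < 0.5 else "-"
                tss = s if strand == "+" else e - 1
                gid = f"bg_{g}_{chrom}_{j}"
                gene_rows[g].append((gid, chrom, s, e, strand, tss))
                ecls = classes[int(rng.choice(len(classes), p=probs))]
                expr_rows.append(_draw_expression(rng, gid, ecls))
    genes = {
        g: pd.DataFrame(v, columns=["gene_id", "chrom", "start", "end", "strand", "tss"])
        .sort_values(["chrom", "start"]).reset_index(drop=True)
        for g, v in gene_rows.items()
    }
    expression = pd.DataFrame(
        expr_rows, columns=["gene_id", "mean_a", "mean_b", "log2fc", "p_value"]
    )

    # 8) cytosine tables
    cytosines = {}
    cytosines[g_src] = pd.concat(
        [_simulate_cytosines(cfg, rng, c, src_sizes[c], src_labels[c])
         for c in chrom_names], ignore_index=True,
    )
    cytosines[g_tgt] = pd.concat(
        [_simulate_cytosines(cfg, rng, c, tgt_sizes[c], tgt_labels[c])
         for c in chrom_names], ignore_index=True,
    )

    truth_rows = [
        (
            p["feature_id"], p["chrom"], p["start"], p["end"], p["chrom"],
            p["tgt_start"], p["tgt_end"],
            p["class"].split(":")[0],
            p["class"].split(":")[1] if ":" in p["class"] else "unset",
            p["acr_status"], p["gene_id"], p["expression_class"],
        )
        for p in placements
    ]
    truth = pd.DataFrame(truth_rows, columns=TRUTH_COLS).sort_values(
        ["chrom", "start"]).reset_index(drop=True)

    return SimBundle(
        config=cfg,
        chrom_sizes={g_src: src_sizes, g_tgt: tgt_sizes},
        cytosines=cytosines,
        insertions=insertions,
        candidates=candidates,
        genes=genes,
        synteny=synteny,
        variants=variants,
        expression=expression,
        truth=truth,
    )


def _draw_expression(rng: np.random.Generator, gene_id: str, cls: str) -> tuple:
    if cls == "silent":
        a = float(rng.uniform(0.05, 0.8))
        b = float(rng.uniform(0.05, 0.8))
        return (gene_id, a, b, float(np.log2((a + 0.01) / (b + 0.01))),
                float(rng.uniform(0.2, 0.9)))
    if cls == "de_higher_A":
        a = float(rng.uniform(10, 100))
        lfc = float(rng.uniform(2.5, 6.0))
        return (gene_id, a, a / 2 ** lfc, lfc, float(10 ** -rng.uniform(2, 6)))
    if cls == "de_higher_B":
        b = float(rng.uniform(10, 100))
        lfc = float(rng.uniform(2.5, 6.0))
        return (gene_id, b / 2 ** lfc, b, -lfc, float(10 ** -rng.uniform(2, 6)))
    a = float(rng.uniform(2, 50))
    u = float(rng.uniform(-1, 1))
    return (gene_id, a, a * 2 ** -u, u, float(rng.uniform(0.1, 0.9)))


# --------------------------------------------------------------------------
# fixtures on disk
# --------------------------------------------------------------------------

def write_fixture(bundle: SimBundle, directory: str | Path) -> dict[str, str]:
    """Write every pipeline input of a bundle to ``directory``.

    Returns the manifest (relative path -> sha256) which is also written as
    manifest.json.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    g_src, g_tgt = bundle.config.genotypes
    for g in bundle.config.genotypes:
        pio.write_methratio(bundle.cytosines[g], directory / f"{g}_cytosines.tsv")
        pio.write_insertions(bundle.insertions[g], directory / f"{g}_insertions.bed")
        pio.write_bed3(bundle.candidates[g], directory / f"{g}_candidates.bed")
        pio.write_gff3_genes(bundle.genes[g], directory / f"{g}_genes.gff3")
        pio.write_chrom_sizes(bundle.chrom_sizes[g], directory / f"{g}_chrom_sizes.tsv")
    pio.write_blocks_tsv(bundle.synteny, directory / "synteny_blocks.tsv")
    pio.write_chain(
        bundle.synteny, bundle.chrom_sizes[g_src], bundle.chrom_sizes[g_tgt],
        directory / "synteny.chain",
    )
    pio.write_variants(bundle.variants, directory / "variants.tsv")
    pio.write_expression(bundle.expression, directory / "expression.tsv")
    bundle.truth.to_csv(directory / "truth.tsv", sep="\t", index=False)
    with open(directory / "sim_config.json", "w") as fh:
        json.dump(dataclasses.asdict(bundle.config), fh, indent=1, default=list)
    manifest = {}
    for f in sorted(directory.iterdir()):
        if f.name == "manifest.json" or f.is_dir():
            continue
        manifest[f.name] = hashlib.sha256(f.read_bytes()).hexdigest()
    with open(directory / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return manifest


def load_fixture(directory: str | Path, cfg: SimConfig | None = None) -> SimBundle:
    """Read a written fixture back into a SimBundle (round-trip of
    :func:`write_fixture`)."""
    directory = Path(directory)
    if cfg is None:
        with open(directory / "sim_config.json") as fh:
            raw = json.load(fh)
        raw["genotypes"] = tuple(raw["genotypes"])
        raw["ibs_blocks"] = tuple(tuple(b) for b in raw["ibs_blocks"])
        raw["domain_levels"] = {k: tuple(v) for k, v in raw["domain_levels"].items()}
        cfg = SimConfig(**raw)
    g_src, g_tgt = cfg.genotypes
    chrom_sizes, cytosines, insertions, candidates, genes = {}, {}, {}, {}, {}
    for g in cfg.genotypes:
        chrom_sizes[g] = pio.read_chrom_sizes(directory / f"{g}_chrom_sizes.tsv")
        cytosines[g] = pio.read_methratio(directory / f"{g}_cytosines.tsv")
        insertions[g] = pio.read_insertions(directory / f"{g}_insertions.bed")
        candidates[g] = pio.read_bed3(directory / f"{g}_candidates.bed")
        genes[g] = pio.read_gff3_genes(directory / f"{g}_genes.gff3")
    return SimBundle(
        config=cfg,
        chrom_sizes=chrom_sizes,
        cytosines=cytosines,
        insertions=insertions,
        candidates=candidates,
        genes=genes,
        synteny=pio.read_blocks_tsv(directory / "synteny_blocks.tsv"),
        variants=pio.read_variants(directory / "variants.tsv"),
        expression=pio.read_expression(directory / "expression.tsv"),
        truth=pd.read_csv(directory / "truth.tsv", sep="\t"),
    )


# --------------------------------------------------------------------------
# truth scoring
# --------------------------------------------------------------------------

def evaluate_recovery(truth: pd.DataFrame, comparisons: pd.DataFrame) -> dict:
    """Score pipeline comparisons against the planted truth table.

    Each planted UMR is matched to the comparison row with maximal source-
    interval overlap. Returns category recovery (all planted), polymorphic-
    type recovery (planted polymorphic only) and the matched table.
    """
    matched = []
    for t in truth.itertuples(index=False):
        sub = comparisons[comparisons["chrom"] == t.chrom]
        ov = np.minimum(sub["end"], t.end) - np.maximum(sub["start"], t.start)
        if len(sub) == 0 or ov.max() <= 0:
            matched.append((t.feature_id, t.category, t.polymorphic_type,
                            "not_recovered", "unset"))
            continue
        row = sub.loc[ov.idxmax()]
        matched.append((t.feature_id, t.category, t.polymorphic_type,
                        row["category"], row["polymorphic_type"]))
    df = pd.DataFrame(
        matched,
        columns=["feature_id", "true_category", "true_type",
                 "called_category", "called_type"],
    )
    cat_ok = (df["true_category"] == df["called_category"]).mean()
    poly = df[df["true_category"] == "polymorphic"]
    type_ok = (
        (poly["true_type"] == poly["called_type"]).mean() if len(poly) else np.nan
    )
    return {
        "category_recovery": float(cat_ok),
        "type_recovery": float(type_ok) if not np.isnan(type_ok) else np.nan,
        "n_planted": len(df),
        "n_polymorphic_planted": len(poly),
        "matched": df,
    }
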