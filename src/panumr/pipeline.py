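"""End-to-end orchestration: bins -> UMRs/ACRs -> crossmap -> IBS/DMTs ->
comparison -> report.

:func:`run_bundle` drives the whole analysis on an in-memory input bundle;
:func:`run_all` is its file-based counterpart reading a fixture directory
and writing every stage output plus a manifest with the config hash.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as pio
from .acr_caller import call_acrs, classify_umr_accessibility
from .comparative import attribute_dmts, compare_umrs, link_expression
from .config import ThresholdConfig
from .crossmap import SyntenyMap, filter_shared, map_bins, shared_space_summary
from .dmt_caller import call_dmts, make_dmt_tiles
from .ibs_detector import call_ibs, snp_density_windows
from .methylome_bins import classify_bins, summarize_bins
from .umr_caller import call_umrs, classify_umr_location

logger = logging.getLogger(__name__)

STAGES = ("bins", "umrs", "acrs", "crossmap", "ibs", "dmts", "compare", "report")

STAGE_DEPS = {
    "bins": (),
    "umrs": ("bins",),
    "acrs": (),
    "crossmap": (),
    "ibs": ("crossmap",),
    "dmts": ("bins", "crossmap"),
    "compare": ("umrs", "acrs", "crossmap"),
    "report": ("compare", "dmts", "ibs"),
}


@dataclass
class RunConfig:
    """File-based run description (paths resolved against fixture_dir)."""

    fixture_dir: str | Path
    outdir: str | Path
    thresholds: ThresholdConfig = field(default_factory=ThresholdConfig)
    source: str = "A"
    target: str = "B"
    stages: tuple[str, ...] = STAGES


@dataclass
class Results:
    """All stage outputs of one in-memory run."""

    bin_stats: dict[str, pd.DataFrame]
    tracks: dict[str, pd.DataFrame]
    umrs: dict[str, pd.DataFrame]
    acrs: dict[str, pd.DataFrame]
    mappings: pd.DataFrame
    shared_summary: pd.DataFrame
    ibs: pd.DataFrame
    dmts: pd.DataFrame
    comparisons: pd.DataFrame
    report: dict[str, pd.DataFrame]


def run_bundle(bundle, cfg: ThresholdConfig | None = None) -> Results:
    """Run the full pipeline on a :class:`~panumr.synthetic_data.SimBundle`
    (or any object with the same attributes)."""
    cfg = cfg or ThresholdConfig()
    g_src, g_tgt = bundle.config.genotypes

    bin_stats, tracks, umrs, acrs = {}, {}, {}, {}
    for g in (g_src, g_tgt):
        sizes = bundle.chrom_sizes[g]
        logger.info("[bins] %s: %d cytosine calls", g, len(bundle.cytosines[g]))
        bin_stats[g] = summarize_bins(bundle.cytosines[g], sizes, cfg.bin_size)
        tracks[g] = classify_bins(bin_stats[g], cfg)
        u = call_umrs(tracks[g], cfg)
        u = classify_umr_location(u, bundle.genes[g], cfg.proximal_bp)
        a = call_acrs(
            bundle.insertions[g], bundle.candidates[g],
            int(sum(sizes.values())), cfg,
        )
        umrs[g] = classify_umr_accessibility(u, a)
        acrs[g] = a
        logger.info("[umrs/acrs] %s: %d UMRs, %d ACRs", g, len(u), len(a))

    mappings = filter_shared(
        map_bins(bundle.chrom_sizes[g_src], bundle.synteny, bundle.variants,
                 cfg.bin_size),
        cfg.max_indels, cfg.max_indel_len,
    )
    _, shared_summary = shared_space_summary(
        {g_tgt: mappings}, bundle.chrom_sizes[g_src]
    )

    snps = bundle.variants[bundle.variants["kind"] == "snp"]
    ibs = call_ibs(
        snp_density_windows(snps, bundle.synteny, bundle.chrom_sizes[g_src],
                            cfg.ibs_window),
        cfg.ibs_max_density, cfg.ibs_min_span,
    )

    tiles = make_dmt_tiles(
        bin_stats[g_src], tracks[g_src], bin_stats[g_tgt], tracks[g_tgt],
        mappings, cfg.bin_size,
    )
    dmts = call_dmts(tiles, cfg)

    comparisons = compare_umrs(
        umrs[g_src], mappings, tracks[g_tgt], umrs[g_tgt], cfg,
        source_acrs=acrs[g_src], target_acrs=acrs[g_tgt],
    )
    logger.info(
        "[compare] %d source UMRs, %d DMT calls, %d IBS regions",
        len(comparisons), len(dmts), len(ibs),
    )

    report = make_report(comparisons, dmts, ibs, cfg)
    return Results(
        bin_stats=bin_stats, tracks=tracks, umrs=umrs, acrs=acrs,
        mappings=mappings, shared_summary=shared_summary, ibs=ibs, dmts=dmts,
        comparisons=comparisons, report=report,
    )


def _proportions(series: pd.Series, index: tuple[str, ...]) -> pd.Series:
    counts = series.value_counts()
    out = pd.Series(0.0, index=list(index))
    total = counts.sum()
    if total:
        for k, v in counts.items():
            out[k] = v / total
    return out


def make_report(
    comparisons: pd.DataFrame,
    dmts: pd.DataFrame,
    ibs: pd.DataFrame,
    cfg: ThresholdConfig | None = None,
) -> dict[str, pd.DataFrame]:
    """Figure-style proportion tables; every proportion row sums to 1.

    * umr_categories — stability-category proportions over all source UMRs;
    * acr_variability — ACR-class proportions per stability category;
    * dmt_attribution — hypomethylated DMT bins by UMR context;
    * ibs_categories — stability-category proportions for UMRs inside IBS
      blocks next to the genome-wide proportions.
    """
    from .config import ThresholdConfig as _T

    cfg = cfg or _T()
    categories = ("nonshared", "missing_data", "identical", "partial", "polymorphic")
    tables: dict[str, pd.DataFrame] = {}
    if comparisons.empty:
        logger.warning("empty comparison table; report tables will be empty")
        return {k: pd.DataFrame() for k in
                ("umr_categories", "acr_variability", "dmt_attribution",
                 "ibs_categories")}

    tables["umr_categories"] = _proportions(
        comparisons["category"], categories).to_frame("proportion").T

    acr_rows = {}
    for cat, grp in comparisons.groupby("category"):
        if (grp["acr_class"] == "unset").all():
            continue
        acr_rows[cat] = _proportions(
            grp["acr_class"],
            ("stable_acr", "source_only_acr", "target_only_acr", "no_acr"),
        )
    tables["acr_variability"] = pd.DataFrame(acr_rows).T

    tables["dmt_attribution"] = attribute_dmts(dmts, comparisons).to_frame("fraction").T

    if ibs is not None and not ibs.empty:
        in_ibs = np.zeros(len(comparisons), dtype=bool)
        for r in ibs.itertuples(index=False):
            in_ibs |= (
                (comparisons["chrom"] == r.chrom)
                & (comparisons["start"] >= r.start)
                & (comparisons["end"] <= r.end)
            ).to_numpy()
        rows = {"genome_wide": _proportions(comparisons["category"], categories)}
        if in_ibs.any():
            rows["ibs"] = _proportions(comparisons.loc[in_ibs, "category"], categories)
        tables["ibs_categories"] = pd.DataFrame(rows).T
    else:
        tables["ibs_categories"] = pd.DataFrame()
    return tables


def run_all(run_cfg: RunConfig) -> dict:
    """File-based end-to-end run over a fixture directory.

    Executes the requested stages in dependency order (refusing when a
    dependency is toggled off), writes every output under ``outdir`` and a
    run_manifest.json with the threshold-config hash and per-file sha256
    checksums. Rerunning with identical config and inputs reproduces
    identical checksums.
    """
    from .synthetic_data import load_fixture

    fixture = Path(run_cfg.fixture_dir)
    outdir = Path(run_cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stages = tuple(run_cfg.stages)
    for st in stages:
        missing = [d for d in STAGE_DEPS[st] if d not in stages]
        if missing:
            raise ValueError(f"stage {st!r} requires disabled stage(s) {missing}")

    if not fixture.exists():
        raise FileNotFoundError(f"fixture directory not found: {fixture}")
    for required in (f"{run_cfg.source}_cytosines.tsv", "synteny_blocks.tsv"):
        if not (fixture / required).exists():
            raise FileNotFoundError(f"[stage input] missing {fixture / required}")

    bundle = load_fixture(fixture)
    results = run_bundle(bundle, run_cfg.thresholds)

    g_src, g_tgt = bundle.config.genotypes
    for g in (g_src, g_tgt):
        if "bins" in stages:
            pio.write_bin_stats(results.bin_stats[g], outdir / f"{g}_bin_stats.tsv")
            pio.write_domain_bed(results.tracks[g], outdir / f"{g}_domains.bed")
        if "umrs" in stages:
            pio.write_umr_bed(results.umrs[g], outdir / f"{g}_umrs.bed")
        if "acrs" in stages:
            pio.write_acr_bed(results.acrs[g], outdir / f"{g}_acrs.bed")
    if "crossmap" in stages:
        results.mappings.to_csv(outdir / "bin_mappings.tsv", sep="\t", index=False)
        results.shared_summary.to_csv(outdir / "shared_space.tsv", sep="\t", index=False)
    if "ibs" in stages:
        results.ibs.to_csv(outdir / "ibs_regions.tsv", sep="\t", index=False)
    if "dmts" in stages:
        results.dmts.to_csv(outdir / "dmts.tsv", sep="\t", index=False)
    if "compare" in stages:
        results.comparisons.to_csv(outdir / "umr_comparisons.tsv", sep="\t", index=False)
    if "report" in stages:
        for name, table in results.report.items():
            table.to_csv(outdir / f"report_{name}.tsv", sep="\t", float_format="%.6g")

    manifest = {"config_hash": run_cfg.thresholds.config_hash(), "files": {}}
    for f in sorted(outdir.iterdir()):
        if f.name == "run_manifest.json" or f.is_dir():
            continue
        manifest["files"][f.name] = hashlib.sha256(f.read_bytes()).hexdigest()
    with open(outdir / "run_manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return manifest
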