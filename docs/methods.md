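# Methods

This note documents the models, thresholds and design choices behind
`panumr`, and what the synthetic-data experiments do and do not show.

## Coordinates and bins

All coordinates are 0-based half-open. Bins are 100 bp, anchored at
multiples of 100 from each chromosome start. A ragged final bin is
summarised and classified like any other but never joins a UMR, so UMR
length accounting is exact multiples of the bin size.

## Bin summarisation and domain classification

Per-cytosine counts are pooled across strands per (position, context).
The bin methylation level is read-weighted, Σmeth / Σtotal, rather than a
mean of per-site ratios: it matches the "reads per site" coverage
bookkeeping and is robust when individual sites have few reads. Every
(bin, context) pair is emitted, including empty ones (n_sites = 0, level
undefined), so downstream joins never silently drop bins.

The six-domain hierarchy is applied strictly in order (missing data →
RdDM → heterochromatin → CG-only → unmethylated → intermediate) with the
edge semantics of the original wording: strict ">" for RdDM (15%) and
CG-only (40%), "≥" for heterochromatin (40%), strict "<" for unmethylated
(10%). The missing-data gate (< 2 cytosines or < 5× coverage) uses sites
and coverage **pooled over the three contexts**; whether it should be
per-context is genuinely ambiguous, so both the scope (by construction)
and every threshold live in `ThresholdConfig`. A context with zero sites
contributes level 0 to the comparisons: absent CHH sites cannot trigger
RdDM and cannot veto an unmethylated call. A documented alternative
threshold set (unmethylated as CHH < 15% with CG/CHG < 20%) is expressible
through the same config; the defaults are the stricter all-contexts-< 10%
rule.

## UMR calling

Candidates are maximal runs of unmethylated or missing-data bins. Missing
bins are trimmed from both ends so every UMR starts and ends on an
unmethylated bin. The < 33% missing ceiling is a constraint without a
prescribed resolution procedure; this package resolves violations
deterministically by splitting the candidate at its longest internal
missing run (leftmost on ties) and re-evaluating each side recursively,
which preserves maximal unmethylated content. Survivors shorter than
300 bp are removed; the 300-bp filter counts the interval span, i.e.
tolerated missing bins count toward length.

Gene context: genic means ≥ 1 bp overlap with a gene body; proximal means
the gap to the nearest gene-body edge is ≤ 2000 bp, inclusive at exactly
2000; ties between equidistant genes do not affect the class.

## ACR post-processing

"Normalised to the average frequency in the total genome" is read as the
per-bp insertion rate times the window length (a windowed alternative
would differ only by edge effects; the per-bp reading makes the uniform
field normalise to exactly 1). The > 25-fold filter is applied per window
before merging; gaps are measured between qualifying-window edges; the
> 50 bp size filter is strict and re-applied after blacklist subtraction
(organelle homology is consumed as a blacklist BED, not recomputed).
Summits are reported as the midpoint of the max-count window (leftmost on
ties); per-base summits are available via window = 1. An ACR without any
insertion (possible only after blacklist surgery) gets its midpoint,
flagged.

## Cross-genotype mapping

The synteny map is a set of single-coverage chains of ungapped segments
(read from UCSC chain files or a simplified block TSV; building the
alignment itself is upstream). A bin is mappable when it lies entirely
within one chain's source span — block-internal indels are allowed, bins
only partially covered are unmapped (strict reading, since whole 100-bp
tiles are projected). The target interval is the hull of the projected
first and last aligned bases, so a k-bp deletion shrinks the target by k
and an insertion grows it. Reverse-strand chains report forward-strand
target coordinates with a reverse flag.

Variant counts per bin come from the variant table, not from chain gaps.
The shared-space filter keeps bins with at most 4 indel **events**, each
≤ 20 bp; the alternative reading (total indel bp) would be a config
change. When a projected interval straddles a target bin boundary the
target bin with maximal overlap is used, leftmost on ties — the same rule
everywhere (comparison, DMT tiles, generator), which keeps bin-set
identity well defined under sub-bin coordinate offsets.

## IBS detection

Windows are 1 Mb; density = SNPs / syntenic bp. Windows with no syntenic
bp have undefined density and terminate runs (absence of alignment is not
evidence of identity). Runs are maximal sequences of consecutive windows
with density strictly < 0.0005; the ≥ 5 Mb minimum applies to the run
span, not to a sliding re-evaluation. Boundaries are reported at window
edges, so planted blocks are recovered within one window of truth by
construction; projection of IBS boundaries into the contrasting genome
uses the ordinary bin mapping (a documented simplification of the
TE-anchored original).

## DMTs

Purely threshold-based, no smoothing or multiple-testing machinery:
CG/CHG calls need |Δ| ≥ 0.40 (inclusive) with min < 0.10 and max > 0.40;
CHH calls need min < 0.05 and max > 0.25 (no explicit difference clause —
the two bounds already force a gap > 0.20). Calls are restricted to
shared tiles whose domain track is not missing data in either genotype.
Swapping genotypes flips the direction and never creates or destroys a
call.

## Stability classification

Per source UMR: any member bin unmapped or excluded ⇒ *nonshared*. The
methylated-bin fraction uses target bins **with data** as denominator
(missing target bins are excluded; the original states the proportion
without a denominator rule). More than half of target bins lacking data ⇒
*missing data* (threshold configurable at 0.5). Fraction > 0.5 (strict) ⇒
*polymorphic*; the type hierarchy (CHH → CG/CHG → CG-only) takes the
first class with > 50% of methylated bins, falling back to the largest
class in the same order when none reaches a majority. Otherwise identity
is evaluated on 100-bp bin sets, not base pairs: the projected bin set
must equal the union of overlapping target-UMR bin sets to be
*identical*; any other overlap is *partial*. An overlapping UMR without
any target UMR (possible when target unmethylated bins are too scattered
to form one) is reported partial with a `no_target_umr` flag.

ACR variability is a cross of source/target ACR overlap (stable / source-
only / target-only / none); a polymorphic UMR that still overlaps a target
ACR carries an `acr_only_in_target` flag rather than forming a fifth
mutually exclusive category, since its precedence against polymorphic is
not fully specified. DMT attribution deduplicates hypomethylated-in-source
bins across contexts and assigns each to polymorphic UMR ⊃ partial UMR ⊃
other; fractions sum to 1. Expression linkage takes genes whose TSS lies
within 200 bp of a classified UMR; classes are silent (both means < 1),
DE (|log2FC| > 2, p < 0.05, direction by sign), else expressed-not-DE.
Replicate self-consistency checks use the same code path with the source
genotype as its own contrast, which is exactly identical on noise-free
tracks.

## Synthetic data generator

The generator defines the package's study conditions; defaults are two
5-Mb chromosomes, 80% shared space, 100 planted UMRs (30 identical, 30
partial, 40 polymorphic split 14/13/13 across CHH, CG/CHG and CG-only
types), 20× mean coverage and beta-binomial dispersion 0.02.

* **Structure.** Nonshared source blocks (~250 kb each) alternate with
  syntenic chains; about half the nonshared positions also receive a
  target-only insertion. Small indels (geometric lengths, mean 4 bp,
  capped at 20 bp, with 3% drawn 21–60 bp to exercise the exclusion
  filter) punctuate chains at 2 × 10⁻⁴ per bp; SNPs at 5 × 10⁻³ per bp
  outside IBS blocks and 5 × 10⁻⁵ inside. Indels are kept out of planted
  UMR footprints (± 500 bp) so planted boundaries are well defined;
  generator chains are forward-strand (reverse-strand projection is
  exercised by hand-built maps in the unit tests).
* **Methylation.** A background mosaic (heterochromatin 70%, RdDM,
  CG-only, intermediate 10% each; geometric patch lengths, mean 10 bins)
  underlies planted features. Domain mean levels: heterochromatin
  CG/CHG ≈ 0.90/0.85, RdDM CHH 0.25, CG-only CG 0.80, unmethylated 0.02.
  Cytosine densities are maize-like and strand-pooled — CG and CHG 0.08
  per bp, CHH 0.20 per bp — dense enough that a well-covered bin
  essentially never flips class through site-sampling granularity, while
  the ≥ 2-site / ≥ 5× missing-data path is still exercised by sparse tail
  bins. Planted UMRs abut two heterochromatin guard bins on each side so
  their boundaries are crisp (real UMR edges sit against dense
  methylation; without the guard, a CG-only flank that happens to draw
  zero CG sites would itself read as unmethylated and blur the planted
  boundary).
* **Read model.** Per site, p ~ Beta with mean equal to the domain level
  and dispersion ρ (Var = μ(1−μ)ρ), coverage ~ Poisson(20), methylated
  reads ~ Binomial. ρ = 0 switches to deterministic expected counts
  (fixed coverage, rounded methylated reads) — the zero-noise fixed point
  at which recovery must be exact.
* **Planted classes.** Identical UMRs occupy the max-overlap projection
  of their source bins in the target. Partial UMRs shift one boundary by
  1–5 bins (extensions, or contractions capped so the methylated fraction
  stays below the polymorphic threshold); contracted bins revert to
  heterochromatin. Polymorphic UMRs resample max(85%, majority) of their
  target bins to the designated methylated domain, the rest staying
  unmethylated.
* **ATAC.** Background insertions at 0.01 per bp; pileups are 300
  insertions drawn N(centre, 50 bp) inside 40% of planted UMRs, with 80%
  of non-polymorphic accessible UMRs also piled in the target (stable
  ACRs) and a 10% target-only rate among the rest; MACS2-like candidate
  peaks are centre ± 750 bp plus a few signal-free decoys.
* **Genes/expression.** Each planted UMR gets a downstream gene with its
  TSS within 150 bp, plus background genes; expression summaries are
  drawn per designated class (DE: |log2FC| 2.5–6 at p ≤ 10⁻²; silent:
  both means < 1; expressed: means 2–50 with |log2FC| < 1).

What passing recovery tests show — and what they do not: the synthetic
pair exercises the full decision logic (coordinate projection under
indels, threshold edges, class hierarchies, missing-data handling) under
calibrated sampling noise, so ≥ 95% category and ≥ 90% type recovery
demonstrates the pipeline's internal consistency. It does not demonstrate
performance on real WGBS/ATAC data, where alignment artefacts, repeat
mappability, conversion failure, non-stationary coverage and
strand-specific effects are all absent from the model, nor does it
validate the upstream alignment/peak-calling steps the pipeline consumes.

## Problem sizes and numerical choices

The reference acceptance run uses two 5-Mb chromosomes (≈ 3.6 M simulated
cytosines per genotype), a 30-Mb chromosome for IBS detection, and a
0.4-Mb pair for byte-identity checks; the unit-test fixtures use 0.3–1 Mb
chromosomes. All randomness flows from one `numpy` Generator per bundle,
so a seed fixes every output byte. Ties are always resolved leftmost
(summits, max-overlap bins, missing-run splits). Report proportions are
exact rational counts over pandas tables; rows sum to 1 up to float
rounding (asserted at 10⁻⁹).

## Known limitations

* TE-relative UMR classes, TE expression and tissue-specific
  accessibility are out of scope; annotations beyond gene bodies are
  consumed, not analysed.
* The shared-space filter treats the variant table as truth; chain gaps
  and variant calls are assumed consistent (the generator guarantees
  this; real inputs may not).
* Statistical DMR testing (binomial/Fisher smoothing, FDR control) is
  deliberately absent — the tile definition is threshold-based.
* `compare` assumes single-coverage synteny; overlapping chains are
  rejected rather than resolved.
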