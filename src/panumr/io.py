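"""Readers and writers for the pipeline's file formats.

Tabular formats (methratio-style cytosine tables, BED, block TSV, variant
TSV, expression TSV) go through pandas; gene annotations are read from
GFF3 via gffutils; the UCSC chain format has a small dedicated parser.
All coordinates are converted to 0-based half-open on read.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .crossmap import SEGMENT_COLS, SyntenyMap

METHRATIO_COLS = ["chr", "pos", "strand", "context", "ratio", "eff_CT", "C", "CT"]


def _require(df: pd.DataFrame, cols: list[str], path) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    if df[cols].isna().any().any():
        raise ValueError(f"{path}: malformed or truncated rows (NaN fields)")


# --- cytosine tables -------------------------------------------------------

def read_methratio(path: str | Path) -> pd.DataFrame:
    """Read a methratio-style per-cytosine table.

    Expected tab-separated columns: chr, pos, strand, context, ratio,
    eff_CT, C, CT. Returns chrom, pos, strand, context, meth_reads,
    total_reads with meth/total from the C and CT count columns.
    """
    df = pd.read_csv(path, sep="\t")
    _require(df, METHRATIO_COLS, path)
    out = pd.DataFrame(
        {
            "chrom": df["chr"].astype(str),
            "pos": df["pos"].astype(np.int64),
            "strand": df["strand"].astype(str),
            "context": df["context"].astype(str),
            "meth_reads": df["C"].astype(np.int64),
            "total_reads": df["CT"].astype(np.int64),
        }
    )
    if (out["meth_reads"] > out["total_reads"]).any():
        raise ValueError(f"{path}: methylated counts exceed total counts")
    return out


def write_methratio(calls: pd.DataFrame, path: str | Path) -> None:
    with np.errstate(invalid="ignore", divide="ignore"):
        ratio = np.where(
            calls["total_reads"] > 0,
            calls["meth_reads"] / calls["total_reads"].clip(lower=1),
            0.0,
        )
    out = pd.DataFrame(
        {
            "chr": calls["chrom"],
            "pos": calls["pos"],
            "strand": calls.get("strand", "+"),
            "context": calls["context"],
            "ratio": np.round(ratio, 4),
            "eff_CT": calls["total_reads"],
            "C": calls["meth_reads"],
            "CT": calls["total_reads"],
        }
    )
    out.to_csv(path, sep="\t", index=False)


def write_bin_stats(bin_stats: pd.DataFrame, path: str | Path) -> None:
    cols = ["chrom", "start", "end", "context", "n_sites", "coverage", "level"]
    bin_stats[cols].to_csv(path, sep="\t", index=False, float_format="%.6g")


# --- BED -------------------------------------------------------------------

def read_bed3(path: str | Path) -> pd.DataFrame:
    """Read the first three BED columns; extra columns are ignored."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    if df.shape[1] < 3:
        raise ValueError(f"{path}: BED needs at least 3 columns")
    out = df.iloc[:, :3].copy()
    out.columns = ["chrom", "start", "end"]
    _require(out, ["chrom", "start", "end"], path)
    out["chrom"] = out["chrom"].astype(str)
    out[["start", "end"]] = out[["start", "end"]].astype(np.int64)
    return out


def read_insertions(path: str | Path) -> pd.DataFrame:
    """Tn5 insertion positions from a BED-like file (pos = start)."""
    bed = read_bed3(path)
    return pd.DataFrame({"chrom": bed["chrom"], "pos": bed["start"]})


def write_insertions(insertions: pd.DataFrame, path: str | Path) -> None:
    pd.DataFrame(
        {
            "chrom": insertions["chrom"],
            "start": insertions["pos"],
            "end": insertions["pos"] + 1,
        }
    ).to_csv(path, sep="\t", header=False, index=False)


def write_bed3(df: pd.DataFrame, path: str | Path) -> None:
    df[["chrom", "start", "end"]].to_csv(path, sep="\t", header=False, index=False)


def write_umr_bed(umrs: pd.DataFrame, path: str | Path) -> None:
    """BED6: name = location class, score = 1000 * (1 - missing_fraction)."""
    out = pd.DataFrame(
        {
            "chrom": umrs["chrom"],
            "start": umrs["start"],
            "end": umrs["end"],
            "name": umrs.get("location", pd.Series("unset", index=umrs.index)),
            "score": (1000 * (1 - umrs["missing_fraction"])).round().astype(int),
            "strand": ".",
        }
    )
    out.to_csv(path, sep="\t", header=False, index=False)


def write_acr_bed(acrs: pd.DataFrame, path: str | Path) -> None:
    """BED6+1: summit offset from the interval start in column 7."""
    out = pd.DataFrame(
        {
            "chrom": acrs["chrom"],
            "start": acrs["start"],
            "end": acrs["end"],
            "name": "ACR",
            "score": acrs["max_norm_freq"].round(2),
            "strand": ".",
            "summit_offset": acrs["summit"] - acrs["start"],
        }
    )
    out.to_csv(path, sep="\t", header=False, index=False)


def write_domain_bed(track: pd.DataFrame, path: str | Path) -> None:
    """BED with the methylation-domain label in the name field."""
    out = track[["chrom", "start", "end", "label"]]
    out.to_csv(path, sep="\t", header=False, index=False)


# --- GFF3 ------------------------------------------------------------------

def read_gff3_genes(path: str | Path) -> pd.DataFrame:
    """Extract gene models from a GFF3 file.

    Returns gene_id, chrom, start (0-based), end, strand, tss — the TSS is
    the strand-aware 5' end.
    """
    import gffutils

    db = gffutils.create_db(
        str(path), ":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
    )
    rows = []
    for gene in db.features_of_type("gene"):
        start0 = gene.start - 1
        tss = start0 if gene.strand != "-" else gene.end - 1
        gid = gene.attributes.get("ID", [gene.id])[0]
        rows.append((gid, gene.seqid, start0, gene.end, gene.strand, tss))
    return pd.DataFrame(
        rows, columns=["gene_id", "chrom", "start", "end", "strand", "tss"]
    )


def write_gff3_genes(genes: pd.DataFrame, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes.itertuples(index=False):
            fh.write(
                f"{g.chrom}\tpanumr\tgene\t{g.start + 1}\t{g.end}\t.\t{g.strand}\t.\t"
                f"ID={g.gene_id}\n"
            )


# --- synteny: block TSV and UCSC chain ------------------------------------

def read_blocks_tsv(path: str | Path) -> SyntenyMap:
    df = pd.read_csv(path, sep="\t")
    _require(df, SEGMENT_COLS, path)
    return SyntenyMap(df[SEGMENT_COLS])


def write_blocks_tsv(synteny: SyntenyMap, path: str | Path) -> None:
    synteny.segments[SEGMENT_COLS].to_csv(path, sep="\t", index=False)


def write_chain(
    synteny: SyntenyMap,
    src_sizes: dict[str, int],
    tgt_sizes: dict[str, int],
    path: str | Path,
) -> None:
    """Write a UCSC chain file; the source genome is the chain 'target'
    (first) genome, following liftover convention."""
    with open(path, "w") as fh:
        for cid, grp in synteny.segments.groupby("chain_id", sort=False):
            grp = grp.sort_values("src_start")
            strand = grp["strand"].iloc[0]
            sc = grp["src_chrom"].iloc[0]
            tc = grp["tgt_chrom"].iloc[0]
            s0, s1 = int(grp["src_start"].min()), int(grp["src_end"].max())
            t0, t1 = int(grp["tgt_start"].min()), int(grp["tgt_end"].max())
            tsize = tgt_sizes[tc]
            if strand == "-":
                q0, q1 = tsize - t1, tsize - t0
            else:
                q0, q1 = t0, t1
            fh.write(
                f"chain 1000 {sc} {src_sizes[sc]} + {s0} {s1} "
                f"{tc} {tsize} {strand} {q0} {q1} {cid}\n"
            )
            rows = list(grp.itertuples(index=False))
            for i, seg in enumerate(rows):
                size = seg.src_end - seg.src_start
                if i == len(rows) - 1:
                    fh.write(f"{size}\n")
                else:
                    nxt = rows[i + 1]
                    dt = nxt.src_start - seg.src_end
                    if strand == "-":
                        # query gap in reverse-strand coordinates
                        dq = seg.tgt_start - nxt.tgt_end
                    else:
                        dq = nxt.tgt_start - seg.tgt_end
                    fh.write(f"{size}\t{dt}\t{dq}\n")
            fh.write("\n")


def read_chain(path: str | Path) -> SyntenyMap:
    """Parse a UCSC chain file into a SyntenyMap (source = first genome)."""
    segments = []
    with open(path) as fh:
        header = None
        src_pos = tgt_pos = 0
        for raw in fh:
            line = raw.strip()
            if not line:
                header = None
                continue
            if line.startswith("chain"):
                parts = line.split()
                if len(parts) != 13:
                    raise ValueError(f"{path}: malformed chain header: {line}")
                header = {
                    "src_chrom": parts[2], "src_size": int(parts[3]),
                    "src_start": int(parts[5]),
                    "tgt_chrom": parts[7], "tgt_size": int(parts[8]),
                    "strand": parts[9], "tgt_start": int(parts[10]),
                    "chain_id": parts[12],
                }
                src_pos = header["src_start"]
                tgt_pos = header["tgt_start"]
                continue
            if header is None:
                raise ValueError(f"{path}: alignment line outside a chain block")
            fields = [int(x) for x in line.split()]
            size = fields[0]
            dt, dq = (fields[1], fields[2]) if len(fields) == 3 else (0, 0)
            if header["strand"] == "-":
                t0 = header["tgt_size"] - (tgt_pos + size)
                t1 = header["tgt_size"] - tgt_pos
            else:
                t0, t1 = tgt_pos, tgt_pos + size
            segments.append(
                (
                    header["chain_id"], header["src_chrom"], src_pos, src_pos + size,
                    header["tgt_chrom"], t0, t1, header["strand"],
                )
            )
            src_pos += size + dt
            tgt_pos += size + dq
    df = pd.DataFrame(segments, columns=SEGMENT_COLS)
    return SyntenyMap(df)


# --- simple TSVs -----------------------------------------------------------

def read_variants(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    _require(df, ["chrom", "pos", "kind", "length"], path)
    bad = set(df["kind"].unique()) - {"snp", "ins", "del"}
    if bad:
        raise ValueError(f"{path}: unknown variant kinds {sorted(bad)}")
    df["chrom"] = df["chrom"].astype(str)
    df[["pos", "length"]] = df[["pos", "length"]].astype(np.int64)
    return df


def write_variants(variants: pd.DataFrame, path: str | Path) -> None:
    variants[["chrom", "pos", "kind", "length"]].to_csv(path, sep="\t", index=False)


def read_expression(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    _require(df, ["gene_id", "mean_a", "mean_b", "log2fc", "p_value"], path)
    return df


def write_expression(expression: pd.DataFrame, path: str | Path) -> None:
    expression[["gene_id", "mean_a", "mean_b", "log2fc", "p_value"]].to_csv(
        path, sep="\t", index=False, float_format="%.6g"
    )


def read_chrom_sizes(path: str | Path) -> dict[str, int]:
    df = pd.read_csv(path, sep="\t", header=None, names=["chrom", "size"])
    _require(df, ["chrom", "size"], path)
    return dict(zip(df["chrom"].astype(str), df["size"].astype(int)))


def write_chrom_sizes(sizes: dict[str, int], path: str | Path) -> None:
    with open(path, "w") as fh:
        for chrom, size in sizes.items():
            fh.write(f"{chrom}\t{size}\n")
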