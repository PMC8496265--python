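"""Bin projection through synteny chains, shared-space filters, chain IO."""

import numpy as np
import pandas as pd
import pytest

from panumr import SyntenyMap, filter_shared, map_bins, shared_space_summary
from panumr.crossmap import SEGMENT_COLS, target_bin_of
from panumr import io as pio


def _syn(rows):
    return SyntenyMap(pd.DataFrame(rows, columns=SEGMENT_COLS))


IDENTITY = [("c1", "chr1", 0, 1000, "chr1", 0, 1000, "+")]


class TestProjection:
    def test_identity_projection(self):
        mp = map_bins({"chr1": 1000}, _syn(IDENTITY))
        assert (mp["status"] == "shared_exact").all()
        assert (mp["tgt_start"] == mp["start"]).all()
        assert ((mp["tgt_end"] - mp["tgt_start"]) == 100).all()

    def test_bin_outside_blocks_unmapped(self):
        syn = _syn([("c1", "chr1", 0, 300, "chr1", 0, 300, "+")])
        mp = map_bins({"chr1": 1000}, syn)
        assert list(mp["status"][:3]) == ["shared_exact"] * 3
        assert (mp["status"][3:] == "unmapped").all()

    def test_partially_covered_bin_unmapped(self):
        syn = _syn([("c1", "chr1", 0, 250, "chr1", 0, 250, "+")])
        mp = map_bins({"chr1": 1000}, syn)
        assert mp.iloc[2]["status"] == "unmapped"  # bin [200,300) half-covered

    def test_deletion_shrinks_target(self):
        # chain: [0,450) then a 10-bp target deletion at 450, then [460,1000)
        syn = _syn(
            [
                ("c1", "chr1", 0, 450, "chr1", 0, 450, "+"),
                ("c1", "chr1", 460, 1000, "chr1", 450, 990, "+"),
            ]
        )
        variants = pd.DataFrame(
            {"chrom": ["chr1"], "pos": [450], "kind": ["del"], "length": [10]}
        )
        mp = map_bins({"chr1": 1000}, syn, variants)
        row = mp.iloc[4]  # bin [400,500) spans the deletion
        assert row["status"] == "shared_indel"
        assert row["tgt_end"] - row["tgt_start"] == 90
        # brute-force per-base liftover agrees on the interval hull
        def lift(p):
            if p < 450:
                return p
            if p >= 460:
                return p - 10
            return None
        lifted = [lift(p) for p in range(400, 500) if lift(p) is not None]
        assert row["tgt_start"] == min(lifted)
        assert row["tgt_end"] == max(lifted) + 1

    def test_insertion_grows_target(self):
        syn = _syn(
            [
                ("c1", "chr1", 0, 450, "chr1", 0, 450, "+"),
                ("c1", "chr1", 450, 1000, "chr1", 470, 1020, "+"),
            ]
        )
        mp = map_bins({"chr1": 1000}, syn)
        row = mp.iloc[4]
        assert row["tgt_end"] - row["tgt_start"] == 120

    def test_reverse_strand_projection_and_round_trip(self):
        syn = _syn([("c1", "chr1", 0, 1000, "chr2", 500, 1500, "-")])
        mp = map_bins({"chr1": 1000}, syn)
        assert mp["reverse"].all()
        # source bin [0,100) maps to the far end of the target interval
        assert (mp.iloc[0]["tgt_start"], mp.iloc[0]["tgt_end"]) == (1400, 1500)
        # round-trip through the inverted map recovers each source bin
        inv = syn.invert()
        for _, row in mp.iterrows():
            back = inv.project_interval(row["tgt_chrom"], row["tgt_start"], row["tgt_end"])
            assert back == ("chr1", row["start"], row["end"], True)

    def test_overlapping_blocks_raise(self):
        with pytest.raises(ValueError):
            _syn(
                [
                    ("c1", "chr1", 0, 500, "chr1", 0, 500, "+"),
                    ("c2", "chr1", 400, 900, "chr2", 0, 500, "+"),
                ]
            )


class TestFilterShared:
    def _mapping(self, n_snps=0, n_indels=0, max_indel_len=0):
        return pd.DataFrame(
            {
                "chrom": ["chr1"], "start": [0], "end": [100],
                "tgt_chrom": ["chr1"], "tgt_start": [0], "tgt_end": [100],
                "reverse": [False], "n_snps": [n_snps], "n_indels": [n_indels],
                "max_indel_len": [max_indel_len],
                "status": ["shared_exact" if not (n_snps or n_indels)
                           else ("shared_snp" if not n_indels else "shared_indel")],
            }
        )

    def test_five_indels_excluded(self):
        out = filter_shared(self._mapping(n_indels=5, max_indel_len=3))
        assert out.iloc[0]["status"] == "excluded"

    def test_21bp_indel_excluded(self):
        out = filter_shared(self._mapping(n_indels=1, max_indel_len=21))
        assert out.iloc[0]["status"] == "excluded"

    def test_snp_only_stays_shared(self):
        out = filter_shared(self._mapping(n_snps=1))
        assert out.iloc[0]["status"] == "shared_snp"

    def test_four_indels_of_20bp_stay_shared(self):
        out = filter_shared(self._mapping(n_indels=4, max_indel_len=20))
        assert out.iloc[0]["status"] == "shared_indel"


class TestSharedSpace:
    def test_conservation_and_brute_force_counts(self):
        rng = np.random.default_rng(9)
        sizes = {"chr1": 5000}
        contrasts = {}
        shared_sets = {}
        for name in ("g1", "g2", "g3"):
            # random subset of bins covered by one chain each
            blocks = []
            pos = 0
            cid = 0
            while pos < 5000:
                span = int(rng.integers(1, 8)) * 100
                if rng.random() < 0.6:
                    blocks.append(
                        (f"{name}_{cid}", "chr1", pos, min(pos + span, 5000),
                         "chr1", pos, min(pos + span, 5000), "+")
                    )
                    cid += 1
                pos += span
            syn = _syn(blocks)
            mp = filter_shared(map_bins(sizes, syn))
            contrasts[name] = mp
            shared_sets[name] = {
                (r.chrom, r.start) for r in mp.itertuples(index=False)
                if r.status.startswith("shared")
            }
        per_bin, per_contrast = shared_space_summary(contrasts, sizes)
        assert (per_contrast["shared_bp"] + per_contrast["nonshared_bp"]
                == per_contrast["genome_bp"]).all()
        # brute-force set intersection per bin
        for r in per_bin.itertuples(index=False):
            expected = sum((r.chrom, r.start) in s for s in shared_sets.values())
            assert r.n_shared_genotypes == expected

    def test_inconsistent_tiling_raises(self):
        mp = filter_shared(map_bins({"chr1": 1000}, _syn(IDENTITY)))
        with pytest.raises(ValueError):
            shared_space_summary({"a": mp, "b": mp.iloc[:-1]}, {"chr1": 1000})


class TestChainIO:
    def test_round_trip_forward_and_reverse(self, tmp_path):
        syn = _syn(
            [
                ("c1", "chr1", 0, 450, "chr1", 100, 550, "+"),
                ("c1", "chr1", 460, 800, "chr1", 560, 900, "+"),
                ("c2", "chr2", 0, 300, "chr2", 700, 1000, "-"),
            ]
        )
        path = tmp_path / "test.chain"
        pio.write_chain(syn, {"chr1": 1000, "chr2": 500},
                        {"chr1": 1200, "chr2": 1000}, path)
        back = pio.read_chain(path)
        a = syn.segments.sort_values(["src_chrom", "src_start"]).reset_index(drop=True)
        b = back.segments.sort_values(["src_chrom", "src_start"]).reset_index(drop=True)
        pd.testing.assert_frame_equal(
            a[SEGMENT_COLS].astype(str), b[SEGMENT_COLS].astype(str)
        )

    def test_blocks_tsv_round_trip(self, tmp_path):
        syn = _syn(IDENTITY)
        path = tmp_path / "blocks.tsv"
        pio.write_blocks_tsv(syn, path)
        back = pio.read_blocks_tsv(path)
        assert back.segments["src_end"].iloc[0] == 1000

    def test_truncated_blocks_file_raises(self, tmp_path):
        path = tmp_path / "trunc.tsv"
        syn = _syn(IDENTITY)
        pio.write_blocks_tsv(syn, path)
        text = path.read_text().splitlines()
        path.write_text("\n".join(text[:1] + [text[1].rsplit("\t", 3)[0]]))
        with pytest.raises((ValueError, Exception)):
            pio.read_blocks_tsv(path)


def test_target_bin_max_overlap_and_tie():
    assert target_bin_of(137, 237) == 100   # 63 bp in bin 100
    assert target_bin_of(163, 263) == 200   # 63 bp in bin 200
    assert target_bin_of(150, 250) == 100   # 50/50 tie -> leftmost
    assert target_bin_of(0, 100) == 0
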