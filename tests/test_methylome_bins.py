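"""Bin summarisation and the six-domain classification hierarchy."""

import numpy as np
import pandas as pd
import pytest

from panumr import BinContextStats, ThresholdConfig, classify_bin, classify_bins, summarize_bins


def _stats(n_sites=10, coverage=20.0, level=0.0):
    return BinContextStats(n_sites=n_sites, coverage=coverage, level=level)


def brute_force_label(cg, chg, chh, total_sites, pooled_cov, t=None):
    """Independent re-statement of the classification hierarchy."""
    t = t or ThresholdConfig()
    if total_sites < t.min_sites or pooled_cov < t.min_coverage:
        return "missing_data"
    if chh > t.chh_rddm:
        return "rddm"
    if cg >= t.cg_chg_het and chg >= t.cg_chg_het:
        return "heterochromatin"
    if cg > t.cg_only:
        return "cg_only"
    if cg < t.unmethylated_max and chg < t.unmethylated_max and chh < t.unmethylated_max:
        return "unmethylated"
    return "intermediate"


class TestClassifyBin:
    @pytest.mark.parametrize(
        "cg,chg,chh,expected",
        [
            (0.0, 0.0, 0.20, "rddm"),
            (0.50, 0.45, 0.05, "heterochromatin"),
            (0.50, 0.05, 0.05, "cg_only"),
            (0.05, 0.05, 0.05, "unmethylated"),
            (0.20, 0.05, 0.05, "intermediate"),
            (0.90, 0.05, 0.20, "rddm"),  # hierarchy: CHH test precedes CG-only
            (0.40, 0.40, 0.0, "heterochromatin"),  # >= at the het boundary
            (0.40, 0.05, 0.0, "intermediate"),  # CG-only needs strictly > 0.40
            (0.10, 0.0, 0.0, "intermediate"),  # unmethylated needs strictly < 0.10
            (0.15, 0.0, 0.15, "intermediate"),  # RdDM needs strictly > 0.15
        ],
    )
    def test_hierarchy(self, cg, chg, chh, expected):
        got = classify_bin(_stats(level=cg), _stats(level=chg), _stats(level=chh))
        assert got == expected

    def test_single_cytosine_is_missing_data(self):
        got = classify_bin(
            _stats(n_sites=1, level=0.9),
            _stats(n_sites=0, coverage=0.0, level=None),
            _stats(n_sites=0, coverage=0.0, level=None),
        )
        assert got == "missing_data"

    def test_low_pooled_coverage_is_missing_data(self):
        got = classify_bin(
            _stats(coverage=2.0, level=0.9),
            _stats(coverage=2.0, level=0.9),
            _stats(coverage=2.0, level=0.0),
        )
        assert got == "missing_data"

    def test_zero_site_context_cannot_veto_unmethylated(self):
        got = classify_bin(
            _stats(level=0.02),
            _stats(level=0.02),
            BinContextStats(n_sites=0, coverage=0.0, level=None),
        )
        assert got == "unmethylated"

    def test_negative_level_raises(self):
        with pytest.raises(ValueError):
            classify_bin(_stats(level=-0.1), _stats(), _stats())

    def test_matches_brute_force_on_random_tuples(self):
        rng = np.random.default_rng(42)
        n = 2000
        levels = rng.uniform(0, 1, size=(n, 3))
        # sprinkle values at the decision boundaries
        mask = rng.random((n, 3)) < 0.15
        levels[mask] = rng.choice([0.10, 0.15, 0.40], size=int(mask.sum()))
        sites = rng.integers(0, 6, size=(n, 3))
        cov = rng.uniform(0, 12, size=(n, 3))
        for i in range(n):
            parts = [
                BinContextStats(int(sites[i, j]), float(cov[i, j]), float(levels[i, j]))
                for j in range(3)
            ]
            total_sites = int(sites[i].sum())
            total_reads = float((sites[i] * cov[i]).sum())
            pooled = total_reads / total_sites if total_sites else 0.0
            expected = brute_force_label(*levels[i], total_sites, pooled)
            assert classify_bin(*parts) == expected


class TestSummarizeBins:
    sizes = {"chr1": 1000}

    def _calls(self, rows):
        return pd.DataFrame(
            rows, columns=["chrom", "pos", "strand", "context", "meth_reads", "total_reads"]
        )

    def test_weighted_level_and_coverage(self):
        calls = self._calls(
            [("chr1", 110, "+", "CHG", 0, 3), ("chr1", 190, "-", "CHG", 7, 7)]
        )
        out = summarize_bins(calls, self.sizes)
        row = out[(out["start"] == 100) & (out["context"] == "CHG")].iloc[0]
        assert row["n_sites"] == 2
        assert row["level"] == pytest.approx(0.7)
        assert row["coverage"] == pytest.approx(5.0)

    def test_uniform_sites(self):
        calls = self._calls(
            [("chr1", 200 + 10 * i, "+", "CG", 8, 10) for i in range(4)]
        )
        row = summarize_bins(calls, self.sizes)
        row = row[(row["start"] == 200) & (row["context"] == "CG")].iloc[0]
        assert row["level"] == pytest.approx(0.8)
        assert row["coverage"] == pytest.approx(10.0)

    def test_empty_bins_emitted_with_undefined_level(self):
        out = summarize_bins(self._calls([("chr1", 5, "+", "CG", 1, 2)]), self.sizes)
        empty = out[(out["start"] == 500) & (out["context"] == "CG")].iloc[0]
        assert empty["n_sites"] == 0
        assert np.isnan(empty["level"])
        # full grid: every (bin, context) combination exists
        assert len(out) == 10 * 3

    def test_meth_exceeding_total_raises(self):
        with pytest.raises(ValueError):
            summarize_bins(self._calls([("chr1", 5, "+", "CG", 3, 2)]), self.sizes)

    def test_positions_beyond_chromosome_dropped_with_warning(self, caplog):
        calls = self._calls(
            [("chr1", 5, "+", "CG", 1, 2), ("chr1", 5000, "+", "CG", 1, 2)]
        )
        import logging

        with caplog.at_level(logging.WARNING):
            out = summarize_bins(calls, self.sizes)
        assert "beyond chromosome" in caplog.text
        assert out["n_sites"].sum() == 1

    def test_agrees_with_per_site_accumulator_and_is_order_invariant(self):
        rng = np.random.default_rng(7)
        n = 400
        pos = rng.integers(0, 1000, size=n)
        ctx = rng.choice(["CG", "CHG", "CHH"], size=n)
        total = rng.integers(0, 30, size=n)
        meth = rng.binomial(total, 0.3)
        calls = self._calls(
            list(zip(["chr1"] * n, pos, ["+"] * n, ctx, meth, total))
        )
        out = summarize_bins(calls, self.sizes)
        # independent per-site accumulator
        acc: dict = {}
        for p, c, m, t in zip(pos, ctx, meth, total):
            key = ((p // 100) * 100, c)
            s = acc.setdefault(key, [0, 0, 0])
            s[0] += 1
            s[1] += m
            s[2] += t
        for (start, c), (ns, m, t) in acc.items():
            row = out[(out["start"] == start) & (out["context"] == c)].iloc[0]
            assert row["n_sites"] == ns
            assert row["total_reads"] == t
            if t:
                assert row["level"] == pytest.approx(m / t)
        # permutation invariance
        shuffled = calls.sample(frac=1, random_state=0).reset_index(drop=True)
        assert summarize_bins(shuffled, self.sizes).equals(out)


def test_classify_bins_partitions_every_bin(cfg):
    rng = np.random.default_rng(3)
    sizes = {"chr1": 2000, "chr2": 1100}
    rows = []
    for chrom, size in sizes.items():
        n = rng.integers(50, 120)
        pos = rng.integers(0, size, size=n)
        for p in pos:
            t = int(rng.integers(0, 25))
            rows.append(
                (chrom, p, "+", rng.choice(["CG", "CHG", "CHH"]), int(rng.binomial(t, 0.4)), t)
            )
    calls = pd.DataFrame(
        rows, columns=["chrom", "pos", "strand", "context", "meth_reads", "total_reads"]
    )
    track = classify_bins(summarize_bins(calls, sizes), cfg)
    n_bins = sum(-(-s // 100) for s in sizes.values())
    assert len(track) == n_bins
    assert track["label"].isin(
        ["missing_data", "rddm", "heterochromatin", "cg_only", "unmethylated", "intermediate"]
    ).all()
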