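"""UMR stability classification, polymorphic typing, ACR variability,
DMT attribution and expression linkage on hand-built fixtures."""

from collections import Counter

import numpy as np
import pandas as pd
import pytest

from panumr import (
    SyntenyMap,
    ThresholdConfig,
    classify_overlap_boundary,
    classify_polymorphic_type,
    compare_umrs,
    attribute_dmts,
    link_expression,
)
from panumr.comparative import classify_acr_variability, classify_expression
from panumr.crossmap import SEGMENT_COLS, filter_shared, map_bins


def _identity_mappings(n_bins=20, unmapped=(), indels=()):
    rows = []
    for i in range(n_bins):
        status = "shared_exact"
        if i in unmapped:
            status = "unmapped"
        elif i in indels:
            status = "shared_indel"
        rows.append(
            ("chr1", i * 100, (i + 1) * 100, "chr1" if status != "unmapped" else None,
             i * 100 if status != "unmapped" else -1,
             (i + 1) * 100 if status != "unmapped" else -1,
             False, 0, 5 if i in indels else 0, 30 if i in indels else 0, status)
        )
    df = pd.DataFrame(
        rows, columns=["chrom", "start", "end", "tgt_chrom", "tgt_start",
                       "tgt_end", "reverse", "n_snps", "n_indels",
                       "max_indel_len", "status"])
    return filter_shared(df)


def _track(labels, chrom="chr1"):
    code = {"U": "unmethylated", "m": "missing_data", "H": "heterochromatin",
            "R": "rddm", "C": "cg_only", "I": "intermediate"}
    return pd.DataFrame(
        {"chrom": chrom, "start": [i * 100 for i in range(len(labels))],
         "end": [(i + 1) * 100 for i in range(len(labels))],
         "label": [code[c] for c in labels]})


def _umrs(intervals, chrom="chr1"):
    return pd.DataFrame(
        [(chrom, s, e, (e - s) // 100, 0, 0.0) for s, e in intervals],
        columns=["chrom", "start", "end", "n_bins", "n_missing", "missing_fraction"])


class TestStability:
    def test_identical(self):
        comp = compare_umrs(
            _umrs([(300, 700)]), _identity_mappings(),
            _track("HHHUUUUHHH"), _umrs([(300, 700)]))
        assert comp.iloc[0]["category"] == "identical"
        assert comp.iloc[0]["methylated_bin_fraction"] == 0.0

    def test_partial_when_target_extends(self):
        comp = compare_umrs(
            _umrs([(300, 700)]), _identity_mappings(),
            _track("HHHUUUUUUH"), _umrs([(300, 900)]))
        assert comp.iloc[0]["category"] == "partial"

    def test_partial_when_shifted_both_sides(self):
        comp = compare_umrs(
            _umrs([(300, 700)]), _identity_mappings(),
            _track("HUUUUUHHHH"), _umrs([(100, 600)]))
        assert comp.iloc[0]["category"] == "partial"

    def test_polymorphic_above_half(self):
        # 3 of 4 target bins methylated -> 0.75 > 0.5
        comp = compare_umrs(
            _umrs([(300, 700)]), _identity_mappings(),
            _track("HHHHHHUHHH"), _umrs([]))
        row = comp.iloc[0]
        assert row["category"] == "polymorphic"
        assert row["methylated_bin_fraction"] == pytest.approx(0.75)
        assert row["polymorphic_type"] == "cg_chg"

    def test_exactly_half_is_overlapping_not_polymorphic(self):
        comp = compare_umrs(
            _umrs([(300, 700)]), _identity_mappings(),
            _track("HHHHHUUHHH"), _umrs([(500, 800)]))
        assert comp.iloc[0]["category"] == "partial"  # 0.5 not > 0.5

    def test_any_unmapped_bin_makes_nonshared(self):
        comp = compare_umrs(
            _umrs([(300, 700)]), _identity_mappings(unmapped={4}),
            _track("HHHUUUUHHH"), _umrs([(300, 700)]))
        assert comp.iloc[0]["category"] == "nonshared"

    def test_excluded_bin_makes_nonshared(self):
        comp = compare_umrs(
            _umrs([(300, 700)]), _identity_mappings(indels={4}),
            _track("HHHUUUUHHH"), _umrs([(300, 700)]))
        assert comp.iloc[0]["category"] == "nonshared"

    def test_majority_missing_target_data(self):
        comp = compare_umrs(
            _umrs([(300, 700)]), _identity_mappings(),
            _track("HHHmmmUHHH"), _umrs([]))
        assert comp.iloc[0]["category"] == "missing_data"

    def test_self_comparison_is_identical(self):
        track = _track("HHHUUUUHHHHUUUHH")
        umrs = _umrs([(300, 700), (1100, 1400)])
        comp = compare_umrs(umrs, _identity_mappings(16), track, umrs)
        assert (comp["category"] == "identical").all()

    def test_categories_partition(self, small_bundle, small_results):
        comp = small_results.comparisons
        counts = comp["category"].value_counts()
        assert counts.sum() == len(small_results.umrs["A"])
        assert set(counts.index) <= {
            "nonshared", "missing_data", "identical", "partial", "polymorphic"}


class TestPolymorphicType:
    def test_majority_rddm(self):
        assert classify_polymorphic_type(Counter(rddm=6, heterochromatin=4)) == "chh"

    def test_hierarchy_prefers_chh_first(self):
        # 40% rddm / 60% het -> het majority wins after CHH fails
        assert classify_polymorphic_type(Counter(rddm=4, heterochromatin=6)) == "cg_chg"

    def test_all_cg_only(self):
        assert classify_polymorphic_type(Counter(cg_only=5)) == "cg_only"

    def test_no_majority_falls_back_to_hierarchy_order(self):
        counts = Counter(rddm=3, heterochromatin=3, cg_only=3)
        assert classify_polymorphic_type(counts) == "chh"

    def test_zero_methylated_raises(self):
        with pytest.raises(ValueError):
            classify_polymorphic_type(Counter())


class TestBoundary:
    def test_identical_bin_sets(self):
        p = {("chr1", 300), ("chr1", 400)}
        assert classify_overlap_boundary(p, [p.copy()]) == ("identical", False)

    def test_larger_target_is_partial(self):
        p = {("chr1", 300), ("chr1", 400)}
        t = p | {("chr1", 500)}
        assert classify_overlap_boundary(p, [t]) == ("partial", False)

    def test_no_target_umr_flagged(self):
        assert classify_overlap_boundary({("chr1", 300)}, []) == ("partial", True)


class TestAcrVariability:
    def test_classes(self):
        assert classify_acr_variability(True, True) == "stable_acr"
        assert classify_acr_variability(True, False) == "source_only_acr"
        assert classify_acr_variability(False, True) == "target_only_acr"
        assert classify_acr_variability(False, False) == "no_acr"

    def test_in_comparison_table(self):
        src_acr = pd.DataFrame({"chrom": ["chr1"], "start": [350], "end": [450]})
        tgt_acr = pd.DataFrame({"chrom": ["chr1"], "start": [600], "end": [680]})
        comp = compare_umrs(
            _umrs([(300, 700)]), _identity_mappings(),
            _track("HHHUUUUHHH"), _umrs([(300, 700)]),
            source_acrs=src_acr, target_acrs=tgt_acr)
        assert comp.iloc[0]["acr_class"] == "stable_acr"


class TestDmtAttribution:
    def test_buckets_and_sum(self):
        comp = pd.DataFrame(
            {"chrom": "chr1", "start": [1000, 3000], "end": [1500, 3400],
             "category": ["polymorphic", "partial"]})
        dmts = pd.DataFrame(
            {"chrom": "chr1",
             "start": [1000, 1100, 3000, 9000, 9000],
             "end": [1100, 1200, 3100, 9100, 9100],
             "context": ["CG", "CG", "CHG", "CG", "CHG"],
             "level_a": 0.0, "level_b": 0.9,
             "direction": ["hypo_in_A"] * 5})
        frac = attribute_dmts(dmts, comp)
        # 4 unique bins: 2 polymorphic, 1 partial, 1 other
        assert frac["polymorphic"] == pytest.approx(0.5)
        assert frac["partial"] == pytest.approx(0.25)
        assert frac["other"] == pytest.approx(0.25)
        assert frac.sum() == pytest.approx(1.0)

    def test_hypo_in_target_ignored(self):
        comp = pd.DataFrame(
            {"chrom": "chr1", "start": [0], "end": [300], "category": ["polymorphic"]})
        dmts = pd.DataFrame(
            {"chrom": "chr1", "start": [0], "end": [100], "context": ["CG"],
             "level_a": 0.9, "level_b": 0.0, "direction": ["hypo_in_B"]})
        assert attribute_dmts(dmts, comp).isna().all()


class TestExpression:
    expr = pd.DataFrame(
        {
            "gene_id": ["g_de", "g_expr", "g_silent", "g_de_b"],
            "mean_a": [50.0, 10.0, 0.5, 1.0],
            "mean_b": [4.0, 8.0, 0.4, 30.0],
            "log2fc": [3.0, 0.3, 0.3, -4.5],
            "p_value": [0.01, 0.5, 0.8, 0.001],
        }
    )

    def test_gene_classes(self):
        classes = classify_expression(self.expr)
        assert list(classes) == [
            "de_higher_A", "expressed_not_de", "silent", "de_higher_B"]

    def test_tss_window_rule(self):
        comp = pd.DataFrame(
            {"chrom": "chr1", "start": [1000], "end": [1300],
             "category": ["identical"], "polymorphic_type": ["unset"]})
        genes = pd.DataFrame(
            {"gene_id": ["g_de", "g_expr"], "chrom": "chr1",
             "start": [1450, 1550], "end": [3000, 3500],
             "strand": "+", "tss": [1450, 1550]})
        links = link_expression(comp, genes, self.expr)
        # TSS at 1450 is 151 bp from the UMR end -> linked;
        # TSS at 1550 is 251 bp away -> not linked
        assert list(links["gene_id"]) == ["g_de"]
        assert links.iloc[0]["expression_class"] == "de_higher_A"

    def test_gene_without_expression_record_excluded(self):
        comp = pd.DataFrame(
            {"chrom": "chr1", "start": [1000], "end": [1300],
             "category": ["polymorphic"], "polymorphic_type": ["chh"]})
        genes = pd.DataFrame(
            {"gene_id": ["unknown"], "chrom": "chr1", "start": [1350],
             "end": [2000], "strand": "+", "tss": [1350]})
        assert link_expression(comp, genes, self.expr).empty
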