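import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from oracles import bh_stepup
from ringkit.dup_expr import (
    bh_adjust,
    call_degs,
    classify_tandem,
    livak,
    multi_timepoint_sets,
    pair_concordance,
)
from ringkit.synthetic import make_duplicate_fixture, make_expression_fixture


def _order(rows):
    return pd.DataFrame(
        rows, columns=["gene_id", "chromosome", "start", "end", "strand"]
    )


class TestClassifyTandem:
    ORDER = _order([
        ("gA", "A13", 100, 200, "+"),
        ("gB", "A13", 300, 400, "+"),
        ("gC", "A13", 500, 600, "+"),
        ("gD", "A13", 700, 800, "+"),
        ("gE", "A13", 900, 1000, "+"),
        ("gF", "A13", 1100, 1200, "+"),
        ("gX", "D02", 100, 200, "-"),
    ])

    def test_adjacent_genes_are_tandem(self):
        pairs = pd.DataFrame({"gene_a": ["gA"], "gene_b": ["gB"]})
        out = classify_tandem(pairs, self.ORDER)
        assert out["mode"].tolist() == ["tandem"]

    def test_different_chromosomes_nontandem(self):
        pairs = pd.DataFrame({"gene_a": ["gA"], "gene_b": ["gX"]})
        assert classify_tandem(pairs, self.ORDER)["mode"].tolist() == ["nontandem"]

    def test_max_gap_semantics(self):
        # ranks 1 and 5 (gB..gF): nontandem at max_gap 0, tandem at 3
        pairs = pd.DataFrame({"gene_a": ["gB"], "gene_b": ["gF"]})
        assert classify_tandem(pairs, self.ORDER, max_gap=0)["mode"][0] == "nontandem"
        assert classify_tandem(pairs, self.ORDER, max_gap=3)["mode"][0] == "tandem"

    def test_missing_gene_named_in_error(self):
        pairs = pd.DataFrame({"gene_a": ["gA"], "gene_b": ["missing"]})
        with pytest.raises(KeyError, match="missing"):
            classify_tandem(pairs, self.ORDER)

    def test_planted_fixture_recovered(self):
        order, pairs = make_duplicate_fixture(seed=1)
        out = classify_tandem(pairs[["gene_a", "gene_b"]], order)
        assert (out["mode"] == pairs["mode"]).all()


class TestBhAdjust:
    def test_hand_example(self):
        out = bh_adjust([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(out, [0.04, 0.04, 0.04, 0.04])

    def test_single_and_equal_values_unchanged(self):
        assert bh_adjust([0.3])[0] == pytest.approx(0.3)
        assert np.allclose(bh_adjust([0.2, 0.2, 0.2]), 0.2)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])

    @settings(deadline=None, max_examples=50)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=40))
    def test_matches_stepup_oracle_and_bounds(self, pvals):
        out = bh_adjust(pvals)
        assert np.allclose(out, bh_stepup(pvals))
        assert (out >= np.asarray(pvals) - 1e-12).all()
        assert (out <= 1.0).all()


class TestCallDegs:
    def _frame(self, rows):
        return pd.DataFrame(
            rows, columns=["gene_id", "timepoint", "log2fc", "padj"]
        )

    def test_boundary_inclusive(self):
        df = self._frame([("g1", 1, 1.0, 0.05)])
        flagged, counts, _ = call_degs(df)
        assert flagged["deg"].tolist() == ["up"]
        assert counts[1] == 1

    def test_subthreshold_fold_change_not_deg(self):
        df = self._frame([("g1", 1, 0.99, 0.001)])
        flagged, _, _ = call_degs(df)
        assert flagged["deg"].tolist() == ["none"]

    def test_down_direction_by_sign(self):
        df = self._frame([("g1", 1, -2.0, 0.01), ("g2", 1, 2.0, 0.2)])
        flagged, _, _ = call_degs(df)
        assert flagged["deg"].tolist() == ["down", "none"]

    def test_missing_values_excluded_and_counted(self):
        df = self._frame([("g1", 1, np.nan, 0.01), ("g2", 1, 2.0, 0.01)])
        flagged, _, n_excluded = call_degs(df)
        assert n_excluded == 1
        assert len(flagged) == 1

    def test_threshold_monotonicity(self):
        table, _ = make_expression_fixture(n_genes=100,
                                           per_timepoint_degs=(25, 30, 30, 15),
                                           n_total_degs=60, n_min2=25,
                                           n_all=5, n_all_up=3,
                                           n_concordant_pairs=5, seed=5)
        loose, _, _ = call_degs(table, lfc=1.0)
        strict, _, _ = call_degs(table, lfc=2.0)
        loose_set = set(loose[loose["deg"] != "none"].index)
        strict_set = set(strict[strict["deg"] != "none"].index)
        assert strict_set <= loose_set

    def test_planted_counts_recovered(self):
        table, truth = make_expression_fixture(seed=0)
        _, counts, _ = call_degs(table)
        assert counts.to_dict() == truth["per_timepoint"].to_dict()


class TestMultiTimepointSets:
    def _flag(self, cells, timepoints=(1, 3, 12, 48)):
        rows = []
        genes = {g for g, _t, _d in cells}
        lookup = {(g, t): d for g, t, d in cells}
        for g in sorted(genes):
            for t in timepoints:
                rows.append((g, t, lookup.get((g, t), "none")))
        return pd.DataFrame(rows, columns=["gene_id", "timepoint", "deg"])

    def test_two_timepoints_not_all(self):
        df = self._flag([("g1", 1, "up"), ("g1", 3, "up")])
        sets = multi_timepoint_sets(df)
        assert "g1" in sets["min_k"]
        assert "g1" not in sets["all_up"] and "g1" not in sets["all_down"]

    def test_mixed_direction_in_neither_directional_set(self):
        df = self._flag([
            ("g1", 1, "up"), ("g1", 3, "up"),
            ("g1", 12, "up"), ("g1", 48, "down"),
        ])
        sets = multi_timepoint_sets(df)
        assert "g1" in sets["min_k"]
        assert "g1" not in sets["all_up"] and "g1" not in sets["all_down"]

    def test_set_nesting(self):
        table, _ = make_expression_fixture(seed=1)
        flagged, _, _ = call_degs(table)
        sets = multi_timepoint_sets(flagged)
        assert sets["all_up"] | sets["all_down"] <= sets["min_k"] <= sets["any"]

    def test_planted_sets_recovered(self):
        table, truth = make_expression_fixture(seed=2)
        flagged, _, _ = call_degs(table)
        sets = multi_timepoint_sets(flagged)
        assert sets["min_k"] == truth["min2"]
        assert sets["all_up"] == truth["all_up"]
        assert sets["all_down"] == truth["all_down"]


class TestPairConcordance:
    def _flag(self, cells):
        rows = [(g, t, d) for g, t, d in cells]
        return pd.DataFrame(rows, columns=["gene_id", "timepoint", "deg"])

    def test_both_up_concordant(self):
        records = self._flag([
            ("a", 1, "up"), ("a", 3, "up"),
            ("b", 1, "up"), ("b", 3, "up"),
        ])
        pairs = pd.DataFrame({"gene_a": ["a"], "gene_b": ["b"]})
        out, skipped = pair_concordance(pairs, records)
        assert out["status"].tolist() == ["concordant"]
        assert skipped == []

    def test_opposite_directions_discordant(self):
        records = self._flag([("a", 12, "up"), ("b", 12, "down")])
        pairs = pd.DataFrame({"gene_a": ["a"], "gene_b": ["b"]})
        out, _ = pair_concordance(pairs, records)
        assert out["status"].tolist() == ["discordant"]

    def test_no_shared_deg_timepoint_untested(self):
        records = self._flag([("a", 1, "up"), ("b", 1, "none"), ("b", 3, "none")])
        pairs = pd.DataFrame({"gene_a": ["a"], "gene_b": ["b"]})
        out, _ = pair_concordance(pairs, records)
        assert out["status"].tolist() == ["untested"]

    def test_missing_gene_skipped_and_reported(self):
        records = self._flag([("a", 1, "up")])
        pairs = pd.DataFrame({"gene_a": ["a"], "gene_b": ["ghost"]})
        out, skipped = pair_concordance(pairs, records)
        assert out.empty
        assert skipped == [("a", "ghost")]

    def test_planted_concordance_recovered(self):
        table, truth = make_expression_fixture(
            n_concordant_pairs=40, n_discordant_pairs=5, seed=3
        )
        flagged, _, _ = call_degs(table)
        out, skipped = pair_concordance(truth["pairs"], flagged)
        assert skipped == []
        merged = out.merge(truth["pairs"], on=["gene_a", "gene_b"])
        assert ((merged["status"] == "concordant")
                == merged["concordant"]).all()
        assert (merged["status"] != "untested").all()


class TestLivak:
    def test_no_change(self):
        assert livak(20, 15, 20, 15) == pytest.approx(1.0)

    def test_target_ct_drop_doubles_expression(self):
        assert livak(19, 15, 20, 15) == pytest.approx(2.0)

    def test_ddct_of_two_quarters_expression(self):
        assert livak(22, 15, 20, 15) == pytest.approx(0.25)

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            livak(float("nan"), 15, 20, 15)
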