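import math

import numpy as np
import pandas as pd
import pytest

from spongetx.differential_expression import (AnalysisParams, classify_transition,
                                              extreme_table, extreme_upregulation,
                                              relative_expression_matrix,
                                              settlement_calls, settlement_test,
                                              stage_specific_calls,
                                              stage_specific_test,
                                              transition_calls)
from spongetx.io_models import CountTable
from tests.conftest import make_table


def p_twotailed_df2(t):
    """Closed-form two-tailed p for Student t with 2 degrees of freedom."""
    t = abs(t)
    return 1.0 - t / math.sqrt(t * t + 2.0)


def table_from_log2(values, **kw):
    """Counts whose log2(count + 1) equal the given per-stage levels."""
    return make_table({g: [2.0 ** v - 1 for v in row] for g, row in values.items()},
                      **kw)


class TestStageSpecific:
    def test_strong_focal_shift_is_called_up_with_closed_form_p(self):
        table = table_from_log2({"g": [8.0, 2.0, 2.1, 1.9]})
        rec = stage_specific_test(table, "g", "PRE")
        sd = np.std([2.0, 2.1, 1.9], ddof=1)
        t = (2.0 - 8.0) / (sd / math.sqrt(3))
        assert rec.p_value == pytest.approx(p_twotailed_df2(t), rel=1e-9)
        assert rec.p_value < 0.001
        assert 2 ** rec.log2_ratio == pytest.approx(64.0)
        assert rec.direction == "up"

    def test_focal_equal_to_mean_of_others_is_unchanged(self):
        table = table_from_log2({"g": [3.0, 2.0, 3.0, 4.0]})
        rec = stage_specific_test(table, "g", "PRE")
        assert rec.log2_ratio == pytest.approx(0.0)
        assert rec.direction == "unchanged"

    def test_small_fold_fails_despite_tiny_p(self):
        # under four-fold but highly consistent others: filter conjunction
        table = table_from_log2({"g": [3.58, 2.0, 2.001, 1.999]})  # ~3-fold
        rec = stage_specific_test(table, "g", "PRE")
        assert rec.p_value < 0.01
        assert rec.direction == "unchanged"

    def test_degenerate_constant_others_flagged(self):
        table = table_from_log2({"g": [8.0, 2.0, 2.0, 2.0]})
        rec = stage_specific_test(table, "g", "PRE")
        assert rec.p_value == 0.0
        assert rec.flagged
        same = table_from_log2({"g": [2.0, 2.0, 2.0, 2.0]})
        rec = stage_specific_test(same, "g", "PRE")
        assert rec.p_value == 1.0 and not rec.flagged

    def test_vectorized_calls_match_per_gene_function(self):
        rng = np.random.default_rng(8)
        table = make_table({f"g{i}": rng.integers(0, 2000, 4).tolist()
                            for i in range(40)})
        frame = stage_specific_calls(table).set_index(["gene_id", "contrast"])
        for gene in table.gene_ids:
            for stage in table.sample_ids:
                rec = stage_specific_test(table, gene, stage)
                row = frame.loc[(gene, stage)]
                assert row["p_value"] == pytest.approx(rec.p_value, rel=1e-12)
                assert row["direction"] == rec.direction


class TestSettlement:
    def test_pelagic_high_benthic_low_called_down(self):
        table = table_from_log2({"g": [8.0, 8.1, 2.0, 2.1]})
        rec = settlement_test(table, "g")
        sp = math.sqrt((0.005 + 0.005) / 2)
        assert rec.p_value == pytest.approx(p_twotailed_df2(-6.0 / sp), rel=1e-9)
        assert rec.log2_ratio == pytest.approx(-6.0)
        assert rec.direction == "down"

    def test_identical_groups_unchanged(self):
        table = table_from_log2({"g": [5.0, 5.0, 5.0, 5.0]})
        assert settlement_test(table, "g").direction == "unchanged"

    def test_exact_fourfold_boundary_is_called(self):
        table = table_from_log2({"g": [4.0, 4.001, 6.0, 6.001]})
        rec = settlement_test(table, "g")
        assert rec.log2_ratio == pytest.approx(2.0, abs=1e-3)
        assert rec.direction == "up"

    def test_vectorized_matches_per_gene(self):
        rng = np.random.default_rng(9)
        table = make_table({f"g{i}": rng.integers(0, 2000, 4).tolist()
                            for i in range(30)})
        frame = settlement_calls(table).set_index("gene_id")
        for gene in table.gene_ids:
            rec = settlement_test(table, gene)
            assert frame.at[gene, "p_value"] == pytest.approx(rec.p_value, rel=1e-12)
            assert frame.at[gene, "direction"] == rec.direction


class TestTransitions:
    def test_fourfold_rise_passing_gate_is_up(self):
        table = make_table({"g": [64, 260, 260, 260]})
        rec = classify_transition(table, "g", ("PRE", "COMP"))
        assert rec.direction == "up"
        assert rec.passed_error_gate  # |196| > 5 * sqrt(260) ~ 80.6

    def test_equal_counts_unchanged(self):
        table = make_table({"g": [100, 100, 100, 100]})
        rec = classify_transition(table, "g", ("PRE", "COMP"))
        assert rec.direction == "unchanged"

    def test_large_fold_but_failed_gate_is_unchanged(self):
        table = make_table({"g": [1, 5, 5, 5]})
        params = AnalysisParams(detection_threshold=1.0)
        rec = classify_transition(table, "g", ("PRE", "COMP"), params)
        assert rec is not None
        assert not rec.passed_error_gate  # |4| < 5 * sqrt(5) ~ 11.2
        assert rec.direction == "unchanged"

    def test_below_detection_in_both_stages_is_excluded(self):
        table = make_table({"g": [10, 20, 100, 100]})
        assert classify_transition(table, "g", ("PRE", "COMP")) is None

    def test_swapping_stages_swaps_up_and_down(self):
        rng = np.random.default_rng(10)
        table = make_table({f"g{i}": rng.integers(0, 3000, 4).tolist()
                            for i in range(50)})
        flip = {"up": "down", "down": "up", "unchanged": "unchanged"}
        for gene in table.gene_ids:
            fwd = classify_transition(table, gene, ("PRE", "COMP"))
            rev = classify_transition(table, gene, ("COMP", "PRE"))
            if fwd is None:
                assert rev is None
            else:
                assert rev.direction == flip[fwd.direction]

    def test_vectorized_matches_per_gene(self):
        rng = np.random.default_rng(12)
        table = make_table({f"g{i}": rng.integers(0, 3000, 4).tolist()
                            for i in range(50)})
        frame = transition_calls(table)
        seen = set(zip(frame["gene_id"], frame["contrast"]))
        samples = table.sample_ids
        for gene in table.gene_ids:
            for pair in zip(samples[:-1], samples[1:]):
                rec = classify_transition(table, gene, pair)
                key = (gene, f"{pair[0]}->{pair[1]}")
                if rec is None:
                    assert key not in seen
                else:
                    row = frame[(frame["gene_id"] == gene)
                                & (frame["contrast"] == key[1])].iloc[0]
                    assert row["direction"] == rec.direction

    def test_twofold_calls_contain_fourfold_calls(self, small_dataset):
        from spongetx.noise_detection import normalize_depth
        norm = normalize_depth(small_dataset.counts, "PRE")
        four = transition_calls(norm, AnalysisParams(fold_cutoff=4))
        two = transition_calls(norm, AnalysisParams(fold_cutoff=2))
        called4 = set(map(tuple, four[four.direction != "unchanged"]
                          [["gene_id", "contrast", "direction"]].to_numpy()))
        called2 = set(map(tuple, two[two.direction != "unchanged"]
                          [["gene_id", "contrast", "direction"]].to_numpy()))
        assert called4 <= called2


class TestExtreme:
    def test_thousandfold_single_stage_gene_is_extreme(self):
        table = make_table({"g": [1023, 0, 0, 0]})
        stat, is_extreme, stage = extreme_upregulation(table, "g")
        assert stat == pytest.approx(10.0)
        assert is_extreme and stage == "PRE"

    def test_constant_gene_is_not_extreme(self):
        table = make_table({"g": [7, 7, 7, 7]})
        stat, is_extreme, _ = extreme_upregulation(table, "g")
        assert stat == pytest.approx(0.0)
        assert not is_extreme

    def test_sixty_fourfold_differential_is_below_the_bar(self):
        table = make_table({"g": [255, 3, 3, 3]})
        stat, is_extreme, _ = extreme_upregulation(table, "g")
        assert stat == pytest.approx(6.0)
        assert not is_extreme  # log2(100) ~ 6.644

    def test_table_matches_per_gene(self):
        rng = np.random.default_rng(13)
        table = make_table({f"g{i}": rng.integers(0, 5000, 4).tolist()
                            for i in range(30)})
        frame = extreme_table(table)
        for gene in table.gene_ids:
            stat, is_extreme, stage = extreme_upregulation(table, gene)
            assert frame.at[gene, "max_upregulation_log2"] == pytest.approx(stat)
            assert frame.at[gene, "focal_stage"] == stage
            assert bool(frame.at[gene, "is_extreme"]) == is_extreme


class TestRelativeExpression:
    def test_endpoints_hit_zero_and_one(self):
        table = make_table({"g": [0, 10, 40, 100]})
        rel = relative_expression_matrix(table)
        assert rel.at["g", "PRE"] == 0.0
        assert rel.at["g", "ADULT"] == 1.0

    def test_constant_gene_sits_at_half(self):
        table = make_table({"g": [5, 5, 5, 5]})
        assert (relative_expression_matrix(table).loc["g"] == 0.5).all()

    def test_rows_span_the_unit_interval(self):
        table = make_table({"a": [0, 10, 40, 100], "b": [9, 3, 1, 2],
                            "c": [50, 60, 20, 90]})
        rel = relative_expression_matrix(table)
        assert (rel.min(axis=1) == 0).all()
        assert (rel.max(axis=1) == 1).all()
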