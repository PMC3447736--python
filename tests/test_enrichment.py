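import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from spongetx.enrichment import (AtPeakMatrix, at_peak, bh_adjust,
                                 resampling_enrichment, stage_family_enrichment,
                                 transfer_annotations)
from spongetx.io_models import AnnotationRecord
from tests.conftest import make_table


class TestTransfer:
    def test_best_surviving_hit_wins(self):
        records = [AnnotationRecord("g1", "S_weak", 1e-3),
                   AnnotationRecord("g1", "S_best", 1e-10),
                   AnnotationRecord("g1", "S_ok", 1e-6)]
        terms, hits = transfer_annotations(records, {"S_best": ["T1"],
                                                     "S_ok": ["T2"]})
        assert terms["g1"] == {"T1"}
        assert hits["g1"] == ("S_best", 1e-10)

    def test_only_weak_hit_leaves_gene_unannotated(self):
        records = [AnnotationRecord("g1", "S", 1e-3)]
        terms, hits = transfer_annotations(records, {"S": ["T1"]})
        assert "g1" not in terms and "g1" not in hits

    def test_evalue_tie_breaks_to_smaller_subject_id(self):
        records = [AnnotationRecord("g1", "S_b", 1e-9),
                   AnnotationRecord("g1", "S_a", 1e-9)]
        terms, hits = transfer_annotations(records, {"S_a": ["TA"], "S_b": ["TB"]})
        assert terms["g1"] == {"TA"}


class TestResampling:
    def test_small_universe_matches_hypergeometric_closed_form(self):
        # universe 10, set 4, term on 5, overlap 4: P = C(5,4)C(5,0)/C(10,4)
        universe = [f"g{i}" for i in range(10)]
        gene_terms = {g: {"T"} for g in universe[:5]}
        results = resampling_enrichment(universe[1:5], gene_terms, universe,
                                        R=20_000, seed=4)
        (res,) = results
        assert res.overlap == 4
        assert res.p_raw == pytest.approx(5 / 210, abs=0.01)

    def test_universal_term_has_p_one(self):
        universe = [f"g{i}" for i in range(20)]
        gene_terms = {g: {"T"} for g in universe}
        (res,) = resampling_enrichment(universe[:5], gene_terms, universe,
                                       R=1000, seed=1)
        assert res.p_raw == 1.0

    def test_p_floor_is_one_over_r_plus_one(self):
        universe = [f"g{i}" for i in range(60)]
        gene_terms = {g: {"T"} for g in universe[:10]}
        (res,) = resampling_enrichment(universe[:10], gene_terms, universe,
                                       R=1000, seed=2)
        assert res.p_raw >= 1 / 1001
        assert res.p_adj >= res.p_raw

    def test_seed_is_mandatory_and_set_must_be_subset(self):
        universe = ["a", "b"]
        with pytest.raises(ValueError, match="seed"):
            resampling_enrichment(["a"], {}, universe, R=1000)
        with pytest.raises(ValueError, match="subset"):
            resampling_enrichment(["z"], {}, universe, R=1000, seed=1)

    def test_empty_gene_set_gives_empty_result(self):
        assert resampling_enrichment([], {}, ["a"], R=1000, seed=1) == []


class TestBh:
    def test_worked_step_up_example(self):
        np.testing.assert_allclose(bh_adjust([0.01, 0.02, 0.04]),
                                   [0.03, 0.03, 0.04])

    def test_single_p_unchanged_and_all_ones_stay_one(self):
        np.testing.assert_allclose(bh_adjust([0.2]), [0.2])
        np.testing.assert_allclose(bh_adjust([1.0, 1.0, 1.0]), [1.0, 1.0, 1.0])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])

    def test_monotone_along_sorted_order_and_permutation_invariant(self):
        rng = np.random.default_rng(6)
        p = rng.uniform(size=50)
        adj = bh_adjust(p)
        order = np.argsort(p)
        assert (np.diff(adj[order]) >= -1e-12).all()
        perm = rng.permutation(50)
        np.testing.assert_allclose(bh_adjust(p[perm]), adj[perm])
        assert (adj >= p).all() and (adj <= 1).all()


class TestAtPeak:
    def test_cutoff_is_min_plus_three_quarters_of_range(self):
        table = make_table({"g": [10, 20, 90, 100]})
        peaks = at_peak(table, ["g"], q=0.75)
        # cutoff = 10 + 0.75 * 90 = 77.5 -> POST and ADULT qualify
        assert peaks.matrix.loc["g"].tolist() == [False, False, True, True]

    def test_constant_gene_peaks_everywhere(self):
        table = make_table({"g": [5, 5, 5, 5]})
        assert at_peak(table, ["g"]).matrix.loc["g"].all()

    def test_strictly_increasing_gene_peaks_at_last_stage(self):
        table = make_table({"g": [1, 2, 4, 8]})
        assert bool(at_peak(table, ["g"]).matrix.at["g", "ADULT"])

    def test_every_gene_peaks_somewhere_and_scaling_is_invariant(self):
        rng = np.random.default_rng(5)
        table = make_table({f"g{i}": rng.integers(0, 1000, 4).tolist()
                            for i in range(50)})
        peaks = at_peak(table, table.gene_ids)
        assert peaks.matrix.any(axis=1).all()
        scaled = make_table({g: (table.counts.loc[g] * 7.5).tolist()
                             for g in table.gene_ids})
        pd.testing.assert_frame_equal(at_peak(scaled, table.gene_ids).matrix,
                                      peaks.matrix)


def enumeration_fisher(n_universe, family, at_peak_total, overlap):
    """Exact tails by explicit enumeration over fixed-margin 2x2 tables."""
    denom = math.comb(n_universe, at_peak_total)
    lo = max(0, at_peak_total - (n_universe - family))
    hi = min(family, at_peak_total)
    probs = {j: math.comb(family, j) * math.comb(n_universe - family,
                                                 at_peak_total - j) / denom
             for j in range(lo, hi + 1)}
    upper = sum(p for j, p in probs.items() if j >= overlap)
    lower = sum(p for j, p in probs.items() if j <= overlap)
    return upper, lower


def peaks_from_counts(n_universe, at_peak_total, family, overlap, stage="PRE"):
    """One-stage AtPeakMatrix realizing the requested 2x2 table."""
    genes = [f"g{i}" for i in range(n_universe)]
    fam = genes[:family]
    col = np.zeros(n_universe, dtype=bool)
    col[:overlap] = True                      # family members at peak
    col[family:family + (at_peak_total - overlap)] = True
    matrix = pd.DataFrame({stage: col}, index=genes)
    return fam, AtPeakMatrix(matrix=matrix, q=0.75)


class TestStageFamily:
    def test_worked_example_matches_closed_form(self):
        fam, peaks = peaks_from_counts(20, 4, 5, 4)
        enr, dep = stage_family_enrichment(fam, peaks, "PRE")
        assert enr.p_raw == pytest.approx(5 / 4845, rel=1e-9)
        assert enr.overlap == 4

    def test_background_rate_family_is_not_enriched(self):
        fam, peaks = peaks_from_counts(20, 10, 10, 5)  # family rate == background
        enr, _ = stage_family_enrichment(fam, peaks, "PRE")
        assert enr.p_raw >= 0.5

    def test_matches_enumeration_for_small_margins(self):
        for n in (6, 9, 12):
            for family in (2, n // 2):
                for total in (1, n // 3, n - 2):
                    lo = max(0, total - (n - family))
                    hi = min(family, total)
                    for overlap in range(lo, hi + 1):
                        fam, peaks = peaks_from_counts(n, total, family, overlap)
                        enr, dep = stage_family_enrichment(fam, peaks, "PRE")
                        upper, lower = enumeration_fisher(n, family, total, overlap)
                        assert enr.p_raw == pytest.approx(upper, abs=1e-12)
                        assert dep.p_raw == pytest.approx(lower, abs=1e-12)

    def test_enrichment_of_family_equals_depletion_of_complement(self):
        fam, peaks = peaks_from_counts(20, 7, 6, 5)
        comp = sorted(set(peaks.universe) - set(fam))
        enr, _ = stage_family_enrichment(fam, peaks, "PRE")
        _, dep = stage_family_enrichment(comp, peaks, "PRE")
        assert enr.p_raw == pytest.approx(dep.p_raw, rel=1e-9)

    def test_empty_family_rejected(self):
        _, peaks = peaks_from_counts(10, 3, 2, 1)
        with pytest.raises(ValueError):
            stage_family_enrichment([], peaks, "PRE")
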