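import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from spongetx.enrichment import transfer_annotations
from spongetx.synthetic_data import (SynthConfig, SynthTruth, evaluate_calls,
                                     generate_dataset,
                                     generate_technical_replicates,
                                     planted_stage_specific_table, write_dataset)


class TestConfig:
    def test_fractions_must_sum_to_one(self):
        with pytest.raises(ValueError, match="sum to 1"):
            SynthConfig(seed=1, class_fractions={"constant": 0.9, "silent": 0.2,
                                                 "stage_specific": 0.0,
                                                 "transition": 0.0})

    def test_unknown_keys_rejected(self):
        with pytest.raises(ValueError, match="unknown"):
            SynthConfig.from_dict({"seed": 1, "bogus": 3})

    def test_depths_must_match_stages(self):
        with pytest.raises(ValueError):
            SynthConfig(seed=1, depths=(1.0, 2.0))


class TestGeneration:
    def test_gene_count_is_conserved(self):
        ds = generate_dataset(SynthConfig(seed=7, n_genes=100, n_reads=500))
        assert len(ds.models) == 100
        assert len(ds.counts.gene_ids) == 100
        assert len(ds.truth.genes) == 100

    def test_all_constant_config_has_flat_truth(self):
        cfg = SynthConfig(seed=7, n_genes=50, n_reads=500,
                          class_fractions={"constant": 1.0, "stage_specific": 0.0,
                                           "transition": 0.0, "silent": 0.0})
        ds = generate_dataset(cfg)
        p = ds.truth.expression
        # relative abundance identical across stages when nothing is planted
        np.testing.assert_allclose(
            p.to_numpy(), np.tile(p.iloc[:, [0]].to_numpy(), (1, p.shape[1])),
            rtol=1e-12)

    def test_same_seed_writes_byte_identical_files(self, tmp_path):
        cfg = SynthConfig(seed=7, n_genes=60, n_reads=400)
        h = {}
        for run in ("a", "b"):
            paths = write_dataset(generate_dataset(cfg), tmp_path / run)
            h[run] = {k: hashlib.sha256(p.read_bytes()).hexdigest()
                      for k, p in paths.items()}
        assert h["a"] == h["b"]

    def test_column_totals_concentrate_around_configured_depths(self, small_dataset):
        cfg = small_dataset.truth.config
        for depth, stage in zip(cfg.depths, cfg.stage_ids):
            total = small_dataset.counts.counts[stage].sum()
            assert abs(total - depth) <= 3 * np.sqrt(depth)

    def test_truth_round_trips_through_json(self, tmp_path, small_dataset):
        path = tmp_path / "truth.json"
        small_dataset.truth.to_json(path)
        again = SynthTruth.from_json(path)
        pd.testing.assert_frame_equal(again.genes, small_dataset.truth.genes)
        pd.testing.assert_frame_equal(again.expression,
                                      small_dataset.truth.expression)
        assert again.planted_terms == small_dataset.truth.planted_terms


class TestReplicates:
    def test_silent_gene_is_zero_in_both(self):
        cfg = SynthConfig(seed=1, n_genes=4)
        expr = np.array([0.0, 10.0, 5.0, 0.0])
        r1, r2 = generate_technical_replicates(cfg, expr)
        assert r1[0] == r2[0] == 0 and r1[3] == r2[3] == 0

    def test_difference_variance_matches_poisson_oracle(self):
        # at mean 64, sd(rep1 - rep2) should be sqrt(2 * 64)
        cfg = SynthConfig(seed=1, n_genes=4)
        rng = np.random.default_rng(17)
        expr = np.full(100_000, 1.0)
        r1, r2 = generate_technical_replicates(cfg, expr, rng=rng,
                                               depth=64.0 * 100_000)
        sd = (r1.astype(float) - r2).std()
        assert sd == pytest.approx(np.sqrt(128.0), rel=0.02)

    def test_deep_replicates_agree_tightly(self):
        cfg = SynthConfig(seed=1, n_genes=4)
        rng = np.random.default_rng(19)
        r1, r2 = generate_technical_replicates(cfg, np.ones(20), rng=rng,
                                               depth=20e6)
        ratio = r1 / r2
        assert (np.abs(ratio - 1) < 0.01).all()


class TestPlantedStructure:
    def test_planted_terms_are_hypergeometrically_enriched(self, small_dataset):
        ds = small_dataset
        gene_terms, _ = transfer_annotations(ds.annotations, ds.subject_terms)
        universe = sorted(gene_terms)
        truth = ds.truth
        for label, terms in truth.planted_terms.items():
            cls, key, direction = label.split(":")
            g = truth.genes
            if cls == "stage_specific":
                members = g[(g["class_label"] == cls) & (g["focal_stage"] == key)
                            & (g["direction"] == direction)].index
            else:
                members = g[(g["class_label"] == cls) & (g["transition"] == key)
                            & (g["direction"] == direction)].index
            members = sorted(set(members) & set(universe))
            if len(members) < 10:
                continue  # tiny classes at desk scale carry no testable signal
            for term in terms:
                term_genes = {x for x in universe if term in gene_terms[x]}
                overlap = len(term_genes & set(members))
                p = stats.hypergeom.sf(overlap - 1, len(universe),
                                       len(term_genes), len(members))
                assert p < 1e-3

    def test_planted_table_recovers_exact_means(self):
        table, truth = planted_stage_specific_table(500, baseline=256, fold=8,
                                                    focal="COMP", seed=3)
        planted = truth.index[truth["planted"]]
        rest = truth.index[~truth["planted"]]
        assert table.counts.loc[planted, "COMP"].mean() == pytest.approx(2048, rel=0.05)
        assert table.counts.loc[rest, "COMP"].mean() == pytest.approx(256, rel=0.05)


class TestEvaluation:
    def _truth(self, small_dataset):
        return small_dataset.truth

    def test_perfect_calls_score_perfectly(self, small_dataset):
        truth = self._truth(small_dataset)
        ss = truth.genes[truth.genes["class_label"] == "stage_specific"]
        calls = pd.DataFrame({
            "gene_id": ss.index,
            "contrast": ss["focal_stage"],
            "direction": ss["direction"],
        })
        metrics = evaluate_calls(truth, calls)
        assert metrics["stage_specific"]["sensitivity"] == 1.0
        assert metrics["stage_specific"]["false_discovery_proportion"] == 0.0
        assert metrics["stage_specific"]["direction_accuracy"] == 1.0

    def test_empty_call_set_has_zero_sensitivity(self, small_dataset):
        truth = self._truth(small_dataset)
        calls = pd.DataFrame({"gene_id": list(truth.genes.index[:5]),
                              "contrast": ["PRE"] * 5,
                              "direction": ["unchanged"] * 5})
        metrics = evaluate_calls(truth, calls)
        assert metrics["stage_specific"]["sensitivity"] == 0.0

    def test_unknown_gene_id_rejected(self, small_dataset):
        truth = self._truth(small_dataset)
        calls = pd.DataFrame({"gene_id": ["not_a_gene"], "contrast": ["PRE"],
                              "direction": ["up"]})
        with pytest.raises(ValueError, match="mismatch"):
            evaluate_calls(truth, calls)

    def test_metrics_match_confusion_matrix_recomputation(self, small_dataset):
        truth = self._truth(small_dataset)
        rng = np.random.default_rng(4)
        ss = truth.genes[truth.genes["class_label"] == "stage_specific"]
        hit = ss.sample(frac=0.6, random_state=1)
        null = truth.genes[truth.genes["class_label"] == "constant"].sample(
            10, random_state=2)
        calls = pd.DataFrame({
            "gene_id": list(hit.index) + list(null.index),
            "contrast": list(hit["focal_stage"]) + ["PRE"] * len(null),
            "direction": list(hit["direction"]) + ["up"] * len(null),
        })
        metrics = evaluate_calls(truth, calls)
        called = set(calls["gene_id"])
        tp = called & set(ss.index)
        assert metrics["stage_specific"]["sensitivity"] == pytest.approx(
            len(tp) / len(ss))
        assert metrics["stage_specific"]["false_discovery_proportion"] == \
            pytest.approx(len(null) / len(called))
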