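"""Balanced forests, Brier scoring, model comparison, and importance."""

import numpy as np
import pandas as pd
import pytest

from wearphen.modeling import (
    BalancedRandomForest,
    MODEL_TYPES,
    ModelSpec,
    RiskModel,
    assemble_model_features,
    brier_score,
    compare_models,
    evaluate_model,
    model_spec,
    rank_importance,
)


class TestModelSpecs:
    @pytest.mark.parametrize(
        "name,count",
        [
            ("Baseline", 2),
            ("RestingHR", 3),
            ("SummaryStats", 12),
            ("HighRes.ActiveSeg", 24),
            ("HighRes.SedenSeg", 24),
            ("HighRes.SleepSeg", 24),
            ("Unified", 79),
        ],
    )
    def test_feature_counts(self, name, count):
        assert len(model_spec(name).columns()) == count

    def test_all_types_contain_baseline(self):
        for name in MODEL_TYPES:
            cols = model_spec(name).columns()
            assert "age" in cols and "gender" in cols

    def test_age_dropped_for_genomic_targets(self):
        cols = model_spec("HighRes.SedenSeg", include_age=False).columns()
        assert "age" not in cols and "gender" in cols
        assert len(cols) == 23

    def test_unknown_type_rejected(self):
        with pytest.raises(ValueError):
            model_spec("DeepNet")

    def test_assemble_names_missing_column(self):
        table = pd.DataFrame({"age": [1.0], "gender": [0.0]})
        with pytest.raises(KeyError, match="resting_hr"):
            assemble_model_features(table, model_spec("RestingHR"))


class TestBrierScore:
    def test_perfect_predictions_score_zero(self):
        assert brier_score([1.0, 0.0, 1.0], [1, 0, 1]) == 0.0

    def test_uninformative_half_scores_quarter(self):
        assert brier_score([0.5] * 8, [1, 0, 1, 1, 0, 0, 1, 0]) == 0.25

    def test_worked_example(self):
        assert brier_score([0.8, 0.3], [1, 0]) == pytest.approx(0.065)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            brier_score([0.5], [1, 0])

    def test_out_of_range_probability_rejected(self):
        with pytest.raises(ValueError):
            brier_score([1.2], [1])


def _noise_data(n=200, p=6, seed=0, pos=None):
    rng = np.random.default_rng(seed)
    X = pd.DataFrame(rng.normal(size=(n, p)), columns=[f"f{i}" for i in range(p)])
    y = np.zeros(n, dtype=int)
    pos = n // 2 if pos is None else pos
    y[:pos] = 1
    rng.shuffle(y)
    return X, y


class TestBalancedForest:
    def test_each_tree_trains_on_twice_80pct_of_minority(self):
        X, y = _noise_data(n=250, pos=100, seed=1)  # minority size 100
        forest = BalancedRandomForest(n_trees=25, seed=0).fit(X, y)
        assert forest.per_tree_sample_size_ == 160
        for tree in forest.trees_:
            assert tree.tree_.n_node_samples[0] == 160

    def test_same_seed_reproduces_oob_probabilities(self):
        X, y = _noise_data(seed=2)
        a = BalancedRandomForest(n_trees=40, seed=9).fit(X, y)
        b = BalancedRandomForest(n_trees=40, seed=9).fit(X, y)
        np.testing.assert_array_equal(a.oob_probability_, b.oob_probability_)

    def test_wide_margin_data_scores_nearly_zero(self):
        rng = np.random.default_rng(3)
        n = 300
        y = rng.integers(0, 2, n)
        X = pd.DataFrame({"sig": y * 10.0 + rng.normal(0, 0.1, n),
                          "noise": rng.normal(size=n)})
        forest = BalancedRandomForest(n_trees=150, min_samples_leaf=5, seed=0).fit(X, y)
        assert forest.oob_brier() < 0.05

    def test_label_permutation_null_is_calibrated(self):
        X, y = _noise_data(n=400, p=24, seed=4)
        scores = [
            BalancedRandomForest(n_trees=250, seed=s).fit(X, y).oob_brier()
            for s in range(3)
        ]
        assert 0.23 < np.mean(scores) < 0.27

    def test_single_class_labels_rejected(self):
        X, _ = _noise_data(seed=5)
        with pytest.raises(ValueError):
            BalancedRandomForest(n_trees=5).fit(X, np.zeros(len(X), dtype=int))

    def test_tiny_sample_rejected(self):
        X, y = _noise_data(n=10, seed=6, pos=5)
        with pytest.raises(ValueError):
            BalancedRandomForest(n_trees=5).fit(X.iloc[:10], y[:10])


class TestEvaluateAndCompare:
    def test_replicate_count_matches_request(self):
        X, y = _noise_data(n=100, seed=7)
        ev = evaluate_model(X, y, ModelSpec("noise", tuple(X.columns)), n_replicates=5,
                            n_trees=30, seed=0)
        assert len(ev.brier_scores) == 5

    def test_identical_models_compare_flat(self):
        X, y = _noise_data(n=100, seed=8)
        spec = ModelSpec("noise", tuple(X.columns))
        a = RiskModel(X, y, spec=spec, n_trees=30).fit(n_replicates=4, seed=1)
        b = RiskModel(X, y, spec=spec, n_trees=30).fit(n_replicates=4, seed=1)
        row = compare_models([a, b]).iloc[0]
        assert row.p_value == 1.0
        assert row.mean_difference == 0.0

    def test_planted_signal_beats_noise_model_decisively(self):
        rng = np.random.default_rng(9)
        n = 240
        y = rng.integers(0, 2, n)
        table = pd.DataFrame(
            {
                "sig": y + rng.normal(0, 0.4, n),
                "n1": rng.normal(size=n),
                "n2": rng.normal(size=n),
            }
        )
        good = RiskModel(table, y, spec=ModelSpec("signal", ("sig", "n1"))).fit(
            n_replicates=8, seed=0
        )
        bad = RiskModel(table, y, spec=ModelSpec("noise", ("n1", "n2"))).fit(
            n_replicates=8, seed=0
        )
        comp = compare_models([bad, good])
        row = comp.iloc[0]
        assert good.mean_brier < bad.mean_brier
        assert row.q_value < 0.001
        assert row.improvement_pct > 0

    def test_qvalues_dominate_pvalues_and_are_monotone(self):
        X, y = _noise_data(n=120, seed=10)
        specs = [ModelSpec(f"m{i}", tuple(X.columns[: 2 + i])) for i in range(4)]
        results = [
            RiskModel(X, y, spec=s, n_trees=25).fit(n_replicates=4, seed=i)
            for i, s in enumerate(specs)
        ]
        table = compare_models(results)
        assert (table.q_value >= table.p_value - 1e-12).all()
        srt = table.sort_values("p_value")
        assert srt.q_value.is_monotonic_increasing

    def test_mismatched_replicate_counts_rejected(self):
        X, y = _noise_data(n=100, seed=11)
        spec = ModelSpec("noise", tuple(X.columns))
        a = RiskModel(X, y, spec=spec, n_trees=20).fit(n_replicates=3, seed=0)
        b = RiskModel(X, y, spec=spec, n_trees=20).fit(n_replicates=4, seed=0)
        with pytest.raises(ValueError):
            compare_models([a, b])


class TestImportance:
    def test_dominant_feature_ranks_first(self):
        rng = np.random.default_rng(12)
        n = 240
        y = rng.integers(0, 2, n)
        table = pd.DataFrame(
            {"aaa_noise": rng.normal(size=n), "planted": y + rng.normal(0, 0.3, n),
             "zzz_noise": rng.normal(size=n)}
        )
        res = RiskModel(table, y, spec=ModelSpec("m", tuple(table.columns)),
                        n_trees=60).fit(n_replicates=2, seed=0, compute_importance=True)
        assert res.top_features(1) == ["planted"]

    def test_rank_union_preserves_order_and_caps_length(self):
        rng = np.random.default_rng(13)
        n = 200
        y = rng.integers(0, 2, n)
        table = pd.DataFrame(rng.normal(size=(n, 12)),
                             columns=[f"f{i:02d}" for i in range(12)])
        results = {}
        for t, target in enumerate(["t1", "t2"]):
            results[target] = RiskModel(
                table, y, spec=ModelSpec("m", tuple(table.columns)), n_trees=30, target=target
            ).fit(n_replicates=2, seed=t, compute_importance=True)
        per_target, union = rank_importance(results, k=10)
        assert all(len(v) == 10 for v in per_target.values())
        assert len(union) <= 20
        assert len(union) == len(set(union))

    def test_summary_mentions_scores_and_features(self):
        X, y = _noise_data(n=100, seed=14)
        res = RiskModel(X, y, spec=ModelSpec("m", tuple(X.columns)), n_trees=20).fit(
            n_replicates=3, seed=0
        )
        text = res.summary()
        assert "OOB Brier" in text and "replicates:          3" in text
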