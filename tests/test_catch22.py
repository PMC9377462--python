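"""The 22 canonical characteristics: reference equivalence and properties."""

import csv
from pathlib import Path

import numpy as np
import pytest

from wearphen.catch22 import (
    FEATURE_NAMES,
    FeatureVector,
    HighResFeatures,
    co_trev_1_num,
    compute_catch22,
    dn_histogram_mode,
    high_res_features,
    pairwise_state_correlations,
    segment_length_sensitivity,
    zscore,
)

from reference_series import N_SERIES, reference_series

DATA = Path(__file__).parent / "data" / "catch22_reference.csv"


def _load_reference():
    with open(DATA) as fh:
        return list(csv.DictReader(fh))


class TestReferenceEquivalence:
    def test_matches_published_reference_within_1e6_relative(self):
        """All 22 features agree with the reference implementation's frozen
        values on 100 regenerated series of lengths 50-500."""
        rows = _load_reference()
        assert len(rows) == N_SERIES
        worst = 0.0
        for row in rows:
            i = int(row["series_index"])
            y = reference_series(i)
            assert y.size == int(row["n"])
            mine = compute_catch22(y)
            for name in FEATURE_NAMES:
                ref = float(row[name])
                got = mine[name]
                err = abs(got - ref) / max(abs(ref), 1e-10)
                worst = max(worst, err)
                assert err <= 1e-6, f"series {i}, {name}: {got} vs {ref}"
        assert worst <= 1e-6


class TestZScore:
    def test_symmetric_triple(self):
        z, flat = zscore([1.0, 2.0, 3.0])
        assert not flat
        assert z.tolist() == [-1.0, 0.0, 1.0]

    def test_constant_input_flagged(self):
        z, flat = zscore([5.0, 5.0, 5.0, 5.0])
        assert flat
        assert (z == 0).all()

    def test_affine_invariance_propagates_to_features(self):
        rng = np.random.RandomState(4)
        y = rng.randn(120)
        a = compute_catch22(y)
        b = compute_catch22(3.7 * y + 55.0)
        for name in FEATURE_NAMES:
            assert a[name] == pytest.approx(b[name], rel=1e-9, abs=1e-9)

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            zscore([1.0])


class TestTrev:
    def test_alternating_sequence_cancels(self):
        # odd length gives an even number of successive differences, whose
        # cubes (+8 and -8) pair off exactly
        y = np.concatenate([np.tile([1.0, -1.0], 10), [1.0]])
        assert co_trev_1_num(y) == pytest.approx(0.0)

    def test_rising_ramp_positive(self):
        z, _ = zscore(np.arange(30.0))
        # direct evaluation: equal steps d>0 give mean(d^3) > 0
        d = z[1] - z[0]
        assert co_trev_1_num(z) == pytest.approx(d**3)
        assert co_trev_1_num(z) > 0

    def test_antisymmetric_under_time_reversal(self):
        rng = np.random.RandomState(9)
        for _ in range(10):
            y = rng.randn(rng.randint(20, 200))
            assert co_trev_1_num(y[::-1]) == pytest.approx(-co_trev_1_num(y), rel=1e-12)


class TestHistogramMode:
    def test_concentrated_sample_mode_near_zero(self):
        rng = np.random.RandomState(11)
        z, _ = zscore(rng.randn(5000))
        assert abs(dn_histogram_mode(z, 5)) < 0.7  # within one bin width of 0

    def test_outlier_pattern_puts_mode_in_heavy_bin(self):
        # 99 points near 5.0 and one at 0: brute-force binning says the top
        # bin (containing the cluster) wins
        y = np.concatenate([np.full(99, 5.0) + np.arange(99) * 1e-4, [0.0]])
        z, _ = zscore(y)
        counts, edges = np.histogram(z, bins=5, range=(z.min(), z.max()))
        expected_center = 0.5 * (edges[-2] + edges[-1])
        assert counts.argmax() == 4
        assert dn_histogram_mode(z, 5) == pytest.approx(expected_center, rel=1e-6)

    def test_tied_bins_average_their_centers(self):
        # two bins with equal counts; the reference convention averages them
        y = np.array([0.05, 0.1, 2.1, 2.15, 4.0, 1.0])
        centers = []
        step = (y.max() - y.min()) / 5
        idx = np.clip(((y - y.min()) / step).astype(int), 0, 4)
        counts = np.bincount(idx, minlength=5)
        tied = np.nonzero(counts == counts.max())[0]
        centers = y.min() + step * (tied + 0.5)
        assert dn_histogram_mode(y, 5) == pytest.approx(centers.mean())


class TestDegenerateInputs:
    def test_constant_segment_gives_zero_vector_with_flags(self):
        vec = compute_catch22([64.0] * 50)
        assert all(vec[name] == 0.0 for name in FEATURE_NAMES)
        assert vec.degenerate == frozenset(FEATURE_NAMES)

    def test_fluctuation_features_zero_on_20_point_segments(self):
        rng = np.random.RandomState(13)
        for _ in range(25):
            vec = compute_catch22(rng.uniform(50, 120, 20))
            assert vec["SC_FluctAnal_2_rsrangefit_50_1_logi_prop_r1"] == 0.0
            assert vec["SC_FluctAnal_2_dfa_50_1_2_logi_prop_r1"] == 0.0

    def test_all_values_finite_on_varied_inputs(self):
        rng = np.random.RandomState(14)
        for n in (5, 10, 21, 60, 300):
            vec = compute_catch22(rng.randn(n))
            assert np.isfinite(vec.as_array()).all()

    def test_wrong_name_set_rejected(self):
        with pytest.raises(ValueError):
            FeatureVector(values={"foo": 1.0})


class TestHighResFeatures:
    def test_all_three_states_give_66_features(self, small_cohort):
        from wearphen.pipeline import process_recording

        series = process_recording(next(iter(small_cohort.recordings.values())))
        feats = high_res_features(series)
        row = feats.to_row()
        assert len(row) == 66
        assert sum(k.endswith(".sedentary") for k in row) == 22

    def test_missing_state_omitted(self):
        from wearphen.annotation import annotate_states

        from conftest import make_minute_series

        steps = np.zeros(200)
        steps[0:45] = 5  # active 45, sedentary 155, no sleep log
        series = annotate_states(make_minute_series(np.random.RandomState(0).uniform(60, 90, 200), steps))
        row = high_res_features(series).to_row()
        assert len(row) == 44
        assert not any(k.endswith(".sleep") for k in row)

    def test_no_segments_gives_empty_mapping(self):
        from wearphen.annotation import annotate_states

        from conftest import make_minute_series

        series = annotate_states(make_minute_series([70.0] * 10, [5.0] * 10))
        assert high_res_features(series).states == {}


def _fake_features(rng, n, overrides=None):
    """Synthesize HighResFeatures with random per-state values."""
    out = []
    for i in range(n):
        states = {}
        for state in ("ACTIVE", "SEDENTARY", "SLEEP"):
            vals = {name: float(rng.randn()) for name in FEATURE_NAMES}
            if overrides:
                vals.update(overrides(state, i))
            states[state] = FeatureVector(values={k: vals[k] for k in FEATURE_NAMES})
        out.append(HighResFeatures(participant_id=f"P{i}", states=states))
    return out


class TestStateCorrelations:
    def test_identical_features_across_states_correlate_fully(self):
        rng = np.random.RandomState(17)
        shared = {i: {name: float(rng.randn()) for name in FEATURE_NAMES} for i in range(20)}
        feats = _fake_features(rng, 20, overrides=lambda s, i: shared[i])
        table = pairwise_state_correlations(feats)
        assert np.allclose(table["correlation"], 1.0)

    def test_constant_feature_in_one_state_is_na(self):
        rng = np.random.RandomState(18)

        def overrides(state, i):
            if state == "ACTIVE":
                return {"SC_FluctAnal_2_dfa_50_1_2_logi_prop_r1": 0.0}
            return {}

        table = pairwise_state_correlations(_fake_features(rng, 15, overrides))
        sub = table[
            (table["feature"] == "SC_FluctAnal_2_dfa_50_1_2_logi_prop_r1")
            & (table["state_a"] == "ACTIVE")
        ]
        assert sub["correlation"].isna().all()

    def test_independent_features_weakly_correlated(self):
        rng = np.random.RandomState(19)
        table = pairwise_state_correlations(_fake_features(rng, 500))
        trev = table[table["feature"] == "CO_trev_1_num"]
        assert (trev["correlation"].abs() < 0.1).all()


class TestLengthSensitivity:
    def test_equal_lengths_give_unit_correlation(self, small_cohort):
        from wearphen.pipeline import process_recording

        series = [process_recording(r) for r in small_cohort.recordings.values()]
        table = segment_length_sensitivity(series, "SEDENTARY", [20, 20])
        same = table[table["length_a"] == table["length_b"]]
        nonconst = same.dropna(subset=["correlation"])
        assert np.allclose(nonconst["correlation"], 1.0)

    def test_nearby_lengths_computable_for_all_features(self, small_cohort):
        from wearphen.pipeline import process_recording

        series = [process_recording(r) for r in small_cohort.recordings.values()]
        table = segment_length_sensitivity(series, "SEDENTARY", [40, 60])
        pair = table[table["length_a"] != table["length_b"]]
        assert len(pair) == 22

    def test_insufficient_participants_rejected(self, small_cohort):
        from wearphen.pipeline import process_recording

        series = [process_recording(next(iter(small_cohort.recordings.values())))]
        with pytest.raises(ValueError):
            segment_length_sensitivity(series, "SEDENTARY", [20, 30])
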