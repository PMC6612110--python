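import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from egohand.timeline import (Timeline, build_timeline,
                              extract_metrics, smooth_threshold,
                              validate_metrics)

FPS = 30.0


def _smooth_oracle(x, window=120, threshold=0.5):
    """Direct per-index implementation of the moving average ->
    normalisation -> threshold chain."""
    x = np.asarray(x, float)
    n = x.size
    out = np.empty(n)
    for i in range(n):
        lo = max(i - window // 2, 0)
        hi = min(i + window - window // 2, n)
        out[i] = x[lo:hi].mean()
    mn, mx = out.min(), out.max()
    if mx > mn:
        out = (out - mn) / (mx - mn)
    return (out >= threshold).astype(int)


class TestBuildTimeline:
    def _states(self, tl):
        return list(tl.states)

    def test_gap_of_60_after_interaction_is_bridged(self):
        fs = {0: "interaction", 61: "interaction"}
        tl = build_timeline(fs, 62, FPS)
        assert all(s == "interaction" for s in tl.states)

    def test_gap_of_exactly_90_is_bridged(self):
        fs = {0: "interaction", 91: "interaction"}
        tl = build_timeline(fs, 92, FPS)
        assert all(s == "interaction" for s in tl.states)

    def test_gap_of_91_is_not_bridged(self):
        fs = {0: "interaction", 92: "interaction"}
        tl = build_timeline(fs, 93, FPS)
        assert list(tl.states[1:92]) == ["no_interaction"] * 91

    def test_absence_after_no_interaction_not_bridged(self):
        fs = {0: "no_interaction", 10: "interaction"}
        tl = build_timeline(fs, 11, FPS)
        assert list(tl.states[1:10]) == ["no_interaction"] * 9

    def test_no_detections_gives_all_no_interaction(self):
        tl = build_timeline({}, 50, FPS)
        assert all(s == "no_interaction" for s in tl.states)

    def test_never_promotes_classifier_negative(self):
        fs = {5: "interaction", 6: "no_interaction"}
        tl = build_timeline(fs, 10, FPS)
        assert tl.states[6] == "no_interaction"

    def test_out_of_range_index_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            build_timeline({10: "interaction"}, 5, FPS)

    def test_trailing_absence_bridged_from_interaction(self):
        fs = {0: "interaction"}
        tl = build_timeline(fs, 30, FPS)
        assert all(s == "interaction" for s in tl.states)


class TestSmoothThreshold:
    def test_all_ones_stay_ones(self):
        out = smooth_threshold(np.ones(500))
        assert (out == 1).all()

    def test_all_zeros_stay_zeros(self):
        out = smooth_threshold(np.zeros(500))
        assert (out == 0).all()

    def test_single_spike_matches_convolution_oracle(self):
        x = np.zeros(3000)
        x[1500] = 1
        out = smooth_threshold(x)
        assert np.array_equal(out, _smooth_oracle(x))
        # normalisation rescales the lone spike's window to the maximum,
        # so a run around the spike survives the 0.5 threshold
        assert out.sum() > 0

    def test_square_wave_recovered_up_to_edge_shifts(self):
        x = np.tile(np.concatenate([np.ones(600), np.zeros(600)]), 3)
        out = smooth_threshold(x)
        assert np.array_equal(out, _smooth_oracle(x))
        assert np.count_nonzero(out != x) <= 60 * 6  # <= 60 per transition
        # interiors of each half-period are untouched
        assert (out[100:500] == 1).all()
        assert (out[700:1100] == 0).all()

    def test_idempotent_up_to_edge_windows(self):
        rng = np.random.default_rng(0)
        for _ in range(5):
            x = (rng.random(2000) < 0.4).astype(float)
            once = smooth_threshold(x)
            twice = smooth_threshold(once.astype(float))
            transitions = np.count_nonzero(np.diff(once))
            assert np.count_nonzero(once != twice) < 120 * max(transitions, 1)

    def test_accepts_timeline_object(self):
        tl = Timeline(states=np.array(["interaction"] * 200), fps=FPS)
        assert (smooth_threshold(tl) == 1).all()


class TestExtractMetrics:
    def test_two_runs_hand_computed_values(self):
        x = np.zeros(3600, int)
        x[100:400] = 1
        x[2000:2300] = 1
        m = extract_metrics(x, FPS)
        assert m.pct_interaction == pytest.approx(100 * 600 / 3600, abs=1e-9)
        assert m.mean_duration_s == pytest.approx(10.0, abs=1e-9)
        assert m.interactions_per_hour == pytest.approx(60.0, abs=1e-9)

    def test_all_zero_sequence(self):
        m = extract_metrics(np.zeros(100, int), FPS)
        assert m.pct_interaction == 0.0
        assert m.mean_duration_s is None
        assert m.interactions_per_hour is None

    def test_all_one_sequence_single_run(self):
        n = 900
        m = extract_metrics(np.ones(n, int), FPS)
        assert m.pct_interaction == 100.0
        assert m.mean_duration_s == pytest.approx(n / FPS)
        assert m.interactions_per_hour == pytest.approx(3600 * FPS / n)

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            extract_metrics(np.array([]), FPS)

    @given(st.integers(min_value=0, max_value=2**31 - 1))
    @settings(max_examples=50, deadline=None)
    def test_conservation_identity(self, seed):
        """pct == n_runs x mean_duration / total_time x 100, exactly."""
        rng = np.random.default_rng(seed)
        x = (rng.random(rng.integers(10, 500)) < 0.3).astype(int)
        m = extract_metrics(x, FPS)
        if m.mean_duration_s is None:
            assert m.pct_interaction == 0.0
            return
        n_runs = m.interactions_per_hour * (x.size / FPS / 3600)
        ident = n_runs * m.mean_duration_s / (x.size / FPS) * 100
        assert m.pct_interaction == pytest.approx(ident, abs=1e-9)


class TestValidateMetrics:
    def test_perfect_agreement(self):
        rng = np.random.default_rng(0)
        v = rng.normal(10, 2, 9)
        res = validate_metrics(v, v)
        assert res.coefficient == pytest.approx(1.0)
        assert res.p_value < 0.05

    def test_normal_data_selects_pearson(self):
        rng = np.random.default_rng(1)
        a = rng.normal(0, 1, 20)
        b = a + rng.normal(0, 0.5, 20)
        assert validate_metrics(a, b).method == "pearson"

    def test_heavy_tailed_data_selects_spearman(self):
        rng = np.random.default_rng(2)
        a = rng.standard_cauchy(30)
        b = a + rng.normal(0, 0.1, 30)
        assert validate_metrics(a, b).method == "spearman"

    def test_antimonotone_heavy_tailed_pair(self):
        a = np.array([1.0, 2, 3, 4, 5, 6, 7, 8, 1000.0])
        b = -a
        res = validate_metrics(a, b)
        assert res.method == "spearman"
        assert res.coefficient == pytest.approx(-1.0)
        assert res.p_value > 0.95

    def test_constant_vector_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            validate_metrics(np.ones(9), np.arange(9.0))

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValueError):
            validate_metrics(np.array([1.0, 2]), np.array([1.0, 2]))
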