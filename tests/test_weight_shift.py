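import numpy as np
import pytest

from n2g.io_preproc import Recording
from n2g.weight_shift import (MergedTrace, compute_visit_shift,
                              merge_and_mirror, normalize_across_visits,
                              rescale_by_weight, windowed_shift,
                              WeightShiftSeries)
from oracles import brute_force_weight_shift


def force_recording(left, right, fs=100.0):
    return Recording(data=np.vstack([left, right]), fs=fs,
                     channel_labels=("FP_L", "FP_R"))


class TestRescale:
    def test_balanced_stance(self):
        rec = force_recording(np.full(10, 400.0), np.full(10, 400.0))
        out = rescale_by_weight(rec, 800.0)
        np.testing.assert_allclose(out.data, 0.5)

    def test_full_left_loading(self):
        rec = force_recording(np.full(10, 800.0), np.zeros(10))
        out = rescale_by_weight(rec, 800.0)
        np.testing.assert_allclose(out.data[0], 1.0)
        np.testing.assert_allclose(out.data[1], 0.0)

    def test_scale_invariance(self, rng):
        left = rng.uniform(0, 800, 50)
        right = rng.uniform(0, 800, 50)
        a = rescale_by_weight(force_recording(left, right), 800.0).data
        b = rescale_by_weight(force_recording(2 * left, 2 * right), 1600.0).data
        np.testing.assert_allclose(a, b)

    def test_nonpositive_weight(self):
        rec = force_recording(np.zeros(10), np.zeros(10))
        with pytest.raises(ValueError):
            rescale_by_weight(rec, 0.0)


class TestMergeAndMirror:
    def test_full_left(self):
        m = merge_and_mirror(np.array([1.0]), np.array([0.0]))
        assert m.values[0] == 1.0

    def test_full_right_mirrors_to_zero(self):
        m = merge_and_mirror(np.array([0.0]), np.array([1.0]))
        assert m.values[0] == 0.0

    def test_hand_evaluated_sequence(self):
        # left >= right -> left; else 1 - right
        m = merge_and_mirror(np.array([0.5, 0.7, 0.2]),
                             np.array([0.5, 0.3, 0.9]))
        np.testing.assert_allclose(m.values, [0.5, 0.7, 0.1])
        np.testing.assert_array_equal(m.origin_flags, [True, True, False])

    def test_balanced_is_half(self):
        m = merge_and_mirror(np.array([0.5]), np.array([0.5]))
        assert m.values[0] == 0.5

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            merge_and_mirror(np.zeros(3), np.zeros(4))

    def test_swap_antisymmetry(self, rng):
        left = rng.uniform(0, 1, 200)
        right = rng.uniform(0, 1, 200)
        m1 = merge_and_mirror(left, right).values
        m2 = merge_and_mirror(right, left).values
        # mirror identity holds wherever left != right; ties both give the
        # tied value, so 1 - m2 differs from m1 only at exact ties
        np.testing.assert_allclose(m1, 1.0 - m2, atol=1e-12)


class TestWindowedShift:
    def test_motionless_is_zero(self):
        merged = MergedTrace(values=np.full(500, 0.5), fs=100.0,
                             origin_flags=np.ones(500, bool))
        out = windowed_shift(merged)
        assert len(out) > 0
        np.testing.assert_allclose(out.raw_values, 0.0)

    def test_triangle_excursion_scores_two(self):
        vals = np.full(400, 0.0)
        # one full 0 -> 1 -> 0 excursion inside the second window
        vals[250:300] = np.linspace(0, 1, 50)
        vals[300:350] = np.linspace(1, 0, 50)
        merged = MergedTrace(values=vals, fs=100.0,
                             origin_flags=np.ones(400, bool))
        out = windowed_shift(merged)
        assert out.raw_values.max() == pytest.approx(2.0, abs=0.05)

    def test_homogeneity(self, rng):
        base = rng.uniform(0.3, 0.7, 600)
        m1 = MergedTrace(values=base, fs=100.0, origin_flags=np.ones(600, bool))
        m2 = MergedTrace(values=0.5 + 2 * (base - 0.5), fs=100.0,
                         origin_flags=np.ones(600, bool))
        np.testing.assert_allclose(windowed_shift(m2).raw_values,
                                   2 * windowed_shift(m1).raw_values,
                                   rtol=1e-9)

    def test_times_on_grid(self):
        merged = MergedTrace(values=np.zeros(1000), fs=100.0,
                             origin_flags=np.ones(1000, bool))
        out = windowed_shift(merged)
        np.testing.assert_allclose(out.times, np.arange(2.0, 10.01, 0.1))

    def test_too_short_warns_empty(self):
        merged = MergedTrace(values=np.zeros(100), fs=100.0,
                             origin_flags=np.ones(100, bool))
        with pytest.warns(UserWarning):
            out = windowed_shift(merged)
        assert len(out) == 0


class TestNormalize:
    def _series(self, peak):
        vals = np.linspace(0, peak, 50)
        return WeightShiftSeries(times=np.arange(50) * 0.1 + 2.0,
                                 raw_values=vals)

    def test_three_visit_normalizer(self):
        out = normalize_across_visits({"a": self._series(1.4),
                                       "b": self._series(2.0),
                                       "c": self._series(1.1)})
        assert out["a"].normalizer == pytest.approx(2.0)
        assert out["a"].normalized_values.max() == pytest.approx(0.7)
        assert out["b"].normalized_values.max() == pytest.approx(1.0)

    def test_single_visit(self):
        out = normalize_across_visits({"only": self._series(0.42)})
        assert out["only"].normalized_values.max() == pytest.approx(1.0)

    def test_restricted_normalizer(self):
        out = normalize_across_visits({"train": self._series(1.0),
                                       "test": self._series(4.0)},
                                      normalizer_visits=["train"])
        assert out["test"].normalized_values.max() == pytest.approx(4.0)

    def test_all_zero_rejected(self):
        zero = WeightShiftSeries(times=np.arange(5.0), raw_values=np.zeros(5))
        with pytest.raises(ValueError, match="no movement"):
            normalize_across_visits({"a": zero})

    def test_ranges_within_unit_interval(self, rng):
        visits = {f"v{i}": self._series(rng.uniform(0.5, 3.0))
                  for i in range(3)}
        out = normalize_across_visits(visits)
        for series in out.values():
            assert series.normalized_values.min() >= 0.0
            assert series.normalized_values.max() <= 1.0 + 1e-12
        peaks = [s.normalized_values.max() for s in out.values()]
        assert max(peaks) == pytest.approx(1.0)


class TestOracleEquivalence:
    def test_pipeline_matches_brute_force(self, rng):
        weight = 800.0
        for _ in range(20):
            n = int(rng.integers(300, 800))
            left = rng.uniform(0, weight, n)
            right = rng.uniform(0, weight, n)
            rec = rescale_by_weight(force_recording(left, right), weight)
            out = compute_visit_shift(rec)
            t_ref, v_ref = brute_force_weight_shift(left, right, weight)
            np.testing.assert_allclose(out.times, t_ref, atol=1e-9)
            np.testing.assert_allclose(out.raw_values, v_ref, atol=1e-9)

    def test_swap_invariance_of_shift(self, rng):
        left = rng.uniform(0, 1, 500)
        right = rng.uniform(0, 1, 500)
        a = windowed_shift(merge_and_mirror(left, right)).raw_values
        b = windowed_shift(merge_and_mirror(right, left)).raw_values
        np.testing.assert_allclose(a, b, atol=1e-9)


def test_amplitude_monotonicity():
    """Larger stepping amplitude does not decrease the mean raw shift."""
    from n2g.synthetic_data import SyntheticSpec, generate_forces, _smooth_vigor
    from n2g.io_preproc import preprocess_force
    means = []
    for scale in (0.4, 1.0):
        spec = SyntheticSpec(seed=3, duration_s=20.0, baseline_s=5.0,
                             force_noise_n=0.0)
        rng = np.random.default_rng(3)
        vigor = _smooth_vigor(spec, rng, amplitude_scale=scale)
        force, _ = generate_forces(spec, rng, vigor=vigor)
        bw = rescale_by_weight(preprocess_force(force), spec.weight_n)
        means.append(compute_visit_shift(bw).raw_values.mean())
    assert means[1] >= means[0]
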