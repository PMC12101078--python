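"""KDE estimation, threshold detection, and binding-percentage summaries."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from membind import (
    AnalysisConfig,
    InsufficientDataError,
    ParameterError,
    ReplicaSet,
    MinDistanceTrace,
    bound_fraction,
    detect_bound_threshold,
    estimate_kde,
    simulate_replicas,
    summarize_binding,
)

from conftest import make_params


def make_trace(values):
    values = np.asarray(values, dtype=float)
    return MinDistanceTrace(times=np.arange(values.size, dtype=float), values=values)


def bimodal_sample(rng, n=4000, w=0.5):
    """Distance-like mixture: contact mode ~0.45 nm, unbound mode ~2.5 nm."""
    n1 = rng.binomial(n, w)
    x = np.concatenate([
        rng.normal(0.45, 0.05, n1),
        rng.normal(2.5, 0.3, n - n1),
    ])
    return np.abs(x)


class TestKde:
    def test_density_integrates_to_one_and_peaks_at_the_mode(self):
        rng = np.random.default_rng(0)
        sample = np.abs(rng.normal(2.0, 0.3, 40_000))
        curve = estimate_kde(make_trace(sample), bandwidth=0.05)
        assert curve.integral() == pytest.approx(1.0, abs=1e-9)
        peak = curve.grid[np.argmax(curve.density)]
        assert abs(peak - 2.0) <= 0.05

    def test_constant_trace_yields_single_peak_at_value(self):
        curve = estimate_kde(make_trace(np.full(100, 1.0)), bandwidth=0.02)
        peak = curve.grid[np.argmax(curve.density)]
        assert abs(peak - 1.0) < 0.01

    def test_matches_scipy_gaussian_kde_on_well_conditioned_sample(self):
        from scipy.stats import gaussian_kde

        rng = np.random.default_rng(1)
        sample = np.abs(rng.normal(1.5, 0.4, 5000))
        h = 0.1
        curve = estimate_kde(make_trace(sample), bandwidth=h)
        ref = gaussian_kde(sample, bw_method=h / sample.std(ddof=1))
        ref_density = ref(curve.grid)
        ref_density /= np.trapezoid(ref_density, curve.grid)
        assert np.allclose(curve.density, ref_density, atol=1e-6)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ParameterError):
            estimate_kde(make_trace([1.0, 2.0]), bandwidth=-0.1)
        with pytest.raises(InsufficientDataError):
            estimate_kde(make_trace([1.0]))


class TestThresholdDetection:
    def test_bimodal_valley_detected_between_the_modes(self):
        rng = np.random.default_rng(2)
        curve = estimate_kde(make_trace(bimodal_sample(rng)))
        threshold, tag = detect_bound_threshold(curve)
        assert tag == "detected"
        assert 0.6 <= threshold <= 1.4

    def test_unimodal_density_falls_back_to_conventional_cutoff(self):
        rng = np.random.default_rng(3)
        sample = np.abs(rng.normal(3.0, 0.2, 5000))
        threshold, tag = detect_bound_threshold(estimate_kde(make_trace(sample)))
        assert (threshold, tag) == (0.7, "fallback")


class TestBoundFraction:
    @pytest.mark.parametrize("method", ["empirical", "kde_area"])
    def test_all_bound_and_never_bound_extremes(self, method):
        all_bound = make_trace(np.full(100, 0.4))
        never = make_trace(np.full(100, 3.0))
        assert bound_fraction(all_bound, 0.7, method) == pytest.approx(1.0, abs=1e-6)
        assert bound_fraction(never, 0.7, method) == pytest.approx(0.0, abs=1e-6)

    def test_threshold_comparison_is_inclusive(self):
        trace = make_trace([0.7, 0.7001])
        assert bound_fraction(trace, 0.7) == 0.5

    def test_empirical_fraction_monotone_in_threshold(self):
        rng = np.random.default_rng(4)
        trace = make_trace(bimodal_sample(rng, 2000))
        thresholds = np.linspace(0.1, 4.0, 40)
        fracs = [bound_fraction(trace, t) for t in thresholds]
        assert np.all(np.diff(fracs) >= 0)

    def test_kde_area_converges_to_empirical_at_small_bandwidth(self):
        rng = np.random.default_rng(5)
        trace = make_trace(bimodal_sample(rng, 10_000))
        emp = bound_fraction(trace, 0.7, "empirical")
        kde = bound_fraction(trace, 0.7, "kde_area", bandwidth=0.01)
        assert abs(kde - emp) <= 0.01

    def test_empty_trace_rejected(self):
        with pytest.raises(InsufficientDataError):
            bound_fraction(np.array([]), 0.7)


class TestSummarizeBinding:
    def test_identical_replicas_have_zero_standard_error(self):
        traces = [make_trace(np.full(50, 0.4))] * 8
        summary = summarize_binding(ReplicaSet([], "x"), traces=traces)
        assert summary.mean_percentage == 100.0
        assert summary.standard_error == 0.0

    def test_hand_computed_standard_error_for_half_bound_replicas(self):
        # fractions {0,0,1,1}: sample sd 0.57735, SE = 100*0.57735/sqrt(4)
        traces = [make_trace(np.full(10, v)) for v in (3.0, 3.0, 0.1, 0.1)]
        summary = summarize_binding(ReplicaSet([], "x"), traces=traces)
        assert summary.mean_percentage == pytest.approx(50.0, abs=1e-9)
        assert summary.standard_error == pytest.approx(28.8675, abs=1e-3)

    def test_summary_invariants_hold_on_generated_replicas(self, small_replicas):
        replica_set, _ = small_replicas
        summary = summarize_binding(replica_set)
        arr = np.array(summary.per_replica_fraction)
        assert summary.mean_percentage == pytest.approx(100 * arr.mean(), abs=1e-9)
        assert summary.standard_error == pytest.approx(
            100 * arr.std(ddof=1) / np.sqrt(arr.size), abs=1e-9
        )

    def test_recovers_ground_truth_occupancy(self, small_replicas):
        replica_set, truths = small_replicas
        summary = summarize_binding(replica_set)
        for frac, truth in zip(summary.per_replica_fraction, truths):
            assert frac == pytest.approx(truth.true_occupancy, abs=1e-12)

    def test_mean_percentage_increases_with_true_occupancy(self):
        means = []
        for i, occ in enumerate([0.05, 0.2, 0.5, 0.8, 0.95]):
            params = make_params(p_bind=0.2 * occ, p_unbind=0.2 * (1 - occ),
                                 n_frames=1500, seed=100 + i)
            replica_set, _ = simulate_replicas(params, 2)
            means.append(summarize_binding(replica_set).mean_percentage)
        assert np.all(np.diff(means) > 0)

    def test_empty_replica_set_rejected(self):
        with pytest.raises(InsufficientDataError):
            summarize_binding(ReplicaSet([], "x"))

    def test_detected_threshold_shared_across_replicas(self, small_replicas):
        replica_set, truths = small_replicas
        summary = summarize_binding(replica_set, detect_threshold=True)
        assert summary.threshold_method in ("detected", "fallback")
        if summary.threshold_method == "detected":
            # valley must separate contact (<0.5) from excursion (>2) distances
            assert 0.5 < summary.threshold < 2.5
        for frac, truth in zip(summary.per_replica_fraction, truths):
            assert frac == pytest.approx(truth.true_occupancy, abs=1e-12)


@given(st.floats(min_value=0.05, max_value=4.5))
def test_bound_fraction_always_in_unit_interval(threshold):
    rng = np.random.default_rng(9)
    trace = make_trace(np.abs(rng.normal(1.0, 0.8, 500)))
    assert 0.0 <= bound_fraction(trace, threshold) <= 1.0
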