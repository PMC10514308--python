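"""Tests of the constrained two-state fit, its errors and burst metrics."""

import warnings

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from burstfish import (
    CountHistogram,
    FitOptions,
    KineticParams,
    NascentTally,
    active_inactive_ratio,
    bin_probabilities,
    build_histogram,
    burst_metrics,
    compare_fits,
    fit_two_state,
    goodness_of_fit,
    monte_carlo_errors,
    sample_counts,
    sample_counts_with_state,
    to_absolute_rates,
)
from burstfish.exceptions import (
    ArgumentError,
    BoundaryFitError,
    InsufficientDataError,
    UndefinedRatioError,
)


def _fit_dataset(params, n, seed, rule="fd", n_starts=6):
    """Sample a dataset with jointly simulated promoter states and fit it."""
    counts, on = sample_counts_with_state(params, n, seed)
    tally = NascentTally(int(on.sum()), n - int(on.sum()))
    hist = build_histogram(counts, rule=rule)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fit = fit_two_state(hist, tally, FitOptions(n_starts=n_starts))
    return fit, hist, tally


class TestActiveInactiveRatio:
    @pytest.mark.parametrize(
        "nascent,empty,expected",
        [(41, 59, 41 / 59), (35, 965, 35 / 965), (10, 10, 1.0), (75, 109, 75 / 109)],
    )
    def test_ratio_is_nascent_over_empty(self, nascent, empty, expected):
        assert active_inactive_ratio(NascentTally(nascent, empty)) == pytest.approx(
            expected
        )

    def test_all_active_population_is_undefined(self):
        with pytest.raises(UndefinedRatioError):
            active_inactive_ratio(NascentTally(50, 0))

    def test_negative_or_empty_tally_rejected(self):
        with pytest.raises(ArgumentError):
            NascentTally(-1, 5)
        with pytest.raises(ArgumentError):
            NascentTally(0, 0)


class TestBuildHistogram:
    def test_fixed_width_bins(self):
        hist = build_histogram([0, 0, 5, 5], rule="fixed", width=5)
        assert np.allclose(hist.edges, [0.0, 5.0, 10.0])
        assert np.allclose(hist.frequencies, [0.5, 0.5])

    def test_identical_counts_collapse_to_single_full_bin(self):
        hist = build_histogram([7, 7, 7])
        assert hist.n_bins == 1
        assert hist.frequencies[0] == 1.0

    def test_freedman_diaconis_resolves_wild_type_histogram(self, wt_params):
        counts = sample_counts(wt_params, 5000, seed=13)
        hist = build_histogram(counts, rule="fd")
        assert (hist.frequencies > 0).sum() >= 20

    def test_empty_input_rejected(self):
        with pytest.raises(ArgumentError):
            build_histogram([])

    def test_frequencies_sum_to_one(self, mutant_params):
        counts = sample_counts(mutant_params, 777, seed=3)
        hist = build_histogram(counts)
        assert hist.frequencies.sum() == pytest.approx(1.0, abs=1e-12)


class TestFitTwoState:
    def test_noise_free_histogram_recovers_exact_parameters(self, wt_params):
        edges = np.arange(0.0, 3300.0, 110.0)
        probs = bin_probabilities(wt_params, edges)
        hist = CountHistogram(edges, probs / probs.sum(), 5000, "fixed:110")
        fit = fit_two_state(hist, wt_params.k_on / wt_params.k_off)
        assert fit.converged
        assert fit.params.k_on == pytest.approx(2.7, rel=1e-3)
        assert fit.params.k_prod == pytest.approx(1524.0, rel=1e-3)

    def test_constraint_binds_k_off_exactly(self, wt_params):
        fit, _, _ = _fit_dataset(wt_params, 500, seed=101)
        assert fit.params.k_off == fit.params.k_on / fit.fixed_ratio

    def test_all_zero_counts_is_a_boundary_fit(self):
        hist = build_histogram(np.zeros(100))
        with pytest.raises(BoundaryFitError):
            fit_two_state(hist, 0.5)

    def test_zero_nascent_ratio_warns_and_degenerates(self):
        hist = build_histogram(sample_counts(KineticParams(1, 1, 20), 200, 1))
        with pytest.warns(UserWarning, match="boundary"):
            with pytest.raises(BoundaryFitError):
                fit_two_state(hist, NascentTally(0, 200))

    def test_recovery_grid_median_errors(self):
        """Median parameter-recovery error over the bursty-to-busy grid at
        n=2000 cells: k_prod under 10%, k_on under 25%."""
        errs_on, errs_prod = [], []
        seed = 0
        for k_on in (0.2, 2.7):
            for ratio in (0.036, 0.69):
                for k_prod in (50.0, 571.0, 1524.0):
                    truth = KineticParams(k_on, k_on / ratio, k_prod)
                    counts = sample_counts(truth, 2000, seed=seed)
                    hist = build_histogram(counts)
                    with warnings.catch_warnings():
                        warnings.simplefilter("ignore")
                        fit = fit_two_state(hist, ratio, FitOptions(n_starts=6))
                    errs_on.append(abs(fit.params.k_on - k_on) / k_on)
                    errs_prod.append(abs(fit.params.k_prod - k_prod) / k_prod)
                    seed += 1
        assert np.median(errs_prod) < 0.10
        assert np.median(errs_on) < 0.25


class TestMonteCarloErrors:
    def test_single_replicate_is_rejected(self, wt_params):
        fit, _, _ = _fit_dataset(wt_params, 300, seed=17)
        with pytest.raises(ArgumentError):
            monte_carlo_errors(fit, n_reps=1)

    def test_errors_shrink_with_sample_size(self, wt_params):
        """Parametric-bootstrap SEs follow the 1/sqrt(n) law:
        SE at 736 cells is about half the SE at 184 cells."""
        fit, _, _ = _fit_dataset(wt_params, 400, seed=23)
        se_small = monte_carlo_errors(fit, n_cells=184, n_reps=40, seed=1)
        se_large = monte_carlo_errors(fit, n_cells=736, n_reps=40, seed=2)
        ratio = se_large.se_k_prod / se_small.se_k_prod
        assert 0.35 < ratio < 0.65
        assert se_small.se_k_on > 0 and se_small.se_k_prod > 0


class TestGoodnessOfFit:
    def test_exact_agreement_scores_zero(self, wt_params):
        edges = np.arange(0.0, 3300.0, 150.0)
        probs = bin_probabilities(wt_params, edges)
        hist = CountHistogram(edges, probs / probs.sum(), 1000, "fixed:150")
        fit = fit_two_state(hist, wt_params.k_on / wt_params.k_off)
        gof = goodness_of_fit(fit, hist)
        assert gof.reduced == pytest.approx(0.0, abs=1e-4)
        assert gof.dof >= 1

    def test_null_calibration_of_reduced_statistic(self, wt_params):
        """Data generated by the fitted family give reduced chi-square
        near 1 in the vast majority of replicates."""
        in_range = 0
        n_reps = 25
        for seed in range(n_reps):
            fit, hist, _ = _fit_dataset(wt_params, 1000, seed=300 + seed)
            gof = goodness_of_fit(fit, hist)
            if 0.5 <= gof.reduced <= 2.0:
                in_range += 1
        assert in_range >= int(0.8 * n_reps)

    def test_detects_misspecified_poisson_fit_of_bursty_data(self):
        truth = KineticParams(0.2, 5.0, 100.0)
        counts = sample_counts(truth, 2000, seed=55)
        hist = build_histogram(counts)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            good = fit_two_state(hist, 0.04, FitOptions(n_starts=6))
            poissonish = fit_two_state(hist, 1e6, FitOptions(n_starts=6))
        g1 = goodness_of_fit(good, hist)
        g2 = goodness_of_fit(poissonish, hist)
        assert g2.reduced > 5 * g1.reduced

    def test_too_few_bins_is_an_error(self, wt_small):
        counts = sample_counts(wt_small, 50, seed=5)
        hist = build_histogram(counts, rule="fixed", width=200)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit, _, _ = _fit_dataset(wt_small, 400, seed=5)
        with pytest.raises(InsufficientDataError):
            goodness_of_fit(fit, hist)


class TestBurstMetrics:
    def test_wild_type_metrics_from_printed_rates(self, wt_params):
        m = burst_metrics(wt_params)
        assert m.burst_frequency == pytest.approx(2.7 * 3.7 / 6.4, rel=1e-12)
        assert m.burst_size == pytest.approx(1524.0 / 3.7, rel=1e-12)
        assert m.mean_expression == pytest.approx(642.9375, rel=1e-12)

    def test_mutant_metrics_from_printed_rates(self, mutant_params):
        m = burst_metrics(mutant_params)
        assert m.burst_frequency == pytest.approx(0.19 * 5.1 / 5.29, rel=1e-12)
        assert m.burst_size == pytest.approx(571.0 / 5.1, rel=1e-12)

    def test_symmetric_switching_frequency(self):
        m = burst_metrics(KineticParams(4.0, 4.0, 10.0))
        assert m.burst_frequency == pytest.approx(2.0)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        k_on=st.floats(1e-2, 50.0),
        k_off=st.floats(1e-2, 50.0),
        k_prod=st.floats(0.1, 2000.0),
    )
    def test_mean_is_frequency_times_size(self, k_on, k_off, k_prod):
        m = burst_metrics(KineticParams(k_on, k_off, k_prod))
        assert m.mean_expression == pytest.approx(
            m.burst_frequency * m.burst_size, rel=1e-12
        )


class TestCompareFits:
    def test_identical_parameter_sets_fold_one(self, wt_params):
        fc = compare_fits(wt_params, wt_params)
        for name in ("k_on", "k_off", "k_prod", "burst_frequency", "burst_size"):
            assert getattr(fc, name).fold == pytest.approx(1.0)
            assert getattr(fc, name).direction == "unchanged"

    def test_reference_and_comparison_are_reciprocal(self, wt_params, mutant_params):
        ab = compare_fits(wt_params, mutant_params)
        ba = compare_fits(mutant_params, wt_params)
        for name in ("k_on", "k_off", "k_prod", "burst_frequency", "burst_size"):
            assert getattr(ab, name).ratio == pytest.approx(
                1.0 / getattr(ba, name).ratio, rel=1e-12
            )

    def test_direction_labels(self, wt_params, mutant_params):
        fc = compare_fits(wt_params, mutant_params)
        assert fc.k_on.direction == "reduction"
        assert fc.k_off.direction == "increase"
        assert fc.burst_frequency.direction == "reduction"


class TestAbsoluteRates:
    def test_half_life_of_ln2_time_units_is_identity(self, wt_params):
        rates = to_absolute_rates(wt_params, np.log(2.0))
        assert rates.k_on == pytest.approx(2.7)
        assert rates.k_prod == pytest.approx(1524.0)
        assert rates.degradation_rate == pytest.approx(1.0)

    def test_doubling_half_life_halves_every_rate(self, wt_params):
        a = to_absolute_rates(wt_params, 30.0)
        b = to_absolute_rates(wt_params, 60.0)
        for name in ("k_on", "k_off", "k_prod", "degradation_rate"):
            assert getattr(a, name) == pytest.approx(2.0 * getattr(b, name))

    def test_sixty_minute_half_life_production_rate(self, wt_params):
        rates = to_absolute_rates(wt_params, 60.0)
        assert rates.k_prod == pytest.approx(1524.0 * np.log(2.0) / 60.0, rel=1e-12)
        assert rates.k_prod == pytest.approx(17.61, abs=0.01)

    def test_nonpositive_half_life_rejected(self, wt_params):
        with pytest.raises(ArgumentError):
            to_absolute_rates(wt_params, 0.0)
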