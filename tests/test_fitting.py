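"""Least-squares estimation, goodness-of-fit statistics and calibration."""

import warnings

import numpy as np
import pytest

from tbm import (
    AgeRateSeries,
    FitConfig,
    NoiseSpec,
    chi_square_conventional,
    chi_square_origin,
    evaluate_rate,
    fit_tbm,
    generate_series,
    initialize_parameters,
    p_value,
    select_exponent,
)
from tbm.core import PARAMETER_NAMES


class TestChiSquareStatistics:
    def test_both_forms_vanish_iff_residuals_vanish(self):
        obs = np.array([3.0, 7.0, 1.0])
        assert chi_square_origin(obs, obs, 1) == 0.0
        assert chi_square_conventional(obs, obs) == 0.0
        exp = obs + 0.1
        assert chi_square_origin(obs, exp, 1) > 0.0
        assert chi_square_conventional(obs, exp) > 0.0

    def test_hand_computed_toy_values(self):
        obs, exp = np.array([4.0, 6.0]), np.array([5.0, 5.0])
        # Pearson: 1/5 + 1/5
        assert chi_square_conventional(obs, exp) == pytest.approx(0.4)
        # non-conventional: (1 + 1) / (2 - 0)
        assert chi_square_origin(obs, exp, 0) == pytest.approx(1.0)

    def test_free_parameter_count_only_affects_nonconventional_form(self):
        obs, exp = np.array([4.0, 6.0, 5.5]), np.array([5.0, 5.0, 5.0])
        assert chi_square_conventional(obs, exp) == pytest.approx(
            chi_square_conventional(obs, exp)
        )
        assert chi_square_origin(obs, exp, 1) == pytest.approx(
            1.5 * chi_square_origin(obs, exp, 0)
        )

    def test_floor_excludes_zero_expectation_points(self):
        # a single point with zero expectation leaves nothing to sum
        with pytest.raises(ValueError):
            chi_square_conventional(np.array([10.0]), np.array([0.0]))
        # mixed case: the zero-expectation point simply drops out
        stat = chi_square_conventional(np.array([10.0, 4.0]), np.array([0.0, 5.0]))
        assert stat == pytest.approx(0.2)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            chi_square_origin(np.ones(3), np.ones(2), 0)
        with pytest.raises(ValueError):
            chi_square_conventional(np.ones(3), np.ones(2))


class TestPValue:
    @pytest.mark.parametrize(
        "chi2,dof,expected",
        [(25.08, 10, 0.005), (14.54, 8, 0.069), (1.076, 11, 1.000)],
    )
    def test_reported_upper_tail_probabilities(self, chi2, dof, expected):
        assert round(p_value(chi2, dof), 3) == pytest.approx(expected)

    def test_zero_statistic_gives_certainty(self):
        assert p_value(0.0, 5) == 1.0

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            p_value(-1.0, 5)
        with pytest.raises(ValueError):
            p_value(1.0, 0)


class TestInitialisation:
    def test_half_life_expectancy_and_rate_product_rule(self, usa_both_2001):
        series = generate_series(usa_both_2001)
        init = initialize_parameters(series, life_expectancy=95.0)
        assert init.middle_age == pytest.approx(47.5)
        # theta * K equals the model rate at the middle age, so the start
        # matches the observed rate nearest the middle-age start.
        nearest = series.rates[np.argmin(np.abs(series.ages - 47.5))]
        assert init.threshold * init.apex_constant == pytest.approx(nearest)
        assert init.exponent % 2 == 1

    def test_plateau_heuristic_without_life_expectancy(self, usa_both_2001):
        series = generate_series(usa_both_2001)
        init = initialize_parameters(series)
        # rate-weighted median age lands inside the curve's support
        assert 38.0 < init.middle_age < 60.0

    def test_all_zero_series_rejected(self):
        series = AgeRateSeries(ages=np.arange(10.0, 20.0), rates=np.zeros(10))
        with pytest.raises(ValueError):
            initialize_parameters(series)


class TestFit:
    def test_noise_free_self_consistency(self, usa_both_2001):
        series = generate_series(usa_both_2001)
        result = fit_tbm(series, FitConfig(initial=usa_both_2001))
        assert result.converged
        for name in PARAMETER_NAMES:
            assert getattr(result.params, name) == pytest.approx(
                getattr(usa_both_2001, name), rel=1e-6, abs=1e-9
            )
        assert result.chi2_origin == pytest.approx(0.0, abs=1e-12)
        assert result.p_value == pytest.approx(1.0)

    def test_more_free_parameters_than_points_rejected(self, usa_both_2001):
        series = AgeRateSeries(
            ages=np.array([40.0, 45.0, 50.0, 55.0]),
            rates=np.asarray(
                evaluate_rate(np.array([40.0, 45.0, 50.0, 55.0]), usa_both_2001)
            ),
        )
        with pytest.raises(ValueError):
            fit_tbm(series, FitConfig(initial=usa_both_2001))

    def test_dof_bookkeeping_with_fixed_parameters(self, usa_both_2001):
        series = generate_series(
            usa_both_2001, noise=NoiseSpec("gaussian", sigma=0.5, seed=9)
        )
        free = fit_tbm(series, FitConfig(initial=usa_both_2001))
        fixed = fit_tbm(
            series,
            FitConfig(
                initial=usa_both_2001,
                fixed=frozenset({"middle_age", "quiescent_drive"}),
            ),
        )
        assert fixed.dof == free.dof + 2
        assert fixed.std_errors["middle_age"] is None
        assert fixed.params.middle_age == usa_both_2001.middle_age

    def test_objective_not_worse_than_start(self, usa_both_2001):
        series = generate_series(
            usa_both_2001, noise=NoiseSpec("gaussian", sigma=0.5, seed=11)
        )
        start = usa_both_2001.replace(threshold=18.0, apex_constant=80.0)
        result = fit_tbm(series, FitConfig(initial=start))
        rss_start = float(
            np.sum((np.asarray(evaluate_rate(series.ages, start)) - series.rates) ** 2)
        )
        rss_end = result.chi2_origin * (series.n_points - result.n_free)
        assert rss_end <= rss_start + 1e-9

    def test_iteration_cap_flags_nonconvergence(self, usa_both_2001):
        series = generate_series(
            usa_both_2001, noise=NoiseSpec("gaussian", sigma=2.0, seed=13)
        )
        start = usa_both_2001.replace(threshold=25.0, apex_constant=40.0)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            result = fit_tbm(series, FitConfig(initial=start, max_iterations=1))
        assert not result.converged
        assert result.n_points == series.n_points  # best-so-far state returned

    def test_free_critical_age_switch(self, usa_both_2001):
        series = generate_series(
            usa_both_2001, noise=NoiseSpec("gaussian", sigma=0.5, seed=15)
        )
        derived = fit_tbm(series, FitConfig(initial=usa_both_2001))
        free = fit_tbm(
            series, FitConfig(initial=usa_both_2001, critical_age_free=True)
        )
        assert derived.critical_age_source == "derived"
        assert free.critical_age_source == "free"
        assert free.dof == derived.dof - 1  # the cutoff consumes a dof

    def test_standard_error_calibration_one_sigma(self, usa_both_2001):
        """On an in-support grid with honest Gaussian noise, the truth lands
        within one reported standard error in roughly 68% of replicates
        (bounds are a 3-sigma binomial band at 100 replicates)."""
        truth = usa_both_2001
        ages = np.arange(40.0, 56.25, 0.25)
        clean = np.asarray(evaluate_rate(ages, truth))
        rng = np.random.default_rng(123)
        hits = dict.fromkeys(PARAMETER_NAMES, 0)
        for _ in range(100):
            noisy = np.maximum(clean + rng.normal(0.0, 0.5, ages.size), 0.0)
            result = fit_tbm(
                AgeRateSeries(ages=ages, rates=noisy), FitConfig(initial=truth)
            )
            for name in PARAMETER_NAMES:
                err = result.std_errors[name]
                if err and abs(getattr(result.params, name) - getattr(truth, name)) <= err:
                    hits[name] += 1
        for name, count in hits.items():
            assert 54 <= count <= 82, f"{name}: {count}/100 within 1 SE"


class TestExponentSelection:
    def test_singleton_grid_equals_plain_fit(self, usa_both_2001):
        series = generate_series(
            usa_both_2001, noise=NoiseSpec("gaussian", sigma=0.5, seed=17)
        )
        cfg = FitConfig(initial=usa_both_2001, exponent_candidates=(9,))
        assert (
            select_exponent(series, cfg).chi2_conventional
            == fit_tbm(series, cfg).chi2_conventional
        )

    def test_recovers_generating_exponent_noise_free(self, usa_both_2001):
        series = generate_series(usa_both_2001)  # generated with n = 9
        cfg = FitConfig(
            initial=usa_both_2001.replace(exponent=7),
            exponent_candidates=(7, 9, 11),
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            assert select_exponent(series, cfg).params.exponent == 9

    def test_recovers_higher_exponent_under_mild_noise(self, usa_both_2001):
        truth = usa_both_2001.replace(exponent=11)
        wins = 0
        for seed in range(5):
            series = generate_series(
                truth, noise=NoiseSpec("gaussian", sigma=0.2, seed=seed)
            )
            cfg = FitConfig(
                initial=truth.replace(exponent=9), exponent_candidates=(9, 11, 13)
            )
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                wins += select_exponent(series, cfg).params.exponent == 11
        assert wins >= 3  # majority of seeded replicates

    def test_even_candidate_rejected(self, usa_both_2001):
        with pytest.raises(ValueError):
            FitConfig(initial=usa_both_2001, exponent_candidates=(8,))
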