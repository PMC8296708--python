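"""Unit and property tests for the decile Q-Q shift model."""

import numpy as np
import pytest

from myoshift.csa_shift import (
    CSASample,
    DecileVector,
    DegenerateRegressionError,
    InsufficientSampleError,
    MisalignedDecilesError,
    ShiftFit,
    analyze_pair,
    compute_deciles,
    estimate_shift,
    fit_decile_regression,
    k_from_intercept,
    select_model,
)


def quantile_oracle(values, p):
    """Brute-force linear-interpolation quantile with rank h = (n-1)p + 1."""
    v = sorted(values)
    h = (len(v) - 1) * p  # 0-based fractional rank
    lo = int(np.floor(h))
    frac = h - lo
    if lo + 1 >= len(v):
        return v[-1]
    return v[lo] + frac * (v[lo + 1] - v[lo])


class TestComputeDeciles:
    def test_constant_sample_has_constant_deciles(self):
        s = CSASample(np.full(50, 100.0))
        d = compute_deciles(s)
        assert np.all(d.values == 100.0)

    def test_matches_interpolation_oracle(self):
        areas = np.arange(1.0, 101.0)
        rng = np.random.default_rng(0)
        rng.shuffle(areas)
        d = compute_deciles(CSASample(areas))
        for p, v in zip(d.probs, d.values):
            assert v == pytest.approx(quantile_oracle(areas, p), abs=1e-12)
        # the p = 0.1 decile of 1..100 interpolates to 10.9
        assert d.values[0] == pytest.approx(10.9)

    def test_scale_equivariance(self, lognormal_sample):
        d1 = compute_deciles(lognormal_sample)
        d2 = compute_deciles(CSASample(2.0 * lognormal_sample.areas))
        np.testing.assert_allclose(d2.values, 2.0 * d1.values, rtol=1e-12)

    def test_insufficient_sample_rejected(self):
        with pytest.raises(InsufficientSampleError):
            compute_deciles(CSASample(np.ones(9)))

    def test_decile_vector_rejects_decreasing_values(self):
        with pytest.raises(ValueError):
            DecileVector(np.array([0.25, 0.5, 0.75]), np.array([3.0, 2.0, 1.0]))


class TestDecileRegression:
    def test_identity_pair_is_exact_null(self, lognormal_sample):
        d = compute_deciles(lognormal_sample)
        fit = fit_decile_regression(d, d, "natural")
        assert fit.slope == pytest.approx(1.0, abs=1e-9)
        assert fit.intercept == pytest.approx(0.0, abs=1e-6)
        assert fit.p_slope_vs_1 == 1.0
        assert fit.p_intercept_vs_0 == 1.0

    def test_pure_shift_gives_unit_slope_and_shift_intercept(self, lognormal_sample):
        d = compute_deciles(lognormal_sample)
        shifted = DecileVector(d.probs, d.values + 140.0)
        fit = fit_decile_regression(shifted, d, "natural")
        assert fit.slope == pytest.approx(1.0, abs=1e-9)
        assert fit.intercept == pytest.approx(140.0, rel=1e-9)
        assert fit.r2 == pytest.approx(1.0)
        assert fit.p_slope_vs_1 > 0.05
        assert fit.p_intercept_vs_0 <= 0.05

    def test_pure_scaling_on_log_scale(self, lognormal_sample):
        d = compute_deciles(lognormal_sample)
        scaled = DecileVector(d.probs, 2.0 * d.values)
        fit = fit_decile_regression(scaled, d, "log10")
        assert fit.slope == pytest.approx(1.0, abs=1e-9)
        assert fit.intercept == pytest.approx(np.log10(2.0), rel=1e-9)

    def test_misaligned_probs_rejected(self, lognormal_sample):
        d = compute_deciles(lognormal_sample)
        other = compute_deciles(lognormal_sample, np.array([0.25, 0.5, 0.75]))
        with pytest.raises(MisalignedDecilesError):
            fit_decile_regression(other, d)

    def test_zero_variance_control_rejected(self):
        d_const = compute_deciles(CSASample(np.full(20, 5.0)))
        d = compute_deciles(CSASample(np.arange(1.0, 21.0)))
        with pytest.raises(DegenerateRegressionError):
            fit_decile_regression(d, d_const)


@pytest.mark.parametrize(
    "a, expected",
    [(0.0, 1.0), (1.0, 10.0), (np.log10(1.72), 1.72)],
)
def test_k_from_intercept(a, expected):
    assert k_from_intercept(a) == pytest.approx(expected, rel=1e-12)


def _fit(scale, p_slope, p_int):
    return ShiftFit(scale, 1.0, 0.1, 0.01, 0.01, p_slope, p_int, 0.99, 9)


class TestSelectModel:
    def test_natural_only_admissible_gives_additive(self):
        model, trace = select_model(
            _fit("natural", 0.5, 0.01), _fit("log10", 0.01, 0.01)
        )
        assert model == "additive"
        assert trace["additive_admissible"] and not trace["multiplicative_admissible"]

    def test_log_only_admissible_gives_multiplicative(self):
        model, _ = select_model(
            _fit("natural", 0.5, 0.5), _fit("log10", 0.5, 0.01)
        )
        assert model == "multiplicative"

    def test_neither_admissible_gives_none(self):
        model, _ = select_model(
            _fit("natural", 0.5, 0.5), _fit("log10", 0.5, 0.5)
        )
        assert model == "none"

    def test_both_admissible_tie_breaks_on_lower_ssq(self):
        nat, log = _fit("natural", 0.5, 0.01), _fit("log10", 0.5, 0.01)
        model, trace = select_model(
            nat, log, ssq_additive=10.0, ssq_multiplicative=1.0
        )
        assert model == "multiplicative" and trace["tie_break"] == "lower SSQ"
        model, _ = select_model(nat, log, ssq_additive=1.0, ssq_multiplicative=10.0)
        assert model == "additive"

    def test_forced_choice_attributes_by_ssq_when_inadmissible(self):
        nat, log = _fit("natural", 0.01, 0.5), _fit("log10", 0.01, 0.5)
        model, trace = select_model(
            nat, log, ssq_additive=5.0, ssq_multiplicative=2.0, force=True
        )
        assert model == "multiplicative" and trace["forced"]

    def test_true_multiplicative_family_wins_forced_monte_carlo(self):
        # truth K = 2.5 (far from 1): the lower-SSQ attribution must pick
        # the multiplicative family nearly always across replicates
        from myoshift.synthetic import CSAGenConfig, gen_csa_samples

        wins = 0
        n_rep = 500
        for seed in range(n_rep):
            c, t = gen_csa_samples(
                CSAGenConfig(
                    n_fibers=500, effect_kind="multiplicative",
                    effect_value=2.5, noise_frac=0.05, seed=seed,
                )
            )
            wins += analyze_pair(c, t, force=True).model == "multiplicative"
        assert wins / n_rep >= 0.95


class TestEstimateShift:
    def test_identity_pair_recovers_zero_shift_and_unit_factor(self, lognormal_sample):
        est_s = estimate_shift(lognormal_sample, lognormal_sample, "additive")
        est_k = estimate_shift(lognormal_sample, lognormal_sample, "multiplicative")
        assert est_s.parameter == pytest.approx(0.0, abs=1e-6)
        assert est_k.parameter == pytest.approx(1.0, abs=1e-6)
        assert est_s.ssq < 1e-10 and est_k.ssq < 1e-10

    def test_exact_scaling_matches_grid_search_oracle(self, lognormal_sample):
        treated = CSASample(1.5 * lognormal_sample.areas)
        est = estimate_shift(lognormal_sample, treated, "multiplicative")
        # independent oracle: dense grid over K
        qc = np.quantile(lognormal_sample.areas, np.arange(0.1, 1.0, 0.1))
        qt = np.quantile(treated.areas, np.arange(0.1, 1.0, 0.1))
        grid = np.arange(0.5, 3.0, 1e-4)
        ssqs = ((qt[None, :] - grid[:, None] * qc[None, :]) ** 2).sum(axis=1)
        k_grid = grid[np.argmin(ssqs)]
        assert est.parameter == pytest.approx(1.5, rel=1e-6)
        assert est.parameter == pytest.approx(k_grid, abs=2e-4)
        assert est.ssq == pytest.approx(0.0, abs=1e-10)

    def test_exact_shift_matches_grid_search_oracle(self, lognormal_sample):
        treated = CSASample(lognormal_sample.areas + 140.0)
        est = estimate_shift(lognormal_sample, treated, "additive")
        qc = np.quantile(lognormal_sample.areas, np.arange(0.1, 1.0, 0.1))
        qt = np.quantile(treated.areas, np.arange(0.1, 1.0, 0.1))
        grid = np.arange(0.0, 300.0, 1e-3)
        ssqs = ((qt[None, :] - (qc[None, :] + grid[:, None])) ** 2).sum(axis=1)
        assert est.parameter == pytest.approx(140.0, rel=1e-6)
        assert est.parameter == pytest.approx(grid[np.argmin(ssqs)], abs=2e-3)

    def test_scale_equivariance(self, lognormal_sample):
        treated = CSASample(lognormal_sample.areas + 100.0)
        s1 = estimate_shift(lognormal_sample, treated, "additive").parameter
        c = 3.7
        s2 = estimate_shift(
            CSASample(c * lognormal_sample.areas), CSASample(c * treated.areas),
            "additive",
        ).parameter
        assert s2 == pytest.approx(c * s1, rel=1e-5)
        k1 = estimate_shift(lognormal_sample, treated, "multiplicative").parameter
        k2 = estimate_shift(
            CSASample(c * lognormal_sample.areas), CSASample(c * treated.areas),
            "multiplicative",
        ).parameter
        assert k2 == pytest.approx(k1, rel=1e-5)

    def test_translation_equivariance_additive(self, lognormal_sample):
        treated = CSASample(lognormal_sample.areas + 100.0)
        s1 = estimate_shift(lognormal_sample, treated, "additive").parameter
        c = 250.0
        s2 = estimate_shift(
            CSASample(lognormal_sample.areas + c), CSASample(treated.areas + c),
            "additive",
        ).parameter
        assert s2 == pytest.approx(s1, abs=1e-4)

    def test_consistency_with_log_intercept(self, paired_multiplicative_pair):
        control, treated = paired_multiplicative_pair
        est = estimate_shift(control, treated, "multiplicative")
        dc, dt = compute_deciles(control), compute_deciles(treated)
        fit = fit_decile_regression(dt, dc, "log10")
        assert est.parameter == pytest.approx(
            k_from_intercept(fit.intercept), rel=1e-6
        )

    def test_parameter_recovery_bias_under_noise(self):
        # K = 1.72, n = 500, 5% multiplicative noise: |bias| < 3% of K
        from myoshift.synthetic import CSAGenConfig, gen_csa_samples

        ks = []
        for seed in range(200):
            c, t = gen_csa_samples(
                CSAGenConfig(
                    n_fibers=500, median_um2=500.0, sigma_log=0.5,
                    effect_kind="multiplicative", effect_value=1.72,
                    noise_frac=0.05, seed=seed,
                )
            )
            ks.append(estimate_shift(c, t, "multiplicative").parameter)
        assert abs(np.mean(ks) - 1.72) < 0.03 * 1.72


class TestAnalyzePair:
    def test_identity_pair_selects_none(self, lognormal_sample):
        report = analyze_pair(lognormal_sample, lognormal_sample)
        assert report.model == "none"
        assert report.estimate.parameter is None

    def test_noise_free_additive_pair(self, paired_additive_pair):
        control, treated = paired_additive_pair
        report = analyze_pair(control, treated)
        assert report.model == "additive"
        assert report.estimate.parameter == pytest.approx(140.0, rel=1e-6)
        assert report.estimate.ssq == pytest.approx(0.0, abs=1e-8)

    def test_noise_free_multiplicative_pair(self, paired_multiplicative_pair):
        control, treated = paired_multiplicative_pair
        report = analyze_pair(control, treated)
        assert report.model == "multiplicative"
        assert report.estimate.parameter == pytest.approx(1.72, rel=1e-6)

    def test_report_serializes_to_json(self, paired_multiplicative_pair):
        import json

        control, treated = paired_multiplicative_pair
        payload = json.loads(analyze_pair(control, treated).to_json())
        assert payload["selected"]["model"] == "multiplicative"
        assert len(payload["control_deciles"]) == 9
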