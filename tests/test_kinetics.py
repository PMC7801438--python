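"""Arrhenius / deformed-Arrhenius fitting: exact recovery, oracles, errors."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import hydrokin as hk
from hydrokin.constants import R_GAS
from hydrokin.errors import DomainError, InsufficientDataError, SingularDesignError


def series_from(ln_pre, B, C, temps, kind="rate"):
    return hk.generate_rate_series(ln_pre, B, C, temps, 0.0, value_kind=kind)


class TestRateSeries:
    def test_canonicalized_ascending(self):
        s = hk.RateSeries([330.0, 270.0, 300.0], [3.0, 1.0, 2.0])
        assert list(s.temperatures) == [270.0, 300.0, 330.0]
        assert list(s.values) == [1.0, 2.0, 3.0]

    def test_duplicate_temperature_rejected(self):
        with pytest.raises(DomainError, match="duplicate"):
            hk.RateSeries([300.0, 300.0], [1.0, 2.0])

    def test_nonpositive_value_names_temperature(self):
        with pytest.raises(DomainError, match="290"):
            hk.RateSeries([280.0, 290.0], [1.0, -2.0])

    def test_too_short(self):
        with pytest.raises(InsufficientDataError):
            hk.RateSeries([300.0], [1.0])


class TestArrheniusFit:
    def test_exact_recovery(self):
        s = series_from(5.0, -40000.0, 0.0, [270.0, 300.0, 330.0])
        f = hk.fit_arrhenius(s)
        assert f.ln_pre == pytest.approx(5.0, abs=1e-9)
        assert f.B == pytest.approx(-40000.0, rel=1e-9)
        assert f.C == 0.0
        # -B is the constant activation energy
        assert hk.activation_energy(f, 300.0) == pytest.approx(40000.0, rel=1e-9)

    def test_constant_series_zero_slope(self):
        s = hk.RateSeries([270.0, 300.0, 330.0], np.full(3, np.e**3))
        f = hk.fit_arrhenius(s)
        assert f.ln_pre == pytest.approx(3.0, abs=1e-12)
        assert f.B == pytest.approx(0.0, abs=1e-8)

    def test_noisy_recovery_matches_closed_form_ols(self):
        temps = np.arange(270.0, 341.0, 10.0)
        s = hk.generate_rate_series(2.0, -25000.0, 0.0, temps, 0.02, seed=11)
        f = hk.fit_arrhenius(s)
        # independent closed-form slope/intercept on (1/RT, ln v)
        x = 1.0 / (R_GAS * s.temperatures)
        y = np.log(s.values)
        slope = np.sum((x - x.mean()) * (y - y.mean())) / np.sum((x - x.mean()) ** 2)
        intercept = y.mean() - slope * x.mean()
        assert f.B == pytest.approx(slope, rel=1e-10)
        assert f.ln_pre == pytest.approx(intercept, rel=1e-10)
        # recovered B within 3 standard errors of the truth
        assert abs(f.B - (-25000.0)) <= 3 * f.stderr[1]

    def test_matches_c_constrained_quadratic(self):
        # Arrhenius fit == deformed fit with the quadratic column removed
        temps = np.arange(270.0, 341.0, 10.0)
        s = hk.generate_rate_series(1.0, -2e4, -5e7, temps, 0.05, seed=4)
        f = hk.fit_arrhenius(s)
        X = np.column_stack([np.ones(len(s)), 1.0 / (R_GAS * s.temperatures)])
        beta = np.linalg.solve(X.T @ X, X.T @ np.log(s.values))
        assert f.ln_pre == pytest.approx(beta[0], rel=1e-10)
        assert f.B == pytest.approx(beta[1], rel=1e-10)


class TestSuperArrheniusFit:
    def test_exact_recovery_published_scale(self):
        temps = np.arange(270.0, 341.0, 10.0)
        s = series_from(-33.77, 9.98e4, -1.58e8, temps)
        f = hk.fit_super_arrhenius(s)
        assert f.ln_pre == pytest.approx(-33.77, rel=1e-8)
        assert f.B == pytest.approx(9.98e4, rel=1e-8)
        assert f.C == pytest.approx(-1.58e8, rel=1e-8)
        assert f.r_squared == pytest.approx(1.0)

    def test_three_points_interpolate(self):
        rng = np.random.default_rng(0)
        temps = np.array([275.0, 301.0, 333.0])
        vals = rng.uniform(0.5, 5.0, 3)
        s = hk.RateSeries(temps, vals)
        f = hk.fit_super_arrhenius(s)
        assert np.allclose(hk.predict(f, temps), vals, rtol=1e-9)
        assert f.r_squared == pytest.approx(1.0)
        # oracle: direct 3x3 linear solve of the Vandermonde system
        x = 1.0 / (R_GAS * temps)
        V = np.vander(x, 3, increasing=True)
        beta = np.linalg.solve(V, np.log(vals))
        assert f.ln_pre == pytest.approx(beta[0], rel=1e-8)
        assert f.B == pytest.approx(beta[1], rel=1e-8)
        assert f.C == pytest.approx(beta[2], rel=1e-8)

    def test_arrhenius_data_gives_negligible_curvature(self):
        temps = np.arange(270.0, 341.0, 10.0)
        s = hk.generate_rate_series(3.0, -30000.0, 0.0, temps, 0.02, seed=9)
        f = hk.fit_super_arrhenius(s)
        # oracle: solve the 3x3 normal equations directly
        x = 1.0 / (R_GAS * s.temperatures)
        X = np.vander(x, 3, increasing=True)
        beta = np.linalg.solve(X.T @ X, X.T @ np.log(s.values))
        assert f.C == pytest.approx(beta[2], rel=1e-6)
        assert abs(f.C) < f.stderr_C

    def test_equal_weights_match_unweighted(self):
        temps = np.arange(270.0, 341.0, 10.0)
        s = hk.generate_rate_series(1.0, -2e4, -5e7, temps, 0.05, seed=2)
        unweighted = hk.fit_super_arrhenius(s)
        weighted = hk.fit_super_arrhenius(s, weights=np.full(len(s), 4.0))
        assert weighted.B == pytest.approx(unweighted.B, rel=1e-10)
        assert weighted.C == pytest.approx(unweighted.C, rel=1e-10)
        # degenerate weights rejected
        with pytest.raises(DomainError):
            hk.fit_super_arrhenius(s, weights=np.zeros(len(s)))

    def test_insufficient_and_degenerate(self):
        with pytest.raises(InsufficientDataError):
            hk.fit_super_arrhenius(hk.RateSeries([280.0, 300.0], [1.0, 2.0]))
        s = hk.RateSeries([280.0, 300.0, 320.0], [1.0, 2.0, 3.0])
        X = np.vander(np.ones(3), 3, increasing=True)  # rank-deficient by hand
        from hydrokin.kinetics import _ols
        with pytest.raises(SingularDesignError):
            _ols(X, np.log(s.values))


class TestActivationEnergy:
    @pytest.mark.parametrize(
        "B,C,T,expected_kJ",
        [
            (2.49e4, -6.40e7, 300.0, 26.4),  # interface-channel worked value
            (8.31e3, -3.86e7, 290.0, 23.7),  # porous-channel worked value
        ],
    )
    def test_published_worked_values(self, B, C, T, expected_kJ):
        f = hk.SuperArrheniusFit(0.0, B, C, 1.0, np.zeros((3, 3)))
        assert hk.activation_energy(f, T) / 1000 == pytest.approx(expected_kJ, abs=0.5)

    def test_arrhenius_limit_is_minus_B(self):
        f = hk.SuperArrheniusFit(0.0, -50000.0, 0.0, 1.0, np.zeros((3, 3)))
        for T in (250.0, 300.0, 1000.0):
            assert hk.activation_energy(f, T) == pytest.approx(50000.0)

    def test_invalid_temperature(self):
        f = hk.SuperArrheniusFit(0.0, 0.0, 0.0, 1.0, np.zeros((3, 3)))
        with pytest.raises(DomainError):
            hk.activation_energy(f, 0.0)

    @given(
        B=st.floats(-2e5, 2e5),
        C=st.floats(-5e8, 5e8).filter(lambda c: abs(c) > 1e3),
    )
    @settings(max_examples=50, deadline=None)
    def test_monotone_in_T_iff_C_negative(self, B, C):
        f = hk.SuperArrheniusFit(0.0, B, C, 1.0, np.zeros((3, 3)))
        grid = np.linspace(260.0, 340.0, 17)
        ea = np.array([hk.activation_energy(f, T) for T in grid])
        if C < 0:
            assert np.all(np.diff(ea) < 0)
        else:
            assert np.all(np.diff(ea) > 0)


class TestClassify:
    def test_published_transient_is_super(self):
        f = hk.SuperArrheniusFit(-33.77, 9.98e4, -1.58e8, 1.0, np.zeros((3, 3)))
        assert hk.classify_arrhenius(f, tolerance=0.0) == "super"

    def test_zero_curvature_is_arrhenius(self):
        f = hk.SuperArrheniusFit(0.0, -1e4, 0.0, 1.0, np.zeros((3, 3)))
        assert hk.classify_arrhenius(f, tolerance=0.0) == "arrhenius"

    def test_positive_generator_curvature_classified_sub(self):
        temps = np.arange(270.0, 341.0, 10.0)
        f = hk.fit_super_arrhenius(series_from(1.0, -3e4, 1e7, temps))
        assert hk.classify_arrhenius(f) == "sub"

    def test_negative_tolerance_rejected(self):
        f = hk.SuperArrheniusFit(0.0, 0.0, 0.0, 1.0, np.zeros((3, 3)))
        with pytest.raises(DomainError):
            hk.classify_arrhenius(f, tolerance=-1.0)


class TestPredict:
    def test_unit_fit(self):
        f = hk.SuperArrheniusFit(0.0, 0.0, 0.0, 1.0, np.zeros((3, 3)))
        assert hk.predict(f, 123.4) == pytest.approx(1.0)

    def test_roundtrip_identity_on_zero_noise_data(self):
        temps = np.arange(270.0, 341.0, 10.0)
        s = series_from(-20.0, 3e4, -7e7, temps, kind="diffusion")
        f = hk.fit_super_arrhenius(s)
        assert np.allclose(hk.predict(f, temps), s.values, rtol=1e-8)

    def test_diffusion_increases_with_temperature_published_params(self):
        f = hk.SuperArrheniusFit(-33.77, 9.98e4, -1.58e8, 1.0, np.zeros((3, 3)),
                                 value_kind="diffusion")
        assert hk.predict(f, 310.0) > hk.predict(f, 290.0)
        grid = np.linspace(270.0, 340.0, 15)
        assert np.all(np.diff(hk.predict(f, grid)) > 0)

    def test_invalid_temperature(self):
        f = hk.SuperArrheniusFit(0.0, 0.0, 0.0, 1.0, np.zeros((3, 3)))
        with pytest.raises(DomainError):
            hk.predict(f, -10.0)


class TestCompareModels:
    def test_exact_quadratic_prefers_quadratic(self):
        temps = np.arange(270.0, 341.0, 10.0)
        cmp = hk.compare_models(series_from(-33.0, 1e5, -1.6e8, temps))
        assert cmp.preferred == "super_arrhenius"
        assert cmp.super_arrhenius.r_squared == pytest.approx(1.0)

    def test_exact_linear_prefers_linear(self):
        temps = np.arange(270.0, 341.0, 10.0)
        cmp = hk.compare_models(series_from(2.0, -2e4, 0.0, temps))
        assert cmp.preferred == "arrhenius"

    def test_too_few_points(self):
        with pytest.raises(InsufficientDataError):
            hk.compare_models(hk.RateSeries([1.0, 2.0, 3.0], [1.0, 2.0, 3.0]))

    def test_noisy_super_replicates_mostly_prefer_quadratic(self):
        temps = np.arange(270.0, 341.0, 10.0)
        wins = sum(
            hk.compare_models(
                hk.generate_rate_series(-33.77, 9.98e4, -1.6e8, temps, 0.02, seed)
            ).preferred == "super_arrhenius"
            for seed in range(100)
        )
        assert wins >= 90
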