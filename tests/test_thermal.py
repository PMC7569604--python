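"""Thermal-response curves: development, mortality, adult timing, fecundity."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from whitefly_phenology import (
    AdjustmentFactors,
    JanischParams,
    MortalityParams,
    adult_median_time,
    apply_adjustment,
    degree_day_fit,
    immature_mortality,
    janisch_rate,
    janisch_time,
    mean_fecundity,
)

T_GRID = np.linspace(0.0, 40.0, 401)


class TestJanischRate:
    def test_rate_at_optimum_is_reciprocal_dmin(self, bundle):
        egg = bundle.development["egg"]
        assert janisch_rate(egg, egg.t_opt) == pytest.approx(1.0 / egg.d_min, rel=1e-12)

    @pytest.mark.parametrize(
        "stage,T,expected",
        [
            # frozen from direct evaluation of the catenary formula
            ("egg", 15.0, 1.0 / (0.5 * 4.98 * (math.exp(0.15 * (15 - 27.4)) + math.exp(-0.15 * (15 - 27.4))))),
            ("puparium", 32.0, 1.0 / (0.5 * 3.46 * (math.exp(0.24 * (32 - 23.0)) + math.exp(-0.24 * (32 - 23.0))))),
        ],
    )
    def test_known_evaluations(self, bundle, stage, T, expected):
        assert janisch_rate(bundle.development[stage], T) == pytest.approx(expected, rel=1e-12)
        # the two frozen points land near the published medians
        if stage == "egg":
            assert 1.0 / expected == pytest.approx(16.4, abs=0.1)

    def test_rate_bounded_by_optimum_on_grid(self, bundle):
        for p in bundle.development.values():
            r = janisch_rate(p, T_GRID)
            assert np.all(r <= 1.0 / p.d_min + 1e-12)
            assert np.all(r > 0)
            # equality only at the optimum
            off = T_GRID[np.abs(T_GRID - p.t_opt) > 0.5]
            assert np.all(janisch_rate(p, off) < 1.0 / p.d_min)

    def test_non_finite_temperature_rejected(self, bundle):
        with pytest.raises(ValueError):
            janisch_rate(bundle.development["egg"], float("nan"))

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            JanischParams(d_min=-1, t_opt=25, k=0.1)
        with pytest.raises(ValueError):
            JanischParams(d_min=5, t_opt=55, k=0.1)


class TestImmatureMortality:
    def test_minimum_at_optimum_closed_form(self, bundle):
        pup = bundle.mortality["puparium"]
        expected = 1.0 - math.exp(-4.0 * pup.h)
        assert immature_mortality(pup, pup.t_opt) == pytest.approx(expected, rel=1e-12)
        assert expected == pytest.approx(0.0696, abs=5e-4)

    def test_egg_mortality_at_cold_extreme_matches_observation(self, bundle):
        # observed egg mortality at 10 C was 87 %
        m = immature_mortality(bundle.mortality["egg"], 10.0)
        assert m == pytest.approx(0.84, abs=0.01)

    @given(d=st.floats(0.0, 25.0))
    @settings(max_examples=50, deadline=None)
    def test_symmetry_around_optimum(self, d):
        p = MortalityParams(h=0.01, b=2.0, t_opt=21.8)
        assert immature_mortality(p, p.t_opt + d) == pytest.approx(
            immature_mortality(p, p.t_opt - d), rel=1e-10, abs=1e-12
        )

    def test_bounded_and_flat_at_optimum(self, bundle):
        for p in bundle.mortality.values():
            m = immature_mortality(p, np.linspace(-20, 60, 500))
            assert np.all((m >= 0) & (m <= 1))
            eps = 1e-5
            deriv = (immature_mortality(p, p.t_opt + eps)
                     - immature_mortality(p, p.t_opt - eps)) / (2 * eps)
            assert abs(deriv) < 1e-6

    def test_monotone_away_from_optimum(self, bundle):
        p = bundle.mortality["puparium"]
        above = np.linspace(p.t_opt, 45, 100)
        assert np.all(np.diff(immature_mortality(p, above)) >= -1e-12)

    def test_literal_form_available(self, bundle):
        p = bundle.mortality["puparium"]
        lit = immature_mortality(p, 21.8, form="literal")
        assert 0.0 <= lit <= 1.0
        with pytest.raises(ValueError):
            immature_mortality(p, 21.8, form="bogus")


class TestAdultTiming:
    def test_oviposition_median_at_15(self, bundle):
        # 1 / (0.068 * e^{0.0405*15}) ~ 8.0 d; observed median 8.4 (6.2-10.5)
        t = adult_median_time(bundle.adult, 15.0, "oviposition")
        assert t == pytest.approx(8.01, abs=0.02)
        assert 6.2 < t < 10.5

    def test_male_survival_shorter_by_factor(self, bundle):
        t_ovi = adult_median_time(bundle.adult, 15.0, "oviposition")
        t_m = adult_median_time(bundle.adult, 15.0, "male_survival")
        assert t_m == pytest.approx(t_ovi * math.exp(bundle.adult.factor_male), rel=1e-12)
        assert t_m == pytest.approx(5.6, abs=0.05)

    def test_sex_ratio_of_medians_constant_over_temperature(self, bundle):
        Ts = np.linspace(5, 35, 20)
        f = adult_median_time(bundle.adult, Ts, "female_survival")
        m = adult_median_time(bundle.adult, Ts, "male_survival")
        expected = math.exp(bundle.adult.factor_male - bundle.adult.factor_female)
        assert np.allclose(m / f, expected, rtol=1e-12)

    def test_strictly_decreasing_in_temperature(self, bundle):
        for role in ("oviposition", "female_survival", "male_survival"):
            t = adult_median_time(bundle.adult, T_GRID, role)
            assert np.all(np.diff(t) < 0)

    def test_unknown_role_rejected(self, bundle):
        with pytest.raises(ValueError):
            adult_median_time(bundle.adult, 20.0, "larval")


class TestFecundity:
    def test_peak_near_20_degrees(self, bundle):
        F = mean_fecundity(bundle.fecundity, T_GRID)
        assert T_GRID[np.argmax(F)] == pytest.approx(20.0, abs=1.0)
        assert mean_fecundity(bundle.fecundity, 20.0) == pytest.approx(40.1, abs=2.0)

    def test_reproduction_limits(self, bundle):
        assert mean_fecundity(bundle.fecundity, 10.0) < 1.0
        # hot side declines, though more gently (weakly constrained there)
        assert mean_fecundity(bundle.fecundity, 40.0) < 0.2 * mean_fecundity(bundle.fecundity, 20.0)
        assert np.all(mean_fecundity(bundle.fecundity, T_GRID) >= 0)

    def test_unimodal(self, bundle):
        F = mean_fecundity(bundle.fecundity, T_GRID)
        i = int(np.argmax(F))
        assert np.all(np.diff(F[: i + 1]) >= -1e-9)
        assert np.all(np.diff(F[i:]) <= 1e-9)


class TestDegreeDayFit:
    def test_exact_collinear_points(self):
        fit = degree_day_fit([(10, 0.03), (15, 0.08), (20, 0.13)], high_T_cutoff=28)
        assert fit.slope == pytest.approx(0.01, rel=1e-12)
        assert fit.t0 == pytest.approx(7.0, abs=1e-9)
        assert fit.K == pytest.approx(100.0, rel=1e-9)

    def test_K_is_reciprocal_slope(self, rng):
        T = rng.uniform(8, 26, size=6)
        r = 0.004 * (T - 6.0) + rng.normal(0, 1e-4, size=6)
        fit = degree_day_fit(list(zip(T, r)))
        assert fit.K == pytest.approx(1.0 / fit.slope, rel=1e-12)

    def test_high_temperature_points_removed(self, bundle):
        egg = bundle.development["egg"]
        pts = [(T, float(janisch_rate(egg, T))) for T in (10, 15, 18, 20, 25, 28, 32)]
        fit = degree_day_fit(pts, high_T_cutoff=28)
        assert fit.n_used == 5
        # threshold in the physiologically sensible range
        assert 5.0 < fit.t0 < 12.0

    def test_errors(self):
        with pytest.raises(ValueError):
            degree_day_fit([(10, 0.03), (15, 0.08)])
        with pytest.raises(ValueError):
            degree_day_fit([(10, 0.13), (15, 0.08), (20, 0.03)])  # negative slope
        with pytest.raises(ValueError):
            degree_day_fit([(10, 0.1), (10, 0.1), (10, 0.1)])


class TestAdjustment:
    def test_identity_factors_change_nothing(self, bundle):
        same = apply_adjustment(bundle, AdjustmentFactors(1.0, 1.0, 1.0))
        Ts = np.linspace(5, 35, 10)
        for s in bundle.mortality:
            assert np.allclose(immature_mortality(same.mortality[s], Ts),
                               immature_mortality(bundle.mortality[s], Ts))
        assert np.allclose(adult_median_time(same.adult, Ts),
                           adult_median_time(bundle.adult, Ts))
        assert np.allclose(mean_fecundity(same.fecundity, Ts),
                           mean_fecundity(bundle.fecundity, Ts))

    def test_wider_mortality_window_never_raises_mortality(self, bundle):
        adj = apply_adjustment(bundle)
        Ts = np.linspace(-5, 45, 200)
        for s in bundle.mortality:
            assert np.all(immature_mortality(adj.mortality[s], Ts)
                          <= immature_mortality(bundle.mortality[s], Ts) + 1e-12)

    def test_default_factors_scale_times_and_fecundity(self, bundle):
        adj = apply_adjustment(bundle)
        assert mean_fecundity(adj.fecundity, 20.0) == pytest.approx(
            4.0 * mean_fecundity(bundle.fecundity, 20.0), rel=1e-12)
        for role in ("oviposition", "female_survival", "male_survival"):
            assert adult_median_time(adj.adult, 22.0, role) == pytest.approx(
                2.0 * adult_median_time(bundle.adult, 22.0, role), rel=1e-12)
        # original bundle untouched
        assert bundle.adult.intercept == pytest.approx(0.068)

    def test_non_positive_factor_rejected(self):
        with pytest.raises(ValueError):
            AdjustmentFactors(mortality_b=0.0)
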