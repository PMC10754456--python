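"""Time reconstruction, propagation, survival ratio, expansion profiles."""

import numpy as np
import pandas as pd
import pytest

from clonalclock import chronology as chron


class TestTimeArbitrary:
    def test_unit_exposure_over_one_to_e_integrates_to_one(self):
        tc = chron.time_arbitrary(np.array([1.0, np.e]), np.array([1.0]))
        assert abs(tc.t_au[-1] - 1.0) < 1e-9

    def test_unit_exposure_two_to_eight_gives_log_four(self):
        edges = np.linspace(2.0, 8.0, 13)
        tc = chron.time_arbitrary(edges, np.ones(12))
        assert abs(tc.t_au[-1] - np.log(4.0)) < 1e-9

    def test_time_is_linear_in_exposure_scale(self):
        edges = np.linspace(1.0, 6.0, 11)
        t1 = chron.time_arbitrary(edges, np.ones(10)).t_au
        t3 = chron.time_arbitrary(edges, 3.0 * np.ones(10)).t_au
        np.testing.assert_allclose(t3, 3.0 * t1)

    def test_constant_exposure_time_is_logarithmic_in_u(self):
        edges = np.geomspace(1.0, 20.0, 40)
        tc = chron.time_arbitrary(edges, np.full(39, 2.0))
        np.testing.assert_allclose(tc.t_au, 2.0 * np.log(edges / edges[0]),
                                   atol=1e-9)

    def test_zero_exposure_flagged(self):
        tc = chron.time_arbitrary(np.array([1.0, 2.0, 4.0]), np.zeros(2))
        assert tc.no_clock_signal and np.all(tc.t_au == 0)

    def test_monotone_time_under_any_nonnegative_exposure(self):
        rng = np.random.default_rng(1)
        edges = np.sort(rng.uniform(1, 30, 25))
        edges = np.unique(edges)
        theta = rng.uniform(0, 5, len(edges) - 1)
        tc = chron.time_arbitrary(edges, theta)
        assert np.all(np.diff(tc.t_au) >= 0)


class TestCalibration:
    def _tc(self):
        return chron.time_arbitrary(np.array([1.0, 2.0, 4.0, 16.0]),
                                    np.array([1.0, 1.0, 1.0]))

    def test_scaling_factor(self):
        tc = self._tc()
        tc.t_au = np.array([0.0, 2.0, 4.0])
        tc.u = np.array([1.0, 2.0, 4.0])
        tc.theta = np.ones(2)
        chron.calibrate_recurrence(tc, 12.0)
        np.testing.assert_allclose(tc.t_real, [0.0, 6.0, 12.0])

    def test_identity_when_span_matches(self):
        tc = self._tc()
        chron.calibrate_recurrence(tc, float(tc.t_au[-1]))
        np.testing.assert_allclose(tc.t_real, tc.t_au)

    def test_monotonicity_preserved(self):
        tc = self._tc()
        chron.calibrate_recurrence(tc, 7.5)
        assert np.all(np.diff(tc.t_real) >= 0)

    def test_zero_span_rejected(self):
        tc = chron.time_arbitrary(np.array([1.0, 2.0]), np.zeros(1))
        with pytest.raises(ValueError, match="calibrate"):
            chron.calibrate_recurrence(tc, 10.0)


class TestBoundaryFlux:
    def _tc(self, n_bins=40):
        edges = np.linspace(1.0, 21.0, n_bins + 1)
        tc = chron.time_arbitrary(edges, np.ones(n_bins),
                                  counts=np.full(n_bins, 10.0))
        return tc

    def test_symmetric_windows_have_equal_flux(self):
        tc = self._tc()
        p = chron.boundary_flux(tc, "primary-end", window_frac=0.10)
        r = chron.boundary_flux(tc, "recurrence-start", window_frac=0.10)
        assert p.dm == r.dm

    def test_flux_arithmetic(self):
        edges = np.array([1.0, 2.0, 3.0])
        tc = chron.TimeCourse(u=edges, t_au=np.array([0.0, 1.0, 3.0]),
                              theta=np.ones(2), counts=np.array([40.0, 100.0]))
        out = chron.boundary_flux(tc, "primary-end", window_frac=0.5)
        assert out.dm == 100.0 and out.dt == 2.0 and out.dm_dt == 50.0

    def test_zero_span_window_rejected(self):
        tc = chron.TimeCourse(u=np.array([1.0, 2.0, 3.0]),
                              t_au=np.array([0.0, 0.0, 0.0]),
                              theta=np.zeros(2), counts=np.array([1.0, 1.0]),
                              no_clock_signal=True)
        with pytest.raises(ValueError, match="zero time span"):
            chron.boundary_flux(tc, "primary-end", window_frac=0.67)


class TestPropagationAndSurvival:
    def test_propagation_substitution(self):
        t_au = np.linspace(0.0, 5.0, 100)
        dt_p, t_real = chron.propagate_primary(
            dm_p=100.0, u_p=4.0, u_r=2.0, dmdt_r=50.0, t_au_primary=t_au,
            gamma_pr=1.0 / 300.0)
        assert dt_p == pytest.approx(300.0)
        assert np.all(np.diff(t_real) >= 0)

    def test_continuation_limit(self):
        t_au = np.linspace(0.0, 1.0, 21)
        # with gamma_pr=1 and equal u the propagated span is dM/dMdt
        dt_p, _ = chron.propagate_primary(80.0, 3.0, 3.0, 20.0, t_au, gamma_pr=1.0)
        assert dt_p == pytest.approx(4.0)

    def test_zero_recurrence_flux_rejected(self):
        with pytest.raises(ValueError, match="recurrence flux"):
            chron.propagate_primary(1.0, 1.0, 1.0, 0.0, np.linspace(0, 1, 10))

    def test_survival_ratio_substitution(self):
        assert chron.survival_ratio(10.0, 2.0, 5.0, 1.0) == pytest.approx(25.0)
        assert chron.survival_ratio(3.0, 4.0, 4.0, 3.0) == pytest.approx(1.0)
        with pytest.raises(ValueError):
            chron.survival_ratio(-1.0, 1.0, 1.0, 1.0)

    def test_propagation_survival_round_trip_is_exact(self):
        """Assuming gamma_P/gamma_R = g to calibrate the primary and then
        re-estimating the ratio from the calibrated flux returns exactly 1/g."""
        rng = np.random.default_rng(11)
        for _ in range(20):
            g = rng.uniform(1e-4, 1.0)
            dm_p = rng.uniform(10, 500)
            u_p, u_r = rng.uniform(1, 50, 2)
            dmdt_r = rng.uniform(0.1, 100)
            t_au = np.cumsum(rng.uniform(0.01, 1.0, 60))
            t_au = np.concatenate([[0.0], t_au])
            dt_p, t_real = chron.propagate_primary(dm_p, u_p, u_r, dmdt_r,
                                                   t_au, gamma_pr=g)
            w = max(2, int(np.ceil(chron.WINDOW_FRACTION * len(t_real))))
            dmdt_p = dm_p / (t_real[-1] - t_real[-w])
            est = chron.survival_ratio(dmdt_r, u_r, u_p, dmdt_p)
            assert est == pytest.approx(1.0 / g, rel=1e-12)

    def test_survival_ratio_bounds_ordering(self):
        t_au = np.concatenate([[0.0], np.cumsum(np.full(59, 0.1))])
        res = chron.survival_ratio_bounds(dm_p=50.0, u_p=6.0, u_r=2.0,
                                          dmdt_r=30.0, t_au_primary=t_au)
        # a longer assumed primary duration lowers (dM/dt)_P, raising the ratio
        assert res.lower < res.upper
        assert res.durations_months == (24.0, 84.0)

    def test_window_aggregate_is_harmonic(self):
        f = np.array([0.5, 0.25])
        assert chron.window_inverse_frequency(f) == pytest.approx(1 / 0.375)


class TestExpansionProfile:
    def test_linear_time_gives_constant_profile(self):
        t = np.linspace(0.0, 5.0, 50)
        u = 2.0 + 3.0 * t
        prof = chron.expansion_profile(u, t, smooth=False)
        np.testing.assert_allclose(prof.values, 3.0, atol=1e-9)

    def test_quadratic_u_gives_linear_profile(self):
        t = np.linspace(0.1, 2.0, 100)
        prof = chron.expansion_profile(t ** 2, t, smooth=False)
        interior = slice(1, -1)
        np.testing.assert_allclose(prof.values[interior], 2.0 * t[interior],
                                   rtol=0.02)

    def test_survival_drop_shows_as_profile_dip(self):
        from clonalclock import sim
        gamma = np.concatenate([np.full(18, 0.95), np.full(8, 0.5),
                                np.full(18, 0.95)])
        cfg = sim.SimulationConfig(mu=0.0, omega=0.3, gamma=gamma, n0=200,
                                   n_generations=len(gamma), seed=13)
        _, truth = sim.simulate_clonal_expansion(cfg)
        n = truth.n_per_generation.astype(float)
        u = 2.0 * n                       # pi * N, the inverse-frequency scale
        t = np.arange(len(n), dtype=float)
        prof = chron.expansion_profile(u, t, smooth=True)
        mid = prof.values[20:26].mean()
        flank = prof.values[8:17].mean()
        assert mid < 0.6 * flank

    def test_nonmonotone_time_rejected(self):
        with pytest.raises(ValueError, match="increasing"):
            chron.expansion_profile(np.arange(5.0), np.array([0, 1, 1, 2, 3.0]))


class TestRecurrenceRegression:
    def test_recovers_generating_coefficients(self):
        rng = np.random.default_rng(17)
        ratios = 10 ** rng.uniform(0.5, 2.5, 40)
        times = 19.5 - 5.8 * np.log10(ratios) + rng.normal(0, 1.0, 40)
        fits = chron.recurrence_time_regression(ratios, times)
        fit1 = fits[fits["fit"] == "fit1"].iloc[0]
        assert abs(fit1["slope"] - (-5.8)) <= 2 * fit1["slope_se"]
        assert fits.shape[0] == 2

    def test_collinear_data_exact(self):
        ratios = np.array([10.0, 100.0, 1000.0])
        times = 20.0 - 4.0 * np.log10(ratios)
        fits = chron.recurrence_time_regression(ratios, times)
        fit1 = fits[fits["fit"] == "fit1"].iloc[0]
        assert fit1["slope"] == pytest.approx(-4.0)
        assert fit1["slope_se"] == pytest.approx(0.0, abs=1e-8)

    def test_two_points_rejected(self):
        with pytest.raises(ValueError):
            chron.recurrence_time_regression(np.array([10.0, 20.0]),
                                             np.array([5.0, 4.0]))

    def test_subunit_ratios_excluded_from_double_log(self):
        ratios = np.array([0.5, 10.0, 100.0, 1000.0, 50.0])
        times = np.array([20.0, 15.0, 10.0, 5.0, 12.0])
        with pytest.warns(UserWarning, match="excluded"):
            fits = chron.recurrence_time_regression(ratios, times)
        assert fits.loc[fits["fit"] == "fit2", "n"].iloc[0] == 4


def test_inherited_mutations_bias_the_ratio_upward_via_inverse_frequency():
    """Inherited mutations are clonal in the recurrence (high f), so when
    the start-of-recurrence window is delimited on the observed 1/f axis
    they deflate the window aggregate (1/f)_R — the proxy for N_R — and
    inflate the survival-ratio estimate. Restricting the window to de novo
    mutations removes the bias; both modes are exposed."""
    from clonalclock import sim
    from clonalclock.chronology import survival_ratio_from_pair

    p, r, truth, w = sim.primary_recurrent_study(seed=5)
    rg = truth.resection_generation
    g = p["origin_gen"].to_numpy()
    win_p = p[(g > rg - w) & (g <= rg)]
    dmdt_p = len(win_p) / w
    u_p = chron.window_inverse_frequency(win_p["f"].to_numpy())

    denovo = r[r["de_novo"]]
    gr = denovo["origin_gen"].to_numpy()
    first = rg + 2
    win_r_clean = denovo[(gr >= first) & (gr < first + w)]
    dmdt_r = len(win_r_clean) / w
    u_r_clean = chron.window_inverse_frequency(win_r_clean["f"].to_numpy())
    # contaminated window: same mutation count taken from the low-u end of
    # the full recurrence table, where inherited clonal mutations pile up
    contaminated = r.nlargest(len(win_r_clean), "f")
    assert (~contaminated["de_novo"]).any()
    u_r_contaminated = chron.window_inverse_frequency(
        contaminated["f"].to_numpy())
    assert u_r_contaminated < u_r_clean
    biased = chron.survival_ratio(dmdt_r, u_r_contaminated, u_p, dmdt_p)
    clean = chron.survival_ratio(dmdt_r, u_r_clean, u_p, dmdt_p)
    assert biased > clean

    # the pair estimator exposes the same switch
    est_clean = survival_ratio_from_pair(p, r, rg, w, de_novo_only=True)
    assert est_clean == pytest.approx(clean, rel=1e-9)
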