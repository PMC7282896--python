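"""Diel-DO metabolism model: saturation, forward simulation, inversion."""

import numpy as np
import pytest

from conftest import simulate_day
from riversubsidy.metabolism import (
    DielSeries,
    MetabolismEstimate,
    MetabolismParams,
    er_at_temperature,
    fit_daily_metabolism,
    gpp_instantaneous,
    o2_saturation,
    simulate_diel_do,
    theta_sensitivity,
    weekly_metabolism_summary,
)
from riversubsidy.synthdata import generate_drivers


class TestO2Saturation:
    def test_benson_krause_at_20C(self):
        # frozen from direct evaluation of the Benson-Krause equation
        assert o2_saturation(20.0) == pytest.approx(9.092, abs=0.001)

    def test_monotone_decreasing(self):
        temps = np.linspace(-1, 45, 200)
        assert np.all(np.diff(o2_saturation(temps)) < 0)

    def test_continuity(self):
        assert abs(o2_saturation(20.0 + 1e-6) - o2_saturation(20.0)) < 1e-4

    def test_range_validation(self):
        with pytest.raises(ValueError):
            o2_saturation(50.0)


class TestERTemperature:
    def test_reference_temperature(self):
        assert er_at_temperature(5.0, 1.1085, 20.0) == 5.0

    def test_ten_degrees_warmer(self):
        # 1.1085**10, direct evaluation
        assert er_at_temperature(1.0, 1.1085, 30.0) == pytest.approx(2.8015, abs=1e-3)

    def test_theta_one_is_inert(self):
        temps = np.array([5.0, 20.0, 35.0])
        assert np.allclose(er_at_temperature(3.0, 1.0, temps), 3.0)


class TestGPPInstantaneous:
    def test_zero_light(self, one_day_drivers):
        p = MetabolismParams(gpp_daily=6.0)
        assert gpp_instantaneous(p, 0.0, light_day_integral=1000.0) == 0.0

    def test_linear_daily_integral_is_gpp(self, one_day_drivers):
        t, _, light = one_day_drivers
        p = MetabolismParams(gpp_daily=6.0)
        integral = np.trapezoid(light, t)
        rate = gpp_instantaneous(p, light, light_day_integral=integral)
        assert np.trapezoid(rate, t) == pytest.approx(6.0, abs=1e-8)

    def test_zero_integral_rejected(self):
        p = MetabolismParams(gpp_daily=6.0)
        with pytest.raises(ValueError):
            gpp_instantaneous(p, 5.0, light_day_integral=0.0)

    def test_saturating_small_light_limit(self):
        p = MetabolismParams(light_model="saturating", pmax=10.0, alpha=0.01)
        small = 1.0
        assert gpp_instantaneous(p, small) == pytest.approx(p.alpha * small, rel=0.01)

    def test_saturating_scale_invariance_in_linear_regime(self):
        # doubling light while halving alpha leaves the rate unchanged
        p1 = MetabolismParams(light_model="saturating", pmax=10.0, alpha=0.02)
        p2 = MetabolismParams(light_model="saturating", pmax=10.0, alpha=0.01)
        assert gpp_instantaneous(p1, 50.0) == pytest.approx(
            gpp_instantaneous(p2, 100.0), rel=0.01
        )


class TestForwardSimulation:
    def test_equilibrium_is_constant(self):
        t = np.arange(288) / 288.0
        temp = np.full_like(t, 20.0)
        p = MetabolismParams(gpp_daily=0, er20=0, k=5.0)
        sim = simulate_diel_do(p, t, temp, np.zeros_like(t), o0=o2_saturation(20.0))
        assert np.allclose(sim.do_mgL, o2_saturation(20.0), atol=1e-12)

    def test_deficit_decays_exponentially(self):
        # gpp = er = 0: O - O_sat relaxes as exp(-k t), half-life ln2/k
        t = np.arange(288) / 288.0
        temp = np.full_like(t, 20.0)
        k = 5.0
        p = MetabolismParams(gpp_daily=0, er20=0, k=k)
        sim = simulate_diel_do(p, t, temp, np.zeros_like(t), o0=o2_saturation(20.0) + 2.0)
        deficit = sim.do_mgL - o2_saturation(20.0)
        assert deficit[144] / deficit[0] == pytest.approx(np.exp(-k * t[144]), rel=1e-6)

    def test_coarse_grid_rejected(self):
        t = np.arange(0, 1, 1 / 96)  # 15-minute steps
        with pytest.raises(ValueError):
            simulate_diel_do(
                MetabolismParams(k=1.0), t, np.full_like(t, 20.0), np.zeros_like(t), 8.0
            )

    def test_conservation_of_daily_do_change(self, one_day_drivers):
        # integral of dO/dt over the record equals the simulated Delta-DO
        t, temp, light = one_day_drivers
        p = MetabolismParams(gpp_daily=6, er20=4, theta=1.045, k=5)
        sim = simulate_diel_do(p, t, temp, light, o0=o2_saturation(temp[0]))
        from riversubsidy.metabolism import _rate_arrays

        gpp, er = _rate_arrays(p, t, temp, light)
        dodt = gpp - er + p.k * (o2_saturation(temp) - sim.do_mgL)
        assert np.trapezoid(dodt, t) == pytest.approx(
            sim.do_mgL[-1] - sim.do_mgL[0], abs=1e-4
        )


class TestInversion:
    def test_noise_free_round_trip(self):
        sim = simulate_day(6.0, 4.0, 5.0, theta=1.045)
        est = fit_daily_metabolism(sim, theta=1.045, k_mode="fit")[0]
        assert est.converged
        assert est.gpp == pytest.approx(6.0, rel=1e-2)
        assert est.er20 == pytest.approx(4.0, rel=1e-2)
        assert est.k == pytest.approx(5.0, rel=1e-2)

    def test_fixed_k_mode(self):
        sim = simulate_day(6.0, 4.0, 5.0, theta=1.045)
        est = fit_daily_metabolism(sim, theta=1.045, k_mode="fixed", k_fixed=5.0)[0]
        assert not est.k_fitted and est.k == 5.0
        assert est.gpp == pytest.approx(6.0, rel=1e-3)

    def test_dark_day_er_matches_deficit_regression(self):
        # no light: GPP is structurally zero and nocturnal decline sets ER.
        # Oracle: instantaneous mass balance er(t) = k*(Osat - O) - dO/dt,
        # normalised by theta^(T-20), averaged over the day.
        t, light, temp = generate_drivers(1, 5.0)
        theta, k = 1.045, 5.0
        p = MetabolismParams(gpp_daily=0.0, er20=3.0, theta=theta, k=k)
        sim = simulate_diel_do(p, t, temp, np.zeros_like(t), o0=o2_saturation(temp[0]))
        est = fit_daily_metabolism(sim, theta=theta, k_mode="fixed", k_fixed=k)[0]
        assert est.gpp == 0.0
        dodt = np.gradient(sim.do_mgL, t)
        er_t = k * (o2_saturation(temp) - sim.do_mgL) - dodt
        oracle_er20 = np.mean(er_t / theta ** (temp - 20.0))
        assert est.er20 == pytest.approx(oracle_er20, rel=0.02)
        assert est.er20 == pytest.approx(3.0, rel=0.02)

    def test_non_convergence_is_flagged_not_raised(self):
        # DO trace unrelated to the drivers: fit must return, flag optional
        t, light, temp = generate_drivers(1, 5.0)
        rng = np.random.default_rng(0)
        do = 8.0 + rng.normal(0, 0.5, t.size) ** 2 + 0.1
        series = DielSeries(t, do, temp, light)
        ests = fit_daily_metabolism(series, k_mode="fit")
        assert len(ests) == 1  # no exception

    def test_theta_inert_at_constant_20C(self):
        t, light, _ = generate_drivers(2, 5.0)
        temp = np.full_like(t, 20.0)
        p = MetabolismParams(gpp_daily=5.0, er20=2.0, theta=1.045, k=6.0)
        sim = simulate_diel_do(p, t, temp, light, o0=o2_saturation(20.0))
        sim.mesocosm = "a"
        sim2 = DielSeries(t, sim.do_mgL.copy(), temp, light, mesocosm="b")
        ests, rank = theta_sensitivity(
            [sim, sim2], thetas=(1.045, 1.1085), k_mode="fixed",
            k_fixed_by_mesocosm={"a": 6.0, "b": 6.0},
        )
        g_low = [e.gpp for e in ests[1.045]]
        g_high = [e.gpp for e in ests[1.1085]]
        assert np.allclose(g_low, g_high, atol=1e-6)

    def test_single_theta_rank_is_one(self):
        sim = simulate_day(6.0, 4.0, 5.0)
        sim.mesocosm = "a"
        sim2 = simulate_day(3.0, 2.0, 5.0)
        sim2.mesocosm = "b"
        _, rank = theta_sensitivity(
            [sim, sim2], thetas=(1.1085,), k_mode="fixed",
            k_fixed_by_mesocosm={"a": 5.0, "b": 5.0},
        )
        assert rank == {"gpp": 1.0, "er": 1.0}


class TestWeeklySummary:
    @staticmethod
    def _est(day, gpp, er, meso="m1", pct=0.0):
        return MetabolismEstimate(
            day=day, gpp=gpp, er=er, er20=er, k=5.0, k_fitted=False,
            sse=0.0, converged=True, mesocosm=meso, treatment_pct_cattle=pct,
        )

    def test_constant_rates(self):
        ests = [self._est(d, 2.0, 1.0) for d in range(1, 8)]
        wk = weekly_metabolism_summary(ests)
        assert len(wk) == 1
        row = wk.iloc[0]
        assert row.week == 1
        assert row.nep_mean == pytest.approx(1.0)
        assert row.trophic_state == "autotrophic"

    def test_balanced_metabolism(self):
        ests = [self._est(d, 3.0, 3.0) for d in range(1, 8)]
        row = weekly_metabolism_summary(ests).iloc[0]
        assert row.nep_mean == pytest.approx(0.0)
        assert row.gpp_er_ratio == pytest.approx(1.0)

    def test_week_binning(self):
        ests = [self._est(d, 1.0, 2.0) for d in range(1, 15)]
        wk = weekly_metabolism_summary(ests)
        assert sorted(wk.week) == [1, 2]
        assert set(wk.trophic_state) == {"heterotrophic"}
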