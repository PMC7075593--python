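"""Flight power curve, thermoregulation and energy-ledger arithmetic."""

import numpy as np
import pandas as pd
import pytest

from gannetrack import energetics
from gannetrack.energetics import (AeroParams, Morphology, ThermoParams,
                                   chemical_power_curve, daily_energy,
                                   dee_benchmark, flight_muscle_efficiency,
                                   mechanical_power, seasonal_totals,
                                   thermo_cost_kj)


class TestEfficiencyAndBMR:
    def test_unit_mass(self):
        assert flight_muscle_efficiency(1.0) == pytest.approx(0.3)

    def test_study_mass(self):
        assert flight_muscle_efficiency(3.03) == pytest.approx(0.349, abs=0.001)

    def test_monotone_in_mass(self):
        masses = np.linspace(0.5, 10, 20)
        eff = [flight_muscle_efficiency(m) for m in masses]
        assert np.all(np.diff(eff) > 0)

    def test_nonpositive_mass_rejected(self):
        with pytest.raises(ValueError):
            flight_muscle_efficiency(0.0)


class TestMechanicalPower:
    def test_functional_form_a_over_v_plus_bv3_plus_c(self):
        # P(V) = A/V + B V^3 + C exactly: fit the three coefficients on
        # three speeds and predict a fourth
        m, a = Morphology(), AeroParams()
        v = np.array([5.0, 12.0, 25.0])
        design = np.column_stack([1.0 / v, v ** 3, np.ones(3)])
        coef = np.linalg.solve(design, mechanical_power(v, m, a))
        assert coef[0] > 0 and coef[1] > 0 and coef[2] > 0
        v4 = 17.0
        pred = coef[0] / v4 + coef[1] * v4 ** 3 + coef[2]
        assert mechanical_power(v4, m, a) == pytest.approx(pred, rel=1e-12)

    def test_air_density_scalings(self):
        # doubling rho halves the induced coefficient and doubles parasite
        m = Morphology()
        v = np.array([5.0, 12.0, 25.0])
        design = np.column_stack([1.0 / v, v ** 3, np.ones(3)])
        fit = lambda rho: np.linalg.solve(
            design, mechanical_power(v, m, AeroParams(air_density=rho)))
        a1, b1, _ = fit(1.23)
        a2, b2, _ = fit(2.46)
        assert a2 == pytest.approx(a1 / 2, rel=1e-9)
        assert b2 == pytest.approx(2 * b1, rel=1e-9)

    def test_zero_speed_rejected(self):
        with pytest.raises(ValueError):
            mechanical_power(0.0)


class TestChemicalPowerCurve:
    def test_gannet_anchor_values(self):
        res = chemical_power_curve()
        assert res.v_mp == pytest.approx(15.2, abs=0.5)
        assert res.p_min_w == pytest.approx(84.0, rel=0.05)
        assert res.p_mr_w == pytest.approx(103.0, rel=0.08)
        assert res.p_min_w / res.bmr_w == pytest.approx(10.0, rel=0.10)
        assert res.p_mr_w / res.bmr_w == pytest.approx(12.0, rel=0.10)

    def test_vmr_exceeds_vmp_generic_morphologies(self):
        for mb, b, s in [(0.5, 0.8, 0.05), (3.03, 1.83, 0.262), (8.0, 2.8, 0.6)]:
            res = chemical_power_curve(Morphology(mb, b, s))
            assert res.v_mr > res.v_mp
            assert res.p_mr_w > res.p_min_w

    def test_golden_section_matches_dense_grid(self):
        res = chemical_power_curve()
        v = res.curve["speed_ms"].to_numpy()
        pc = res.curve["p_chem_w"].to_numpy()
        assert abs(v[np.argmin(pc)] - res.v_mp) < 0.3
        assert abs(v[np.argmin(pc / v)] - res.v_mr) < 0.3

    def test_curve_is_u_shaped(self):
        res = chemical_power_curve()
        pc = res.curve["p_chem_w"].to_numpy()
        i = int(np.argmin(pc))
        assert 0 < i < len(pc) - 1
        assert np.all(np.diff(pc[:i + 1]) <= 0) and np.all(np.diff(pc[i:]) >= 0)

    def test_bmr_variant_also_near_anchor(self):
        res = chemical_power_curve(aero=AeroParams(bmr_in_chemical=True))
        assert res.p_min_w == pytest.approx(84.0, rel=0.05)


class TestThermo:
    def test_hand_arithmetic_exact(self):
        # 0.93 x (39-9) x 14 x 3030 g = 1,183,518 J
        assert thermo_cost_kj(14.0, 9.0, 3.03) == pytest.approx(1183.518)

    def test_zero_wet_hours(self):
        assert thermo_cost_kj(0.0, 9.0, 3.03) == 0.0

    def test_strictly_decreasing_in_sst(self):
        costs = thermo_cost_kj(14.0, np.linspace(0, 30, 31), 3.03)
        assert np.all(np.diff(costs) < 0)

    def test_sst_above_core_rejected(self):
        with pytest.raises(ValueError):
            thermo_cost_kj(5.0, 40.0, 3.03)


def ledger_frame(power):
    days = pd.DataFrame({
        "date": pd.date_range("2010-11-01", periods=6, freq="D"),
        "season": ["fall_migration"] * 2 + ["winter"] * 4,
        "dry_h": [5.4, 5.4, 3.8, 3.8, 0.0, 3.8],
        "wet_h": [18.6, 18.6, 20.2, 20.2, 24.0, 20.2],
        "sst_mean": [15.0, 15.0, 9.0, 9.0, 9.0, np.nan],
    })
    return daily_energy(days, power)


class TestLedger:
    def test_flight_cost_uses_seasonal_power(self):
        power = chemical_power_curve()
        led = ledger_frame(power)
        assert led["flight_kj"].iloc[0] == pytest.approx(5.4 * 3600 * power.p_mr_w / 1000)
        assert led["flight_kj"].iloc[2] == pytest.approx(3.8 * 3600 * power.p_min_w / 1000)
        assert led["flight_kj"].iloc[4] == 0.0

    def test_missing_sst_filled_with_season_mean_and_flagged(self):
        led = ledger_frame(chemical_power_curve())
        assert led["sst_filled"].iloc[5]
        assert led["sst_used"].iloc[5] == pytest.approx(9.0)

    def test_seasonal_totals_additivity(self):
        power = chemical_power_curve()
        led = ledger_frame(power)
        tot = seasonal_totals(led, {"fall_migration": 30, "winter": 100})
        w = tot[tot["season"] == "winter"].iloc[0]
        assert w["total_mj"] == pytest.approx(w["total_kj_d"] * 100 / 1000)
        nb = tot[tot["season"] == "non_breeding_total"].iloc[0]
        assert nb["total_mj"] == pytest.approx(tot["total_mj"].iloc[:2].sum())

    def test_constant_rate_cumulative(self):
        led = pd.DataFrame({
            "season": ["winter"] * 10, "flight_kj": [500.0] * 10,
            "resting_kj": [1000.0] * 10, "total_kj": [1500.0] * 10})
        tot = seasonal_totals(led, {"winter": 100})
        assert tot["total_mj"].iloc[0] == pytest.approx(150.0)

    def test_split_season_leaves_total_unchanged(self):
        led = pd.DataFrame({
            "season": ["winter_a"] * 5 + ["winter_b"] * 5,
            "flight_kj": [500.0] * 10, "resting_kj": [1000.0] * 10,
            "total_kj": [1500.0] * 10})
        tot = seasonal_totals(led, {"winter_a": 50, "winter_b": 50})
        assert tot["total_mj"].iloc[-1] == pytest.approx(150.0)


class TestDEE:
    def test_printed_rates_mean_and_whole_animal(self):
        mean_rate, dee, _ = dee_benchmark()
        assert mean_rate == pytest.approx(1428.75)
        assert dee == pytest.approx(4329.1, abs=0.5)

    def test_single_rate(self):
        mean_rate, dee, _ = dee_benchmark(3.03, (1000.0,))
        assert dee == pytest.approx(3030.0)

    def test_ledger_fractions(self):
        led = pd.DataFrame({"total_kj": [3600.0]})
        _, dee, frac = dee_benchmark(ledger=led)
        assert frac.iloc[0] == pytest.approx(3600.0 / dee)
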