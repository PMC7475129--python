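"""Metabolic computation, challenge/drug windowing, tissue utilities."""

import math

import numpy as np
import pandas as pd
import pytest

import cihpheno as cp
from test_events import synthetic_breath_table


def metric_series(duration_s=2400.0, hz=1.0, value=53.0):
    t = np.arange(int(duration_s * hz)) / hz
    return pd.Series(np.full(len(t), value), index=t)


STANDARD_EPOCHS = [
    cp.EpochDefinition("baseline_1", 0.0, 300.0),
    cp.EpochDefinition("baseline_2", 300.0, 600.0),
    cp.EpochDefinition("baseline_3", 600.0, 900.0),
    cp.EpochDefinition("hypoxia", 1000.0, 1600.0),
]


class TestMetabolism:
    def test_round_trip_recovers_planted_rates(self):
        gas = cp.simulate_gas_traces(9.0, 6.0, 3000.0)
        m = cp.compute_metabolism(gas, 3000.0, (0.0, 60.0), body_mass_g=300.0)
        assert m.vo2_ml_min_100g == pytest.approx(3.0, rel=1e-9)
        assert m.vco2_ml_min_100g == pytest.approx(2.0, rel=1e-9)

    def test_ventilatory_equivalent_at_printed_scale(self):
        # V_I 53, VCO2 1.9 -> V_I/VCO2 = 27.89, the printed ~28 baseline
        gas = cp.simulate_gas_traces(8.1, 1.9 * 3.0, 3000.0)
        m = cp.compute_metabolism(gas, 3000.0, (0.0, 60.0), 300.0, v_i_ml_min_100g=53.0)
        assert m.ve_eq == pytest.approx(53.0 / 1.9, rel=1e-9)
        assert m.ve_eq == pytest.approx(27.89, abs=0.01)

    def test_zero_gradient_gives_zero_uptake(self):
        gas = cp.simulate_gas_traces(0.0, 0.0, 3000.0)
        m = cp.compute_metabolism(gas, 3000.0, (0.0, 60.0), 300.0)
        assert m.vo2_ml_min_100g == 0.0
        assert m.vco2_ml_min_100g == 0.0

    def test_swapped_sensors_detected(self):
        gas = cp.simulate_gas_traces(9.0, 6.0, 3000.0)
        swapped = cp.GasTraces(gas.time_s, gas.fio2_out, gas.fio2_in, gas.fico2_in, gas.fico2_out)
        with pytest.raises(ValueError, match="sensor"):
            cp.compute_metabolism(swapped, 3000.0, (0.0, 60.0), 300.0)


class TestBaselineAveraging:
    def test_mean_of_epoch_means(self):
        t = np.arange(900.0)
        v = np.where(t < 300, 50.0, np.where(t < 600, 52.0, 54.0))
        series = pd.Series(v, index=t)
        assert cp.baseline_from_epochs(series, STANDARD_EPOCHS) == pytest.approx(52.0)

    def test_single_epoch(self):
        series = metric_series(value=48.0)
        assert cp.baseline_from_epochs(series, [STANDARD_EPOCHS[0]]) == pytest.approx(48.0)

    def test_unweighted_even_with_unequal_lengths(self):
        # 100 s at 10 vs 900 s at 40: epoch-mean average is 25, pooled would be 37
        t = np.arange(1000.0)
        series = pd.Series(np.where(t < 100, 10.0, 40.0), index=t)
        epochs = [
            cp.EpochDefinition("baseline_1", 0.0, 100.0),
            cp.EpochDefinition("baseline_2", 100.0, 1000.0),
        ]
        assert cp.baseline_from_epochs(series, epochs) == pytest.approx(25.0)

    def test_missing_baseline_raises(self):
        with pytest.raises(ValueError, match="baseline"):
            cp.baseline_from_epochs(metric_series(), [STANDARD_EPOCHS[-1]])


class TestChallengeResponse:
    def test_pleth_mode_absolute_change(self):
        t = np.arange(2400.0)
        v = np.where(t < 1000, 53.0, np.where(t < 1300, 80.0, 99.0))
        series = pd.Series(v, index=t)
        r = cp.challenge_response(series, STANDARD_EPOCHS, "hypoxia", mode="pleth")
        assert r.baseline_value == pytest.approx(53.0)
        assert r.response_value == pytest.approx(99.0)  # final 5 min only
        assert r.delta == pytest.approx(46.0)  # the printed hypoxia scale

    def test_anaesth_mode_percent_change(self):
        t = np.arange(2400.0)
        v = np.where(t < 1000, 100.0, 120.0)
        series = pd.Series(v, index=t)
        r = cp.challenge_response(series, STANDARD_EPOCHS, "hypoxia", mode="anaesth")
        assert r.baseline_value == pytest.approx(100.0)
        assert r.pct_change == pytest.approx(20.0)

    def test_null_response(self):
        r = cp.challenge_response(metric_series(), STANDARD_EPOCHS, "hypoxia")
        assert r.delta == 0.0
        assert r.pct_change == 0.0

    def test_zero_baseline_flags_pct_undefined(self):
        t = np.arange(2400.0)
        series = pd.Series(np.where(t < 1000, 0.0, 5.0), index=t)
        r = cp.challenge_response(series, STANDARD_EPOCHS, "hypoxia")
        assert r.pct_undefined
        assert math.isnan(r.pct_change)
        assert r.delta == pytest.approx(5.0)

    def test_short_epoch_raises(self):
        epochs = STANDARD_EPOCHS[:3] + [cp.EpochDefinition("hypoxia", 1000.0, 1100.0)]
        with pytest.raises(ValueError, match="shorter"):
            cp.challenge_response(metric_series(), epochs, "hypoxia")

    def test_delta_pct_consistency(self):
        t = np.arange(2400.0)
        series = pd.Series(np.where(t < 1000, 40.0, 55.0), index=t)
        r = cp.challenge_response(series, STANDARD_EPOCHS, "hypoxia")
        assert r.pct_change * r.baseline_value / 100.0 == pytest.approx(r.delta, rel=1e-12)

    def test_window_tracks_epoch_shift_exactly(self):
        # moving the challenge epoch moves the response window with it
        t = np.arange(2400.0)
        series = pd.Series(np.where(t < 1590, 50.0, 90.0), index=t)
        base = STANDARD_EPOCHS[:3]
        r0 = cp.challenge_response(series, base + [cp.EpochDefinition("hypoxia", 1000.0, 1600.0)], "hypoxia")
        r1 = cp.challenge_response(series, base + [cp.EpochDefinition("hypoxia", 1010.0, 1610.0)], "hypoxia")
        # window [1300,1600): 10 s of 90 -> mean 51.333; [1310,1610): 20 s -> 52.667
        assert r0.response_value == pytest.approx(50 + 40 * 10 / 300)
        assert r1.response_value == pytest.approx(50 + 40 * 20 / 300)


class TestDrugResponse:
    def test_planted_depressor_transient(self):
        # -30% dip 10 s after injection, recovered within 1% with 3 s bins
        t = np.arange(0.0, 300.0, 0.1)
        v = np.full(len(t), 100.0)
        v[(t >= 130.0) & (t < 136.0)] = 70.0
        r = cp.drug_response(pd.Series(v, index=t), injection_time_s=120.0, bin_s=3.0)
        assert r.pct_change == pytest.approx(-30.0, abs=1.0)

    def test_flat_series_gives_zero(self):
        t = np.arange(0.0, 300.0, 0.1)
        r = cp.drug_response(pd.Series(np.full(len(t), 100.0), index=t), 120.0)
        assert r.pct_change == 0.0

    def test_pressor_sign_positive(self):
        t = np.arange(0.0, 300.0, 0.1)
        v = np.full(len(t), 100.0)
        v[(t >= 125.0) & (t < 131.0)] = 140.0
        r = cp.drug_response(pd.Series(v, index=t), 120.0)
        assert r.pct_change > 0

    def test_injection_outside_record_raises(self):
        t = np.arange(0.0, 100.0, 0.1)
        with pytest.raises(ValueError, match="outside"):
            cp.drug_response(pd.Series(np.full(len(t), 1.0), index=t), 10.0)


class TestPBG:
    def test_normalised_apnoea_arithmetic(self):
        # baseline T_tot 600 ms; planted 3.0 s pause -> 5.0 cycles
        b = synthetic_breath_table(n=120, t_tot_ms=600.0)
        i = np.searchsorted(b["onset_s"].to_numpy(), 40.0)
        b.loc[i:, "onset_s"] += 3.0
        b.loc[i - 1, "t_e_ms"] += 3000.0
        b.loc[i - 1, "t_tot_ms"] += 3000.0
        r = cp.pbg_apnoea_tachypnoea(b, injection_time_s=35.0)
        assert r.apnoea_found
        assert r.apnoea_cycles == pytest.approx(5.0, rel=1e-6)

    def test_no_apnoea_flagged(self):
        b = synthetic_breath_table(n=120, t_tot_ms=600.0)
        r = cp.pbg_apnoea_tachypnoea(b, injection_time_s=35.0)
        assert r == cp.PBGResponse(0.0, 0.0, False)

    def test_planted_apnoea_and_tachypnoea_recovered(self):
        # apnoea of 4 cycles then 10 breaths at 0.7x T_tot, slight baseline jitter
        rng = np.random.default_rng(0)
        t_tot = 600.0
        durs = list(rng.normal(t_tot, 5.0, 60)) + [t_tot + 4 * t_tot] + [0.7 * t_tot] * 10 + list(
            rng.normal(t_tot, 5.0, 20)
        )
        onsets = np.concatenate([[0.0], np.cumsum(durs)[:-1]]) / 1000.0
        b = synthetic_breath_table(n=len(durs), t_tot_ms=t_tot)
        b["onset_s"] = onsets
        b["t_tot_ms"] = durs
        inj = onsets[60] - 0.05
        r = cp.pbg_apnoea_tachypnoea(b, injection_time_s=inj)
        assert r.apnoea_found
        assert r.apnoea_cycles == pytest.approx(4.0, rel=0.1)
        assert r.tachypnoea_cycles == pytest.approx(7.0, rel=0.1)  # 10 x 0.7 cycles


class TestTissueUtilities:
    @pytest.mark.parametrize(
        "wet,dry,expected", [(1000.0, 220.0, 78.0), (500.0, 125.0, 75.0), (400.0, 400.0, 0.0)]
    )
    def test_oedema_index(self, wet, dry, expected):
        assert cp.oedema_index(wet, dry) == pytest.approx(expected)

    def test_oedema_dry_exceeding_wet_raises(self):
        with pytest.raises(ValueError, match="dry"):
            cp.oedema_index(100.0, 150.0)

    @pytest.mark.parametrize(
        "a,i,amt,cf,expected", [(2.0, 1.0, 2.0, 1.0, 4.0), (0.0, 1.0, 2.0, 1.0, 0.0), (3.0, 1.0, 2.0, 0.5, 3.0)]
    )
    def test_ratio_quantify(self, a, i, amt, cf, expected):
        assert cp.ratio_quantify(a, i, amt, calibration_factor=cf) == pytest.approx(expected)

    def test_zero_internal_standard_raises(self):
        with pytest.raises(ValueError):
            cp.ratio_quantify(1.0, 0.0, 2.0)
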