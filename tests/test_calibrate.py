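"""Calibration: error functions, grid-search parameter recovery on
synthetic references, resistivity tuning, error-bar propagation."""

import numpy as np
import pandas as pd
import pytest

from thermoblock.calibrate import (ConductanceSearch, GridSearchSpec,
                                   Q10Search, ReferenceTable, ResistivityFit,
                                   measure_rates, propagate_error_bars,
                                   rise_fall_errors)
from thermoblock.membrane import MembraneParams, peak_conductances
from thermoblock.synth import SynthSpec, generate_reference


def table_from_rows(rows):
    return ReferenceTable(pd.DataFrame(rows))


def simple_table():
    return table_from_rows([
        {"temperature_c": 5.0, "rise": 300.0, "rise_lower": 280.0,
         "rise_upper": 320.0, "fall": -500.0, "fall_lower": -520.0,
         "fall_upper": -480.0},
        {"temperature_c": 10.0, "rise": 400.0, "rise_lower": 380.0,
         "rise_upper": 420.0, "fall": -600.0, "fall_lower": -620.0,
         "fall_upper": -580.0},
    ])


class TestReferenceTable:
    def test_bounds_validated(self):
        with pytest.raises(ValueError, match="lower <= mean <= upper"):
            table_from_rows([{"temperature_c": 5.0, "rise": 300.0,
                              "rise_lower": 310.0, "rise_upper": 320.0,
                              "fall": -500.0, "fall_lower": -520.0,
                              "fall_upper": -480.0}])

    def test_duplicate_temperatures_rejected(self):
        rows = simple_table().frame.to_dict("records")
        rows[1]["temperature_c"] = 5.0
        with pytest.raises(ValueError, match="distinct"):
            table_from_rows(rows)

    def test_csv_round_trip(self, tmp_path):
        ref = simple_table()
        path = tmp_path / "ref.csv"
        ref.to_csv(path)
        back = ReferenceTable.from_csv(path)
        pd.testing.assert_frame_equal(
            back.frame[ref.frame.columns], ref.frame, check_dtype=False)


class TestRiseFallErrors:
    def test_exact_match_zero(self):
        ref = simple_table()
        _, e_fall, _ = rise_fall_errors(ref, {5.0: (300.0, -500.0)})
        assert e_fall[5.0] == 0.0

    def test_ten_percent_fall_error(self):
        ref = simple_table()
        _, e_fall, _ = rise_fall_errors(ref, {5.0: (300.0, -450.0)})
        assert e_fall[5.0] == pytest.approx(0.1)

    def test_hand_summed_etotal(self):
        ref = simple_table()
        rates = {5.0: (270.0, -500.0),    # Erise=0.1, Efall=0
                 10.0: (320.0, -540.0)}   # Erise=0.2, Efall=0.1
        _, _, etotal = rise_fall_errors(ref, rates)
        assert etotal == pytest.approx(0.01 + 0.04 + 0.0 + 0.01)

    def test_order_invariance(self):
        ref = simple_table()
        rates = {5.0: (280.0, -510.0), 10.0: (410.0, -590.0)}
        _, _, e1 = rise_fall_errors(ref, rates)
        _, _, e2 = rise_fall_errors(ref, dict(reversed(list(rates.items()))))
        assert e1 == e2

    def test_zero_reference_rate_rejected(self):
        ref = table_from_rows([{"temperature_c": 5.0, "rise": 0.0,
                                "rise_lower": 0.0, "rise_upper": 0.0,
                                "fall": -1.0, "fall_lower": -1.0,
                                "fall_upper": -1.0}])
        with pytest.raises(ZeroDivisionError):
            rise_fall_errors(ref, {5.0: (1.0, -1.0)})


COARSE = GridSearchSpec(q10_step=0.5)


class TestQ10Recovery:
    def test_recovers_grid_resident_truth(self):
        # truth (3.0, 2.5, 2.0) in the (10,15] interval lies on the coarse grid
        truth = MembraneParams(q10_h=(3.0, 2.5, 3.0, 3.0),
                               q10_n=(3.0, 2.0, 2.4, 2.3))
        ref = generate_reference(SynthSpec(params=truth, noise_sd=0.0,
                                           temperatures=(12.5, 15.0)))
        res = Q10Search(ref, COARSE, params=MembraneParams()).fit()
        assert res.per_interval[1]["q10"] == (3.0, 2.5, 2.0)
        assert res.per_interval[1]["etotal"] == pytest.approx(0.0, abs=1e-20)

    def test_degenerate_single_point_grid(self):
        ref = generate_reference(SynthSpec(noise_sd=0.0, temperatures=(12.5,)))
        one = GridSearchSpec(q10_min=3.0, q10_max=3.0, q10_step=0.1)
        res = Q10Search(ref, one).fit()
        assert res.per_interval[1]["q10"] == (3.0, 3.0, 3.0)

    def test_infeasible_amplitude_band_raises(self):
        ref = generate_reference(SynthSpec(noise_sd=0.0, temperatures=(12.5,)))
        ref.frame["amplitude"] *= 3.0  # no candidate can match this
        with pytest.raises(RuntimeError, match="feasible"):
            Q10Search(ref, COARSE).fit()


class TestConductanceRecovery:
    def test_recovery_within_one_grid_step(self):
        params = MembraneParams()
        t = 10.0
        ref = generate_reference(SynthSpec(params=params, noise_sd=0.0,
                                           temperatures=(t,)))
        spec = GridSearchSpec(gk_range=(0.02, 0.5), gna_range=(0.02, 0.5),
                              spontaneous_window_ms=50.0)
        g_k, g_na, err = ConductanceSearch(ref, spec, params=params).fit_at(t)
        gk_true, gna_true = peak_conductances(t, params)
        assert abs(g_k - gk_true) <= spec.conductance_step + 1e-9
        assert abs(g_na - gna_true) <= spec.conductance_step + 1e-9

    def test_all_pairs_failing_raises(self):
        ref = generate_reference(SynthSpec(noise_sd=0.0, temperatures=(10.0,)))
        # only a tiny potassium conductance available: spontaneous activity
        spec = GridSearchSpec(gk_range=(0.0005, 0.001), conductance_step=0.0005,
                              gna_range=(0.3, 0.3005),
                              spontaneous_window_ms=100.0)
        with pytest.raises(RuntimeError, match="fail"):
            ConductanceSearch(ref, spec).fit_at(10.0)


class TestResistivityFit:
    def test_fixed_point(self):
        fit = ResistivityFit({}, length_mm=30.0)
        v = fit._velocity(5.0, 35.4)
        ra = fit.tune_at(5.0, v)
        assert ra == pytest.approx(35.4, rel=1e-6)

    def test_recovers_model_law(self):
        params = MembraneParams()
        fit = ResistivityFit({}, params=params, length_mm=30.0)
        ra_true = 56.84 * np.exp(-0.03 * 5.0)
        target = fit._velocity(5.0, ra_true)
        ra = fit.tune_at(5.0, target)
        assert ra == pytest.approx(ra_true, rel=0.02)

    def test_unreachable_target_raises(self):
        fit = ResistivityFit({}, length_mm=30.0)
        with pytest.raises(RuntimeError, match="unreachable"):
            fit.tune_at(5.0, 500.0)


class TestPropagateErrorBars:
    def test_linear_slope_two(self):
        p = np.linspace(0.0, 10.0, 11)
        r = 2.0 * p          # measurement per unit parameter
        lo, mean, hi = propagate_error_bars((4.0, 10.0, 16.0), p, r)
        assert (lo, mean, hi) == pytest.approx((2.0, 5.0, 8.0))

    def test_out_of_range_measurement_rejected(self):
        p = np.linspace(0.0, 10.0, 11)
        with pytest.raises(ValueError, match="range"):
            propagate_error_bars((10.0, 20.0, 30.0), p, 2.0 * p)

    def test_zero_width_interval(self):
        p = np.linspace(0.0, 10.0, 11)
        lo, mean, hi = propagate_error_bars((8.0, 8.0, 8.0), p, 2.0 * p)
        assert lo == mean == hi == pytest.approx(4.0)

    def test_decreasing_response(self):
        p = np.linspace(0.0, 10.0, 11)
        r = 100.0 - 3.0 * p
        lo, mean, hi = propagate_error_bars((70.0, 85.0, 100.0), p, r)
        assert (lo, mean, hi) == pytest.approx((0.0, 5.0, 10.0))

    def test_non_monotone_rejected(self):
        p = np.linspace(0.0, 10.0, 11)
        r = (p - 5.0) ** 2
        with pytest.raises(ValueError, match="monotone"):
            propagate_error_bars((1.0, 2.0, 3.0), p, r)

    def test_coverage_of_true_parameter(self):
        # 1-sigma bars on a noisy linear response cover the truth at about
        # the nominal 68% rate; assert a conservative floor
        rng = np.random.default_rng(42)
        p = np.linspace(0.0, 10.0, 101)
        slope, truth = 2.0, 4.0
        hits = 0
        n_rep = 400
        for _ in range(n_rep):
            sigma = 0.8
            measured = slope * truth + sigma * rng.standard_normal()
            lo, _, hi = propagate_error_bars(
                (measured - sigma, measured, measured + sigma), p, slope * p)
            hits += lo <= truth <= hi
        assert hits / n_rep >= 0.60


class TestDeterminism:
    def test_search_is_deterministic(self):
        ref = generate_reference(SynthSpec(noise_sd=0.0, temperatures=(12.5,)))
        r1 = Q10Search(ref, COARSE).fit().per_interval[1]
        r2 = Q10Search(ref, COARSE).fit().per_interval[1]
        assert r1 == r2

    def test_measure_rates_monotone_in_temperature(self):
        params = MembraneParams()
        rises = [measure_rates(t, params)["rise"] for t in (5.0, 10.0, 15.0, 20.0)]
        falls = [measure_rates(t, params)["fall"] for t in (5.0, 10.0, 15.0, 20.0)]
        assert np.all(np.diff(rises) > 0)
        assert np.all(np.diff(falls) > 0)
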