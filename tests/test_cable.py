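"""Cable discretization and solver: axial resistances, temperature fields,
passive-cable oracle, stability and charge bookkeeping."""

import numpy as np
import pytest

from thermoblock.cable import (AxonGeometry, AxonModel, StimulusProtocol,
                               TemperatureField, axial_resistivity,
                               build_axial_resistances, default_dx,
                               run_simulation, segment_current, smooth_profile)
from thermoblock.membrane import MembraneParams


class TestAxialResistivity:
    def test_modified_law(self):
        assert axial_resistivity(0.0) == pytest.approx(56.84)
        assert axial_resistivity(25.0) == pytest.approx(56.84 * np.exp(-0.75),
                                                        rel=1e-12)
        assert axial_resistivity(25.0) == pytest.approx(26.85, rel=1e-3)

    def test_monotone_decreasing(self):
        t = np.linspace(5, 40, 50)
        ra = axial_resistivity(t)
        assert np.all(np.diff(ra) < 0)

    def test_original_fixed(self):
        for t in (0.0, 6.3, 40.0):
            assert axial_resistivity(t, "original_HH") == 35.4


class TestAxialResistances:
    def test_uniform_reference_value(self):
        # d=500 um, Ra=35.4 ohm cm, segment 0.1 mm -> ~180.3 ohm
        ra = build_axial_resistances([0.1, 0.1], [35.4, 35.4], 500.0)
        expected_ohm = 35.4 * 0.01 / (np.pi * 0.025 ** 2)
        assert ra.ra_mohm[0] == pytest.approx(expected_ohm / 1e6, rel=1e-12)
        assert ra.ra_mohm[0] == pytest.approx(1.803e-4, rel=1e-3)

    def test_length_proportionality(self):
        full = build_axial_resistances([0.2, 0.2], [35.4, 35.4], 500.0)
        half = build_axial_resistances([0.1, 0.1], [35.4, 35.4], 500.0)
        assert half.ra_mohm[0] == pytest.approx(full.ra_mohm[0] / 2.0)

    def test_diameter_scaling(self):
        d1 = build_axial_resistances([0.1, 0.1], [35.4, 35.4], 250.0)
        d2 = build_axial_resistances([0.1, 0.1], [35.4, 35.4], 500.0)
        assert d1.ra_mohm[0] == pytest.approx(4.0 * d2.ra_mohm[0])

    def test_mixed_temperature_series(self):
        ra = build_axial_resistances([0.1, 0.1], [40.0, 20.0], 500.0)
        area = np.pi * 0.025 ** 2
        expected = (40.0 * 0.005 + 20.0 * 0.005) / area / 1e6
        assert ra.ra_mohm[0] == pytest.approx(expected, rel=1e-12)

    def test_zero_diameter_rejected(self):
        with pytest.raises(ValueError):
            build_axial_resistances([0.1, 0.1], [35.4, 35.4], 0.0)


class TestSmoothProfile:
    def test_midpoint_and_ends(self):
        assert smooth_profile(50.0, 40.0, 60.0, 6.3, 25.0) == pytest.approx(15.65)
        assert smooth_profile(30.0, 40.0, 60.0, 6.3, 25.0) == 6.3
        assert smooth_profile(70.0, 40.0, 60.0, 6.3, 25.0) == 25.0

    def test_quadratic_branch(self):
        t = smooth_profile(45.0, 40.0, 60.0, 0.0, 8.0)
        assert t == pytest.approx(8.0 * 2 * 0.25 ** 2, rel=1e-12)

    def test_monotone_and_continuous(self):
        x = np.linspace(39, 61, 400)
        t = smooth_profile(x, 40.0, 60.0, 6.3, 25.0)
        assert np.all(np.diff(t) >= -1e-12)
        assert np.max(np.abs(np.diff(t))) < 0.5

    def test_bad_interval_rejected(self):
        with pytest.raises(ValueError):
            smooth_profile(1.0, 5.0, 5.0, 0.0, 1.0)


class TestSegmentCurrent:
    def test_isopotential_zero(self):
        assert segment_current(-65.0, -65.0, -65.0, 1.0, 1.0) == 0.0

    def test_unit_example(self):
        assert segment_current(-64.0, -65.0, -65.0, 1.0, 1.0) == pytest.approx(1.0)

    def test_sealed_end(self):
        assert segment_current(None, -65.0, -65.0, None, 1.0) == 0.0

    def test_antisymmetry_sums_to_zero(self):
        rng = np.random.default_rng(7)
        v = rng.uniform(-80, 20, 12)
        ra = rng.uniform(0.5, 2.0, 11)
        total = 0.0
        for j in range(12):
            total += segment_current(
                v[j - 1] if j > 0 else None, v[j],
                v[j + 1] if j < 11 else None,
                ra[j - 1] if j > 0 else None,
                ra[j] if j < 11 else None)
        assert total == pytest.approx(0.0, abs=1e-9)


class TestGeometryAndFields:
    def test_geometry_validation(self):
        with pytest.raises(ValueError):
            AxonGeometry(length_mm=-1.0)
        with pytest.raises(ValueError):
            AxonGeometry(boundaries_mm=(120.0,))

    def test_three_section_field(self):
        f = TemperatureField.three_section(6.3, 40.0, 8.0, 4.0)
        x = np.array([7.9, 8.0, 11.9, 12.0])
        np.testing.assert_allclose(f.at(x), [6.3, 40.0, 40.0, 6.3])

    def test_temperature_validity_enforced(self):
        with pytest.raises(ValueError, match="validity"):
            AxonModel.uniform(45.0, variant="modified_HH", length_mm=10.0,
                              dx_mm=0.5)

    def test_extrapolation_warns(self):
        with pytest.warns(UserWarning, match="extrapolate"):
            AxonModel.uniform(30.0, variant="modified_HH", length_mm=10.0,
                              dx_mm=0.5)


class TestSolver:
    def test_resting_stability(self, fixtures):
        res = fixtures["uniform_6p3"].simulate(stim=None, dt=0.02, t_end=200.0,
                                               probes=[10.0])
        v = res.probe(10.0)
        assert np.max(np.abs(v - v[0])) < 0.5

    def test_ap_propagates_to_far_end(self, fixtures):
        axon = fixtures["uniform_6p3"]
        stim = StimulusProtocol(segment=0, amplitude_na=2000.0, width_ms=1.0,
                                onset_ms=2.0)
        res = axon.simulate(stim=stim, dt=0.01, t_end=8.0, probes=[19.5])
        assert res.probe(19.5).max() > 0.0

    def test_dt_convergence(self, fixtures):
        axon = fixtures["uniform_6p3"]
        stim = StimulusProtocol(segment=0, amplitude_na=2000.0, width_ms=1.0,
                                onset_ms=2.0)
        v = {}
        for dt in (0.01, 0.005):
            res = axon.simulate(stim=stim, dt=dt, t_end=8.0, probes=[10.0])
            v[dt] = res.probe(10.0)
        coarse = v[0.01]
        fine = v[0.005][::2]
        # implicit first-order scheme: timing shift dominates; sup-norm of
        # the difference must shrink well below AP scale
        assert np.max(np.abs(coarse - fine)) < 3.0

    def test_passive_cable_length_constant_oracle(self):
        # leak-only membrane must match V(x) = V0 exp(-x/lambda) with
        # lambda = sqrt(r / (2 Ra gL)) ~ 10.85 mm at 500 um / 35.4 ohm cm
        axon = AxonModel.uniform(6.3, variant="original_HH", diameter_um=500.0,
                                 length_mm=100.0, dx_mm=0.25)
        passive = axon.with_conductance_scale(np.ones(axon.n_seg, bool),
                                              gk_scale=0.0, gna_scale=0.0)
        mid = passive.segment_at(50.0)
        stim = StimulusProtocol(segment=mid, amplitude_na=-50.0, onset_ms=1.0,
                                width_ms=1.0, steady=True)
        res = passive.simulate(stim=stim, dt=0.05, t_end=80.0,
                               save_v_stride=200)
        dv = res.v_field[-1] - res.v_field[0]
        lam = np.sqrt(0.025 / (2 * 35.4 * 0.3e-3)) * 10.0  # mm
        x = res.x_mm - res.x_mm[mid]
        sel = (x > 0.5) & (x < 1.5 * lam)
        ratio = dv[sel] / dv[mid]
        np.testing.assert_allclose(ratio, np.exp(-x[sel] / lam), rtol=0.01)

    def test_charge_bookkeeping(self, fixtures):
        axon = fixtures["uniform_6p3"]
        stim = StimulusProtocol(segment=0, amplitude_na=2000.0, width_ms=1.0,
                                onset_ms=2.0)
        res = axon.simulate(stim=stim, dt=0.01, t_end=20.0)
        # sealed ends: injected charge = capacitive + ionic charge exactly
        # (background pump/leak at rest integrates to ~0 net)
        assert res.membrane_charge_nc == pytest.approx(res.injected_charge_nc,
                                                       rel=1e-3)

    def test_injected_series_grid_mismatch_rejected(self, fixtures):
        axon = fixtures["uniform_6p3"]
        with pytest.raises(ValueError, match="grid mismatch"):
            axon.simulate(stim=None, dt=0.01, t_end=1.0,
                          injected_currents={0: np.zeros(7)})

    def test_bad_dt_rejected(self, fixtures):
        with pytest.raises(ValueError):
            run_simulation(fixtures["uniform_6p3"], None, dt=0.0, t_end=1.0)

    def test_mixed_temperature_rest_profile(self, fixtures):
        axon = fixtures["two_section_step"]
        v_rest, _ = axon.resting_profile()
        cold = axon.region_mask(0.0, 10.0)
        assert len(np.unique(np.round(v_rest[cold], 6))) == 1
        assert v_rest[~cold].mean() != pytest.approx(v_rest[cold].mean(),
                                                     abs=0.1)
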