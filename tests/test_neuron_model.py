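"""Cable integration: passive oracles, distribution audit, AP structure."""

import math

import numpy as np
import pytest

from navdissect import ap_features as apf
from navdissect.neuron_model import (
    Morphology,
    NeuronModel,
    Phase,
    Section,
    build_model,
    load_default_config,
)


def _passive_cfg(n_segments=1, length=20.0, diameter=20.0, leak=0.1, eleak=-70.0):
    return {
        "morphology": {"axial_resistivity": 150.0, "sections": [
            {"name": "soma", "length_um": length, "diameter_um": diameter,
             "n_segments": n_segments, "cm_uf_cm2": 1.0}]},
        "channels": {"reversal_mv": {"na": 60, "k": -90, "leak": eleak},
                     "densities_ms_cm2": {"soma": {"leak": leak}}},
        "distribution": {},
        "drug": {},
    }


class TestPassiveOracles:
    def test_membrane_time_constant(self):
        """Current step into a passive compartment relaxes with tau=RmCm."""
        m = NeuronModel(_passive_cfg())
        m.init_state(-70.0)
        res = m.run_phases([Phase(100.0, 0.005, i_const_na=0.1,
                                  record_dt_ms=0.05)], reset=False)
        area = math.pi * 20 * 20 * 1e-8
        g = 0.1 * area * 1e3  # µS
        tau = (1.0 * area * 1e3) / g  # ms
        vinf = -70 + 0.1 / g
        pred = -70 + (vinf + 70) * (1 - np.exp(-res.t_ms / tau))
        assert np.max(np.abs(res.v_mv["soma"] - pred)) < 0.05

    def test_two_compartment_cable_steady_state(self):
        """Steady voltage profile matches the analytic 2x2 cable solution."""
        m = NeuronModel(_passive_cfg(n_segments=2, length=100.0, diameter=2.0))
        m.init_state(-70.0)
        res = m.run_phases([Phase(500.0, 0.02, i_const_na=0.05,
                                  record_dt_ms=0.5)], reset=False)
        gseg = 0.1e-3 * (math.pi * 2 * 50 * 1e-8) * 1e6  # µS
        ga = m.ga_us[0]
        G = np.array([[gseg + ga, -ga], [-ga, gseg + ga]])
        b = np.array([gseg * -70.0, gseg * -70.0])
        b[m.soma_idx] += 0.05
        vss = np.linalg.solve(G, b)
        assert res.v_mv["soma"][-1] == pytest.approx(vss[m.soma_idx], abs=1e-6)

    def test_p4_leak_subtraction_cancels_passive_response(self):
        m = NeuronModel(_passive_cfg(eleak=-80.0))
        t, i = m.voltage_clamp([(20.0, -80.0), (20.0, -20.0)], dt=0.01,
                               leak_subtraction="P4")
        # linear system: residual after P/4 is numerically zero
        assert np.max(np.abs(i[t > 20.2])) < 1e-9

    def test_unsupported_leak_mode_rejected(self):
        m = NeuronModel(_passive_cfg())
        with pytest.raises(ValueError):
            m.voltage_clamp([(10.0, -80.0)], leak_subtraction="P2")


class TestDistribution:
    def test_default_config_passes_audit(self, model):
        audit = model.audit_distribution()
        assert audit["all"], audit

    def test_zero_nav16_scale_removes_conductance(self, model):
        model.set_scales(nav16=0.0)
        assert np.all(model.gch_us()[1] == 0.0)

    def test_crossover_dominance_at_33_75(self, model):
        model.set_crossover(33.75)
        d = model.density_ms_cm2
        ais = model.seg_section == "AIS"
        x = model.seg_x_um
        prox = ais & (x < 33.75)
        assert np.all(d[0, prox] > d[1, prox])

    def test_crossover_outside_ais_rejected(self, model):
        with pytest.raises(ValueError):
            model.set_crossover(60.0)

    def test_short_ais_rejected(self):
        with pytest.raises(ValueError):
            Morphology(sections=[
                Section("soma", 20.0, 20.0, 1),
                Section("AIS", 30.0, 1.5, 5),
            ])

    def test_unknown_config_block_rejected(self):
        cfg = load_default_config()
        cfg["extra_block"] = {}
        with pytest.raises(ValueError):
            NeuronModel(cfg)


class TestActionPotential:
    def test_baseline_ap_calibration_bands(self, model, tuned_amp):
        """First evoked AP: threshold and somatic peak dV/dt in the
        empirical calibration bands; 5-6 spikes per 300 ms."""
        model.find_bias_current(-80.0)
        res = model.integrate(tuned_amp, 300.0)
        tr = res.trace("soma")
        f = apf.extract_features(tr)[0]
        train = apf.train_features(tr, (20.0, 320.0))
        assert -47.0 <= f.threshold <= -40.0
        assert f.somatic_peak_dvdt == pytest.approx(556.0, rel=0.15)
        assert 4 <= train["spike_count"] <= 6

    def test_phase_plane_has_two_rising_components(self, model, tuned_amp):
        model.find_bias_current(-80.0)
        res = model.integrate(tuned_amp, 300.0)
        f = apf.extract_features(res.trace("soma"))[0]
        assert not np.isnan(f.ais_inflection_dvdt)
        assert not np.isnan(f.ais_max_dvdt)
        assert f.ais_inflection_dvdt < f.ais_max_dvdt < f.somatic_peak_dvdt

    def test_ap_initiates_in_distal_ais(self, model, tuned_amp):
        """The distal AIS crosses threshold before the soma."""
        model.find_bias_current(-80.0)
        res = model.integrate(tuned_amp, 300.0,
                              record_sites=("soma", "ais_distal"))
        f_soma = apf.extract_features(res.trace("soma"))[0]
        f_ais = apf.extract_features(res.trace("ais_distal"))[0]
        assert f_ais.threshold_time < f_soma.threshold_time

    def test_dt_refinement_changes_peak_dvdt_under_one_percent(self, model, tuned_amp):
        model.find_bias_current(-80.0)
        peaks = []
        for dt in (0.01, 0.005):
            res = model.integrate(tuned_amp, 50.0, dt=dt, record_dt_ms=0.02)
            peaks.append(apf.extract_features(res.trace("soma"))[0].somatic_peak_dvdt)
        assert abs(peaks[1] - peaks[0]) / peaks[1] < 0.01

    def test_ais_segment_refinement_stable_threshold(self, tuned_amp):
        """Doubling AIS segment count moves threshold by < 0.2 mV."""
        thresholds = []
        for nseg in (20, 40):
            cfg = load_default_config()
            for s in cfg["morphology"]["sections"]:
                if s["name"] == "AIS":
                    s["n_segments"] = nseg
            m = NeuronModel(cfg)
            m.find_bias_current(-80.0)
            res = m.integrate(tuned_amp, 50.0)
            thresholds.append(apf.extract_features(res.trace("soma"))[0].threshold)
        assert abs(thresholds[1] - thresholds[0]) < 0.2

    def test_coarse_dt_rejected_for_ap_runs(self, model):
        with pytest.raises(ValueError):
            model.integrate(0.4, 10.0, dt=0.05)


class TestVoltageClamp:
    def test_depolarizing_step_evokes_transient_inward_current(self, model):
        """-80 to -12 mV: transient inward Na current that decays by
        inactivation to near zero within 20 ms."""
        t, i = model.voltage_clamp([(20.0, -80.0), (20.0, -12.0)],
                                   dt=0.01, record_dt_ms=0.01, v_init=-80.0)
        step = (t > 20.05) & (t <= 40.0)
        # steady outward plateau (K + leak of the unclamped arbors); the Na
        # transient is the inward excursion below it that inactivates away
        plateau = i[(t > 38.0) & (t <= 40.0)].mean()
        peak = i[step].min()
        assert peak < plateau - 2.0  # substantial transient inward Na (nA)
        late = i[(t > 36.0) & (t <= 40.0)]
        assert np.abs(late - plateau).max() < 0.05 * (plateau - peak)

    def test_recovery_after_long_hold_without_drug(self, model):
        """After a 10 s hold at -12 mV with no drug, a test pulse within
        5 s recovers most of the baseline current."""
        t0, i0 = model.voltage_clamp([(2000.0, -80.0), (20.0, -12.0)],
                                     dt=0.01, record_dt_ms=0.01, v_init=-80.0)
        base = i0[t0 > 2000.05].min()
        t1, i1 = model.voltage_clamp(
            [(10_000.0, -12.0), (4000.0, -80.0), (20.0, -12.0)],
            dt=0.02, record_dt_ms=0.02, v_init=-80.0)
        rec = i1[t1 > 14_000.1].min()
        assert rec < 0.8 * base < 0  # >= 80% of baseline inward current

    def test_command_outside_range_rejected(self, model):
        with pytest.raises(ValueError):
            model.voltage_clamp([(10.0, 50.0)])


class TestNumericalSafety:
    def test_divergence_raises_with_diagnostic(self):
        cfg = _passive_cfg()
        m = NeuronModel(cfg)
        m.init_state(-70.0)
        m.state["v"][0] = np.nan
        with pytest.raises(FloatingPointError):
            m.run_phases([Phase(1.0, 0.01)], reset=False)
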