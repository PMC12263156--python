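"""Steady-state gating, HH relaxation, and Table round-trips through clamp."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from navdissect.channel_kinetics import (
    TABLE_BOLTZMANN,
    BoltzmannParams,
    GatingState,
    Genotype,
    Isoform,
    boltzmann_activation,
    boltzmann_inactivation,
    conductance_from_current,
    gating_derivatives,
    invert_m_gate,
    make_nav_spec,
    steady_state,
)
from navdissect.curve_fitting import fit_boltzmann
from navdissect.neuron_model import NeuronModel


def _cell_line_model(iso_key: str, genotype: str = "YW") -> NeuronModel:
    """Single-compartment heterologous-expression cell with one isoform."""
    return NeuronModel({
        "morphology": {"axial_resistivity": 150.0, "sections": [
            {"name": "soma", "length_um": 20.0, "diameter_um": 20.0,
             "n_segments": 1, "cm_uf_cm2": 1.0}]},
        "channels": {"gating_context": "cell_line",
                     "reversal_mv": {"na": 60, "k": -90, "leak": -80},
                     "densities_ms_cm2": {"soma": {iso_key: 20.0}}},
        "distribution": {},
        "drug": {"genotype": {"nav12": genotype, "nav16": genotype}},
    })


class TestBoltzmann:
    def test_half_maximal_at_v_half(self):
        p = BoltzmannParams(-20.1, 6.6)
        assert boltzmann_activation(-20.1, p) == pytest.approx(0.5)
        assert boltzmann_inactivation(-20.1, p) == pytest.approx(0.5)

    def test_saturation_limits(self):
        p = BoltzmannParams(-20.1, 6.6)
        assert boltzmann_activation(200.0, p) == pytest.approx(1.0, abs=1e-9)
        assert boltzmann_activation(-300.0, p) == pytest.approx(0.0, abs=1e-9)
        assert boltzmann_inactivation(-300.0, p) == pytest.approx(1.0, abs=1e-9)

    def test_tabulated_row_evaluations(self):
        # one e-fold above/below the half-voltage: 1/(1+e^∓1)
        act = TABLE_BOLTZMANN[(Isoform.NAV12, Genotype.YW)]["activation"]
        assert boltzmann_activation(-13.5, act) == pytest.approx(0.7310585786, abs=1e-6)
        inact = TABLE_BOLTZMANN[(Isoform.NAV12, Genotype.YW)]["inactivation"]
        assert boltzmann_inactivation(-61.4, inact) == pytest.approx(0.2689414213, abs=1e-6)

    def test_monotonicity(self):
        p = BoltzmannParams(-25.0, 7.0)
        v = np.linspace(-100, 40, 200)
        assert np.all(np.diff(boltzmann_activation(v, p)) > 0)
        assert np.all(np.diff(boltzmann_inactivation(v, p)) < 0)

    def test_nonfinite_voltage_rejected(self):
        p = BoltzmannParams(-20.0, 6.0)
        with pytest.raises(ValueError):
            boltzmann_activation(float("nan"), p)
        with pytest.raises(ValueError):
            boltzmann_inactivation(float("inf"), p)

    def test_invalid_slope_rejected(self):
        with pytest.raises(ValueError):
            BoltzmannParams(-20.0, 0.0)


class TestConductance:
    def test_zero_current(self):
        assert conductance_from_current(0.0, -12.0, 60.0) == 0.0

    def test_inward_current_positive_conductance_and_linearity(self):
        g1 = conductance_from_current(-1.0, -12.0, 60.0)
        assert g1 == pytest.approx(1.0 / 72.0)
        assert conductance_from_current(-2.0, -12.0, 60.0) == pytest.approx(2 * g1)

    def test_reversal_degenerate(self):
        with pytest.raises(ZeroDivisionError):
            conductance_from_current(-1.0, 60.0, 60.0)


class TestGatingDynamics:
    def test_fixed_point_has_zero_derivatives(self):
        spec = make_nav_spec(Isoform.NAV16, Genotype.YW)
        st_eq = steady_state(spec, -50.0)
        dm, dh = gating_derivatives(st_eq, -50.0, spec)
        assert abs(dm) < 1e-12 and abs(dh) < 1e-12

    def test_exponential_relaxation_matches_closed_form(self):
        """Euler integration at fixed v converges on the analytic relaxation."""
        spec = make_nav_spec(Isoform.NAV12, Genotype.YW)
        v = -30.0
        m, h = 0.0, 1.0
        dt = 1e-3
        t_end = 20.0
        n = int(t_end / dt)
        for _ in range(n):
            dm, dh = gating_derivatives(GatingState(m, h), v, spec)
            m += dt * dm
            h += dt * dh
        tau_m = float(spec.tau_activation(v))
        tau_h = float(spec.tau_inactivation(v))
        m_exp = float(spec.m_inf(v)) * (1 - math.exp(-t_end / tau_m))
        h_inf = float(spec.h_inf(v))
        h_exp = h_inf + (1 - h_inf) * math.exp(-t_end / tau_h)
        assert m == pytest.approx(m_exp, rel=1e-2)
        assert h == pytest.approx(h_exp, rel=1e-2)

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(st.lists(st.floats(min_value=-120, max_value=40), min_size=1, max_size=8),
           st.floats(min_value=0.01, max_value=5.0))
    def test_gates_stay_in_unit_interval(self, commands, dt):
        """Exponential (Rush-Larsen) updates keep gates in [0,1] for any
        piecewise-constant voltage command."""
        spec = make_nav_spec(Isoform.NAV16, Genotype.YW)
        m, h = 0.3, 0.7
        for v in commands:
            for _ in range(20):
                m += (float(spec.m_inf(v)) - m) * (1 - math.exp(-dt / float(spec.tau_activation(v))))
                h += (float(spec.h_inf(v)) - h) * (1 - math.exp(-dt / float(spec.tau_inactivation(v))))
                assert 0.0 <= m <= 1.0
                assert 0.0 <= h <= 1.0


class TestGenotypeStructure:
    def test_sr_option_changes_only_nav16_by_two_mv(self):
        """Optional derived-SR curves: NaV1.6 hyperpolarized ~2 mV, NaV1.2
        equal to wildtype; drug sensitivity is what differs (see
        pharmacology)."""
        for iso, shift in [(Isoform.NAV12, 0.0), (Isoform.NAV16, -2.0)]:
            wt = make_nav_spec(iso, Genotype.YW)
            sr = make_nav_spec(iso, Genotype.SR, sr_gating_shift=True)
            assert sr.activation.v_half == pytest.approx(wt.activation.v_half + shift)
            assert sr.inactivation.v_half == pytest.approx(wt.inactivation.v_half + shift)
            assert sr.activation.slope_factor == wt.activation.slope_factor

    def test_neuron_context_preserves_isoform_offsets(self):
        cl12 = make_nav_spec(Isoform.NAV12, Genotype.YW)
        cl16 = make_nav_spec(Isoform.NAV16, Genotype.YW)
        n12 = make_nav_spec(Isoform.NAV12, Genotype.YW, context="neuron")
        n16 = make_nav_spec(Isoform.NAV16, Genotype.YW, context="neuron")
        assert (n16.m_gate.v_half - n12.m_gate.v_half) == pytest.approx(
            cl16.m_gate.v_half - cl12.m_gate.v_half, abs=1e-9)


@pytest.mark.parametrize("iso_key,isoform", [("nav12", Isoform.NAV12),
                                             ("nav16", Isoform.NAV16)])
@pytest.mark.parametrize("genotype", ["YW", "SR"])
class TestClampRoundTrip:
    """Simulated voltage-clamp protocols refit to the tabulated Boltzmann
    parameters (within 1 mV / 0.3 slope units) for every isoform/genotype."""

    def test_activation_protocol(self, iso_key, isoform, genotype):
        m = _cell_line_model(iso_key, genotype)
        grid = np.arange(-100.0, -19.9, 5.0)
        dt = 0.005
        peaks = []
        for vtest in grid:
            t, i = m.voltage_clamp([(20.0, -120.0), (30.0, float(vtest))],
                                   dt=dt, record_dt_ms=dt, v_init=-80.0)
            peaks.append(i[t > 20.0].min())
        g = conductance_from_current(np.array(peaks), grid, 60.0)
        fit = fit_boltzmann(grid, g / g.max(), "activation", free_amplitude=True)
        tab = TABLE_BOLTZMANN[(isoform, Genotype(genotype))]["activation"]
        assert fit.converged
        assert fit.params.v_half == pytest.approx(tab.v_half, abs=1.0)
        assert fit.params.slope_factor == pytest.approx(tab.slope_factor, abs=0.3)

    def test_inactivation_protocol(self, iso_key, isoform, genotype):
        m = _cell_line_model(iso_key, genotype)
        vpre = np.arange(-120.0, 30.1, 5.0)
        dt = 0.005
        peaks = []
        for vp in vpre:
            t, i = m.voltage_clamp([(60.0, float(vp)), (20.0, -12.0)],
                                   dt=dt, record_dt_ms=dt, v_init=float(vp))
            peaks.append(i[t > 60.0 + 3 * dt].min())
        yn = np.array(peaks) / min(peaks)
        fit = fit_boltzmann(vpre, yn, "inactivation")
        tab = TABLE_BOLTZMANN[(isoform, Genotype(genotype))]["inactivation"]
        assert fit.converged
        assert fit.params.v_half == pytest.approx(tab.v_half, abs=1.0)
        assert fit.params.slope_factor == pytest.approx(tab.slope_factor, abs=0.3)


def test_m_gate_inversion_is_consistent():
    """The inverted single-gate curve, cubed and refit on the protocol
    grid, returns the observable parameters."""
    obs = BoltzmannParams(-23.9, 6.7)
    mg = invert_m_gate(obs, 3)
    grid = np.arange(-100.0, -19.9, 5.0)
    y = boltzmann_activation(grid, mg) ** 3
    fit = fit_boltzmann(grid, y / y.max(), "activation", free_amplitude=True)
    assert fit.params.v_half == pytest.approx(obs.v_half, abs=0.05)
    assert fit.params.slope_factor == pytest.approx(obs.slope_factor, abs=0.05)
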