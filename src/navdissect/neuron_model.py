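"""Reduced multi-compartment layer-5 pyramidal-cell model.

Morphology is a chain of cylindrical sections rooted at the soma — distal
dendrite, proximal dendrite (first 20 µm), soma, AIS, myelinated-
equivalent distal axon and a node of Ranvier — which keeps the implicit
cable system tridiagonal while preserving the compartment classes the
isoform distribution rules refer to:

* soma and the first 20 µm of dendrite carry equal NaV1.2 and NaV1.6
  densities;
* dendrites distal to that carry NaV1.2 only;
* within the AIS the two isoforms follow piecewise-linear ramps (NaV1.2
  decreasing, NaV1.6 increasing with distance) that intersect at a
  configurable crossover position (default 15 µm from the soma);
* the distal AIS, distal axon and node carry NaV1.6 only, with the node
  enriched by a configurable multiplier.

Global per-isoform density scales model graded pharmacological block or
expression changes (100 % → 0 % sweeps).  Supporting conductances — a
fast perisomatic/axonal Kv, a slow dendritic Kv, and leak — are required
for repetitive firing and for the dendritic Na/K interplay; their
densities come from the packaged calibration (see ``data/default_model
.yaml``), which targets the empirical baseline AP (threshold near
−42.5 mV, somatic peak dV/dt near 556 V/s, 5–6 spikes per 300 ms step).

Integration is backward Euler on the tridiagonal cable (default dt 10 µs
for AP-resolution runs, 50 µs allowed for minute-long protocols), with
Rush–Larsen gating updates from voltage lookup tables.
"""

from __future__ import annotations

import copy
import importlib.resources
import math
from dataclasses import dataclass, field

import numpy as np
import yaml

from . import _engine
from .channel_kinetics import (
    BoltzmannParams,
    ChannelSpec,
    GaussianTau,
    Genotype,
    Isoform,
    make_nav_spec,
)
from .asc_pharmacology import DrugBindingParams, genotype_table
from .ap_features import VoltageTrace

__all__ = [
    "Section",
    "Morphology",
    "ChannelDistribution",
    "Phase",
    "SimResult",
    "NeuronModel",
    "build_model",
    "load_default_config",
    "KVF_SPEC",
    "KVS_SPEC",
]

SECTION_ORDER = (
    "distal_dendrite",
    "proximal_dendrite",
    "soma",
    "AIS",
    "distal_axon",
    "node",
)

# Supporting conductances.  The fast Kv repolarizes the spike; the slow
# dendritic Kv is recruited by backpropagating APs boosted by dendritic
# NaV1.2 and sets the inter-spike membrane potential (the mechanism by
# which NaV1.2 block paradoxically raises AP output).
# fast Kv: high-threshold, rapidly (de)activating (Kv3-like), so it
# repolarizes spikes without loading the subthreshold membrane
KVF_SPEC = ChannelSpec(
    isoform=Isoform.KV,
    genotype=Genotype.YW,
    activation=BoltzmannParams(-5.0, 7.0),
    inactivation=None,
    activation_exponent=1,
    tau_activation=GaussianTau(base=0.25, amp=1.0, mid=-30.0, width=25.0),
    tau_inactivation=None,
    reversal=-90.0,
)
# slow dendritic Kv: recruited by the large depolarization of a
# backpropagating AP (boosted by dendritic NaV1.2) and deactivating over
# tens of ms, so it carries hyperpolarizing current between spikes
KVS_SPEC = ChannelSpec(
    isoform=Isoform.KV,
    genotype=Genotype.YW,
    activation=BoltzmannParams(-20.0, 6.0),
    inactivation=None,
    activation_exponent=1,
    tau_activation=GaussianTau(base=25.0, amp=0.0, mid=0.0, width=1.0),
    tau_inactivation=None,
    reversal=-90.0,
)


@dataclass(frozen=True)
class Section:
    name: str
    length_um: float
    diameter_um: float
    n_segments: int
    cm_uf_cm2: float = 1.0

    def __post_init__(self) -> None:
        if self.n_segments < 1:
            raise ValueError("n_segments must be >= 1")
        if self.length_um <= 0 or self.diameter_um <= 0:
            raise ValueError("geometry must be positive")


@dataclass
class Morphology:
    sections: list[Section]
    axial_resistivity: float = 150.0  # Ω·cm

    def __post_init__(self) -> None:
        names = [s.name for s in self.sections]
        if names != [n for n in SECTION_ORDER if n in names]:
            raise ValueError(f"sections must follow the chain order {SECTION_ORDER}")
        ais = self.section("AIS")
        if ais is not None and ais.length_um < 40.0:
            raise ValueError("AIS must be at least 40 µm to hold all crossover positions")

    def section(self, name: str) -> Section | None:
        for s in self.sections:
            if s.name == name:
                return s
        return None


@dataclass
class ChannelDistribution:
    """Spatial rules plus global per-isoform scaling.

    ``crossover_um`` is the AIS position where the NaV1.2 and NaV1.6 ramp
    profiles intersect; ``scale_nav12``/``scale_nav16`` scale each
    isoform's density everywhere (1.0 = full expression).
    """

    crossover_um: float = 15.0
    scale_nav12: float = 1.0
    scale_nav16: float = 1.0
    densities_ms_cm2: dict[str, dict[str, float]] = field(default_factory=dict)
    ais_nav_total: float = 2600.0  # summed Na density in the AIS (mS/cm²)
    node_enrichment: float = 3.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.scale_nav12 <= 1.0 and 0.0 <= self.scale_nav16 <= 1.0):
            raise ValueError("density scales must lie in [0, 1]")
        if self.crossover_um <= 0:
            raise ValueError("crossover_um must be positive")

    def ais_profiles(self, x_um: np.ndarray, ais_length: float):
        """Unscaled NaV1.2/NaV1.6 densities along the AIS (mS/cm²).

        Piecewise-linear ramps on a constant total density: NaV1.2 falls
        linearly to zero at twice the crossover position (so it is absent
        from the distal AIS), NaV1.6 rises complementarily; the profiles
        therefore intersect at ``crossover_um`` where each carries half
        the total.
        """
        xc = self.crossover_um
        if not 0.0 < xc < ais_length:
            raise ValueError("crossover_um must lie inside the AIS")
        frac12 = np.clip(1.0 - x_um / (2.0 * xc), 0.0, 1.0)
        g12 = self.ais_nav_total * frac12
        g16 = self.ais_nav_total * (1.0 - frac12)
        return g12, g16


@dataclass
class Phase:
    """One stage of a stimulation protocol.

    ``clamp_mv`` switches the somatic electrode to ideal voltage clamp at
    that command; otherwise the phase runs in current clamp with constant
    ``i_const_na`` (bias plus step) or a per-step waveform ``i_wave_na``.
    """

    duration_ms: float
    dt_ms: float = 0.01
    i_const_na: float = 0.0
    i_wave_na: np.ndarray | None = None
    clamp_mv: float | None = None
    record_dt_ms: float | None = 0.02
    label: str = ""


@dataclass
class SimResult:
    """Recorded traces from one phase sequence."""

    t_ms: np.ndarray
    v_mv: dict[str, np.ndarray]
    i_clamp_na: np.ndarray
    blocked: np.ndarray  # (2, nt) conductance-weighted mean per isoform
    phase_edges_ms: list[tuple[str, float, float]]

    def trace(self, site: str) -> VoltageTrace:
        return VoltageTrace(self.t_ms, self.v_mv[site])


def load_default_config() -> dict:
    text = (
        importlib.resources.files("navdissect") / "data" / "default_model.yaml"
    ).read_text()
    return yaml.safe_load(text)


_CONFIG_KEYS = {"morphology", "channels", "distribution", "drug"}


class NeuronModel:
    """Chain-cable model with per-segment channel densities and drug state."""

    def __init__(self, config: dict):
        unknown = set(config) - _CONFIG_KEYS
        if unknown:
            raise ValueError(f"unknown config blocks: {sorted(unknown)}")
        self.config = copy.deepcopy(config)
        mcfg = config["morphology"]
        self.morphology = Morphology(
            sections=[Section(**s) for s in mcfg["sections"]],
            axial_resistivity=float(mcfg.get("axial_resistivity", 150.0)),
        )
        ccfg = config["channels"]
        dcfg = config.get("distribution", {})
        self.distribution = ChannelDistribution(
            crossover_um=float(dcfg.get("crossover_um", 15.0)),
            scale_nav12=float(dcfg.get("scale_nav12", 1.0)),
            scale_nav16=float(dcfg.get("scale_nav16", 1.0)),
            densities_ms_cm2=ccfg["densities_ms_cm2"],
            ais_nav_total=float(ccfg.get("ais_nav_total_ms_cm2", 2600.0)),
            node_enrichment=float(ccfg.get("node_enrichment", 3.0)),
        )
        self.gating_context = str(ccfg.get("gating_context", "neuron"))
        rev = ccfg.get("reversal_mv", {})
        self.e_na = float(rev.get("na", 60.0))
        self.e_k = float(rev.get("k", -90.0))
        self.e_leak = float(rev.get("leak", -82.0))

        drug = config.get("drug", {})
        self.drug_conc_nm = float(drug.get("conc_nM", 0.0))
        self.genotypes = {
            Isoform.NAV12: Genotype(drug.get("genotype", {}).get("nav12", "YW")),
            Isoform.NAV16: Genotype(drug.get("genotype", {}).get("nav16", "YW")),
        }

        self._build_geometry()
        self._build_densities()
        self._tables: dict[float, tuple[np.ndarray, np.ndarray]] = {}
        self._koff_tab: np.ndarray | None = None
        self._state: dict | None = None
        self.bias_na = 0.0

    # ---------------------------------------------------------------- build
    def _build_geometry(self) -> None:
        seg_sec: list[str] = []
        seg_x: list[float] = []       # position within section (µm, center)
        areas: list[float] = []       # cm²
        cms: list[float] = []         # nF
        half_res: list[float] = []    # MΩ from segment center to its edge
        ra = self.morphology.axial_resistivity
        for sec in self.morphology.sections:
            lseg = sec.length_um / sec.n_segments
            area = math.pi * sec.diameter_um * lseg * 1e-8  # cm²
            across = math.pi * (sec.diameter_um / 2.0) ** 2 * 1e-8  # cm²
            rhalf = ra * (lseg / 2.0 * 1e-4) / across / 1e6  # MΩ
            for k in range(sec.n_segments):
                seg_sec.append(sec.name)
                seg_x.append((k + 0.5) * lseg)
                areas.append(area)
                cms.append(sec.cm_uf_cm2 * area * 1e3)  # µF→nF
                half_res.append(rhalf)
        self.seg_section = np.array(seg_sec)
        self.seg_x_um = np.array(seg_x)
        self.area_cm2 = np.array(areas)
        self.cm_nf = np.array(cms)
        r = np.array(half_res)
        self.ga_us = 1.0 / (r[:-1] + r[1:])
        self.n_seg = len(seg_sec)
        self.soma_idx = int(np.where(self.seg_section == "soma")[0][len(
            np.where(self.seg_section == "soma")[0]) // 2])

    def _base_density(self, section: str, channel: str) -> float:
        return float(self.distribution.densities_ms_cm2.get(section, {}).get(channel, 0.0))

    def _build_densities(self) -> None:
        """Per-segment unscaled densities (mS/cm²) for the 4 channels + leak."""
        n = self.n_seg
        dens = np.zeros((4, n))  # nav12, nav16, kvf, kvs
        leak = np.zeros(n)
        dist = self.distribution
        ais_sec = self.morphology.section("AIS")
        ais_len = ais_sec.length_um if ais_sec is not None else 0.0
        for i in range(n):
            sec = self.seg_section[i]
            x = self.seg_x_um[i]
            leak[i] = self._base_density(sec, "leak")
            dens[2, i] = self._base_density(sec, "kvf")
            dens[3, i] = self._base_density(sec, "kvs")
            if sec == "AIS":
                g12, g16 = dist.ais_profiles(np.array([x]), ais_len)
                dens[0, i] = g12[0]
                dens[1, i] = g16[0]
            elif sec in ("soma", "proximal_dendrite"):
                # equal NaV1.2/NaV1.6 split of the total "nav" density;
                # explicit per-isoform keys allow single-isoform cells
                # (heterologous-expression emulation)
                d = self._base_density(sec, "nav")
                dens[0, i] = d / 2.0 + self._base_density(sec, "nav12")
                dens[1, i] = d / 2.0 + self._base_density(sec, "nav16")
            elif sec == "distal_dendrite":
                dens[0, i] = self._base_density(sec, "nav")
            elif sec == "distal_axon":
                dens[1, i] = self._base_density(sec, "nav")
            elif sec == "node":
                dens[1, i] = self._base_density("distal_axon", "nav") * dist.node_enrichment
        self.density_ms_cm2 = dens
        self.gleak_us = leak * self.area_cm2 * 1e3
        self._gch_base_us = dens * self.area_cm2[None, :] * 1e3

    # ------------------------------------------------------------ channels
    def nav_specs(self) -> dict[Isoform, ChannelSpec]:
        return {
            iso: make_nav_spec(iso, self.genotypes[iso], context=self.gating_context)
            for iso in (Isoform.NAV12, Isoform.NAV16)
        }

    def gch_us(self) -> np.ndarray:
        g = self._gch_base_us.copy()
        g[0] *= self.distribution.scale_nav12
        g[1] *= self.distribution.scale_nav16
        return g

    def set_scales(self, nav12: float | None = None, nav16: float | None = None) -> None:
        if nav12 is not None:
            self.distribution.scale_nav12 = float(nav12)
        if nav16 is not None:
            self.distribution.scale_nav16 = float(nav16)
        self.distribution.__post_init__()

    def set_drug(self, conc_nm: float, genotype_nav12=None, genotype_nav16=None) -> None:
        self.drug_conc_nm = float(conc_nm)
        if genotype_nav12 is not None:
            self.genotypes[Isoform.NAV12] = Genotype(genotype_nav12)
        if genotype_nav16 is not None:
            self.genotypes[Isoform.NAV16] = Genotype(genotype_nav16)
        self._tables.clear()  # gating tables depend on the genotype rows

    def set_crossover(self, crossover_um: float) -> None:
        self.distribution.crossover_um = float(crossover_um)
        self._build_densities()

    # -------------------------------------------------------------- tables
    def _gate_specs(self):
        specs = self.nav_specs()
        return (
            specs[Isoform.NAV12],
            specs[Isoform.NAV12],
            specs[Isoform.NAV16],
            specs[Isoform.NAV16],
            KVF_SPEC,
            KVS_SPEC,
        )

    def _tables_for_dt(self, dt: float):
        key = round(dt, 9)
        if key not in self._tables:
            vg = _engine.voltage_grid()
            inf = np.empty((_engine.N_GATES, vg.size))
            ex = np.empty_like(inf)
            for g, spec in enumerate(self._gate_specs()):
                if g in (1, 3):  # inactivation gates
                    inf[g] = spec.h_inf(vg)
                    tau = np.asarray(spec.tau_inactivation(vg), dtype=float)
                else:
                    inf[g] = spec.m_inf(vg)
                    tau = np.asarray(spec.tau_activation(vg), dtype=float)
                ex[g] = 1.0 - np.exp(-dt / tau)
            self._tables[key] = (inf, ex)
        return self._tables[key]

    def _drug_rates(self):
        """(koff table 1/ms, kon per isoform 1/ms at the current dose)."""
        if self._koff_tab is None:
            bp = DrugBindingParams(dose_response=genotype_table(Isoform.NAV12, Genotype.YW))
            vg = _engine.voltage_grid()
            self._koff_tab = np.array([bp.k_off(v) for v in vg]) * 1e-3
        kon = np.zeros(2)
        if self.drug_conc_nm > 0:
            for j, iso in enumerate((Isoform.NAV12, Isoform.NAV16)):
                bp = DrugBindingParams(
                    dose_response=genotype_table(iso, self.genotypes[iso])
                )
                kon[j] = bp.k_on * self.drug_conc_nm * 1e-3  # 1/s → 1/ms
        return self._koff_tab, kon

    # --------------------------------------------------------------- state
    def init_state(self, v0: float = -80.0, reset_block: bool = True) -> None:
        v = np.full(self.n_seg, float(v0))
        gates = np.empty((_engine.N_GATES, self.n_seg))
        for g, spec in enumerate(self._gate_specs()):
            val = spec.h_inf(v0) if g in (1, 3) else float(spec.m_inf(v0))
            gates[g] = float(val)
        b = self._state["b"].copy() if (self._state and not reset_block) else np.zeros((2, self.n_seg))
        self._state = {"v": v, "gates": gates, "b": b}

    @property
    def state(self) -> dict:
        if self._state is None:
            self.init_state()
        return self._state

    def record_index(self, site: str) -> int:
        """Segment index for a named site.

        Sites: soma, ais_mid, ais_distal, ais_proximal, dend, axon, node.
        """
        sec = {
            "soma": "soma", "dend": "distal_dendrite", "axon": "distal_axon",
            "node": "node",
        }
        if site in sec:
            idx = np.where(self.seg_section == sec[site])[0]
            return int(idx[idx.size // 2])
        if site.startswith("ais"):
            idx = np.where(self.seg_section == "AIS")[0]
            if site == "ais_proximal":
                return int(idx[0])
            if site == "ais_distal":
                return int(idx[-2]) if idx.size > 1 else int(idx[-1])
            return int(idx[idx.size // 2])
        raise KeyError(f"unknown record site: {site}")

    # ----------------------------------------------------------------- run
    def run_phases(
        self,
        phases: list[Phase],
        record_sites: tuple[str, ...] = ("soma",),
        reset: bool = True,
        v_init: float = -80.0,
    ) -> SimResult:
        """Integrate a sequence of phases, carrying all state across.

        ``reset`` reinitializes voltage/gating (and block) to the
        steady state at ``v_init`` before the first phase.
        """
        if reset:
            self.init_state(v_init)
        st = self.state
        rec_idx = np.array([self.record_index(s) for s in record_sites], dtype=np.int64)
        koff, kon = self._drug_rates()
        gch = self.gch_us()
        mpow = np.array([3, 3, 1, 1], dtype=np.int64)
        erev = np.array([self.e_na, self.e_na, KVF_SPEC.reversal, KVS_SPEC.reversal])

        all_t, all_v, all_ic, all_bk = [], [], [], []
        edges = []
        t0 = 0.0
        for ph in phases:
            nsteps = int(round(ph.duration_ms / ph.dt_ms))
            if nsteps <= 0:
                raise ValueError("phase duration shorter than dt")
            inf, ex = self._tables_for_dt(ph.dt_ms)
            if ph.i_wave_na is not None:
                wave = np.ascontiguousarray(ph.i_wave_na, dtype=float)
                if wave.size != nsteps:
                    raise ValueError("stimulus waveform length must equal nsteps")
                stim_mode, istim = 2, wave + ph.i_const_na
            elif ph.i_const_na != 0.0:
                stim_mode, istim = 1, np.array([ph.i_const_na])
            else:
                stim_mode, istim = 0, np.zeros(1)
            if ph.clamp_mv is not None:
                clamp_mode, vcl = 1, np.array([float(ph.clamp_mv)])
            else:
                clamp_mode, vcl = 0, np.zeros(1)
            if ph.record_dt_ms is None:
                record_every = nsteps  # record only the final sample
            else:
                record_every = max(int(round(ph.record_dt_ms / ph.dt_ms)), 1)
            nout = nsteps // record_every
            out_v = np.empty((rec_idx.size, nout))
            out_ic = np.zeros(nout)
            out_bk = np.zeros((2, nout))
            _engine.run_chain(
                st["v"], st["gates"], st["b"], gch, mpow, erev,
                self.gleak_us, self.e_leak, self.ga_us, self.cm_nf,
                inf, ex, koff, kon,
                ph.dt_ms, nsteps,
                stim_mode, self.soma_idx, istim,
                clamp_mode, self.soma_idx, vcl,
                record_every, rec_idx, out_v, out_ic, out_bk,
                1,  # Crank-Nicolson for free-running phases (engine falls
                    # back to backward Euler whenever the soma is clamped)
            )
            if not np.all(np.isfinite(st["v"])):
                raise FloatingPointError(
                    f"numerical divergence in phase {ph.label!r} "
                    f"(dt={ph.dt_ms} ms): non-finite voltage"
                )
            tt = t0 + (np.arange(1, nout + 1) * record_every) * ph.dt_ms
            all_t.append(tt)
            all_v.append(out_v)
            all_ic.append(out_ic)
            all_bk.append(out_bk)
            edges.append((ph.label, t0, t0 + ph.duration_ms))
            t0 += ph.duration_ms

        t = np.concatenate(all_t)
        vmat = np.concatenate(all_v, axis=1)
        return SimResult(
            t_ms=t,
            v_mv={s: vmat[i] for i, s in enumerate(record_sites)},
            i_clamp_na=np.concatenate(all_ic),
            blocked=np.concatenate(all_bk, axis=1),
            phase_edges_ms=edges,
        )

    # ------------------------------------------------------------- helpers
    def find_bias_current(self, v_hold: float = -80.0, settle_ms: float = 500.0,
                          dt: float = 0.025) -> float:
        """Constant somatic current that holds the resting Vm at ``v_hold``.

        Measured as the steady electrode current of a somatic voltage
        clamp at ``v_hold`` (the current-clamp analogue of the bias
        current used experimentally).
        """
        self.init_state(v_hold)
        res = self.run_phases(
            [Phase(duration_ms=settle_ms, dt_ms=dt, clamp_mv=v_hold,
                   record_dt_ms=dt, label="bias")],
            record_sites=("soma",), reset=False,
        )
        self.bias_na = float(res.i_clamp_na[-1])
        return self.bias_na

    def integrate(
        self,
        amplitude_na: float,
        duration_ms: float,
        *,
        dt: float = 0.01,
        pre_ms: float = 20.0,
        post_ms: float = 20.0,
        record_sites: tuple[str, ...] = ("soma", "ais_distal", "dend"),
        bias_na: float | None = None,
        record_dt_ms: float = 0.02,
    ) -> SimResult:
        """Current-clamp step protocol from the biased resting state."""
        if dt > 0.025 + 1e-12:
            raise ValueError("AP-resolution runs require dt <= 25 µs")
        bias = self.bias_na if bias_na is None else bias_na
        phases = [
            Phase(pre_ms, dt, i_const_na=bias, record_dt_ms=record_dt_ms, label="pre"),
            Phase(duration_ms, dt, i_const_na=bias + amplitude_na,
                  record_dt_ms=record_dt_ms, label="step"),
            Phase(post_ms, dt, i_const_na=bias, record_dt_ms=record_dt_ms, label="post"),
        ]
        return self.run_phases(phases, record_sites=record_sites, reset=True)

    def voltage_clamp(
        self,
        command: list[tuple[float, float]],
        *,
        dt: float = 0.01,
        record_dt_ms: float = 0.01,
        leak_subtraction: str = "none",
        reset: bool = True,
        v_init: float | None = None,
    ) -> tuple[np.ndarray, np.ndarray]:
        """Somatic voltage clamp; returns (t_ms, electrode current nA).

        ``command`` is a list of (duration_ms, voltage_mV) epochs.  Leak
        subtraction follows the named protocol: "P4" applies four
        quarter-amplitude sub-pulses (from the first epoch's holding
        voltage), "P8" eight eighth-amplitude sub-pulses stepping from
        −80 to −90 mV territory scaled to the test step; the scaled leak
        responses are summed and subtracted from the test response.
        """
        if leak_subtraction not in ("none", "P4", "P8"):
            raise ValueError(f"unsupported leak subtraction: {leak_subtraction}")
        for _, vcmd in command:
            if not (-120.0 <= vcmd <= 40.0):
                raise ValueError("command voltage outside [-120, 40] mV")

        def run(cmds, do_reset):
            phases = [
                Phase(dur, dt, clamp_mv=vc, record_dt_ms=record_dt_ms, label="vc")
                for dur, vc in cmds
            ]
            res = self.run_phases(
                phases, record_sites=("soma",), reset=do_reset,
                v_init=cmds[0][1] if v_init is None else v_init,
            )
            return res.t_ms, res.i_clamp_na

        t, i = run(command, reset)
        if leak_subtraction == "none" or len(command) < 2:
            return t, i
        n_sub = 4 if leak_subtraction == "P4" else 8
        vhold = command[0][1]
        sub_cmds = [
            (dur, vhold + (vc - vhold) / n_sub) for dur, vc in command
        ]
        if leak_subtraction == "P8":
            # sub-pulses run in hyperpolarized territory (−80 → −90 style)
            sub_cmds = [(dur, -80.0 + (vc - vhold) / n_sub) for dur, vc in command]
        saved = self._snapshot()
        _, i_sub = run(sub_cmds, True)
        self._restore(saved)
        return t, i - n_sub * i_sub

    def _snapshot(self) -> dict:
        st = self.state
        return {k: val.copy() for k, val in st.items()}

    def _restore(self, snap: dict) -> None:
        self._state = {k: val.copy() for k, val in snap.items()}

    # --------------------------------------------------------------- audit
    def audit_distribution(self) -> dict:
        """Check every spatial-distribution invariant over the segments."""
        d = self.density_ms_cm2
        sec = self.seg_section
        x = self.seg_x_um
        ais = sec == "AIS"
        xc = self.distribution.crossover_um
        report = {
            "soma_equal": bool(
                np.allclose(d[0, sec == "soma"], d[1, sec == "soma"])
            ),
            "proximal_dendrite_equal": bool(
                np.allclose(d[0, sec == "proximal_dendrite"], d[1, sec == "proximal_dendrite"])
            ),
            "distal_dendrite_nav12_only": bool(
                np.all(d[1, sec == "distal_dendrite"] == 0)
                and np.all(d[0, sec == "distal_dendrite"] > 0)
            ),
            "axon_nav16_only": bool(
                np.all(d[0, (sec == "distal_axon") | (sec == "node")] == 0)
            ),
            "ais_proximal_nav12_dominant": bool(
                np.all(d[0, ais & (x < xc)] > d[1, ais & (x < xc)])
            ),
            "ais_distal_nav16_dominant": bool(
                np.all(d[1, ais & (x > xc)] > d[0, ais & (x > xc)])
            ),
            "node_enriched": bool(
                d[1, sec == "node"].mean()
                >= d[1, sec == "distal_axon"].mean()
            ),
        }
        report["all"] = all(report.values())
        return report


def build_model(config: dict | None = None) -> NeuronModel:
    """Build the calibrated model (packaged defaults) or from a config dict."""
    cfg = load_default_config() if config is None else config
    model = NeuronModel(cfg)
    audit = model.audit_distribution()
    if not audit["all"]:
        bad = [k for k, ok in audit.items() if not ok and k != "all"]
        raise ValueError(f"channel-distribution invariants violated: {bad}")
    return model
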