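"""Executable stimulation/recovery/seizure protocols.

Each protocol mirrors an ex vivo or in silico experiment used to dissect
NaV1.2 vs NaV1.6 roles in pyramidal-cell excitability:

* density and crossover sweeps — graded channel-density reductions and
  AIS crossover-position sensitivity, read out via first-AP phase-plane
  features;
* onboarding/recovery — a 300 ms baseline train, a 30 s voltage-clamp
  hold at −12 mV to inactivate channels and onboard the use-dependent
  blocker, then test stimuli on a log-spaced ladder (2/5/15/30/60 s
  inter-stimulus intervals), summarized over the 12–20 s post-offset
  window;
* nucleated patch — somatic-membrane voltage clamp with −12 mV test
  pulses every 2 s, a 10 s inactivating hold, and P/8 leak subtraction;
* long train — 300 pA for 10 s, features binned at 1 s and delta-
  normalized to the first 500 ms;
* seizure-like activity — Poisson post-synaptic-potential current (50 Hz,
  60 s) at baseline, with a 400 pA standing step during the seizure
  segment, and four 60 s recovery segments, binned at 5 s.

All protocols run on a :class:`~navdissect.neuron_model.NeuronModel` and
return tidy ``pandas`` tables, one row per scale/pulse/bin.  Fine time
steps (10–25 µs) are used wherever APs are measured; inter-stimulus holds
and voltage-clamp plateaus use coarser, still implicit-stable steps.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import ap_features as apf
from .channel_kinetics import Isoform
from .neuron_model import NeuronModel, Phase
from . import synthetic_data as sd

__all__ = [
    "StimulusProtocol",
    "tune_baseline_amplitude",
    "run_density_sweep",
    "run_crossover_sweep",
    "run_onboarding_recovery",
    "run_nucleated_patch",
    "run_long_train",
    "run_seizure_protocol",
    "CROSSOVER_GRID_UM",
    "ISI_LADDER_S",
]

CROSSOVER_GRID_UM = (7.5, 11.25, 15.0, 18.75, 22.5, 26.25, 30.0, 33.75)
ISI_LADDER_S = (2.0, 5.0, 15.0, 30.0, 60.0)

_FINE_DT = 0.01    # ms, AP-resolution phases
_COARSE_DT = 0.1   # ms, subthreshold holds / clamp plateaus


@dataclass(frozen=True)
class StimulusProtocol:
    """Declarative protocol description (kind + parameters + seed)."""

    kind: str
    params: dict = field(default_factory=dict)
    seed: int | None = None

    _KINDS = (
        "step", "train_step", "onboarding_recovery", "nucleated_patch",
        "density_sweep", "crossover_sweep", "seizure_psp",
    )

    def __post_init__(self) -> None:
        if self.kind not in self._KINDS:
            raise ValueError(f"unknown protocol kind: {self.kind!r}")
        isis = self.params.get("isi_ladder_s")
        if isis is not None and list(isis) != sorted(isis):
            raise ValueError("ISI ladder must be strictly increasing")
        for key in ("duration_s", "duration_ms"):
            if key in self.params and not self.params[key] > 0:
                raise ValueError(f"{key} must be positive")


def _first_ap_features(model: NeuronModel, amp_na: float, dur_ms: float = 300.0):
    """First-AP features and train summary for a current step from rest."""
    res = model.integrate(
        amp_na, dur_ms, dt=_FINE_DT, record_sites=("soma",),
    )
    tr = res.trace("soma")
    feats = apf.extract_features(tr)
    train = apf.train_features(tr, (20.0, 20.0 + dur_ms))
    return feats, train


def tune_baseline_amplitude(
    model: NeuronModel,
    target_spikes: tuple[int, int] = (5, 6),
    accept: tuple[int, int] = (4, 6),
    amp_range_na: tuple[float, float] = (0.1, 0.6),
    step_na: float = 0.05,
) -> float:
    """300 ms step amplitude that evokes the target spike count.

    Scans the amplitude range in ``step_na`` increments and returns the
    first amplitude within ``target_spikes``, falling back to the first
    within ``accept``.  Raises if no amplitude qualifies.
    """
    model.find_bias_current(-80.0)
    fallback = None
    amps = np.arange(amp_range_na[0], amp_range_na[1] + 1e-9, step_na)
    for amp in amps:
        _, train = _first_ap_features(model, float(amp))
        n = train["spike_count"]
        if target_spikes[0] <= n <= target_spikes[1]:
            return float(amp)
        if fallback is None and accept[0] <= n <= accept[1]:
            fallback = float(amp)
    if fallback is not None:
        return fallback
    raise RuntimeError(
        f"no amplitude in {amp_range_na} nA evokes "
        f"{accept[0]}-{accept[1]} APs per 300 ms"
    )


def _feature_row(feats, train):
    if not feats:
        return dict(threshold=np.nan, ais_inflection_dvdt=np.nan,
                    ais_max_dvdt=np.nan, somatic_peak_dvdt=np.nan,
                    spike_count=0, last_ahp=np.nan)
    f = feats[0]
    return dict(
        threshold=f.threshold,
        ais_inflection_dvdt=f.ais_inflection_dvdt,
        ais_max_dvdt=f.ais_max_dvdt,
        somatic_peak_dvdt=f.somatic_peak_dvdt,
        spike_count=train["spike_count"],
        last_ahp=train["last_ahp"],
    )


def run_density_sweep(
    model: NeuronModel,
    isoform: str,
    amp_na: float | None = None,
) -> pd.DataFrame:
    """Scale one (or both) isoform densities 100%..0% in 10% steps.

    Returns 11 rows with first-AP features; scales where no AP is evoked
    keep their row with NaN features.
    """
    if isoform not in ("nav12", "nav16", "both"):
        raise ValueError("isoform must be 'nav12', 'nav16' or 'both'")
    if amp_na is None:
        amp_na = tune_baseline_amplitude(model)
    else:
        model.find_bias_current(-80.0)
    rows = []
    try:
        for scale in np.round(np.arange(1.0, -0.01, -0.1), 10):
            s12 = scale if isoform in ("nav12", "both") else 1.0
            s16 = scale if isoform in ("nav16", "both") else 1.0
            model.set_scales(nav12=s12, nav16=s16)
            feats, train = _first_ap_features(model, amp_na)
            rows.append({"scale": float(scale), **_feature_row(feats, train)})
    finally:
        model.set_scales(nav12=1.0, nav16=1.0)
    return pd.DataFrame(rows)


def run_crossover_sweep(
    model: NeuronModel,
    amp_na: float | None = None,
    crossover_grid_um=CROSSOVER_GRID_UM,
) -> pd.DataFrame:
    """Crossover-position × isoform-ratio sensitivity analysis.

    For each AIS crossover position, the NaV1.2 percentage falls 90%→0%
    while NaV1.6 rises 10%→100% (the 100:0 condition evokes no APs and is
    excluded), giving an 8 × 10 grid of first-AP feature rows.
    """
    if amp_na is None:
        amp_na = tune_baseline_amplitude(model)
    else:
        model.find_bias_current(-80.0)
    xc0 = model.distribution.crossover_um
    rows = []
    try:
        for xc in crossover_grid_um:
            model.set_crossover(float(xc))
            for p12 in range(90, -1, -10):
                p16 = 100 - p12
                model.set_scales(nav12=p12 / 100.0, nav16=p16 / 100.0)
                feats, train = _first_ap_features(model, amp_na)
                row = _feature_row(feats, train)
                rows.append({
                    "crossover_um": float(xc),
                    "nav12_pct": p12,
                    "nav16_pct": p16,
                    "threshold": row["threshold"],
                    "ais_peak": row["ais_max_dvdt"],
                    "somatic_peak": row["somatic_peak_dvdt"],
                })
    finally:
        model.set_crossover(xc0)
        model.set_scales(nav12=1.0, nav16=1.0)
    return pd.DataFrame(rows)


def _recovery_stim_times(isi_ladder_s, recovery_s):
    """Test-stimulus offsets (s) after clamp release, log-ladder spacing."""
    spans = {2.0: 20.0, 5.0: 30.0, 15.0: 45.0, 30.0: 90.0, 60.0: 240.0}
    times, t = [], 0.0
    for isi in isi_ladder_s:
        span = spans.get(isi, isi * 3)
        end = min(t + span, recovery_s)
        while t + isi <= end + 1e-9:
            t += isi
            times.append(t)
        if t >= recovery_s:
            break
    return [x for x in times if x <= recovery_s + 1e-9]


def run_onboarding_recovery(
    model: NeuronModel,
    drug_conc_nm: float = 0.0,
    genotype_nav12: str = "YW",
    genotype_nav16: str = "YW",
    *,
    hold_mv: float = -12.0,
    hold_s: float = 30.0,
    recovery_s: float = 185.0,
    isi_ladder_s=ISI_LADDER_S,
    amp_na: float | None = None,
    summary_window_s: tuple[float, float] = (12.0, 20.0),
) -> tuple[pd.DataFrame, dict]:
    """Hybrid clamp protocol: baseline train, −12 mV hold, recovery ladder.

    Returns (table, summary): one row per test stimulus with absolute and
    delta (recovery − baseline) features, and a summary dict averaging
    the stimuli whose offset-relative time falls in ``summary_window_s``.
    """
    model.set_drug(drug_conc_nm, genotype_nav12, genotype_nav16)
    if amp_na is None:
        amp_na = tune_baseline_amplitude(model)
    else:
        model.find_bias_current(-80.0)
    bias = model.bias_na

    # baseline train (drug present but un-onboarded; block starts at 0)
    model.init_state(-80.0)
    base_res = model.run_phases(
        [Phase(20.0, _FINE_DT, i_const_na=bias, record_dt_ms=_FINE_DT, label="pre"),
         Phase(300.0, _FINE_DT, i_const_na=bias + amp_na, record_dt_ms=_FINE_DT, label="stim"),
         Phase(20.0, _FINE_DT, i_const_na=bias, record_dt_ms=_FINE_DT, label="post")],
        reset=False,
    )
    base_tr = base_res.trace("soma")
    base_feats = apf.extract_features(base_tr)
    base_train = apf.train_features(base_tr, (20.0, 320.0))
    if not base_feats:
        raise RuntimeError("baseline tuning failure: no APs in baseline train")
    baseline = _feature_row(base_feats, base_train)

    # onboarding hold (voltage clamp); drug binds the inactivated channels
    model.run_phases(
        [Phase(hold_s * 1000.0, _COARSE_DT, clamp_mv=hold_mv,
               record_dt_ms=None, label="hold")],
        reset=False,
    )

    stim_times = _recovery_stim_times(isi_ladder_s, recovery_s)
    rows = []
    t_prev = 0.0
    for t_stim in stim_times:
        gap_ms = (t_stim - t_prev) * 1000.0 - 340.0
        phases = []
        if gap_ms > 0:
            phases.append(Phase(gap_ms, _COARSE_DT, i_const_na=bias,
                                record_dt_ms=None, label="gap"))
        phases += [
            Phase(20.0, _FINE_DT, i_const_na=bias, record_dt_ms=_FINE_DT, label="pre"),
            Phase(300.0, _FINE_DT, i_const_na=bias + amp_na,
                  record_dt_ms=_FINE_DT, label="stim"),
            Phase(20.0, _FINE_DT, i_const_na=bias, record_dt_ms=_FINE_DT, label="post"),
        ]
        res = model.run_phases(phases, reset=False)
        tr = res.trace("soma")
        t0 = res.phase_edges_ms[-3][1]
        feats = [f for f in apf.extract_features(tr)]
        train = apf.train_features(tr, (t0, t0 + 320.0))
        row = _feature_row(feats, train)
        rows.append({
            "time_since_offset_s": t_stim,
            **row,
            "delta_threshold": row["threshold"] - baseline["threshold"],
            "delta_peak_dvdt": row["somatic_peak_dvdt"] - baseline["somatic_peak_dvdt"],
            "delta_spike_count": row["spike_count"] - baseline["spike_count"],
            "delta_last_ahp": row["last_ahp"] - baseline["last_ahp"],
            "blocked_nav12": float(res.blocked[0, -1]),
            "blocked_nav16": float(res.blocked[1, -1]),
        })
        t_prev = t_stim
    table = pd.DataFrame(rows)

    lo, hi = summary_window_s
    win = table[(table.time_since_offset_s >= lo) & (table.time_since_offset_s <= hi)]
    summary = {
        "baseline": baseline,
        "amp_na": amp_na,
        "window_s": list(summary_window_s),
        "delta_threshold": float(win.delta_threshold.mean()),
        "delta_peak_dvdt": float(win.delta_peak_dvdt.mean()),
        "delta_spike_count": float(win.delta_spike_count.mean()),
        "delta_last_ahp": float(win.delta_last_ahp.mean()),
        "spike_count": float(win.spike_count.mean()),
    }
    return table, summary


def _somatic_patch_model(model: NeuronModel) -> NeuronModel:
    """Somatic-membrane-only variant (nucleated-patch emulation)."""
    cfg = {
        "morphology": {
            "axial_resistivity": model.morphology.axial_resistivity,
            "sections": [{
                "name": "soma", "length_um": 10.0, "diameter_um": 10.0,
                "n_segments": 1, "cm_uf_cm2": 1.0,
            }],
        },
        "channels": {
            "gating_context": model.gating_context,
            "reversal_mv": {"na": model.e_na, "k": model.e_k, "leak": model.e_leak},
            "densities_ms_cm2": {
                "soma": dict(model.distribution.densities_ms_cm2.get("soma", {})),
            },
        },
        "distribution": {},
        "drug": {
            "conc_nM": model.drug_conc_nm,
            "genotype": {
                "nav12": model.genotypes[Isoform.NAV12].value,
                "nav16": model.genotypes[Isoform.NAV16].value,
            },
        },
    }
    return NeuronModel(cfg)


def run_nucleated_patch(
    model: NeuronModel,
    drug_conc_nm: float = 0.0,
    genotype_nav12: str = "YW",
    genotype_nav16: str = "YW",
    *,
    n_baseline: int = 10,
    n_recovery: int = 13,
    pulse_every_s: float = 2.0,
    hold_s: float = 10.0,
    dt: float = 0.01,
) -> pd.DataFrame:
    """Nucleated-patch recovery protocol (somatic voltage clamp).

    Baseline: −80→−12 mV 20 ms pulses every 2 s (×``n_baseline``); then a
    ``hold_s`` inactivating hold at −12 mV onboards the blocker; recovery
    pulses follow every 2 s.  Peak inward Na current per pulse is leak-
    subtracted with a P/8-style protocol (one 1/8-amplitude sub-pulse
    response, scaled ×8 — exact for the linear leak) and normalized to
    the mean baseline peak.  Returns (pulse_time_s, phase,
    normalized_peak_current).
    """
    model.set_drug(drug_conc_nm, genotype_nav12, genotype_nav16)
    patch = _somatic_patch_model(model)

    # P/8 leak template: 1/8-amplitude step from holding, scaled by 8
    sub_step = (-12.0 - (-80.0)) / 8.0
    t_sub, i_sub = patch.voltage_clamp(
        [(1000.0, -80.0), (20.0, -80.0 + sub_step)], dt=dt, record_dt_ms=dt,
    )
    mask_sub = t_sub > 1000.0 + 3 * dt
    leak_template = 8.0 * i_sub[mask_sub]

    def pulse_peak(res_t, res_i, t_on):
        m = res_t > t_on + 3 * dt
        seg = res_i[m][: leak_template.size]
        corr = seg - leak_template[: seg.size]
        return float(corr.min())

    patch.init_state(-80.0)
    rows = []
    t_clock = 0.0
    gap_ms = pulse_every_s * 1000.0 - 20.0

    def one_pulse(phase_name):
        nonlocal t_clock
        res = patch.run_phases(
            [Phase(gap_ms, _COARSE_DT, clamp_mv=-80.0, record_dt_ms=None, label="hold"),
             Phase(20.0, dt, clamp_mv=-12.0, record_dt_ms=dt, label="pulse")],
            reset=False,
        )
        t_clock += pulse_every_s
        t_on = res.phase_edges_ms[-1][1]
        rows.append({
            "pulse_time_s": t_clock,
            "phase": phase_name,
            "peak_na": pulse_peak(res.t_ms, res.i_clamp_na, t_on),
        })

    for _ in range(n_baseline):
        one_pulse("baseline")
    patch.run_phases(
        [Phase(hold_s * 1000.0, _COARSE_DT, clamp_mv=-12.0,
               record_dt_ms=None, label="onboard")],
        reset=False,
    )
    t_clock += hold_s
    for _ in range(n_recovery):
        one_pulse("recovery")

    df = pd.DataFrame(rows)
    base_mean = df.loc[df.phase == "baseline", "peak_na"].mean()
    df["normalized_peak_current"] = df.peak_na / base_mean
    return df


def run_long_train(
    model: NeuronModel,
    amplitude_na: float = 0.3,
    duration_s: float = 10.0,
    drug_conc_nm: float = 0.0,
    genotype_nav12: str = "YW",
    genotype_nav16: str = "YW",
    *,
    bin_s: float = 1.0,
    norm_window_s: float = 0.5,
) -> pd.DataFrame:
    """Sustained firing under constant current; use-dependent drift.

    Injects ``amplitude_na`` for ``duration_s`` and returns per-bin delta
    features (bin mean − initial ``norm_window_s`` mean) for threshold,
    peak dV/dt and instantaneous frequency.
    """
    if amplitude_na <= 0 or duration_s <= 0:
        raise ValueError("amplitude and duration must be positive")
    model.set_drug(drug_conc_nm, genotype_nav12, genotype_nav16)
    model.find_bias_current(-80.0)
    bias = model.bias_na
    model.init_state(-80.0)
    res = model.run_phases(
        [Phase(20.0, _FINE_DT, i_const_na=bias, record_dt_ms=_FINE_DT, label="pre"),
         Phase(duration_s * 1000.0, _FINE_DT, i_const_na=bias + amplitude_na,
               record_dt_ms=_FINE_DT, label="stim")],
        reset=False,
    )
    tr = res.trace("soma")
    feats = [f for f in apf.extract_features(tr) if f.threshold_time >= 20.0]
    if not any(f.threshold_time <= 20.0 + norm_window_s * 1000.0 for f in feats):
        raise RuntimeError("no spikes in the normalization window")
    t = np.array([f.threshold_time - 20.0 for f in feats])  # ms since onset
    rows = []
    for name, series in (
        ("delta_threshold", np.array([f.threshold for f in feats])),
        ("delta_peak_dvdt", np.array([f.somatic_peak_dvdt for f in feats])),
        ("delta_inst_freq", np.array([f.inst_freq for f in feats])),
    ):
        dn = apf.delta_normalize(t, series, bin_s * 1000.0,
                                 (0.0, norm_window_s * 1000.0))
        dn = dn.rename(columns={"delta": name})
        rows.append(dn[[name]])
    out = pd.concat(rows, axis=1)
    out.insert(0, "bin_s", np.arange(len(out)) * bin_s)
    out["spike_count_bin"] = [
        int(((t >= b * 1000.0) & (t < (b + bin_s) * 1000.0)).sum())
        for b in out.bin_s
    ]
    return out


def run_seizure_protocol(
    model: NeuronModel,
    seed: int,
    drug_conc_nm: float = 0.0,
    genotype_nav12: str = "YW",
    genotype_nav16: str = "YW",
    *,
    segment_s: float = 60.0,
    n_recovery_segments: int = 4,
    seizure_step_na: float = 0.4,
    psp_rate_hz: float = 50.0,
    psp_amp_sd_pa: float = 200.0,
    baseline_bias_na: float = 0.28,
    bin_s: float = 5.0,
    dt: float = 0.05,
) -> pd.DataFrame:
    """Seizure-like-activity protocol under Poisson PSP drive.

    One baseline segment of Poisson post-synaptic-potential current, one
    seizure segment with an additional ``seizure_step_na`` standing step,
    then ``n_recovery_segments`` recovery segments.  ``baseline_bias_na``
    is a standing depolarization calibrated so the PSP fluctuations evoke
    sustained baseline spiking.  Features are binned in ``bin_s``
    increments; identical seeds give identical spike times.
    """
    model.set_drug(drug_conc_nm, genotype_nav12, genotype_nav16)
    model.find_bias_current(-80.0)
    hold_bias = model.bias_na
    model.init_state(-80.0)

    segments = (["baseline", "seizure"] + ["recovery"] * n_recovery_segments)
    rng_seeds = np.random.SeedSequence(seed).generate_state(len(segments))
    phases = []
    for k, name in enumerate(segments):
        t_ms, i_pa, _ = sd.gen_psp_train(
            rate_hz=psp_rate_hz, amp_sd_pa=psp_amp_sd_pa,
            duration_s=segment_s, seed=int(rng_seeds[k] % (2 ** 31)),
            dt_ms=dt,
        )
        wave = i_pa * 1e-3 + baseline_bias_na  # pA → nA plus standing bias
        if name == "seizure":
            wave = wave + seizure_step_na
        phases.append(Phase(segment_s * 1000.0, dt, i_const_na=hold_bias,
                            i_wave_na=wave, record_dt_ms=dt, label=name))
    res = model.run_phases(phases, reset=False)
    tr = res.trace("soma")
    feats = apf.extract_features(tr)
    t_spk = np.array([f.threshold_time for f in feats])
    thr = np.array([f.threshold for f in feats])
    freq = np.array([f.inst_freq for f in feats])

    rows = []
    total_s = segment_s * len(segments)
    for b0 in np.arange(0.0, total_s, bin_s):
        sel = (t_spk >= b0 * 1000.0) & (t_spk < (b0 + bin_s) * 1000.0)
        seg_idx = min(int(b0 // segment_s), len(segments) - 1)
        rows.append({
            "bin_start_s": b0,
            "phase": segments[seg_idx],
            "n_spikes": int(sel.sum()),
            "threshold": float(np.nanmean(thr[sel])) if sel.any() else np.nan,
            "inst_freq": float(np.nanmean(freq[sel])) if sel.any() else np.nan,
            "rate_hz": float(sel.sum() / bin_s),
        })
    return pd.DataFrame(rows)
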