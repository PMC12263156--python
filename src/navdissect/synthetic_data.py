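"""Synthetic inputs with known ground truth for every pipeline stage.

The generators emulate the voltage-clamp and current-clamp protocols used
to characterize NaV isoforms and pyramidal-cell firing:

* activation current families (hold -80 mV, prepulse -120 mV, 30 ms test
  pulses -100..-20 mV in 5 mV steps) with an optional linear leak that a
  P/4 protocol removes exactly;
* steady-state inactivation families (prepulses -120..+30 mV in 5 mV
  steps, test pulse to -12 mV);
* Hill dose-response tables over a 30 nM .. 100 µM half-log grid;
* Poisson post-synaptic-potential current trains (50 Hz, 200 pA amplitude
  SD, 60 s) built from biexponential kernels;
* parametric AP voltage fixtures whose rising phase has two components
  (AIS then somatic), built by integrating a two-Gaussian dV/dt pulse so
  every phase-plane landmark is known by construction.

Noise is additive Gaussian on normalized responses (default sd 0.02); all
randomness flows through a caller-provided seed, so a fixed seed yields
byte-identical output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd

from .channel_kinetics import (
    BoltzmannParams,
    boltzmann_activation,
    boltzmann_inactivation,
)
from .asc_pharmacology import DoseResponseParams, hill_equilibrium_block
from .ap_features import VoltageTrace, THRESHOLD_VS

__all__ = [
    "ACTIVATION_GRID_MV",
    "INACTIVATION_GRID_MV",
    "default_dose_grid_nm",
    "gen_activation_family",
    "gen_inactivation_family",
    "p4_subtract",
    "gen_dose_response",
    "gen_psp_train",
    "gen_ap_fixture",
    "gen_ap_train_fixture",
    "APFixtureTruth",
]

# protocol grids
ACTIVATION_GRID_MV = np.arange(-100.0, -20.0 + 1e-9, 5.0)   # 17 steps
INACTIVATION_GRID_MV = np.arange(-120.0, 30.0 + 1e-9, 5.0)  # 31 prepulses
HOLD_MV = -80.0
TEST_PULSE_MV = -12.0


def default_dose_grid_nm() -> np.ndarray:
    """Half-log (1-3-10 series) dose grid from 30 nM to 100 µM (nM)."""
    return np.array([30.0, 100.0, 300.0, 1_000.0, 3_000.0,
                     10_000.0, 30_000.0, 100_000.0])


def gen_activation_family(
    params: BoltzmannParams,
    g_max: float = 0.02,
    v_na: float = 60.0,
    noise_sd: float = 0.02,
    seed: int | None = None,
    *,
    grid_mv: np.ndarray | None = None,
    g_leak: float = 0.0,
    e_leak: float = HOLD_MV,
) -> tuple[pd.DataFrame, dict]:
    """Peak-current activation family.

    Peak Na current obeys I = G(v)(v - v_na) with G(v) = g_max *
    boltzmann_activation(v) (g_max in µS, currents in nA).  When
    ``g_leak`` > 0 a step-evoked linear leak g_leak*(v - hold) is added to
    the total; :func:`p4_subtract` removes it exactly.  Noise (sd as a
    fraction of g_max) applies to the Na conductance.
    """
    v = np.asarray(grid_mv if grid_mv is not None else ACTIVATION_GRID_MV, float)
    rng = np.random.default_rng(seed)
    g = g_max * boltzmann_activation(v, params)
    if noise_sd > 0:
        g = g + rng.normal(0.0, noise_sd * g_max, size=v.shape)
    i_na = g * (v - v_na)
    i_leak = g_leak * (v - HOLD_MV)
    df = pd.DataFrame(
        {
            "v_mV": v,
            "i_peak_nA": i_na,
            "i_leak_nA": i_leak,
            "i_total_nA": i_na + i_leak,
        }
    )
    truth = {
        "kind": "activation_family",
        "v_half": params.v_half,
        "slope_factor": params.slope_factor,
        "g_max_uS": g_max,
        "v_na_mV": v_na,
        "g_leak_uS": g_leak,
        "noise_sd": noise_sd,
        "seed": seed,
    }
    return df, truth


def p4_subtract(df: pd.DataFrame) -> pd.DataFrame:
    """Remove the linear leak with a P/4-style protocol.

    Four quarter-amplitude sub-pulses from holding evoke leak responses of
    g_leak*(v - hold)/4 each; their sum equals the step-evoked leak of the
    full pulse (linearity), so total - 4*subpulse leaves the Na current.
    """
    out = df.copy()
    sub = out["i_leak_nA"] / 4.0
    out["i_corrected_nA"] = out["i_total_nA"] - 4.0 * sub
    return out


def gen_inactivation_family(
    params: BoltzmannParams,
    g_max: float = 0.02,
    v_na: float = 60.0,
    noise_sd: float = 0.02,
    seed: int | None = None,
    *,
    grid_mv: np.ndarray | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Steady-state inactivation family (test pulse to -12 mV).

    The normalized peak test-pulse current follows the inactivation
    Boltzmann of the prepulse voltage.
    """
    vpre = np.asarray(grid_mv if grid_mv is not None else INACTIVATION_GRID_MV, float)
    rng = np.random.default_rng(seed)
    avail = boltzmann_inactivation(vpre, params)
    if noise_sd > 0:
        avail = avail + rng.normal(0.0, noise_sd, size=vpre.shape)
    i_test = g_max * avail * (TEST_PULSE_MV - v_na)
    df = pd.DataFrame(
        {
            "v_prepulse_mV": vpre,
            "i_peak_nA": i_test,
            "i_norm": avail,
        }
    )
    truth = {
        "kind": "inactivation_family",
        "v_half": params.v_half,
        "slope_factor": params.slope_factor,
        "g_max_uS": g_max,
        "v_na_mV": v_na,
        "test_pulse_mV": TEST_PULSE_MV,
        "noise_sd": noise_sd,
        "seed": seed,
    }
    return df, truth


def gen_dose_response(
    p: DoseResponseParams,
    doses_nm: np.ndarray | None = None,
    noise_sd: float = 0.02,
    seed: int | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Normalized remaining current vs dose: ic50^n / (ic50^n + dose^n)."""
    doses = np.asarray(doses_nm if doses_nm is not None else default_dose_grid_nm(), float)
    rng = np.random.default_rng(seed)
    resp = np.array([1.0 - hill_equilibrium_block(d, p) for d in doses])
    if noise_sd > 0:
        resp = resp + rng.normal(0.0, noise_sd, size=doses.shape)
    df = pd.DataFrame({"dose_nM": doses, "normalized_current": resp})
    truth = {
        "kind": "dose_response",
        "ic50_nM": p.ic50,
        "hill_n": p.hill_n,
        "noise_sd": noise_sd,
        "seed": seed,
    }
    return df, truth


def psp_kernel(dt_ms: float, rise_ms: float = 0.5, decay_ms: float = 5.0) -> np.ndarray:
    """Unit-peak biexponential synaptic-current kernel."""
    t = np.arange(0.0, decay_ms * 8.0, dt_ms)
    k = np.exp(-t / decay_ms) - np.exp(-t / rise_ms)
    return k / k.max()


def gen_psp_train(
    rate_hz: float = 50.0,
    amp_sd_pa: float = 200.0,
    duration_s: float = 60.0,
    seed: int | None = None,
    *,
    dt_ms: float = 0.05,
    rise_ms: float = 0.5,
    decay_ms: float = 5.0,
) -> tuple[np.ndarray, np.ndarray, dict]:
    """Poisson post-synaptic-potential current train.

    Event times are homogeneous Poisson at ``rate_hz``; event amplitudes
    are zero-mean Gaussian with SD ``amp_sd_pa`` (mixed EPSC/IPSC signs);
    the train is the event impulses convolved with a biexponential kernel.
    Returns (t_ms, i_pa, truth).
    """
    if rate_hz <= 0 or duration_s <= 0:
        raise ValueError("rate and duration must be positive")
    rng = np.random.default_rng(seed)
    n_events = rng.poisson(rate_hz * duration_s)
    times_ms = np.sort(rng.uniform(0.0, duration_s * 1000.0, size=n_events))
    amps = rng.normal(0.0, amp_sd_pa, size=n_events)
    n = int(round(duration_s * 1000.0 / dt_ms))
    t = np.arange(n) * dt_ms
    impulses = np.zeros(n)
    idx = np.minimum((times_ms / dt_ms).astype(np.int64), n - 1)
    np.add.at(impulses, idx, amps)
    i_pa = np.convolve(impulses, psp_kernel(dt_ms, rise_ms, decay_ms))[:n]
    truth = {
        "kind": "psp_train",
        "rate_hz": rate_hz,
        "amp_sd_pa": amp_sd_pa,
        "duration_s": duration_s,
        "n_events": int(n_events),
        "event_times_ms": times_ms.tolist(),
        "seed": seed,
    }
    return t, i_pa, truth


@dataclass(frozen=True)
class APFixtureTruth:
    """Construction ground truth of a parametric AP fixture."""

    threshold: float
    threshold_time: float
    ais_inflection_dvdt: float
    ais_max_dvdt: float
    somatic_peak_dvdt: float
    peak_v: float
    ahp: float
    inst_freq: float

    def as_dict(self) -> dict:
        return asdict(self)


def _gauss_mix(comps):
    """Closed-form Gaussian-mixture dV/dt and its exact derivatives.

    ``comps`` is a list of (amplitude V/s, center ms, width ms).  Returns
    (f, fp, fpp, vint) where f is dV/dt, fp/fpp its first and second time
    derivatives, and vint the exact voltage integral with vint(0) = 0.
    """
    from scipy.special import erf

    def f(t):
        t = np.asarray(t, dtype=float)
        out = np.zeros_like(t)
        for a, c, s in comps:
            out = out + a * np.exp(-(((t - c) / s) ** 2))
        return out

    def fp(t):
        t = np.asarray(t, dtype=float)
        out = np.zeros_like(t)
        for a, c, s in comps:
            x = (t - c) / s
            out = out + a * (-2.0 * x / s) * np.exp(-(x ** 2))
        return out

    def fpp(t):
        t = np.asarray(t, dtype=float)
        out = np.zeros_like(t)
        for a, c, s in comps:
            x = (t - c) / s
            out = out + a * ((4.0 * x * x - 2.0) / (s * s)) * np.exp(-(x ** 2))
        return out

    def vint(t):
        t = np.asarray(t, dtype=float)
        out = np.zeros_like(t)
        for a, c, s in comps:
            out = out + a * s * (math.sqrt(math.pi) / 2.0) * (
                erf((t - c) / s) - erf((0.0 - c) / s)
            )
        return out

    return f, fp, fpp, vint


def gen_ap_fixture(
    threshold_v: float = -43.0,
    ais_dvdt: float = 180.0,
    somatic_dvdt: float = 550.0,
    *,
    rest_v: float = -78.0,
    after_v: float = -55.0,
    sample_khz: float = 50.0,
    t_ais_ms: float = 4.0,
    t_soma_ms: float = 4.6,
    s_ais_ms: float = 0.25,
    s_soma_ms: float = 0.22,
    duration_ms: float = 10.0,
) -> tuple[VoltageTrace, APFixtureTruth]:
    """Parametric single-AP fixture with closed-form phase-plane landmarks.

    dV/dt is a Gaussian mixture: a slow pre-depolarization (peak 12 V/s,
    below the 15 V/s threshold, carrying the voltage from near ``rest_v``
    toward threshold), a two-Gaussian positive pulse (AIS component at
    ``t_ais_ms``, somatic component at ``t_soma_ms``), and a repolarizing
    Gaussian sized so the voltage settles near ``after_v``.  The voltage
    is the exact (erf) integral, offset so the 15 V/s upward crossing
    occurs exactly at ``threshold_v``.  Ground-truth landmark times are
    roots of the analytic derivatives (bracketed and polished with
    Brent's method), so the construction itself is the oracle.  Setting
    ``ais_dvdt=0`` yields a monophasic fixture whose AIS features are NaN.
    """
    from scipy.optimize import brentq

    if not (t_ais_ms < t_soma_ms):
        raise ValueError("AIS component must precede the somatic component")
    if somatic_dvdt <= THRESHOLD_VS:
        raise ValueError("somatic_dvdt must exceed the 15 V/s threshold")
    if ais_dvdt < 0:
        raise ValueError("ais_dvdt must be >= 0")
    if not (after_v < threshold_v):
        raise ValueError("after_v must be below threshold_v")

    sqrtpi = math.sqrt(math.pi)
    pre_amp = 12.0
    pre_area = max(threshold_v - rest_v, 1.0)
    s_pre = pre_area / (pre_amp * sqrtpi)
    t_pre = t_ais_ms - 3.0 * s_ais_ms - s_pre
    up_area = pre_area + (ais_dvdt * s_ais_ms + somatic_dvdt * s_soma_ms) * sqrtpi
    s_repol = 0.45
    repol_dvdt = (rest_v + up_area - after_v) / (s_repol * sqrtpi)
    t_repol = t_soma_ms + 3.0 * s_soma_ms + 2.0 * s_repol
    if t_repol + 4.0 * s_repol > duration_ms:
        raise ValueError("duration_ms too short for the repolarization")

    comps = [(pre_amp, t_pre, s_pre),
             (somatic_dvdt, t_soma_ms, s_soma_ms),
             (-repol_dvdt, t_repol, s_repol)]
    if ais_dvdt > 0:
        comps.insert(1, (ais_dvdt, t_ais_ms, s_ais_ms))
    f, fp, fpp, vint = _gauss_mix(comps)

    # bracket grid for root polishing
    tg = np.linspace(0.0, duration_ms, 20001)
    fg = f(tg)
    i_gmax = int(np.argmax(fg))
    t_fmax = brentq(fp, tg[i_gmax - 1], tg[i_gmax + 1])

    # threshold: last 15 V/s upcrossing before the dv/dt maximum
    pre = fg[:i_gmax + 1]
    ups = np.where((pre[:-1] < THRESHOLD_VS) & (pre[1:] >= THRESHOLD_VS))[0]
    if ups.size == 0:
        raise ValueError("waveform never crosses 15 V/s")
    k = int(ups[-1])
    t_cross = brentq(lambda t: f(t) - THRESHOLD_VS, tg[k], tg[k + 1])
    offset = threshold_v - float(vint(t_cross))

    # phase-plane landmarks: stationary points of the acceleration d2v=fp,
    # i.e. roots of fpp between threshold and the dv/dt maximum
    truth_infl = truth_aismax = float("nan")
    if ais_dvdt > 0:
        sel = (tg > t_cross) & (tg < t_fmax)
        ts = tg[sel]
        g = fpp(ts)
        roots = []
        sign_change = np.where(np.sign(g[:-1]) * np.sign(g[1:]) < 0)[0]
        for j in sign_change:
            r = brentq(fpp, ts[j], ts[j + 1])
            kind = "max" if g[j] > 0 else "min"
            roots.append((r, kind))
        kinds = [k2 for _, k2 in roots]
        if len(roots) >= 2 and kinds[0] == "max" and kinds[1] == "min":
            truth_infl = float(f(roots[0][0]))
            truth_aismax = float(f(roots[1][0]))
        else:
            raise ValueError(
                "inconsistent landmark specification: AIS component does "
                "not produce a distinct acceleration peak and trough"
            )

    # voltage peak: dv/dt zero crossing after the somatic maximum
    post = fg[i_gmax:]
    downs = np.where((post[:-1] > 0) & (post[1:] <= 0))[0]
    t_vpk = brentq(f, tg[i_gmax + downs[0]], tg[i_gmax + downs[0] + 1])

    truth = APFixtureTruth(
        threshold=float(threshold_v),
        threshold_time=float(t_cross),
        ais_inflection_dvdt=truth_infl,
        ais_max_dvdt=truth_aismax,
        somatic_peak_dvdt=float(f(t_fmax)),
        peak_v=float(vint(t_vpk)) + offset,
        ahp=float(vint(duration_ms - 1.0 / sample_khz)) + offset,
        inst_freq=float("nan"),
    )

    dt = 1.0 / sample_khz
    t = np.arange(0.0, duration_ms, dt)
    v = vint(t) + offset
    return VoltageTrace(t=t, v=v), truth


def gen_ap_train_fixture(
    n_spikes: int = 5,
    isi_ms: float = 100.0,
    ahp_v: float = -50.0,
    **fixture_kwargs,
) -> tuple[VoltageTrace, list[APFixtureTruth]]:
    """Train of identical AP fixtures at a fixed inter-spike interval.

    Each period is a single-AP fixture that starts and settles at
    ``ahp_v`` with a flat gap, so the inter-spike minimum equals ``ahp_v``
    by construction; instantaneous-frequency ground truth is 1000/isi_ms
    for every spike after the first.
    """
    if n_spikes < 1:
        raise ValueError("need at least one spike")
    # the fixture settles slightly above the AHP floor so the flat gap is
    # the unambiguous inter-spike minimum
    fixture_kwargs.setdefault("rest_v", ahp_v + 2.0)
    fixture_kwargs.setdefault("after_v", ahp_v + 2.0)
    single, truth0 = gen_ap_fixture(**fixture_kwargs)
    dt = single.dt_ms
    seg_n = int(round(isi_ms / dt))
    v0 = float(single.v[0])
    v_end = float(single.v[-1])
    if min(v0, v_end) < ahp_v:
        raise ValueError("fixture baseline falls below the requested AHP")
    # descend to the AHP floor, hold it, then return to the next baseline
    n_down = int(round(2.0 / dt))
    gap_n = seg_n - single.t.size - 2 * n_down
    if gap_n < 1:
        raise ValueError("isi_ms shorter than the single-AP fixture")
    gap = np.concatenate([
        np.linspace(v_end, ahp_v, n_down, endpoint=False),
        np.full(gap_n, ahp_v),
        np.linspace(ahp_v, v0, n_down, endpoint=False),
    ])
    segment = np.concatenate([single.v, gap])
    v = np.concatenate([segment] * n_spikes)
    t = np.arange(v.size) * dt
    truths = []
    for k in range(n_spikes):
        truths.append(
            APFixtureTruth(
                threshold=truth0.threshold,
                threshold_time=truth0.threshold_time + k * isi_ms,
                ais_inflection_dvdt=truth0.ais_inflection_dvdt,
                ais_max_dvdt=truth0.ais_max_dvdt,
                somatic_peak_dvdt=truth0.somatic_peak_dvdt,
                peak_v=truth0.peak_v,
                ahp=ahp_v if k < n_spikes - 1 else float("nan"),
                inst_freq=1000.0 / isi_ms if k > 0 else float("nan"),
            )
        )
    return VoltageTrace(t=t, v=v), truths
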