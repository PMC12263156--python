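"""Phase-plane action-potential feature extraction.

Feature definitions follow standard current-clamp practice for dissecting
the two components of the pyramidal-cell AP rising phase:

* threshold — membrane potential where dV/dt first exceeds 15 V/s
  (refined by linear interpolation between samples);
* AIS inflection — dV/dt at the first peak of the second derivative after
  threshold, marking initiation of the axon-initial-segment component;
* AIS max — dV/dt at the subsequent trough (or saddle) of the second
  derivative before the somatic peak, marking the AIS-to-soma handoff;
* somatic peak — maximum dV/dt of the spike, with a prominence fallback
  (dV/dt at the sample where the second derivative is nearest zero in the
  somatic phase) when the somatic component is a shoulder rather than a
  true local maximum;
* AHP — minimum voltage between consecutive spikes;
* instantaneous frequency — reciprocal inter-spike interval.

A trace sampled at 50 kHz may be Bessel low-pass filtered at 20 kHz before
differentiation (10 kHz data at 3 kHz); filtering defaults to off, which is
appropriate for noiseless simulated voltages.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal

__all__ = [
    "VoltageTrace",
    "APFeatures",
    "phase_plane",
    "detect_spikes",
    "detect_threshold",
    "ais_components",
    "somatic_peak",
    "extract_features",
    "train_features",
    "delta_normalize",
    "THRESHOLD_VS",
]

THRESHOLD_VS = 15.0  # V/s crossing that defines spike threshold
REFRACTORY_MS = 1.0  # minimum gap between detected spikes
MIN_SPIKE_RISE_MV = 15.0  # a spike must rise this far above its threshold


@dataclass
class VoltageTrace:
    """Uniformly sampled membrane potential at one site.

    ``t`` in ms, ``v`` in mV.  dV/dt is therefore mV/ms == V/s.
    """

    t: np.ndarray
    v: np.ndarray

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.v = np.asarray(self.v, dtype=float)
        if self.t.ndim != 1 or self.t.shape != self.v.shape:
            raise ValueError("t and v must be 1-d arrays of equal length")
        if self.t.size < 4:
            raise ValueError("trace too short")
        dt = np.diff(self.t)
        if not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-9):
            raise ValueError("time grid must be uniform")

    @property
    def dt_ms(self) -> float:
        return float(self.t[1] - self.t[0])

    @property
    def sample_rate_khz(self) -> float:
        return 1.0 / self.dt_ms

    def filtered(self, cutoff_khz: float | None = None) -> "VoltageTrace":
        """4-pole Bessel low-pass (zero-phase) copy of the trace."""
        if cutoff_khz is None:
            cutoff_khz = 20.0 if self.sample_rate_khz >= 25.0 else 3.0
        wn = cutoff_khz / (0.5 * self.sample_rate_khz)
        if wn >= 1.0:
            return VoltageTrace(self.t.copy(), self.v.copy())
        b, a = signal.bessel(4, wn)
        return VoltageTrace(self.t.copy(), signal.filtfilt(b, a, self.v))


@dataclass
class APFeatures:
    """Per-spike landmark set; NaN marks an absent feature."""

    threshold: float
    threshold_time: float
    ais_inflection_dvdt: float
    ais_max_dvdt: float
    somatic_peak_dvdt: float
    peak_v: float
    peak_time: float
    ahp: float = float("nan")       # minimum voltage before the next spike
    inst_freq: float = float("nan")  # Hz, from the preceding ISI


def phase_plane(trace: VoltageTrace) -> tuple[np.ndarray, np.ndarray]:
    """Return (v, dv/dt) with dv/dt by central differences (V/s).

    Same length as the trace; the endpoints use one-sided differences.
    """
    dvdt = np.gradient(trace.v, trace.t)
    return trace.v, dvdt


def _second_derivative(trace: VoltageTrace, dvdt: np.ndarray) -> np.ndarray:
    return np.gradient(dvdt, trace.t)


def _spike_windows(trace: VoltageTrace, dvdt: np.ndarray) -> list[tuple[int, int, int]]:
    """Detect spikes as 15 V/s upward crossings followed by a voltage peak.

    Returns (crossing_index, v_peak_index, window_end_index) per spike,
    enforcing a >= 1 ms refractory gap between crossings.
    """
    above = dvdt >= THRESHOLD_VS
    ups = np.where(~above[:-1] & above[1:])[0] + 1
    if ups.size == 0:
        return []
    refr = max(int(round(REFRACTORY_MS / trace.dt_ms)), 1)
    kept: list[int] = []
    for i in ups:
        if not kept or i - kept[-1] >= refr:
            kept.append(int(i))
    spikes: list[tuple[int, int, int]] = []
    for k, i in enumerate(kept):
        end = kept[k + 1] if k + 1 < len(kept) else trace.v.size
        ipk = i + int(np.argmax(trace.v[i:end]))
        if ipk >= end - 1 and end == trace.v.size and dvdt[-1] > 0:
            continue  # rising edge truncated by the end of the trace
        if ipk + 1 < trace.v.size and trace.v[ipk + 1] > trace.v[ipk]:
            continue  # no voltage peak inside the window: not a spike
        if trace.v[ipk] - trace.v[i] < MIN_SPIKE_RISE_MV:
            continue  # depolarizing transient without a regenerative spike
        spikes.append((i, ipk, end))
    return spikes


def detect_spikes(trace: VoltageTrace) -> list[tuple[int, int, int]]:
    """Public wrapper for spike-epoch detection (see :func:`_spike_windows`)."""
    _, dvdt = phase_plane(trace)
    return _spike_windows(trace, dvdt)


def _interp_crossing(trace, dvdt, i):
    """Linear interpolation of (time, v) at the exact 15 V/s crossing."""
    d0, d1 = dvdt[i - 1], dvdt[i]
    f = 0.0 if d1 == d0 else (THRESHOLD_VS - d0) / (d1 - d0)
    f = float(np.clip(f, 0.0, 1.0))
    t = trace.t[i - 1] + f * (trace.t[i] - trace.t[i - 1])
    v = trace.v[i - 1] + f * (trace.v[i] - trace.v[i - 1])
    return t, v


def detect_threshold(trace: VoltageTrace) -> np.ndarray:
    """Per-spike threshold (mV): Vm where dV/dt first exceeds 15 V/s.

    Returns an empty array when no spike is detected.
    """
    _, dvdt = phase_plane(trace)
    return np.array(
        [_interp_crossing(trace, dvdt, i)[1] for i, _, _ in _spike_windows(trace, dvdt)]
    )


def _refine_value(y_for_pos, y_for_val, j):
    """Value of ``y_for_val`` at the sub-sample extremum of ``y_for_pos``.

    Fits a parabola through the three samples of ``y_for_pos`` around
    index ``j`` for the sub-sample extremum position, then interpolates
    ``y_for_val`` there quadratically; reduces grid-discretization error
    from O(dt^2) of the raw sample.
    """
    if not 0 < j < y_for_pos.size - 1:
        return float(y_for_val[j])
    a, b, c = y_for_pos[j - 1], y_for_pos[j], y_for_pos[j + 1]
    denom = a - 2.0 * b + c
    delta = 0.0 if denom == 0 else float(np.clip(0.5 * (a - c) / denom, -0.5, 0.5))
    f0, f1, f2 = y_for_val[j - 1], y_for_val[j], y_for_val[j + 1]
    return float(
        f1 + 0.5 * delta * (f2 - f0) + 0.5 * delta * delta * (f0 - 2.0 * f1 + f2)
    )


def _interior_extrema(a, comparator, order=2):
    idx = signal.argrelextrema(a, comparator, order=order)[0]
    return idx[(idx > order - 1) & (idx < a.size - order)]


def _rising_landmarks(trace, dvdt, d2v, i_thr, i_vpk):
    """(inflection_dvdt, ais_max_dvdt, somatic_peak_dvdt).

    The search is restricted to the rising phase [threshold, voltage
    peak].  An AIS component requires the acceleration (d2v) to show a
    peak, then a trough (or saddle), then a second rise before the somatic
    phase; a monophasic rising phase yields NaN for both AIS features
    rather than fabricated values.
    """
    nan = float("nan")
    seg = slice(i_thr, i_vpk + 1)
    a = d2v[seg]
    i_gmax = i_thr + int(np.argmax(dvdt[seg]))
    somatic_default = _refine_value(dvdt, dvdt, i_gmax)
    if a.size < 7:
        return nan, nan, somatic_default

    maxima = _interior_extrema(a, np.greater_equal)
    # deduplicate plateaus
    maxima = maxima[np.concatenate(([True], np.diff(maxima) > 1))] if maxima.size else maxima
    if maxima.size < 2:
        return nan, nan, somatic_default  # monophasic rising phase
    i_infl_rel, i_second_rel = int(maxima[0]), int(maxima[1])

    between = a[i_infl_rel:i_second_rel + 1]
    minima = _interior_extrema(between, np.less_equal)
    if minima.size:
        i_tr_rel = i_infl_rel + int(minima[0])
    else:
        # no stationary trough: saddle as the |d2v| minimum between humps
        if between.size < 3:
            return nan, nan, somatic_default
        i_tr_rel = i_infl_rel + 1 + int(np.argmin(np.abs(between[1:-1])))
    # require a real rebound after the trough (rejects numerical wiggles)
    if not (a[i_second_rel] - a[i_tr_rel]) > 0.02 * max(a[i_infl_rel] - a[i_tr_rel], 1e-12):
        return nan, nan, somatic_default

    i_infl = i_thr + i_infl_rel
    i_tr = i_thr + i_tr_rel
    infl = _refine_value(d2v, dvdt, i_infl)
    ais_max = _refine_value(d2v, dvdt, i_tr)

    # somatic component: last dv/dt local max after the AIS trough, or the
    # prominence fallback (dv/dt where d2v is nearest zero in the somatic
    # phase) when the somatic portion is a shoulder without a true peak
    dseg = dvdt[i_tr:i_vpk + 1]
    dmaxima = _interior_extrema(dseg, np.greater_equal)
    if dmaxima.size:
        i_som = i_tr + int(dmaxima[np.argmax(dseg[dmaxima])])
        somatic = _refine_value(dvdt, dvdt, i_som)
    elif i_vpk - i_tr >= 3:
        j = i_tr + 1 + int(np.argmin(np.abs(d2v[i_tr + 1:i_vpk])))
        somatic = float(dvdt[j])
    else:
        somatic = somatic_default
    return infl, ais_max, somatic


def extract_features(trace: VoltageTrace, *, filter_khz: float | None = None) -> list[APFeatures]:
    """Full per-spike feature table for a trace (possibly multi-spike)."""
    work = trace.filtered(filter_khz) if filter_khz else trace
    _, dvdt = phase_plane(work)
    d2v = _second_derivative(work, dvdt)
    spikes = _spike_windows(work, dvdt)
    feats: list[APFeatures] = []
    for i_thr, i_pk, i_end in spikes:
        t_thr, v_thr = _interp_crossing(work, dvdt, i_thr)
        infl, ais_max, som = _rising_landmarks(work, dvdt, d2v, i_thr, i_pk)
        feats.append(
            APFeatures(
                threshold=v_thr,
                threshold_time=t_thr,
                ais_inflection_dvdt=infl,
                ais_max_dvdt=ais_max,
                somatic_peak_dvdt=som,
                peak_v=float(work.v[i_pk]),
                peak_time=float(work.t[i_pk]),
            )
        )
    # inter-spike AHP and instantaneous frequency
    for k in range(len(feats) - 1):
        i0 = spikes[k][1]
        i1 = int(np.searchsorted(work.t, feats[k + 1].threshold_time))
        if i1 > i0:
            feats[k].ahp = float(np.min(work.v[i0:i1 + 1]))
        isi_ms = feats[k + 1].threshold_time - feats[k].threshold_time
        feats[k + 1].inst_freq = 1000.0 / isi_ms
    return feats


def ais_components(trace: VoltageTrace) -> np.ndarray:
    """(ais_inflection_dvdt, ais_max_dvdt) per spike; NaN when monophasic."""
    feats = extract_features(trace)
    return np.array([[f.ais_inflection_dvdt, f.ais_max_dvdt] for f in feats])


def somatic_peak(trace: VoltageTrace) -> np.ndarray:
    """Somatic peak dV/dt (V/s) per spike, with the prominence fallback."""
    return np.array([f.somatic_peak_dvdt for f in extract_features(trace)])


def train_features(trace: VoltageTrace, stim_window: tuple[float, float]) -> dict:
    """Spike-train summary within a stimulus window.

    Returns spike_count, per-spike threshold times, instantaneous frequency
    series (1/ISI, Hz), AHP series (inter-spike voltage minima, mV) and the
    last AHP.  With fewer than two spikes the AHP/frequency series are
    empty but spike_count is still reported.
    """
    t0, t1 = stim_window
    feats = [f for f in extract_features(trace) if t0 <= f.threshold_time <= t1]
    out = {
        "spike_count": len(feats),
        "spike_times": np.array([f.threshold_time for f in feats]),
        "thresholds": np.array([f.threshold for f in feats]),
        "inst_freq": np.array([f.inst_freq for f in feats[1:]]),
        "ahp": np.array([f.ahp for f in feats[:-1] if not math.isnan(f.ahp)]),
    }
    out["last_ahp"] = float(out["ahp"][-1]) if out["ahp"].size else float("nan")
    return out


def delta_normalize(
    t,
    y,
    bin_width: float,
    norm_window: tuple[float, float],
) -> pd.DataFrame:
    """Bin a feature time series and subtract the normalization-window mean.

    ``t``/``y`` are event times and values (e.g., per-spike thresholds);
    bins start at the first bin containing data.  Empty bins propagate as
    NaN.  Returns columns (bin_start, bin_mean, delta).
    """
    t = np.asarray(t, dtype=float)
    y = np.asarray(y, dtype=float)
    if t.shape != y.shape:
        raise ValueError("t and y must have equal length")
    lo, hi = norm_window
    if t.size and (lo < t.min() - bin_width or hi > t.max() + bin_width):
        pass  # a window slightly outside the data is tolerated; mask decides
    mask = (t >= lo) & (t < hi)
    if not np.any(mask):
        raise ValueError("normalization window contains no events")
    ref = float(np.nanmean(y[mask]))
    start = lo
    n_bins = int(np.ceil((t.max() - start) / bin_width)) if t.size else 0
    rows = []
    for b in range(max(n_bins, 1)):
        b0 = start + b * bin_width
        b1 = b0 + bin_width
        sel = (t >= b0) & (t < b1)
        mean = float(np.nanmean(y[sel])) if np.any(sel) else float("nan")
        rows.append({"bin_start": b0, "bin_mean": mean, "delta": mean - ref})
    return pd.DataFrame(rows)
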