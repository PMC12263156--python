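"""Least-squares fitting of Boltzmann gating curves and Hill dose-response.

The fits mirror how voltage-clamp electrophysiology is quantified: a
normalized conductance (activation) or current (inactivation) curve is fit
with a two-parameter Boltzmann, and normalized remaining current against
inhibitor dose is fit with a Hill curve whose midpoint is the IC50.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Any

import numpy as np
from scipy.optimize import least_squares

from .channel_kinetics import BoltzmannParams, boltzmann_activation, boltzmann_inactivation
from .asc_pharmacology import DoseResponseParams

__all__ = ["FitResult", "fit_boltzmann", "fit_hill", "fold_change"]


@dataclass
class FitResult:
    """Fitted parameters plus diagnostics.

    ``params`` is a domain object (BoltzmannParams or DoseResponseParams);
    ``stderr`` maps parameter names to asymptotic standard errors (NaN when
    the Jacobian is degenerate).
    """

    params: Any
    stderr: dict[str, float]
    residual_norm: float
    converged: bool
    n_points: int
    message: str = ""

    def __post_init__(self) -> None:
        if self.converged and not np.isfinite(self.residual_norm):
            raise ValueError("a converged fit must have a finite residual norm")


def _stderr_from_jac(res, names):
    """Asymptotic parameter standard errors from the LS Jacobian."""
    n, p = res.jac.shape
    dof = max(n - p, 1)
    s2 = 2.0 * res.cost / dof
    try:
        cov = s2 * np.linalg.inv(res.jac.T @ res.jac)
        se = np.sqrt(np.clip(np.diag(cov), 0.0, np.inf))
    except np.linalg.LinAlgError:
        se = np.full(p, np.nan)
    return dict(zip(names, (float(x) for x in se)))


def fit_boltzmann(v, y, kind: str = "activation", *, free_amplitude: bool = False) -> FitResult:
    """Fit a two-parameter Boltzmann to normalized curve data.

    Parameters
    ----------
    v : array of command/prepulse voltages (mV)
    y : normalized conductance (activation) or current (inactivation)
    kind : "activation" (rising) or "inactivation" (falling)
    free_amplitude : also fit a scale factor — appropriate when the
        voltage grid ends before the curve saturates, so normalizing to
        the largest measured point underestimates the plateau

    Deterministic initialization: v_half from the datum nearest y = 0.5 and
    the slope from a local finite difference, so noiseless data round-trips
    to solver precision.
    """
    if kind not in ("activation", "inactivation"):
        raise ValueError(f"unknown kind: {kind!r}")
    v = np.asarray(v, dtype=float)
    y = np.asarray(y, dtype=float)
    if v.shape != y.shape or v.ndim != 1:
        raise ValueError("v and y must be 1-d arrays of equal length")
    if v.size < 5:
        raise ValueError("need at least 5 points to fit a Boltzmann")
    if np.ptp(y) < 0.05:
        return FitResult(
            params=None, stderr={}, residual_norm=float("nan"),
            converged=False, n_points=v.size,
            message="curve is flat; v_half/slope unidentifiable",
        )

    order = np.argsort(v)
    vs, ys = v[order], y[order]
    model = boltzmann_activation if kind == "activation" else boltzmann_inactivation

    i0 = int(np.argmin(np.abs(ys - 0.5)))
    v0 = float(vs[i0])
    j = min(max(i0, 1), vs.size - 1)
    dy_dv = (ys[j] - ys[j - 1]) / (vs[j] - vs[j - 1])
    # Boltzmann midpoint slope is ±1/(4 sf)
    sf0 = 1.0 / max(abs(dy_dv) * 4.0, 1e-3)
    sf0 = float(np.clip(sf0, 0.5, 50.0))

    def resid(theta):
        p = BoltzmannParams(theta[0], max(theta[1], 1e-6))
        amp = theta[2] if free_amplitude else 1.0
        return amp * model(vs, p) - ys

    x0 = [v0, sf0] + ([1.0] if free_amplitude else [])
    lo = [-150.0, 1e-3] + ([0.05] if free_amplitude else [])
    hi = [80.0, 100.0] + ([20.0] if free_amplitude else [])
    res = least_squares(resid, x0=x0, bounds=(lo, hi),
                        xtol=1e-14, ftol=1e-14, gtol=1e-14)
    params = BoltzmannParams(float(res.x[0]), float(res.x[1]))
    names = ("v_half", "slope_factor") + (("amplitude",) if free_amplitude else ())
    return FitResult(
        params=params,
        stderr=_stderr_from_jac(res, names),
        residual_norm=float(np.linalg.norm(res.fun)),
        converged=bool(res.success),
        n_points=v.size,
        message=res.message,
    )


def fit_hill(dose, response, *, fix_hill_n: float | None = 1.0) -> FitResult:
    """Fit remaining-current dose-response: y = ic50^n / (ic50^n + dose^n).

    ``dose`` in nM spanning at least two log units; ``response`` is current
    normalized to the drug-free baseline.  The Hill coefficient is fixed at
    1 by default (free it with ``fix_hill_n=None``); fitting is done in
    log-dose space for conditioning.
    """
    dose = np.asarray(dose, dtype=float)
    response = np.asarray(response, dtype=float)
    if dose.shape != response.shape or dose.ndim != 1:
        raise ValueError("dose and response must be 1-d arrays of equal length")
    if dose.size < 4:
        raise ValueError("need at least 4 doses")
    if np.any(dose <= 0):
        raise ValueError("doses must be positive (nM)")
    if np.log10(dose.max() / dose.min()) < 2.0:
        raise ValueError("dose grid must span at least two log units")
    if np.ptp(response) < 0.02:
        return FitResult(
            params=None, stderr={}, residual_norm=float("nan"),
            converged=False, n_points=dose.size,
            message="responses are all equal; IC50 unidentifiable",
        )

    order = np.argsort(dose)
    d, y = dose[order], response[order]
    logd = np.log10(d)

    # log-interpolate the half-response dose for the start value
    below = np.where(y <= 0.5)[0]
    if below.size and below[0] > 0:
        k = below[0]
        f = (0.5 - y[k - 1]) / (y[k] - y[k - 1])
        log_ic50_0 = logd[k - 1] + f * (logd[k] - logd[k - 1])
    else:
        log_ic50_0 = float(np.median(logd))

    free_n = fix_hill_n is None

    def resid(theta):
        lic50 = theta[0]
        n = theta[1] if free_n else fix_hill_n
        ld = n * (logd - lic50)  # log10 of (dose/ic50)^n
        return 1.0 / (1.0 + np.power(10.0, ld)) - y

    x0 = [log_ic50_0, 1.0] if free_n else [log_ic50_0]
    lo = [-3.0, 0.05] if free_n else [-3.0]
    hi = [9.0, 10.0] if free_n else [9.0]
    res = least_squares(resid, x0=x0, bounds=(lo, hi), xtol=1e-15, ftol=1e-15, gtol=1e-15)

    ic50 = float(10.0 ** res.x[0])
    hill_n = float(res.x[1]) if free_n else float(fix_hill_n)
    # delta-method stderr for ic50 from the log-space error
    se = _stderr_from_jac(res, ("log10_ic50", "hill_n") if free_n else ("log10_ic50",))
    stderr = {"ic50": ic50 * np.log(10.0) * se["log10_ic50"]}
    if free_n:
        stderr["hill_n"] = se["hill_n"]
    return FitResult(
        params=DoseResponseParams(ic50=ic50, hill_n=hill_n),
        stderr=stderr,
        residual_norm=float(np.linalg.norm(res.fun)),
        converged=bool(res.success),
        n_points=dose.size,
        message=res.message,
    )


def fold_change(a: float, b: float) -> float:
    """Potency ratio b/a (e.g., SR-mutant IC50 over wildtype IC50)."""
    if not a > 0:
        raise ValueError("reference potency must be positive")
    return b / a
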