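"""Feature extraction from K+ current traces.

Experimental summed currents are conventionally apportioned into components by
exponential fitting: a single decaying exponential plus offset,
I = A e^{-t/tau} + C, for one component, or a bi-exponential with constant,

    I_Ksum = A_Kto e^{-t/tau_Kto} + A_Kslow e^{-t/tau_Kslow} + A_Kss,

for the summed current.  Amplitude refers to the peak value and tau to the
e^-1 decay time.  The same extraction is applied to simulated traces so that
simulation and experiment are summarized identically.

Fitting uses variable projection: for fixed time constants the amplitudes and
offset are linear, so they are profiled out exactly and the search runs only
over (log) time constants.  This removes any dependence on amplitude starting
values and makes the noiseless round trip exact to optimizer precision.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize, minimize_scalar, nnls

from .clamp import CurrentTrace

__all__ = [
    "TraceFeatures",
    "BiexpFit",
    "find_peak",
    "fit_monoexp",
    "fit_biexp",
    "extract_calibration_features",
]

#: multi-start time-constant grid (ms) for the bi-exponential fit
TAU_FAST_GRID = (10.0, 50.0, 100.0)
TAU_SLOW_GRID = (500.0, 1200.0, 2000.0)


@dataclass
class TraceFeatures:
    """Mono-exponential decay features: I(t) = A e^{-t/tau} + C."""

    A: float
    tau: float
    C: float
    rss: float = np.nan
    converged: bool = True
    method: str = "profiled-ls"
    message: str = ""


@dataclass
class BiexpFit:
    """Bi-exponential decomposition of a summed current trace.

    Component identity is assigned by time-constant ordering: the faster
    exponential is labeled Kto, the slower Kslow, and the constant Kss.
    """

    A_Kto: float
    tau_Kto: float
    A_Kslow: float
    tau_Kslow: float
    A_Kss: float
    rss: float
    converged: bool = True
    degenerate: bool = False
    message: str = ""


def find_peak(trace: CurrentTrace) -> tuple[float, float]:
    """Time and value of the maximum current over the step window (t >= 0).

    Ties are broken by the earliest sample.
    """
    step = trace.step_window()
    if len(step.t) == 0:
        raise ValueError("trace has no samples in the step window (t >= 0)")
    if np.all(np.isnan(step.I)):
        raise ValueError("trace is all-NaN over the step window")
    idx = int(np.nanargmax(step.I))
    return float(step.t[idx]), float(step.I[idx])


def _profile_monoexp(t: np.ndarray, y: np.ndarray, tau: float):
    """Least-squares (A, C) and rss for fixed tau (2x2 normal equations)."""
    e = np.exp(-t / tau)
    n = len(t)
    se, see = e.sum(), (e * e).sum()
    sy, sey = y.sum(), (e * y).sum()
    det = see * n - se * se
    if det <= 0:
        return np.nan, np.nan, np.inf
    A = (sey * n - se * sy) / det
    C = (sy - A * se) / n
    r = y - (A * e + C)
    return A, C, float(r @ r)


def fit_monoexp(
    trace_or_t,
    y=None,
    tau_bounds: tuple[float, float] = (1e-2, 1e6),
) -> TraceFeatures:
    """Fit I = A e^{-t/tau} + C to a post-peak decay segment.

    Accepts a CurrentTrace (fitted from its peak to the end of the step) or
    explicit (t, y) arrays with t relative to the segment origin.  The
    amplitude reported is the fitted value at the segment origin.  A flat
    segment leaves tau unidentifiable and returns a flagged result.
    """
    if isinstance(trace_or_t, CurrentTrace):
        step = trace_or_t.step_window()
        t_pk, _ = find_peak(trace_or_t)
        m = step.t >= t_pk
        t = step.t[m] - t_pk
        y = step.I[m]
    else:
        t = np.asarray(trace_or_t, dtype=float)
        y = np.asarray(y, dtype=float)
    if len(t) < 10:
        raise ValueError(f"need at least 10 samples to fit, got {len(t)}")

    spread = float(np.max(y) - np.min(y))
    scale = max(1.0, float(np.max(np.abs(y))))
    if spread <= 1e-12 * scale:
        return TraceFeatures(
            A=0.0,
            tau=np.nan,
            C=float(np.mean(y)),
            rss=0.0,
            converged=False,
            message="segment is constant; time constant unidentifiable",
        )

    lo, hi = np.log(tau_bounds[0]), np.log(tau_bounds[1])
    res = minimize_scalar(
        lambda lt: _profile_monoexp(t, y, np.exp(lt))[2],
        bounds=(lo, hi),
        method="bounded",
        options={"xatol": 1e-12},
    )
    tau = float(np.exp(res.x))
    A, C, rss = _profile_monoexp(t, y, tau)
    ok = bool(res.success) and np.isfinite(A) and np.isfinite(C)
    at_edge = res.x < lo + 1e-6 or res.x > hi - 1e-6
    return TraceFeatures(
        A=float(A),
        tau=tau,
        C=float(C),
        rss=rss,
        converged=ok and not at_edge,
        message="tau at search bound" if at_edge else "",
    )


def _biexp_design(t: np.ndarray, tau1: float, tau2: float) -> np.ndarray:
    return np.column_stack([np.exp(-t / tau1), np.exp(-t / tau2), np.ones_like(t)])


def _profile_biexp(t, y, tau1, tau2, nonneg):
    X = _biexp_design(t, tau1, tau2)
    if nonneg:
        coef, _ = nnls(X, y)
    else:
        coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    r = y - X @ coef
    return coef, float(r @ r)


def fit_biexp(
    trace: CurrentTrace,
    nonneg: bool = True,
    tau_grid=None,
) -> BiexpFit:
    """Five-parameter bi-exponential-plus-constant fit of the post-peak decay.

    Multi-started over a log-spaced grid of time-constant pairs (amplitudes
    obtained by linear least squares given the pair), then refined by
    Nelder-Mead over (log tau1, log tau2).  Amplitudes are constrained
    nonnegative by default (outward currents).  Labels follow the ordering
    rule tau_Kto < tau_Kslow.
    """
    step = trace.step_window()
    t_pk, _ = find_peak(trace)
    m = step.t >= t_pk
    t = step.t[m] - t_pk
    y = step.I[m]
    if len(t) < 100:
        raise ValueError(f"need at least 100 decay samples, got {len(t)}")

    if tau_grid is None:
        tau_grid = list(itertools.product(TAU_FAST_GRID, TAU_SLOW_GRID))

    best = None
    for tau1, tau2 in tau_grid:
        _, rss = _profile_biexp(t, y, tau1, tau2, nonneg)
        if best is None or rss < best[2]:
            best = (tau1, tau2, rss)

    x0 = np.log([best[0], best[1]])

    def objective(lt):
        return _profile_biexp(t, y, np.exp(lt[0]), np.exp(lt[1]), nonneg)[1]

    res = minimize(
        objective,
        x0,
        method="Nelder-Mead",
        options={"xatol": 1e-12, "fatol": 1e-24, "maxiter": 4000},
    )
    tau1, tau2 = np.exp(res.x)
    coef, rss = _profile_biexp(t, y, tau1, tau2, nonneg)
    # ordering rule: the faster component is Kto
    if tau1 > tau2:
        tau1, tau2 = tau2, tau1
        coef = np.array([coef[1], coef[0], coef[2]])
    degenerate = abs(tau1 - tau2) / max(tau2, 1e-12) < 1e-3
    return BiexpFit(
        A_Kto=float(coef[0]),
        tau_Kto=float(tau1),
        A_Kslow=float(coef[1]),
        tau_Kslow=float(tau2),
        A_Kss=float(coef[2]),
        rss=rss,
        converged=bool(np.isfinite(rss)),
        degenerate=degenerate,
        message="time constants collapsed" if degenerate else "",
    )


def extract_calibration_features(trace: CurrentTrace) -> tuple[float, float]:
    """Amplitude and time constant of a single-current trace.

    The amplitude is the peak current density over the step; the time constant
    comes from the mono-exponential fit of the post-peak decay, so simulated
    and experimental traces are processed through the same estimator.
    """
    _, peak = find_peak(trace)
    feats = fit_monoexp(trace)
    if not feats.converged:
        raise RuntimeError(
            f"time-constant fit did not converge for {trace.kind} at "
            f"{trace.v_step} mV: {feats.message}"
        )
    return peak, feats.tau
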