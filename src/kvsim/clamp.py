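"""Whole-cell voltage-clamp simulation of the Kv current models.

The clamp holds the cell at ``V_hold``, then steps to each test potential for
``t_step`` milliseconds.  Because the potential is piecewise constant, the
gate ODEs are linear within each phase and admit the exact solution

    g(t) = g_inf + (g0 - g_inf) * exp(-t / tau),

which is the default simulation back-end; a scipy ``solve_ivp`` integration of
the same ODEs is provided as an independent numerical route and the two are
required to agree closely.

Time convention: t = 0 at step onset; holding-period samples carry negative t.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .models import GateState, KslowModel, KtoModel, hh_curves, model_for
from .params import KslowParams, KtoParams, ModelConstants

__all__ = [
    "ClampProtocol",
    "SolverOptions",
    "CurrentTrace",
    "gate_closed_form",
    "simulate_current",
    "simulate_iksum",
    "iv_peak_curve",
    "tau_voltage_curve",
    "ssi_curve",
]

DEFAULT_STEPS = tuple(range(-60, 51, 10))


@dataclass(frozen=True)
class ClampProtocol:
    """Voltage-clamp protocol: hold at ``v_hold``, step to each of ``v_steps``.

    Defaults mirror the experimental protocol (hold -70 mV, 4.5-s steps) with
    the simulated step range -60..+50 mV in 10-mV increments.
    """

    v_hold: float = -70.0
    t_hold: float = 1000.0
    v_steps: Sequence[float] = DEFAULT_STEPS
    t_step: float = 4500.0
    dt_out: float = 1.0

    def __post_init__(self) -> None:
        if self.t_step <= 0 or self.dt_out <= 0:
            raise ValueError("t_step and dt_out must be positive")
        if self.t_hold < 0:
            raise ValueError("t_hold must be nonnegative")
        if len(self.v_steps) == 0:
            raise ValueError("v_steps must be non-empty")

    def time_grid(self) -> np.ndarray:
        """Output samples: holding phase at negative t, step phase from 0."""
        n_hold = int(round(self.t_hold / self.dt_out))
        t_hold = -self.dt_out * np.arange(n_hold, 0, -1)
        n_step = int(round(self.t_step / self.dt_out))
        t_step = self.dt_out * np.arange(0, n_step + 1)
        return np.concatenate([t_hold, t_step])


@dataclass(frozen=True)
class SolverOptions:
    """Simulation back-end selection and tolerances.

    ``init='steady_state_at_hold'`` starts the gates at their equilibrium for
    the holding potential, which keeps the pre-step current exactly constant;
    pass a GateState for custom initialization.
    """

    method: str = "analytic"
    rel_tol: float = 1e-8
    abs_tol: float = 1e-10
    init: str | GateState = "steady_state_at_hold"

    def __post_init__(self) -> None:
        if self.method not in ("analytic", "ode"):
            raise ValueError("method must be 'analytic' or 'ode'")
        if self.rel_tol <= 0 or self.abs_tol <= 0:
            raise ValueError("solver tolerances must be positive")


@dataclass
class CurrentTrace:
    """A sampled current-density time series for one voltage step."""

    t: np.ndarray
    I: np.ndarray
    v_step: float
    kind: str
    v_hold: float = -70.0

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.I = np.asarray(self.I, dtype=float)
        if len(self.t) != len(self.I):
            raise ValueError("time and current arrays must have equal length")
        if len(self.t) > 1 and not np.all(np.diff(self.t) > 0):
            raise ValueError("time grid must be strictly increasing")

    def step_window(self) -> "CurrentTrace":
        """The depolarization phase (t >= 0) of the trace."""
        m = self.t >= 0
        return CurrentTrace(self.t[m], self.I[m], self.v_step, self.kind, self.v_hold)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time_ms": self.t,
                "current_pApf": self.I,
                "v_step_mv": self.v_step,
                "kind": self.kind,
            }
        )


def gate_closed_form(g_inf: float, tau: float, g0: float, t) -> np.ndarray:
    """Exact relaxation of a gate at constant voltage.

    g(t) = g_inf + (g0 - g_inf) e^{-t/tau}; equals g0 at t = 0 and tends to
    g_inf as t grows.
    """
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("time offsets must be nonnegative")
    if tau <= 0:
        raise ValueError("time constant must be positive")
    return g_inf + (g0 - g_inf) * np.exp(-t / tau)


def _initial_gates(model, proto: ClampProtocol, opts: SolverOptions) -> GateState:
    if isinstance(opts.init, GateState):
        return opts.init
    if opts.init == "steady_state_at_hold":
        return model.steady_gates(proto.v_hold)
    raise ValueError(f"unknown init mode {opts.init!r}")


def _gates_analytic(model, proto, v_step, g0: GateState, t: np.ndarray):
    """Piecewise closed-form gate trajectories over the full output grid."""
    hold = model.curves(proto.v_hold)
    step = model.curves(v_step)
    a = np.empty_like(t)
    i = np.empty_like(t)
    m_hold = t < 0
    # holding phase runs from -t_hold; elapsed time is t + t_hold
    th = t[m_hold] + proto.t_hold
    a[m_hold] = gate_closed_form(float(hold.a_ss), float(hold.tau_a), g0.a, th)
    i[m_hold] = gate_closed_form(float(hold.i_ss), float(hold.tau_i), g0.i, th)
    # gate values at step onset
    a0 = gate_closed_form(float(hold.a_ss), float(hold.tau_a), g0.a, proto.t_hold)
    i0 = gate_closed_form(float(hold.i_ss), float(hold.tau_i), g0.i, proto.t_hold)
    ts = t[~m_hold]
    a[~m_hold] = gate_closed_form(float(step.a_ss), float(step.tau_a), float(a0), ts)
    i[~m_hold] = gate_closed_form(float(step.i_ss), float(step.tau_i), float(i0), ts)
    return a, i


def _gates_ode(model, proto, v_step, g0: GateState, t: np.ndarray, opts):
    """solve_ivp integration of dg/dt = (g_inf - g)/tau, one phase at a time."""

    def rhs_at(V):
        c = model.curves(V)
        a_ss, i_ss = float(c.a_ss), float(c.i_ss)
        tau_a, tau_i = float(c.tau_a), float(c.tau_i)

        def rhs(_t, y):
            return [(a_ss - y[0]) / tau_a, (i_ss - y[1]) / tau_i]

        return rhs

    a = np.empty_like(t)
    i = np.empty_like(t)
    y0 = [g0.a, g0.i]
    m_hold = t < 0
    if proto.t_hold > 0:
        t_eval = np.concatenate([t[m_hold] + proto.t_hold, [proto.t_hold]])
        sol = solve_ivp(
            rhs_at(proto.v_hold),
            (0.0, proto.t_hold),
            y0,
            method="LSODA",
            t_eval=t_eval,
            rtol=opts.rel_tol,
            atol=opts.abs_tol,
        )
        if not sol.success:
            raise RuntimeError(
                f"gate ODE integration failed during holding phase: {sol.message}"
            )
        a[m_hold] = sol.y[0][:-1]
        i[m_hold] = sol.y[1][:-1]
        y0 = [sol.y[0][-1], sol.y[1][-1]]
    ts = t[~m_hold]
    sol = solve_ivp(
        rhs_at(v_step),
        (0.0, float(ts[-1])),
        y0,
        method="LSODA",
        t_eval=ts,
        rtol=opts.rel_tol,
        atol=opts.abs_tol,
    )
    if not sol.success:
        raise RuntimeError(
            f"gate ODE integration failed at step {v_step} mV "
            f"(rtol={opts.rel_tol}, atol={opts.abs_tol}): {sol.message}"
        )
    a[~m_hold] = sol.y[0]
    i[~m_hold] = sol.y[1]
    return a, i


def _as_model(kind_or_model, p=None, c=ModelConstants()):
    if isinstance(kind_or_model, (KtoModel, KslowModel)):
        return kind_or_model
    if p is None:
        raise ValueError("parameters required when passing a kind string")
    model = model_for(p, c)
    if kind_or_model is not None and model.kind.lower() != str(kind_or_model).lower():
        raise ValueError(f"kind {kind_or_model!r} does not match params {p.kind}")
    return model


def simulate_current(
    kind,
    p=None,
    proto: ClampProtocol = ClampProtocol(),
    opts: SolverOptions = SolverOptions(),
    c: ModelConstants = ModelConstants(),
) -> list[CurrentTrace]:
    """Simulate the clamp protocol; one CurrentTrace per step potential.

    Accepts either a model instance or a (kind, params) pair.  Gates start per
    ``opts.init`` (default: equilibrium at the holding potential), relax during
    the holding phase, then relax toward the step-potential equilibrium; the
    current is Gg(V - E_K) with the kind's activation exponent at each sample.
    """
    model = _as_model(kind, p, c)
    t = proto.time_grid()
    g0 = _initial_gates(model, proto, opts)
    traces = []
    for v_step in proto.v_steps:
        if opts.method == "analytic":
            a, i = _gates_analytic(model, proto, v_step, g0, t)
        else:
            a, i = _gates_ode(model, proto, v_step, g0, t, opts)
        V = np.where(t < 0, proto.v_hold, float(v_step))
        I = model.current_from_gates(a, i, V)
        traces.append(
            CurrentTrace(t, I, float(v_step), model.kind, v_hold=proto.v_hold)
        )
    return traces


def simulate_iksum(
    p_kto: KtoParams,
    p_kslow: KslowParams,
    a_kss: float = 0.0,
    proto: ClampProtocol = ClampProtocol(),
    opts: SolverOptions = SolverOptions(),
    c: ModelConstants = ModelConstants(),
) -> list[CurrentTrace]:
    """Summed K+ current: I_Kto + I_Kslow plus the constant I_Kss offset.

    I_Kss is treated as a voltage-independent constant present during the
    depolarizing step only (zero while holding), matching its role as the
    non-inactivating offset in the bi-exponential decomposition.
    """
    if a_kss < 0:
        raise ValueError("a_kss must be nonnegative")
    kto = simulate_current(KtoModel(p_kto, c), proto=proto, opts=opts)
    kslow = simulate_current(KslowModel(p_kslow, c), proto=proto, opts=opts)
    traces = []
    for tr_to, tr_sl in zip(kto, kslow):
        if tr_to.v_step != tr_sl.v_step or len(tr_to.t) != len(tr_sl.t):
            raise ValueError("component traces use mismatched protocols")
        I = tr_to.I + tr_sl.I + a_kss * (tr_to.t >= 0)
        traces.append(
            CurrentTrace(tr_to.t, I, tr_to.v_step, "Ksum", v_hold=proto.v_hold)
        )
    return traces


def iv_peak_curve(
    kind,
    p=None,
    proto: ClampProtocol = ClampProtocol(),
    opts: SolverOptions = SolverOptions(),
    c: ModelConstants = ModelConstants(),
) -> pd.DataFrame:
    """Peak current density over the step window at each step potential."""
    traces = simulate_current(kind, p, proto, opts, c)
    rows = []
    for tr in traces:
        step = tr.step_window()
        rows.append({"v_step_mv": tr.v_step, "peak_pApf": float(np.max(step.I))})
    return pd.DataFrame(rows)


def tau_voltage_curve(kind, p, V=None) -> pd.DataFrame:
    """Analytic inactivation time constant versus voltage.

    For I_Kslow this is tau_i(V) = x6 - 170/(1+e^{(V+x7)/x8}); for I_Kto it is
    1/(alpha_i + beta_i)(V).
    """
    if V is None:
        V = np.array(DEFAULT_STEPS, dtype=float)
    V = np.asarray(V, dtype=float)
    tau_i = hh_curves(V, p).tau_i
    return pd.DataFrame({"v_mv": V, "tau_ms": np.atleast_1d(tau_i)})


def ssi_curve(kind, p, V=None) -> pd.DataFrame:
    """Steady-state inactivation (channel availability) versus voltage."""
    if V is None:
        V = np.array(DEFAULT_STEPS, dtype=float)
    V = np.asarray(V, dtype=float)
    i_ss = hh_curves(V, p).i_ss
    return pd.DataFrame({"v_mv": V, "i_ss": np.atleast_1d(i_ss)})
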