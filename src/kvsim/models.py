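"""Hodgkin-Huxley gating kinetics and instantaneous currents.

Both currents follow the classic two-gate scheme: an activation gate ``a`` and
an inactivation gate ``i``, each relaxing toward a voltage-dependent steady
state with a voltage-dependent time constant,

    dg/dt = (g_inf(V) - g) / tau_g(V).

I_Kto is parameterized through transition rates (alpha, beta) with
g_inf = alpha/(alpha+beta) and tau = 1/(alpha+beta); I_Kslow directly through
(g_inf, tau) curves.  Instantaneous currents:

    I_Kto   = Gto * a^3 * i * (V - E_K)
    I_Kslow = Gr  * a   * i * (V - E_K)
"""

from __future__ import annotations

from typing import NamedTuple

import numpy as np

from .params import KslowParams, KtoParams, ModelConstants

__all__ = [
    "RateSet",
    "CurveSet",
    "GateState",
    "kto_rates",
    "kto_hh_curves",
    "kslow_curves",
    "hh_curves",
    "instantaneous_current",
    "KtoModel",
    "KslowModel",
    "model_for",
]


class RateSet(NamedTuple):
    """Transition rates in 1/ms (positive for finite V)."""

    alpha_a: np.ndarray
    beta_a: np.ndarray
    alpha_i: np.ndarray
    beta_i: np.ndarray


class CurveSet(NamedTuple):
    """Steady states (dimensionless, in (0,1)) and time constants (ms)."""

    a_ss: np.ndarray
    i_ss: np.ndarray
    tau_a: np.ndarray
    tau_i: np.ndarray


class GateState(NamedTuple):
    """Activation/inactivation gate values, each in [0, 1]."""

    a: float
    i: float


def _check_voltage(V) -> np.ndarray:
    V = np.asarray(V, dtype=float)
    if not np.all(np.isfinite(V)):
        raise ValueError("membrane potential must be finite")
    return V


def kto_rates(V, p: KtoParams) -> RateSet:
    """Transition rates of the I_Kto gates at potential ``V`` (mV).

    alpha_a = 0.18064 e^{0.03577 (V+x1)}
    beta_a  = 0.395   e^{-0.06237 (V+x2)}
    alpha_i = 0.000152 e^{-(V+x3)/x4} / (0.067083 e^{-(V+x5)/x4} + 1)
    beta_i  = 0.00095  e^{(V+x6)/x7}  / (0.051335 e^{(V+x6)/x7} + 1)
    """
    V = _check_voltage(V)
    alpha_a = 0.18064 * np.exp(0.03577 * (V + p.x1))
    beta_a = 0.395 * np.exp(-0.06237 * (V + p.x2))
    alpha_i = 0.000152 * np.exp(-(V + p.x3) / p.x4) / (
        0.067083 * np.exp(-(V + p.x5) / p.x4) + 1.0
    )
    beta_i = 0.00095 * np.exp((V + p.x6) / p.x7) / (
        0.051335 * np.exp((V + p.x6) / p.x7) + 1.0
    )
    return RateSet(alpha_a, beta_a, alpha_i, beta_i)


def kto_hh_curves(V, p: KtoParams) -> CurveSet:
    """Steady states and time constants of I_Kto via the HH identities."""
    r = kto_rates(V, p)
    sa = r.alpha_a + r.beta_a
    si = r.alpha_i + r.beta_i
    return CurveSet(r.alpha_a / sa, r.alpha_i / si, 1.0 / sa, 1.0 / si)


def kslow_curves(V, p: KslowParams) -> CurveSet:
    """Steady states and time constants of I_Kslow.

    a_ss  = 1/(1+e^{-(V+x1)/x2})          tau_a = 0.493 e^{-0.0629 V} + x5
    i_ss  = 1/(1+e^{(V+x3)/x4})           tau_i = x6 - 170/(1+e^{(V+x7)/x8})
    """
    V = _check_voltage(V)
    a_ss = 1.0 / (1.0 + np.exp(-(V + p.x1) / p.x2))
    i_ss = 1.0 / (1.0 + np.exp((V + p.x3) / p.x4))
    tau_a = 0.493 * np.exp(-0.0629 * V) + p.x5
    tau_i = p.x6 - 170.0 / (1.0 + np.exp((V + p.x7) / p.x8))
    return CurveSet(a_ss, i_ss, tau_a, tau_i)


def hh_curves(V, p: KtoParams | KslowParams) -> CurveSet:
    """Dispatch to the appropriate curve set for the parameter kind."""
    if isinstance(p, KtoParams):
        return kto_hh_curves(V, p)
    return kslow_curves(V, p)


def _check_gates(g: GateState) -> None:
    a = np.asarray(g.a, dtype=float)
    i = np.asarray(g.i, dtype=float)
    if np.any((a < 0) | (a > 1)) or np.any((i < 0) | (i > 1)):
        raise ValueError(f"gate values must lie in [0, 1], got a={g.a}, i={g.i}")


def instantaneous_current(
    kind: str,
    g: GateState,
    V,
    p: KtoParams | KslowParams,
    c: ModelConstants = ModelConstants(),
):
    """Current density (pA/pF) for given gate values and potential.

    I_Kto carries a cubed activation gate; I_Kslow a linear one.  The sign
    follows the driving force (V - E_K).
    """
    _check_gates(g)
    V = _check_voltage(V)
    a = np.asarray(g.a, dtype=float)
    i = np.asarray(g.i, dtype=float)
    if kind == "Kto":
        gate = a**3 * i
    elif kind == "Kslow":
        gate = a * i
    else:
        raise ValueError(f"unknown current kind {kind!r}")
    return p.conductance * gate * (V - c.E_K)


class _KvModel:
    """Mechanistic model of a single Kv current under voltage control."""

    kind: str
    activation_exponent: int

    def __init__(self, params, constants: ModelConstants = ModelConstants()):
        self.params = params
        self.constants = constants

    def curves(self, V) -> CurveSet:
        raise NotImplementedError

    def steady_gates(self, V) -> GateState:
        """Equilibrium gate values at constant potential ``V``."""
        c = self.curves(V)
        return GateState(float(c.a_ss), float(c.i_ss))

    def current(self, g: GateState, V):
        return instantaneous_current(self.kind, g, V, self.params, self.constants)

    def current_from_gates(self, a, i, V):
        """Vectorized current without gate-bound validation (internal hot path)."""
        return (
            self.params.conductance
            * np.asarray(a) ** self.activation_exponent
            * np.asarray(i)
            * (V - self.constants.E_K)
        )

    def __repr__(self) -> str:
        return f"{type(self).__name__}({self.params!r})"


class KtoModel(_KvModel):
    kind = "Kto"
    activation_exponent = 3

    def __init__(self, params: KtoParams | None = None, constants=ModelConstants()):
        super().__init__(params if params is not None else KtoParams(), constants)

    def rates(self, V) -> RateSet:
        return kto_rates(V, self.params)

    def curves(self, V) -> CurveSet:
        return kto_hh_curves(V, self.params)


class KslowModel(_KvModel):
    kind = "Kslow"
    activation_exponent = 1

    def __init__(self, params: KslowParams | None = None, constants=ModelConstants()):
        super().__init__(params if params is not None else KslowParams(), constants)

    def curves(self, V) -> CurveSet:
        return kslow_curves(V, self.params)


def model_for(params: KtoParams | KslowParams, constants=ModelConstants()) -> _KvModel:
    """Wrap a parameter vector in the matching model class."""
    if isinstance(params, KtoParams):
        return KtoModel(params, constants)
    if isinstance(params, KslowParams):
        return KslowModel(params, constants)
    raise TypeError(f"unsupported parameter type {type(params).__name__}")
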