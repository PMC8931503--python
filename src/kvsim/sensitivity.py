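"""Two-level full factorial screening of model-parameter effects.

Before calibration, the parameter set is screened for the entries that
actually move the two target responses -- amplitude A and inactivation time
constant tau at a depolarizing step.  Every parameter is assigned a low and a
high level (default: -+20% around its literature default), all 2^p level
combinations are simulated, and the main effect of each factor on each
response is the difference between the mean response at its high level and at
its low level.  Effects are also standardized by the response range across the
design so that A-effects (pA/pF) and tau-effects (ms) can be ranked together.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .clamp import ClampProtocol, SolverOptions, simulate_current
from .features import extract_calibration_features
from .models import model_for

__all__ = [
    "FactorialDesign",
    "EffectTable",
    "two_level_design",
    "evaluate_design",
    "main_effects",
    "screen_parameters",
]

MAX_FACTORS = 12


@dataclass
class FactorialDesign:
    """Coded (-1/+1) full factorial design in standard order.

    The first factor alternates fastest; row q has factor j at +1 iff bit j of
    q is set, giving rows (-,-), (+,-), (-,+), (+,+) for p = 2.
    """

    factors: list
    low: dict
    high: dict
    runs: np.ndarray

    @property
    def n_runs(self) -> int:
        return len(self.runs)

    def levels(self) -> pd.DataFrame:
        """Actual (uncoded) parameter values for each run."""
        cols = {}
        for j, name in enumerate(self.factors):
            cols[name] = np.where(
                self.runs[:, j] > 0, self.high[name], self.low[name]
            )
        return pd.DataFrame(cols)


@dataclass
class EffectTable:
    """Main effects per factor and response, with a combined ranking.

    ``effect_A``/``effect_tau`` are in response units (pA/pF, ms);
    ``std_effect_*`` are the same divided by the response range over all runs.
    ``rank`` orders factors by the larger standardized absolute effect.
    """

    table: pd.DataFrame

    def ranking(self) -> list:
        return list(self.table.sort_values("rank").index)

    def __repr__(self) -> str:
        return f"EffectTable(\n{self.table}\n)"


def two_level_design(factors, low, high) -> FactorialDesign:
    """Full 2^p factorial design over the named factors.

    ``low``/``high`` map factor name to its two levels (low < high).  Refuses
    p > 12 (4096 runs); subset the factors instead.
    """
    factors = list(factors)
    p = len(factors)
    if p == 0:
        raise ValueError("need at least one factor")
    if p > MAX_FACTORS:
        raise ValueError(
            f"{p} factors would need 2^{p} runs; screen at most {MAX_FACTORS} "
            "at a time (split the factor set)"
        )
    for name in factors:
        if name not in low or name not in high:
            raise ValueError(f"missing levels for factor {name!r}")
        if not low[name] < high[name]:
            raise ValueError(
                f"factor {name!r}: low level {low[name]} must be < high "
                f"level {high[name]}"
            )
    q = np.arange(2**p)
    runs = np.where((q[:, None] >> np.arange(p)) & 1, 1, -1).astype(float)
    return FactorialDesign(factors, dict(low), dict(high), runs)


def centered_levels(base, factors=None, spread: float = 0.2):
    """Multiplicative -+``spread`` levels around a parameter vector's values."""
    if factors is None:
        factors = [f.name for f in dataclasses.fields(type(base))]
    low = {n: (1 - spread) * getattr(base, n) for n in factors}
    high = {n: (1 + spread) * getattr(base, n) for n in factors}
    # negative defaults would flip the ordering
    for n in factors:
        if low[n] > high[n]:
            low[n], high[n] = high[n], low[n]
    return list(factors), low, high


def evaluate_design(
    design: FactorialDesign,
    kind: str,
    base,
    proto: ClampProtocol | None = None,
    v_step: float = 50.0,
    max_failed_fraction: float = 0.1,
) -> pd.DataFrame:
    """Simulate every design run and extract (A, tau) at ``v_step``.

    Failed runs are recorded as NaN; more than ``max_failed_fraction`` of
    failures aborts with a diagnostic.
    """
    if base.kind != kind.capitalize() and base.kind.lower() != kind.lower():
        raise ValueError(f"base parameters are {base.kind}, requested {kind}")
    if proto is None:
        proto = ClampProtocol()
    proto = dataclasses.replace(proto, t_hold=0.0, v_steps=(v_step,))
    opts = SolverOptions(method="analytic")
    levels = design.levels()
    rows = []
    failures = []
    for r in range(design.n_runs):
        params = base.replace(**{n: float(levels.iloc[r][n]) for n in design.factors})
        try:
            trace = simulate_current(model_for(params), proto=proto, opts=opts)[0]
            A, tau = extract_calibration_features(trace)
        except Exception as exc:
            failures.append((r, str(exc)))
            A, tau = np.nan, np.nan
        rows.append({"run": r, "A": A, "tau": tau})
    if len(failures) > max_failed_fraction * design.n_runs:
        detail = "; ".join(f"run {r}: {msg}" for r, msg in failures[:5])
        raise RuntimeError(
            f"{len(failures)}/{design.n_runs} design runs failed ({detail})"
        )
    return pd.DataFrame(rows).set_index("run")


def main_effects(design: FactorialDesign, responses: pd.DataFrame) -> EffectTable:
    """Main effect of each factor: mean(high) - mean(low), per response.

    Standardized effects divide by the response range across all runs; a
    zero-variance response yields standardized effects of 0.
    """
    if len(responses) != design.n_runs:
        raise ValueError("responses do not match the design run count")
    used = responses[["A", "tau"]].dropna()
    runs = design.runs[used.index.to_numpy()]
    out = {}
    for col in ("A", "tau"):
        y = used[col].to_numpy()
        rng = float(np.max(y) - np.min(y))
        eff = np.array(
            [y[runs[:, j] > 0].mean() - y[runs[:, j] < 0].mean()
             for j in range(len(design.factors))]
        )
        out[f"effect_{col}"] = eff
        out[f"std_effect_{col}"] = eff / rng if rng > 0 else np.zeros_like(eff)
    table = pd.DataFrame(out, index=pd.Index(design.factors, name="factor"))
    strength = np.maximum(
        table["std_effect_A"].abs(), table["std_effect_tau"].abs()
    )
    # rank 1 = strongest; stable order on exact ties
    order = np.argsort(-strength.to_numpy(), kind="stable")
    rank = np.empty(len(order), dtype=int)
    rank[order] = np.arange(1, len(order) + 1)
    table["rank"] = rank
    return EffectTable(table)


def screen_parameters(effects: EffectTable, top_m: int = 6):
    """Select the ``top_m`` factors by the larger standardized |effect|.

    Returns ``(selected, tied)``: ties spanning the cut are all reported and
    flagged rather than silently broken.
    """
    table = effects.table
    if top_m > len(table):
        raise ValueError(f"top_m={top_m} exceeds the {len(table)} factors screened")
    strength = np.maximum(
        table["std_effect_A"].abs(), table["std_effect_tau"].abs()
    )
    ordered = strength.sort_values(ascending=False, kind="stable")
    if top_m == len(table):
        return list(ordered.index), False
    cut = ordered.iloc[top_m - 1]
    tied = bool(np.isclose(ordered.iloc[top_m], cut))
    if tied:
        selected = list(ordered[np.isclose(ordered, cut) | (ordered > cut)].index)
    else:
        selected = list(ordered.index[:top_m])
    return selected, tied
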