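"""Genetic-algorithm calibration of Kv current models to sparse targets.

When full characteristic curves (steady-state activation/inactivation, tau-V)
cannot be measured -- e.g. when currents are too small at early-activating
voltages -- a model can still be calibrated directly to the two features that
summarize a component current trace: its amplitude A (pA/pF) and inactivation
time constant tau (ms) at a single depolarization.  The objective is the
unweighted L1 discrepancy

    min |A - A_hat| + |tau - tau_hat|,

where (A_hat, tau_hat) are extracted from the simulated trace with the same
peak-plus-mono-exponential estimator used on experimental data.

Two derivative-free optimizers are provided:

* a *self-breeding* genetic algorithm: elitist, crossover-free; each of the
  top-k solutions spawns s offspring by per-parameter Gaussian perturbation
  whose variance is the elite variance pooled over a sliding window of recent
  generations (so the search contracts as the elites agree);
* a standard genetic algorithm baseline with uniform crossover of elite pairs
  plus Gaussian mutation.

With two target features and >= 3 free parameters the problem is
under-determined: runs recover the target *features*, not the generating
parameter vector, and replicate summaries report the spread of equivalent
solutions (mean +- standard error over converged runs).

The calibration surface follows the estimator-object convention: build a
:class:`CurrentCalibration` from a target, call :meth:`~CurrentCalibration.fit`
to obtain a :class:`CalibrationFit` with estimates, discrepancies, history and
a ``summary()`` table.
"""

from __future__ import annotations

import dataclasses
import logging
from collections import deque
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .clamp import ClampProtocol, SolverOptions, simulate_current
from .features import extract_calibration_features
from .models import model_for
from .params import KslowParams, KtoParams, ModelConstants

__all__ = [
    "CalibrationTarget",
    "GAConfig",
    "CurrentCalibration",
    "CalibrationFit",
    "ReplicateSummary",
    "default_bounds",
    "default_tolerances",
    "objective",
    "self_breeding_ga",
    "standard_ga",
    "calibrate_replicates",
    "minimize_self_breeding",
    "minimize_standard_ga",
]

logger = logging.getLogger(__name__)

#: published per-feature convergence tolerances (eps_A pA/pF, eps_tau ms)
TOLERANCES = {"Kto": (0.1, 1.0), "Kslow": (0.1, 5.0)}

#: slope parameters whose lower bound is floored at 1 mV to avoid logistic
#: blowup when the search range would otherwise reach toward zero
_SLOPE_PARAMS = {
    "Kto": ("x4", "x7"),
    "Kslow": ("x2", "x4", "x8"),
}


@dataclass(frozen=True)
class CalibrationTarget:
    """Target amplitude (pA/pF) and time constant (ms) at one step voltage."""

    A: float
    tau: float
    kind: str = "Kto"
    v_step: float = 50.0

    def __post_init__(self) -> None:
        if self.A <= 0 or self.tau <= 0:
            raise ValueError("target amplitude and time constant must be positive")
        if self.kind not in ("Kto", "Kslow"):
            raise ValueError(f"unknown current kind {self.kind!r}")


@dataclass(frozen=True)
class GAConfig:
    """Genetic-algorithm hyperparameters.

    The self-breeding population bookkeeping requires N = k (1 + s): k elites
    each spawning s offspring.  Bounds and tolerances left as None are
    resolved from the model kind at fit time.  ``stop_rule='both'`` stops when
    both discrepancies are below tolerance; 'either' is the permissive
    variant.  ``mutation_sd`` (fraction of the per-parameter range) applies to
    the standard-GA baseline only.
    """

    N: int = 100
    k: int = 10
    s: int = 9
    w: int = 5
    lower: tuple | None = None
    upper: tuple | None = None
    eps_A: float | None = None
    eps_tau: float | None = None
    max_gen: int = 500
    stop_rule: str = "both"
    mutation_sd: float = 0.05
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.N != self.k * (1 + self.s):
            raise ValueError(
                f"population bookkeeping requires N = k(1+s); "
                f"got N={self.N}, k={self.k}, s={self.s}"
            )
        if self.k < 1 or self.k >= self.N:
            raise ValueError("need 1 <= k < N (offspring slots required)")
        if self.w < 1 or self.max_gen < 1:
            raise ValueError("w and max_gen must be positive")
        if self.stop_rule not in ("both", "either"):
            raise ValueError("stop_rule must be 'both' or 'either'")
        for eps in (self.eps_A, self.eps_tau):
            if eps is not None and eps <= 0:
                raise ValueError("tolerances must be positive")
        if self.lower is not None and self.upper is not None:
            lo, up = np.asarray(self.lower), np.asarray(self.upper)
            if lo.shape != up.shape or np.any(lo >= up):
                raise ValueError("bounds must satisfy lower < upper elementwise")


def default_bounds(base: KtoParams | KslowParams) -> tuple[np.ndarray, np.ndarray]:
    """Search box for the free parameters: [0.25x, 6x] the literature default,
    with slope parameters floored at 1 mV.

    The box must admit the kinetics of both experimental groups: the
    slower-inactivating knockout shifts some voltage-shift/slope entries
    (e.g. the Kto beta_i pair) several-fold above their literature defaults,
    so a tighter cap would make amplitude and time constant jointly
    unreachable for that group.
    """
    defaults_cls = type(base)()
    lo, hi = [], []
    slopes = _SLOPE_PARAMS[base.kind]
    for name in base.FREE:
        d = getattr(defaults_cls, name)
        lower = 0.25 * d
        if name in slopes:
            lower = max(lower, 1.0)
        lo.append(lower)
        hi.append(6.0 * d)
    return np.array(lo), np.array(hi)


def default_tolerances(kind: str) -> tuple[float, float]:
    return TOLERANCES[kind]


# ---------------------------------------------------------------------------
# generic GA engines (objective -> (score, delta_A, delta_tau))
# ---------------------------------------------------------------------------


def _ordering(pop: np.ndarray, scores: np.ndarray) -> np.ndarray:
    """Ascending by score; fitness ties broken by lower parameter values in
    index order (deterministic ranking)."""
    keys = [pop[:, j] for j in range(pop.shape[1] - 1, -1, -1)]
    keys.append(scores)
    return np.lexsort(keys)


def _stopped(dA, dtau, eps_A, eps_tau, rule) -> bool:
    if rule == "both":
        return dA < eps_A and dtau < eps_tau
    return dA < eps_A or dtau < eps_tau


def _evaluate(fun, pop: np.ndarray) -> np.ndarray:
    out = np.empty((len(pop), 3))
    for j, x in enumerate(pop):
        try:
            score, dA, dtau = fun(x)
        except Exception as exc:  # failed evaluation ranks strictly last
            logger.debug("objective evaluation failed at x=%s: %s", x, exc)
            score, dA, dtau = np.inf, np.inf, np.inf
        out[j] = (score, dA, dtau)
    return out


def minimize_self_breeding(
    fun,
    cfg: GAConfig,
    lower,
    upper,
    eps_A: float,
    eps_tau: float,
    seed: int | None = None,
) -> dict:
    """Run the self-breeding GA on an arbitrary objective.

    ``fun(x) -> (score, delta_A, delta_tau)``; lower scores are fitter.
    Returns a dict with the best solution, final discrepancies, generation
    count, convergence flag and per-generation history.
    """
    lower = np.asarray(lower, dtype=float)
    upper = np.asarray(upper, dtype=float)
    p = len(lower)
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    k, s = cfg.k, cfg.s

    pop = lower + (upper - lower) * rng.random((cfg.N, p))
    vals = _evaluate(fun, pop)
    var_window: deque = deque(maxlen=cfg.w)
    history = []
    converged = False
    generations = 0

    for gen in range(1, cfg.max_gen + 1):
        generations = gen
        order = _ordering(pop, vals[:, 0])
        elites = pop[order[:k]]
        elite_vals = vals[order[:k]]
        best_score, dA, dtau = elite_vals[0]

        elite_var = elites.var(axis=0, ddof=1) if k > 1 else np.zeros(p)
        var_window.append(elite_var)
        sigma2_p = np.mean(var_window, axis=0)

        history.append(
            {
                "generation": gen,
                "best_score": best_score,
                "delta_A": dA,
                "delta_tau": dtau,
                **{f"elite_var_{j}": elite_var[j] for j in range(p)},
            }
        )
        logger.info(
            "gen %d: best score %.4g (dA=%.4g, dtau=%.4g)", gen, best_score, dA, dtau
        )
        if _stopped(dA, dtau, eps_A, eps_tau, cfg.stop_rule):
            converged = True
            pop, vals = elites, elite_vals
            break

        noise = rng.normal(0.0, np.sqrt(sigma2_p), size=(k * s, p))
        offspring = np.clip(np.repeat(elites, s, axis=0) + noise, lower, upper)
        off_vals = _evaluate(fun, offspring)
        pop = np.vstack([elites, offspring])
        vals = np.vstack([elite_vals, off_vals])

    order = _ordering(pop, vals[:, 0])
    best_x = pop[order[0]].copy()
    best_score, dA, dtau = vals[order[0]]
    return {
        "x": best_x,
        "score": float(best_score),
        "delta_A": float(dA),
        "delta_tau": float(dtau),
        "generations": generations,
        "converged": converged,
        "history": pd.DataFrame(history),
    }


def minimize_standard_ga(
    fun,
    cfg: GAConfig,
    lower,
    upper,
    eps_A: float,
    eps_tau: float,
    seed: int | None = None,
) -> dict:
    """Standard-GA baseline: uniform crossover of elite pairs plus Gaussian
    mutation of fixed scale ``mutation_sd * (upper - lower)``."""
    lower = np.asarray(lower, dtype=float)
    upper = np.asarray(upper, dtype=float)
    p = len(lower)
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    k = cfg.k
    n_off = cfg.N - k
    sd = cfg.mutation_sd * (upper - lower)

    pop = lower + (upper - lower) * rng.random((cfg.N, p))
    vals = _evaluate(fun, pop)
    history = []
    converged = False
    generations = 0

    for gen in range(1, cfg.max_gen + 1):
        generations = gen
        order = _ordering(pop, vals[:, 0])
        elites = pop[order[:k]]
        elite_vals = vals[order[:k]]
        best_score, dA, dtau = elite_vals[0]
        history.append(
            {
                "generation": gen,
                "best_score": best_score,
                "delta_A": dA,
                "delta_tau": dtau,
            }
        )
        if _stopped(dA, dtau, eps_A, eps_tau, cfg.stop_rule):
            converged = True
            pop, vals = elites, elite_vals
            break

        parents = rng.integers(0, k, size=(n_off, 2))
        mask = rng.random((n_off, p)) < 0.5
        offspring = np.where(mask, elites[parents[:, 0]], elites[parents[:, 1]])
        offspring = np.clip(offspring + rng.normal(0.0, sd, (n_off, p)), lower, upper)
        off_vals = _evaluate(fun, offspring)
        pop = np.vstack([elites, offspring])
        vals = np.vstack([elite_vals, off_vals])

    order = _ordering(pop, vals[:, 0])
    best_score, dA, dtau = vals[order[0]]
    return {
        "x": pop[order[0]].copy(),
        "score": float(best_score),
        "delta_A": float(dA),
        "delta_tau": float(dtau),
        "generations": generations,
        "converged": converged,
        "history": pd.DataFrame(history),
    }


# ---------------------------------------------------------------------------
# model-fitting surface
# ---------------------------------------------------------------------------


class CurrentCalibration:
    """Calibration problem: fit a Kv current model to (A, tau) targets.

    Parameters
    ----------
    target : CalibrationTarget
        Amplitude (pA/pF) and time constant (ms) at the target step voltage.
    base : KtoParams or KslowParams, optional
        Full parameter vector supplying the non-calibrated entries; defaults
        to the literature vector of the target's kind.
    config : GAConfig, optional
    protocol, solver, constants : simulation settings for objective
        evaluations (holding equilibration is analytic, so only the step
        window is simulated).

    Examples
    --------
    >>> from kvsim import load_preset, simulate_current, extract_calibration_features
    >>> from kvsim.calibration import CalibrationTarget, CurrentCalibration
    >>> tr = simulate_current("Kto", load_preset("kto_wt"))[-1]
    >>> A, tau = extract_calibration_features(tr)
    >>> fit = CurrentCalibration(CalibrationTarget(A, tau, "Kto")).fit(seed=0)
    >>> fit.converged
    True
    """

    def __init__(
        self,
        target: CalibrationTarget,
        base: KtoParams | KslowParams | None = None,
        config: GAConfig | None = None,
        protocol: ClampProtocol = ClampProtocol(),
        solver: SolverOptions = SolverOptions(),
        constants: ModelConstants = ModelConstants(),
    ):
        self.target = target
        if base is None:
            base = KtoParams() if target.kind == "Kto" else KslowParams()
        if base.kind != target.kind:
            raise ValueError(
                f"base parameters are {base.kind} but target is {target.kind}"
            )
        self.base = base
        self.config = config if config is not None else GAConfig()
        self.free_names = list(base.FREE)
        self.constants = constants
        self.solver = dataclasses.replace(solver, method="analytic")
        # objective evaluations need only the step window at the target
        # voltage; with steady-state-at-hold init the holding phase is exact
        self.protocol = dataclasses.replace(
            protocol, t_hold=0.0, v_steps=(target.v_step,)
        )
        if self.config.lower is not None and self.config.upper is not None:
            self.lower = np.asarray(self.config.lower, dtype=float)
            self.upper = np.asarray(self.config.upper, dtype=float)
        else:
            self.lower, self.upper = default_bounds(base)
        if len(self.lower) != len(self.free_names):
            raise ValueError(
                f"bounds have length {len(self.lower)}, expected "
                f"{len(self.free_names)} free parameters"
            )
        eA, etau = default_tolerances(target.kind)
        self.eps_A = self.config.eps_A if self.config.eps_A is not None else eA
        self.eps_tau = self.config.eps_tau if self.config.eps_tau is not None else etau

    def expand(self, x) -> KtoParams | KslowParams:
        """Insert the free-parameter vector into the full parameter set."""
        return self.base.replace(**dict(zip(self.free_names, np.asarray(x, float))))

    def simulate(self, x=None):
        """Simulated trace at the target voltage for ``x`` (or the base)."""
        params = self.base if x is None else self.expand(x)
        return simulate_current(
            model_for(params, self.constants), proto=self.protocol, opts=self.solver
        )[0]

    def features(self, x=None) -> tuple[float, float]:
        return extract_calibration_features(self.simulate(x))

    def objective(self, x) -> tuple[float, float, float]:
        """(delta_A, delta_tau, score) for a free-parameter vector."""
        A_hat, tau_hat = self.features(x)
        dA = abs(self.target.A - A_hat)
        dtau = abs(self.target.tau - tau_hat)
        return dA, dtau, dA + dtau

    def _ga_fun(self, x):
        dA, dtau, score = self.objective(x)
        return score, dA, dtau

    def fit(self, method: str = "self_breeding", seed: int | None = None):
        """Run the calibration; returns a :class:`CalibrationFit`."""
        engines = {
            "self_breeding": minimize_self_breeding,
            "standard": minimize_standard_ga,
        }
        if method not in engines:
            raise ValueError(f"unknown method {method!r}; use {sorted(engines)}")
        raw = engines[method](
            self._ga_fun,
            self.config,
            self.lower,
            self.upper,
            self.eps_A,
            self.eps_tau,
            seed=seed,
        )
        history = raw["history"].rename(
            columns={
                f"elite_var_{j}": f"elite_var_{n}"
                for j, n in enumerate(self.free_names)
            }
        )
        return CalibrationFit(
            model=self,
            method=method,
            seed=self.config.seed if seed is None else seed,
            x=raw["x"],
            score=raw["score"],
            delta_A=raw["delta_A"],
            delta_tau=raw["delta_tau"],
            generations=raw["generations"],
            converged=raw["converged"],
            history=history,
        )

    def fit_replicates(
        self,
        R: int = 30,
        seed: int | None = None,
        seeds=None,
        method: str = "self_breeding",
    ) -> "ReplicateSummary":
        """Repeat the calibration with independent seeds; summarize converged
        runs as per-parameter mean +- standard error."""
        if seeds is not None:
            seeds = list(seeds)
            if len(set(seeds)) != len(seeds):
                raise ValueError("replicate seeds must be distinct")
            R = len(seeds)
        if R < 2:
            raise ValueError("need at least R=2 replicates")
        if seeds is None:
            ss = np.random.SeedSequence(seed)
            seeds = [int(s) for s in ss.generate_state(R) % (2**31)]
            if len(set(seeds)) != len(seeds):  # astronomically unlikely
                seeds = list(range(R))
        fits = [self.fit(method=method, seed=sd) for sd in seeds]
        return ReplicateSummary(model=self, fits=fits, seeds=seeds)


@dataclass
class CalibrationFit:
    """Result of one calibration run.

    ``x`` is the best free-parameter vector (order: ``model.free_names``);
    ``delta_A``/``delta_tau`` the final feature discrepancies; ``history`` a
    per-generation record of best score, discrepancies and elite variances.
    """

    model: CurrentCalibration
    method: str
    seed: int | None
    x: np.ndarray
    score: float
    delta_A: float
    delta_tau: float
    generations: int
    converged: bool
    history: pd.DataFrame

    @property
    def params(self) -> KtoParams | KslowParams:
        """Best solution expanded into a full parameter vector."""
        return self.model.expand(self.x)

    @property
    def params_series(self) -> pd.Series:
        return pd.Series(dict(zip(self.model.free_names, self.x)))

    def simulate(self):
        return self.model.simulate(self.x)

    def features(self) -> tuple[float, float]:
        return self.model.features(self.x)

    def summary(self) -> str:
        t = self.model.target
        lines = [
            f"{t.kind} calibration ({self.method} GA)",
            "=" * 44,
            f"target          A = {t.A:.4g} pA/pF, tau = {t.tau:.4g} ms "
            f"at {t.v_step:+.0f} mV",
            f"discrepancies   delta_A = {self.delta_A:.4g} "
            f"(eps {self.model.eps_A}), delta_tau = {self.delta_tau:.4g} "
            f"(eps {self.model.eps_tau})",
            f"converged       {self.converged} in {self.generations} generations"
            + (f" (seed {self.seed})" if self.seed is not None else ""),
            "-" * 44,
        ]
        for name, value in zip(self.model.free_names, self.x):
            lines.append(f"{name:>6} {value:14.4f}")
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "kind": self.model.target.kind,
            "method": self.method,
            "seed": self.seed,
            "params": dict(zip(self.model.free_names, map(float, self.x))),
            "delta_A": self.delta_A,
            "delta_tau": self.delta_tau,
            "score": self.score,
            "generations": self.generations,
            "converged": self.converged,
        }


@dataclass
class ReplicateSummary:
    """Per-parameter mean and standard error over replicate calibrations.

    Only converged runs enter the summary; the non-converged count is kept.
    Because the two-feature objective is under-determined, the spread
    describes the family of feature-equivalent solutions, not uncertainty of
    a unique optimum.
    """

    model: CurrentCalibration
    fits: list
    seeds: list

    @property
    def R(self) -> int:
        return len(self.fits)

    @property
    def converged_fits(self) -> list:
        return [f for f in self.fits if f.converged]

    @property
    def R_converged(self) -> int:
        return len(self.converged_fits)

    def table(self) -> pd.DataFrame:
        """Parameter mean +- SE over converged runs (Table-style layout)."""
        good = self.converged_fits
        if not good:
            import warnings

            warnings.warn("no converged replicates; summary table is empty")
            return pd.DataFrame(columns=["mean", "se"], index=self.model.free_names)
        X = np.array([f.x for f in good])
        mean = X.mean(axis=0)
        se = (
            X.std(axis=0, ddof=1) / np.sqrt(len(good))
            if len(good) > 1
            else np.zeros(X.shape[1])
        )
        return pd.DataFrame(
            {"mean": mean, "se": se}, index=self.model.free_names
        )

    def summary(self) -> str:
        t = self.model.target
        tab = self.table()
        lines = [
            f"{t.kind} replicate calibration: {self.R_converged}/{self.R} "
            "runs converged",
            f"target A = {t.A:.4g} pA/pF, tau = {t.tau:.4g} ms at "
            f"{t.v_step:+.0f} mV",
            "-" * 40,
            f"{'parameter':>10} {'mean':>12} {'SE':>10}",
        ]
        for name, row in tab.iterrows():
            lines.append(f"{name:>10} {row['mean']:12.4f} {row['se']:10.4f}")
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# functional wrappers
# ---------------------------------------------------------------------------


def objective(
    x,
    target: CalibrationTarget,
    proto: ClampProtocol = ClampProtocol(),
    opts: SolverOptions = SolverOptions(),
    base=None,
) -> tuple[float, float, float]:
    """Feature discrepancy (delta_A, delta_tau, score) of a free-parameter
    vector against the target."""
    return CurrentCalibration(target, base=base, protocol=proto, solver=opts).objective(
        x
    )


def self_breeding_ga(
    target: CalibrationTarget,
    cfg: GAConfig | None = None,
    base=None,
    seed: int | None = None,
) -> CalibrationFit:
    """Calibrate with the self-breeding GA (see module docstring)."""
    return CurrentCalibration(target, base=base, config=cfg).fit(
        method="self_breeding", seed=seed
    )


def standard_ga(
    target: CalibrationTarget,
    cfg: GAConfig | None = None,
    base=None,
    seed: int | None = None,
) -> CalibrationFit:
    """Calibrate with the standard-GA baseline."""
    return CurrentCalibration(target, base=base, config=cfg).fit(
        method="standard", seed=seed
    )


def calibrate_replicates(
    target: CalibrationTarget,
    cfg: GAConfig | None = None,
    R: int = 30,
    seed: int | None = None,
    seeds=None,
    base=None,
    method: str = "self_breeding",
) -> ReplicateSummary:
    """Repeat the calibration R times with independent seeds."""
    return CurrentCalibration(target, base=base, config=cfg).fit_replicates(
        R=R, seed=seed, seeds=seeds, method=method
    )
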