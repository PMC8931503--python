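"""Synthetic stand-ins for the experimental measurements.

The study's calibration targets are group means of per-cell trace features
(amplitude and time constant of I_Kto and I_Kslow, plus the steady-state
offset I_Kss) from whole-cell recordings of n = 35 WT and n = 38 Mgat1KO
myocytes.  The raw per-cell values are not published, so this module
generates cohorts whose *means* are the features forward-simulated from the
packaged parameter presets and whose cell-to-cell spread follows a
truncated-at-zero normal with a chosen coefficient of variation.  It also
generates noisy summed-current traces for validating the bi-exponential
decomposition under realistic signal-to-noise ratios.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .clamp import ClampProtocol, SolverOptions, simulate_current, simulate_iksum
from .features import extract_calibration_features
from .models import model_for
from .params import KslowParams, KtoParams, load_preset

__all__ = ["SyntheticCohort", "synth_cohort", "synth_iksum_traces", "GROUP_SIZES"]

#: cohort sizes of the experimental groups
GROUP_SIZES = {"WT": 35, "Mgat1KO": 38}

#: default steady-state current offset (pA/pF); placeholder magnitude for a
#: small non-inactivating component, configurable wherever it is used
DEFAULT_A_KSS = 2.0

FEATURE_COLUMNS = ["A_Kto", "tau_Kto", "A_Kslow", "tau_Kslow", "A_Kss"]


@dataclass
class SyntheticCohort:
    """Per-cell feature table for one group."""

    group: str
    cells: pd.DataFrame
    means: pd.Series
    cv: float
    seed: int | None

    @property
    def n(self) -> int:
        return len(self.cells)

    def group_summary(self) -> pd.DataFrame:
        """Mean and standard error per feature, cohort-statistics style."""
        m = self.cells.mean()
        se = self.cells.std(ddof=1) / np.sqrt(self.n) if self.n > 1 else 0 * m
        return pd.DataFrame({"mean": m, "se": se})


def preset_features(
    p_kto: KtoParams,
    p_kslow: KslowParams,
    a_kss: float = DEFAULT_A_KSS,
    v_step: float = 50.0,
) -> pd.Series:
    """Feature means implied by a pair of parameter presets at ``v_step``."""
    proto = ClampProtocol(t_hold=0.0, v_steps=(v_step,))
    opts = SolverOptions(method="analytic")
    vals = {}
    for p, tag in ((p_kto, "Kto"), (p_kslow, "Kslow")):
        tr = simulate_current(model_for(p), proto=proto, opts=opts)[0]
        A, tau = extract_calibration_features(tr)
        vals[f"A_{tag}"] = A
        vals[f"tau_{tag}"] = tau
    vals["A_Kss"] = float(a_kss)
    return pd.Series(vals)[FEATURE_COLUMNS]


def synth_cohort(
    p_kto: KtoParams | str,
    p_kslow: KslowParams | str,
    n: int,
    cv: float = 0.3,
    seed: int | None = None,
    group: str = "WT",
    a_kss: float = DEFAULT_A_KSS,
    v_step: float = 50.0,
) -> SyntheticCohort:
    """Draw a per-cell feature cohort around preset-derived means.

    Each cell's feature is drawn from Normal(mean, cv * mean) truncated at
    zero by rejection, so features stay positive.  A warning is raised if the
    truncation affects more than 1% of the mass (large cv).
    """
    if cv < 0:
        raise ValueError("coefficient of variation must be nonnegative")
    if n < 1:
        raise ValueError("cohort needs at least one cell")
    if isinstance(p_kto, str):
        p_kto = load_preset(p_kto)
    if isinstance(p_kslow, str):
        p_kslow = load_preset(p_kslow)
    means = preset_features(p_kto, p_kslow, a_kss=a_kss, v_step=v_step)
    rng = np.random.default_rng(seed)
    if cv == 0:
        cells = pd.DataFrame([means] * n).reset_index(drop=True)
    else:
        from scipy.stats import norm

        trunc_mass = float(norm.cdf(-1.0 / cv))
        if trunc_mass > 0.01:
            import warnings

            warnings.warn(
                f"cv={cv} truncates about {100 * trunc_mass:.1f}% of the "
                "normal mass at zero; per-cell means will be biased upward"
            )
        data = {}
        for col in FEATURE_COLUMNS:
            mu = means[col]
            draws = rng.normal(mu, cv * mu, size=n)
            while np.any(draws <= 0):  # rejection at zero
                bad = draws <= 0
                draws[bad] = rng.normal(mu, cv * mu, size=int(bad.sum()))
            data[col] = draws
        cells = pd.DataFrame(data)[FEATURE_COLUMNS]
    return SyntheticCohort(group=group, cells=cells, means=means, cv=cv, seed=seed)


def synth_iksum_traces(
    p_kto: KtoParams,
    p_kslow: KslowParams,
    a_kss: float = DEFAULT_A_KSS,
    noise_sd: float = 0.0,
    proto: ClampProtocol = ClampProtocol(),
    seed: int | None = None,
):
    """Summed-current traces with additive i.i.d. Gaussian recording noise."""
    if noise_sd < 0:
        raise ValueError("noise_sd must be nonnegative")
    traces = simulate_iksum(p_kto, p_kslow, a_kss=a_kss, proto=proto)
    if noise_sd == 0:
        return traces
    rng = np.random.default_rng(seed)
    noisy = []
    for tr in traces:
        noisy.append(
            dataclasses.replace(
                tr, I=tr.I + rng.normal(0.0, noise_sd, size=len(tr.I))
            )
        )
    return noisy
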