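"""Parameter vectors for the I_Kto and I_Kslow Hodgkin-Huxley models.

Two currents dominate the decaying part of the summed outward K+ current of
mouse ventricular apex myocytes: the fast transient outward current I_Kto
(Kv4.2, cubed activation gate) and the slowly inactivating delayed-rectifier
type current I_Kslow (linear activation gate).  Each model carries a vector of
voltage-shift / slope parameters ``x1..x7`` (``x1..x8`` for I_Kslow) plus a
maximal conductance.  Calibration only adjusts a sensitivity-screened subset;
the remaining entries stay at the literature defaults of the source
mouse-ventricle formulation.

Presets ship the calibrated group means for wild-type (WT) and Mgat1-knockout
(Mgat1KO, reduced hybrid/complex N-glycosylation) animals, alongside the
literature-default vectors.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass
from importlib import resources
from typing import Iterator


__all__ = [
    "KtoParams",
    "KslowParams",
    "ModelConstants",
    "PRESET_NAMES",
    "load_preset",
    "params_from_dict",
    "read_params_json",
    "write_params_json",
]


def _check_finite(name: str, value: float) -> None:
    if not math.isfinite(value):
        raise ValueError(f"parameter {name} must be finite, got {value!r}")


@dataclass(frozen=True)
class KtoParams:
    """I_Kto model parameters (mV except the conductance).

    ``x4`` and ``x7`` sit in exponential-slope denominators and must be
    nonzero.  ``Gto`` is the maximal conductance in mS/uF so that
    current density comes out in pA/pF.
    """

    x1: float = 30.0
    x2: float = 30.0
    x3: float = 13.5
    x4: float = 7.0
    x5: float = 33.5
    x6: float = 33.5
    x7: float = 7.0
    Gto: float = 0.4067

    #: entries adjusted by calibration (sensitivity-screened subset)
    FREE = ("x1", "x2", "x3", "x6", "x7", "Gto")
    #: entries held at literature defaults
    FIXED = ("x4", "x5")

    kind = "Kto"
    conductance_name = "Gto"

    def __post_init__(self) -> None:
        for name, value in self.as_dict().items():
            _check_finite(name, value)
        if self.x4 == 0 or self.x7 == 0:
            raise ValueError("slope parameters x4 and x7 must be nonzero")
        if self.Gto < 0:
            raise ValueError(f"Gto must be nonnegative, got {self.Gto}")

    def as_dict(self) -> dict[str, float]:
        return {f.name: getattr(self, f.name) for f in dataclasses.fields(self)}

    def replace(self, **changes: float) -> "KtoParams":
        return dataclasses.replace(self, **changes)

    @property
    def conductance(self) -> float:
        return self.Gto

    def free_values(self) -> list[float]:
        return [getattr(self, n) for n in self.FREE]


@dataclass(frozen=True)
class KslowParams:
    """I_Kslow model parameters.

    ``x1..x4`` and ``x7, x8`` are voltage shifts/slopes in mV; ``x5`` is the
    activation time-constant floor in ms and ``x6`` the inactivation
    time-constant plateau in ms.  ``x6`` must exceed 170 ms or the
    inactivation time constant tau_i = x6 - 170/(1+exp((V+x7)/x8)) can
    collapse to zero at hyperpolarized voltages.
    """

    x1: float = 22.5
    x2: float = 7.7
    x3: float = 45.2
    x4: float = 5.7
    x5: float = 2.058
    x6: float = 1200.0
    x7: float = 45.2
    x8: float = 5.7
    Gr: float = 0.16

    FREE = ("x1", "x2", "x3", "x4", "x6", "Gr")
    FIXED = ("x5", "x7", "x8")

    kind = "Kslow"
    conductance_name = "Gr"

    def __post_init__(self) -> None:
        for name, value in self.as_dict().items():
            _check_finite(name, value)
        if self.x2 == 0 or self.x4 == 0 or self.x8 == 0:
            raise ValueError("slope parameters x2, x4 and x8 must be nonzero")
        if self.Gr < 0:
            raise ValueError(f"Gr must be nonnegative, got {self.Gr}")
        if self.x6 <= 170.0:
            import warnings

            warnings.warn(
                f"x6={self.x6} <= 170 ms: tau_i may collapse toward zero at "
                "hyperpolarized voltages",
                stacklevel=3,
            )

    def as_dict(self) -> dict[str, float]:
        return {f.name: getattr(self, f.name) for f in dataclasses.fields(self)}

    def replace(self, **changes: float) -> "KslowParams":
        return dataclasses.replace(self, **changes)

    @property
    def conductance(self) -> float:
        return self.Gr

    def free_values(self) -> list[float]:
        return [getattr(self, n) for n in self.FREE]


@dataclass(frozen=True)
class ModelConstants:
    """Physical constants shared by both currents.

    E_K is the K+ Nernst (reversal) potential.  The default -84.2 mV follows
    from the Nernst relation with the source formulation's [K+]o = 5,400 uM
    and [K+]i = 143,720 uM near room temperature.
    """

    E_K: float = -84.2

    def __post_init__(self) -> None:
        _check_finite("E_K", self.E_K)


PRESET_NAMES = (
    "kto_default",
    "kto_wt",
    "kto_ko",
    "kslow_default",
    "kslow_wt",
    "kslow_ko",
)


def params_from_dict(data: dict) -> KtoParams | KslowParams:
    """Build a parameter vector from a plain dict with a ``kind`` key."""
    kind = data.get("kind")
    if kind not in ("Kto", "Kslow"):
        raise ValueError(f"unknown model kind {kind!r}; expected 'Kto' or 'Kslow'")
    cls = KtoParams if kind == "Kto" else KslowParams
    fields = {f.name for f in dataclasses.fields(cls)}
    values = {k: float(v) for k, v in data.items() if k in fields}
    return cls(**values)


def _preset_files() -> Iterator[str]:
    for name in PRESET_NAMES:
        yield f"{name}.json"


def load_preset(name: str) -> KtoParams | KslowParams:
    """Load a packaged parameter preset.

    ``kto_wt``/``kto_ko``/``kslow_wt``/``kslow_ko`` carry the calibrated group
    means for the WT and Mgat1KO cohorts with unselected entries at the
    literature defaults; ``*_default`` are the pure literature vectors.
    """
    if name not in PRESET_NAMES:
        raise KeyError(
            f"unknown preset {name!r}; valid names: {', '.join(PRESET_NAMES)}"
        )
    ref = resources.files("kvsim.presets").joinpath(f"{name}.json")
    data = json.loads(ref.read_text())
    return params_from_dict(data)


def read_params_json(path) -> KtoParams | KslowParams:
    """Read a parameter vector from a JSON file (same schema as presets)."""
    with open(path) as fh:
        return params_from_dict(json.load(fh))


def write_params_json(params: KtoParams | KslowParams, path) -> None:
    """Write a parameter vector as JSON, recording the non-calibratable set."""
    data = {"kind": params.kind, **params.as_dict(), "fixed": list(params.FIXED)}
    with open(path, "w") as fh:
        json.dump(data, fh, indent=2)
        fh.write("\n")
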