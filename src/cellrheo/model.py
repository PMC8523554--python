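"""Closed-form self-similar hierarchical rheology of living cells.

The cell is idealised as an ``n``-level self-similar hierarchy of
spring--dashpot ladder networks.  The first level represents the cytoplasm
(springs of stiffness ``E1`` immersed in a viscous fluid of viscosity
``eta``); each higher level embeds the previous one as a building block,
with ``E2`` the effective stiffness of microtubules along the load
direction and ``E3`` that of the transverse expansion of cytoskeleton and
cytoplasm.  In the long-time / low-frequency limit the level-``k`` creep
compliance behaves as a power law ``J_k ~ t**(2**-k)``, which is the origin
of the power-law rheology observed across cell types.

This module evaluates the closed forms: creep compliance ``J_n(t)``,
complex modulus ``G_n*(omega)``, their analytic local log-log slopes, and a
Kelvin--Voigt single-element baseline.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np

__all__ = [
    "ValidationError",
    "HierParams",
    "KelvinVoigtParams",
    "CreepCurve",
    "ModulusCurve",
    "creep_compliance",
    "complex_modulus",
    "complex_modulus_values",
    "local_exponent",
    "kelvin_voigt_creep",
    "preset",
    "PRESETS",
    "KV_PRESETS",
]


class ValidationError(ValueError):
    """Raised when model parameters or input arrays are physically invalid."""


def _as_positive_array(x, name: str, allow_zero: bool = False) -> np.ndarray:
    arr = np.atleast_1d(np.asarray(x, dtype=float))
    if arr.ndim != 1:
        raise ValidationError(f"{name} must be one-dimensional")
    lo = 0.0 if allow_zero else np.nextafter(0.0, 1.0)
    if np.any(~np.isfinite(arr)) or np.any(arr < lo):
        kind = "non-negative" if allow_zero else "strictly positive"
        raise ValidationError(f"{name} must be finite and {kind}")
    return arr


# ---------------------------------------------------------------------------
# Parameter containers
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class HierParams:
    """Parameters of the n-level hierarchical model.

    Parameters
    ----------
    stiffness
        Ordered spring stiffnesses ``(E1, ..., En)`` in Pa.  ``E1`` is the
        cytoplasm-level stiffness and sets the relaxation time together
        with the viscosity; the order of the remaining entries is
        load-bearing (each level wraps the previous one).
    viscosity
        Dashpot viscosity ``eta`` of the first level, in Pa*s.
    """

    stiffness: tuple
    viscosity: float

    def __init__(self, stiffness: Sequence[float], viscosity: float):
        stiff = tuple(float(e) for e in np.atleast_1d(stiffness))
        if len(stiff) < 1:
            raise ValidationError("at least one stiffness level is required")
        if any((not np.isfinite(e)) or e <= 0.0 for e in stiff):
            raise ValidationError("every spring stiffness must be finite and > 0")
        visc = float(viscosity)
        if not np.isfinite(visc) or visc <= 0.0:
            raise ValidationError("viscosity must be finite and > 0")
        object.__setattr__(self, "stiffness", stiff)
        object.__setattr__(self, "viscosity", visc)

    @property
    def n_levels(self) -> int:
        return len(self.stiffness)

    @property
    def relaxation_time(self) -> float:
        """First-level relaxation time ``tau = eta / E1`` in seconds."""
        return self.viscosity / self.stiffness[0]

    def with_stiffness(self, level: int, value: float) -> "HierParams":
        """Return a copy with the 1-based ``level`` stiffness replaced."""
        if not 1 <= level <= self.n_levels:
            raise ValidationError(f"level must be in 1..{self.n_levels}")
        stiff = list(self.stiffness)
        stiff[level - 1] = value
        return HierParams(stiff, self.viscosity)


@dataclass(frozen=True)
class KelvinVoigtParams:
    """Spring and dashpot in parallel: ``sigma = E*eps + E*tau*deps/dt``."""

    stiffness: float
    relaxation_time: float

    def __post_init__(self):
        if not (np.isfinite(self.stiffness) and self.stiffness > 0):
            raise ValidationError("stiffness must be finite and > 0")
        if not (np.isfinite(self.relaxation_time) and self.relaxation_time > 0):
            raise ValidationError("relaxation_time must be finite and > 0")

    @property
    def viscosity(self) -> float:
        return self.stiffness * self.relaxation_time


# ---------------------------------------------------------------------------
# Curve containers
# ---------------------------------------------------------------------------


def _check_strictly_increasing(x: np.ndarray, name: str) -> None:
    if x.size >= 2 and np.any(np.diff(x) <= 0):
        raise ValidationError(f"{name} must be strictly increasing")


@dataclass(frozen=True)
class CreepCurve:
    """Sampled creep compliance J(t): times in s, compliance in 1/Pa."""

    times: np.ndarray
    compliance: np.ndarray

    def __post_init__(self):
        t = _as_positive_array(self.times, "times", allow_zero=True)
        j = np.atleast_1d(np.asarray(self.compliance, dtype=float))
        if t.shape != j.shape:
            raise ValidationError("times and compliance must have equal length")
        _check_strictly_increasing(t, "times")
        if np.any(~np.isfinite(j)) or np.any(j < 0):
            raise ValidationError("compliance must be finite and non-negative")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "compliance", j)

    def __len__(self) -> int:
        return self.times.size


@dataclass(frozen=True)
class ModulusCurve:
    """Sampled complex modulus: omega in rad/s, storage/loss in Pa."""

    omega: np.ndarray
    storage: np.ndarray
    loss: np.ndarray

    def __post_init__(self):
        w = _as_positive_array(self.omega, "omega")
        gp = np.atleast_1d(np.asarray(self.storage, dtype=float))
        gpp = np.atleast_1d(np.asarray(self.loss, dtype=float))
        if not (w.shape == gp.shape == gpp.shape):
            raise ValidationError("omega, storage and loss must have equal length")
        _check_strictly_increasing(w, "omega")
        for name, arr in (("storage", gp), ("loss", gpp)):
            if np.any(~np.isfinite(arr)) or np.any(arr < 0):
                raise ValidationError(f"{name} must be finite and non-negative")
        object.__setattr__(self, "omega", w)
        object.__setattr__(self, "storage", gp)
        object.__setattr__(self, "loss", gpp)

    def __len__(self) -> int:
        return self.omega.size

    @property
    def magnitude(self) -> np.ndarray:
        return np.hypot(self.storage, self.loss)

    @property
    def complex(self) -> np.ndarray:
        return self.storage + 1j * self.loss


# ---------------------------------------------------------------------------
# Closed forms
# ---------------------------------------------------------------------------


def _creep_levels(params: HierParams, times: np.ndarray) -> np.ndarray:
    """Level-n compliance.  The recursion is evaluated in the rationalized
    form ``J_{k+1} = 2 J_k / (1 + sqrt(1 + 4 E_{k+1} J_k))`` which is
    algebraically identical to the textbook form but stays finite as
    ``E_{k+1} -> 0`` (the degenerate-level limit)."""
    tau = params.relaxation_time
    e1 = params.stiffness[0]
    j = (-1.0 + np.sqrt(1.0 + 4.0 * times / tau)) / (2.0 * e1)
    for ek in params.stiffness[1:]:
        j = 2.0 * j / (1.0 + np.sqrt(1.0 + 4.0 * ek * j))
    return j


def creep_compliance(params: HierParams, times) -> CreepCurve:
    """Closed-form creep compliance of the level-n hierarchy.

    ``J1(t) = (-1 + sqrt(1 + 4 t/tau)) / (2 E1)`` and each further level
    applies ``J_{k+1} = (-1 + sqrt(1 + 4 E_{k+1} J_k)) / (2 E_{k+1})``.
    Levels beyond three follow the same recursion (an extrapolation beyond
    the three-level cell picture).

    Parameters
    ----------
    params : HierParams
    times : array_like
        Non-negative times in seconds (need not be sorted for evaluation,
        but the returned curve requires a strictly increasing grid).
    """
    t = _as_positive_array(times, "times", allow_zero=True)
    return CreepCurve(times=t, compliance=_creep_levels(params, t))


def _modulus_levels(params: HierParams, omega: np.ndarray) -> np.ndarray:
    tau = params.relaxation_time
    e1 = params.stiffness[0]
    z = 1j * omega * tau
    # G1 = E1 * (1 + sqrt(1 + 4/z)) / (2/z); principal branch.  For z = i*w*tau
    # with w > 0 the argument 1 + 4/z = 1 - 4i/(w*tau) has real part >= 1, so
    # the principal square root is continuous over the whole frequency axis.
    g = e1 * z * (1.0 + np.sqrt(1.0 + 4.0 / z)) / 2.0
    for ek in params.stiffness[1:]:
        g = (g + np.sqrt(g * g + 4.0 * ek * g)) / 2.0
    return g


def complex_modulus(params: HierParams, omega) -> ModulusCurve:
    """Closed-form complex modulus ``G*_n(omega)`` of the hierarchy.

    Frequencies are angular (rad/s).  Returns storage ``G'`` and loss
    ``G''`` parts of the level-n modulus.
    """
    w = _as_positive_array(omega, "omega")
    g = _modulus_levels(params, w)
    return ModulusCurve(omega=w, storage=g.real, loss=g.imag)


def complex_modulus_values(params: HierParams, omega) -> np.ndarray:
    """Complex-valued ``G*_n`` on an arbitrary positive frequency array."""
    w = _as_positive_array(omega, "omega")
    return _modulus_levels(params, w)


def local_exponent(
    params: HierParams,
    at,
    domain: Literal["time", "frequency"] = "time",
    component: Literal["abs", "storage", "loss"] = "abs",
):
    """Analytic local power-law exponent of the hierarchy.

    In the time domain this is ``d log J_n / d log t`` obtained by the
    chain rule through the level recursion; in the frequency domain it is
    the local slope of ``log G`` versus ``log omega`` where ``G`` is the
    modulus magnitude (default), the storage part or the loss part.

    Returns a scalar for scalar input, else an array.
    """
    scalar = np.isscalar(at) or np.ndim(at) == 0
    x = _as_positive_array(at, "at")
    tau = params.relaxation_time
    e1 = params.stiffness[0]
    if domain == "time":
        if component != "abs":
            raise ValidationError("component applies to the frequency domain only")
        u = 1.0 + 4.0 * x / tau
        j = (-1.0 + np.sqrt(u)) / (2.0 * e1)
        dj = 1.0 / (e1 * tau * np.sqrt(u))  # dJ1/dt
        for ek in params.stiffness[1:]:
            r = np.sqrt(1.0 + 4.0 * ek * j)
            dj = dj / r
            j = 2.0 * j / (1.0 + r)
        alpha = x * dj / j
    elif domain == "frequency":
        z = 1j * x * tau
        w = np.sqrt(1.0 + 4.0 / z)
        g = e1 * z * (1.0 + w) / 2.0
        dg = 1j * tau * e1 * (1.0 + w - 2.0 / (z * w)) / 2.0  # dG1/domega
        for ek in params.stiffness[1:]:
            r = np.sqrt(g * g + 4.0 * ek * g)
            dgdG = (1.0 + (g + 2.0 * ek) / r) / 2.0
            dg = dg * dgdG
            g = (g + r) / 2.0
        if component == "abs":
            alpha = np.real(x * dg / g)
        elif component == "storage":
            alpha = x * dg.real / g.real
        elif component == "loss":
            alpha = x * dg.imag / g.imag
        else:
            raise ValidationError(f"unknown component {component!r}")
    else:
        raise ValidationError(f"unknown domain {domain!r}")
    return float(alpha[0]) if scalar else alpha


def kelvin_voigt_creep(kv: KelvinVoigtParams, times) -> CreepCurve:
    """Step-stress creep of the 1-D Kelvin--Voigt element:
    ``J(t) = (1 - exp(-t/tau)) / E``."""
    t = _as_positive_array(times, "times", allow_zero=True)
    j = -np.expm1(-t / kv.relaxation_time) / kv.stiffness
    return CreepCurve(times=t, compliance=j)


# ---------------------------------------------------------------------------
# Named presets (material-table values; they configure examples only)
# ---------------------------------------------------------------------------

#: Kelvin--Voigt material presets: cytoplasm (100 Pa, 300 s) and
#: membrane (1000 Pa, 20 s).
KV_PRESETS = {
    "cytoplasm": KelvinVoigtParams(stiffness=100.0, relaxation_time=300.0),
    "membrane": KelvinVoigtParams(stiffness=1000.0, relaxation_time=20.0),
}

#: Hierarchical-model presets.  "cytoplasm" is the 1-level cytoplasm ladder
#: with the tabulated E = 100 Pa, tau = 300 s.  "cell-2level"/"cell-3level"
#: stack equal-stiffness levels on top of it.  "hasm" is an HASM-like cell
#: for frequency-sweep fitting: same stiffnesses but the experimentally
#: measured cytoplasmic viscosity 1.41 Pa*s (tau ~ 14 ms).
PRESETS = {
    "cytoplasm": HierParams([100.0], viscosity=100.0 * 300.0),
    "cell-2level": HierParams([100.0, 100.0], viscosity=100.0 * 300.0),
    "cell-3level": HierParams([100.0, 100.0, 100.0], viscosity=100.0 * 300.0),
    "hasm": HierParams([100.0, 100.0, 100.0], viscosity=1.41),
}


def preset(name: str) -> HierParams:
    """Look up a named hierarchical-model preset."""
    try:
        return PRESETS[name]
    except KeyError:
        raise ValidationError(
            f"unknown preset {name!r}; available: {sorted(PRESETS)}"
        ) from None
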