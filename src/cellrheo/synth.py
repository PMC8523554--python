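"""Model-faithful synthetic rheology datasets.

Emulates the experimental settings the model addresses: frequency sweeps
of storage/loss moduli over ~4 decades, creep curves over ~5 decades of
time, and populations of synthetic cells whose stiffness is regulated by
one model parameter (varying the level-2 stiffness is the analytic
surrogate for varying the microtubule count).

Noise is multiplicative log-normal (rheology data are strictly positive
and span decades), independent between storage and loss channels, with a
default sigma of 0.05; every generator is a pure function of its spec
and seed.  Instrument artifacts (inertia, tool compliance, drift) are
not emulated.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List

import numpy as np

from .analysis import StiffnessExponentPoint, _apply_param
from .model import (
    CreepCurve,
    HierParams,
    ModulusCurve,
    ValidationError,
    complex_modulus,
    creep_compliance,
    local_exponent,
)

__all__ = [
    "NoiseSpec",
    "PopulationSpec",
    "generate_modulus_dataset",
    "generate_creep_dataset",
    "generate_cell_population",
]


@dataclass(frozen=True)
class NoiseSpec:
    """Multiplicative log-normal noise: each value is multiplied by an
    independent ``exp(N(0, sigma_log**2))`` draw."""

    sigma_log: float = 0.05
    seed: int = 0

    def __post_init__(self):
        if self.sigma_log < 0 or not np.isfinite(self.sigma_log):
            raise ValidationError("sigma_log must be finite and >= 0")


@dataclass(frozen=True)
class PopulationSpec:
    """A population of ``m`` synthetic cells; one parameter is drawn
    log-uniformly in ``[low, high]`` around the base model."""

    base: HierParams
    vary: str = "E2"
    low: float = 0.1
    high: float = 10.0
    m: int = 50
    seed: int = 0

    def __post_init__(self):
        if self.m < 1:
            raise ValidationError("m must be >= 1")
        if not (0 < self.low <= self.high):
            raise ValidationError("range must be positive with low <= high")
        _apply_param(self.base, self.vary, 1.0)  # validates the name


def _noise_factors(rng: np.random.Generator, sigma: float, n: int) -> np.ndarray:
    return np.exp(rng.normal(0.0, sigma, size=n)) if sigma > 0 else np.ones(n)


def generate_modulus_dataset(
    params: HierParams,
    omega_min: float = 1e-2,
    omega_max: float = 1e2,
    n_points: int = 30,
    noise: NoiseSpec = NoiseSpec(),
) -> ModulusCurve:
    """Noisy frequency sweep on a log-spaced grid of angular frequency.

    Storage and loss channels receive independent noise draws; with
    ``sigma_log = 0`` the exact model values are returned.
    """
    if not 0 < omega_min < omega_max:
        raise ValidationError("need 0 < omega_min < omega_max")
    if n_points < 2:
        raise ValidationError("n_points must be >= 2")
    omega = np.logspace(np.log10(omega_min), np.log10(omega_max), int(n_points))
    exact = complex_modulus(params, omega)
    rng = np.random.default_rng(noise.seed)
    gp = exact.storage * _noise_factors(rng, noise.sigma_log, omega.size)
    gpp = exact.loss * _noise_factors(rng, noise.sigma_log, omega.size)
    return ModulusCurve(omega=omega, storage=gp, loss=gpp)


def generate_creep_dataset(
    params: HierParams,
    t_min: float = 1e-1,
    t_max: float = 1e4,
    n_points: int = 30,
    noise: NoiseSpec = NoiseSpec(),
) -> CreepCurve:
    """Noisy creep curve on a log-spaced time grid (5 decades default)."""
    if not 0 < t_min < t_max:
        raise ValidationError("need 0 < t_min < t_max")
    if n_points < 2:
        raise ValidationError("n_points must be >= 2")
    times = np.logspace(np.log10(t_min), np.log10(t_max), int(n_points))
    exact = creep_compliance(params, times)
    rng = np.random.default_rng(noise.seed)
    j = exact.compliance * _noise_factors(rng, noise.sigma_log, times.size)
    return CreepCurve(times=times, compliance=j)


def generate_cell_population(
    spec: PopulationSpec,
    eval_time: float,
    stiffness_time: float = 1.0,
) -> List[StiffnessExponentPoint]:
    """Synthetic (stiffness, exponent) population.

    For each cell the varied parameter is drawn log-uniformly, the
    stiffness is ``1/J(stiffness_time)`` (1 s by convention) and the
    exponent is the analytic local slope at ``eval_time``.  Deterministic
    per seed.
    """
    if eval_time <= 0:
        raise ValidationError("eval_time must be > 0")
    rng = np.random.default_rng(spec.seed)
    if spec.vary == "eta":
        base_value = spec.base.viscosity
    else:
        base_value = spec.base.stiffness[int(spec.vary[1:]) - 1]
    draws = base_value * np.exp(
        rng.uniform(np.log(spec.low), np.log(spec.high), size=spec.m)
    )
    points = []
    for value in draws:
        p = _apply_param(spec.base, spec.vary, float(value))
        j = creep_compliance(p, [stiffness_time]).compliance[0]
        alpha = local_exponent(p, eval_time)
        points.append(StiffnessExponentPoint(stiffness=1.0 / j, exponent=alpha))
    return points
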