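"""Estimation of hierarchical-model parameters from rheology curves.

Fits the closed-form hierarchy to frequency sweeps (storage + loss
moduli) or creep curves by trust-region least squares on log-space
residuals.  Moduli span decades, so residuals are taken on ``ln G``; the
parameters ``(E1..En, eta)`` are optimised in log space, which enforces
positivity and makes multiplicative multistart jitter natural.

The estimator is original to this package: published fits of this model
to cell data report the resulting parameters but not the fitting
algorithm, weights, or initialisation, so every choice here (log-space
loss, 1:1 storage/loss weighting, plateau-based automatic initials,
seeded multistart) is our own and documented as such.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .model import (
    CreepCurve,
    HierParams,
    ModulusCurve,
    ValidationError,
    _creep_levels,
    _modulus_levels,
)

__all__ = [
    "FitConfig",
    "FitResult",
    "ConvergenceError",
    "fit_complex_modulus",
    "fit_creep",
    "profile_identifiability",
    "DRUG_SCENARIOS",
    "apply_drug_scenario",
]


class ConvergenceError(RuntimeError):
    """All multistart attempts failed; message carries per-start detail."""


#: Qualitative drug-treatment directions for synthetic scenario generation:
#: histamine permeabilises the cell and promotes contraction (cytoplasmic
#: stiffness E1 down, cytoskeletal E2/E3 up); DBcAMP inhibits contraction
#: and cytochalasin D dissolves the actin network (both: E2/E3 down).
#: Values are per-parameter multiplicative directions (+1 up, -1 down, 0
#: unchanged) -- metadata, never fitted values.
DRUG_SCENARIOS = {
    "histamine": {"E1": -1, "E2": +1, "E3": +1, "eta": 0},
    "dbcamp": {"E1": 0, "E2": -1, "E3": -1, "eta": 0},
    "cytochalasin_d": {"E1": 0, "E2": -1, "E3": -1, "eta": 0},
}


def apply_drug_scenario(base: HierParams, drug: str, fold: float = 2.0) -> HierParams:
    """Shift ``base`` parameters in the qualitative direction of a drug
    treatment by the multiplicative factor ``fold``."""
    if drug not in DRUG_SCENARIOS:
        raise ValidationError(f"unknown drug {drug!r}; known: {sorted(DRUG_SCENARIOS)}")
    if fold <= 0:
        raise ValidationError("fold must be > 0")
    directions = DRUG_SCENARIOS[drug]
    stiff = list(base.stiffness)
    for level in range(1, base.n_levels + 1):
        d = directions.get(f"E{level}", 0)
        stiff[level - 1] *= fold**d
    eta = base.viscosity * fold ** directions.get("eta", 0)
    return HierParams(stiff, eta)


@dataclass(frozen=True)
class FitConfig:
    """Configuration of a hierarchical-model fit.

    ``init`` may be an explicit :class:`HierParams` start or ``None`` for
    the automatic heuristic (E1 from the low-frequency storage plateau,
    eta from high-frequency G''/omega, upper levels from the geometric
    mean of the modulus range).  ``bounds`` are (lower, upper) multiplier
    ranges applied to a data-derived scale; loss is always computed in
    log space.
    """

    n_levels: int = 3
    init: Optional[HierParams] = None
    bounds: tuple = (1e-6, 1e6)
    n_multistart: int = 5
    seed: int = 0
    loss_weight: float = 1.0  # weight of ln G'' residuals relative to ln G'
    jitter_sigma: float = 1.0  # multistart jitter sd in ln-parameter units

    def __post_init__(self):
        if self.n_levels < 1:
            raise ValidationError("n_levels must be >= 1")
        if self.n_multistart < 1:
            raise ValidationError("n_multistart must be >= 1")
        lo, hi = self.bounds
        if not (0 < lo < hi):
            raise ValidationError("bounds must be positive with lower < upper")
        if self.loss_weight <= 0:
            raise ValidationError("loss_weight must be > 0")


@dataclass(frozen=True)
class FitResult:
    """Outcome of a multistart fit."""

    params: HierParams
    loss: float
    converged: bool
    n_iter: int
    start_index: int
    residuals: np.ndarray
    start_losses: tuple
    config: FitConfig

    def __post_init__(self):
        if self.loss < 0:
            raise ValidationError("loss must be non-negative")

    def to_dict(self) -> dict:
        return {
            "schema_version": 1,
            "stiffness_pa": list(self.params.stiffness),
            "viscosity_pa_s": self.params.viscosity,
            "relaxation_time_s": self.params.relaxation_time,
            "loss": self.loss,
            "converged": self.converged,
            "n_iter": self.n_iter,
            "start_index": self.start_index,
            "start_losses": list(self.start_losses),
            "config": {
                "n_levels": self.config.n_levels,
                "n_multistart": self.config.n_multistart,
                "seed": self.config.seed,
                "bounds": list(self.config.bounds),
                "loss_weight": self.config.loss_weight,
            },
        }


# ---------------------------------------------------------------------------
# Internals
# ---------------------------------------------------------------------------


def _theta_to_params(theta: np.ndarray) -> HierParams:
    return HierParams(np.exp(theta[:-1]), float(np.exp(theta[-1])))


def _auto_init_modulus(data: ModulusCurve, n_levels: int) -> np.ndarray:
    e1 = max(float(np.min(data.storage)), 1e-12)
    eta = float(np.median(data.loss[-5:] / data.omega[-5:]))
    mid = float(np.sqrt(np.max(data.storage) * np.min(data.storage)))
    return np.log(np.array([e1] + [mid] * (n_levels - 1) + [eta]))

def _auto_init_creep(data: CreepCurve, n_levels: int) -> np.ndarray:
    # long-time compliance bounds the softest spring; early slope gives eta
    e1 = 1.0 / float(np.max(data.compliance))
    t, j = data.times, data.compliance
    pos = (t > 0) & (j > 0)
    eta = float(np.median(t[pos][:5] / j[pos][:5]))
    return np.log(np.array([e1] + [e1] * (n_levels - 1) + [eta]))


def _multistart(residual_fn, theta0, config: FitConfig):
    rng = np.random.default_rng(config.seed)
    lo, hi = np.log(config.bounds[0]), np.log(config.bounds[1])
    lower = np.maximum(theta0 + lo, -60.0)
    upper = np.minimum(theta0 + hi, 60.0)
    starts = [np.clip(theta0, lower, upper)]
    for _ in range(config.n_multistart - 1):
        jit = rng.normal(0.0, config.jitter_sigma, size=theta0.size)
        starts.append(np.clip(theta0 + jit, lower, upper))
    best = None
    diagnostics = []
    losses = []
    for idx, start in enumerate(starts):
        try:
            sol = least_squares(
                residual_fn,
                start,
                bounds=(lower, upper),
                method="trf",
                ftol=1e-10,
                xtol=1e-14,
                gtol=1e-8,
                max_nfev=2000,
            )
        except Exception as exc:
            diagnostics.append(f"start {idx}: raised {exc!r}")
            losses.append(np.inf)
            continue
        loss = float(2.0 * sol.cost)
        losses.append(loss)
        if not sol.success:
            diagnostics.append(f"start {idx}: {sol.message}")
            continue
        if best is None or loss < best[1]:
            best = (idx, loss, sol)
    if best is None:
        raise ConvergenceError(
            "no multistart converged: " + "; ".join(diagnostics)
        )
    idx, loss, sol = best
    return FitResult(
        params=_theta_to_params(sol.x),
        loss=loss,
        converged=True,
        n_iter=int(sol.nfev),
        start_index=idx,
        residuals=np.asarray(sol.fun),
        start_losses=tuple(losses),
        config=config,
    )


# ---------------------------------------------------------------------------
# Public fits
# ---------------------------------------------------------------------------


def fit_complex_modulus(data: ModulusCurve, config: FitConfig = FitConfig()) -> FitResult:
    """Fit the n-level hierarchy to a frequency sweep.

    Minimises ``sum[(ln G'_model - ln G'_data)^2 + w*(ln G''_model -
    ln G''_data)^2]`` over log-parameterised ``(E1..En, eta)``; multistart
    with seed-jittered initials; deterministic given the seed.
    """
    if len(data) < 2 * (config.n_levels + 1):
        raise ValidationError(
            f"need at least {2 * (config.n_levels + 1)} data points for "
            f"{config.n_levels + 1} parameters, got {len(data)}"
        )
    if np.any(data.storage <= 0) or np.any(data.loss <= 0):
        raise ValidationError("moduli must be strictly positive for log residuals")
    omega = data.omega
    ln_gp, ln_gpp = np.log(data.storage), np.log(data.loss)
    w = np.sqrt(config.loss_weight)

    def residual(theta):
        g = _modulus_levels(_theta_to_params(theta), omega)
        with np.errstate(divide="ignore", invalid="ignore"):
            rp = np.log(np.maximum(g.real, 1e-300)) - ln_gp
            rpp = np.log(np.maximum(g.imag, 1e-300)) - ln_gpp
        return np.concatenate([rp, w * rpp])

    theta0 = (
        _params_to_theta(config.init)
        if config.init is not None
        else _auto_init_modulus(data, config.n_levels)
    )
    return _multistart(residual, theta0, config)


def fit_creep(data: CreepCurve, config: FitConfig = FitConfig()) -> FitResult:
    """Fit the n-level hierarchy to a creep curve (residuals on ``ln J``)."""
    pos = data.times > 0
    if int(pos.sum()) < 2 * (config.n_levels + 1):
        raise ValidationError(
            f"need at least {2 * (config.n_levels + 1)} positive-time points, "
            f"got {int(pos.sum())}"
        )
    t = data.times[pos]
    j = data.compliance[pos]
    if np.any(j <= 0):
        raise ValidationError("compliance must be strictly positive for log residuals")
    ln_j = np.log(j)

    def residual(theta):
        model = _creep_levels(_theta_to_params(theta), t)
        return np.log(np.maximum(model, 1e-300)) - ln_j

    theta0 = (
        _params_to_theta(config.init)
        if config.init is not None
        else _auto_init_creep(CreepCurve(t, j), config.n_levels)
    )
    return _multistart(residual, theta0, config)


def _params_to_theta(params: HierParams) -> np.ndarray:
    return np.log(np.array(list(params.stiffness) + [params.viscosity]))


def profile_identifiability(
    data: Union[ModulusCurve, CreepCurve],
    result: FitResult,
    param: str,
    grid,
    noise_scale: float = 0.05,
) -> pd.DataFrame:
    """Profile likelihood of one parameter.

    Re-optimises all other parameters at each fixed value of the
    profiled one (grid of multipliers on the fitted value).  The profile
    is flagged flat (non-identifiable) when, over a grid spanning at
    least a decade, the loss changes by less than 1% of the larger of
    the fitted loss and the loss of a typical ``noise_scale``-level
    dataset -- variations far below measurement noise do not constrain
    the parameter.
    """
    if not result.converged:
        raise ValidationError("profile requires a converged FitResult")
    grid = np.atleast_1d(np.asarray(grid, dtype=float))
    if grid.size < 2:
        raise ValidationError("grid must contain at least 2 multipliers")
    if np.any(grid <= 0):
        raise ValidationError("grid multipliers must be > 0")
    n = result.params.n_levels
    names = [f"E{k}" for k in range(1, n + 1)] + ["eta"]
    if param not in names:
        raise ValidationError(f"unknown parameter {param!r}; valid: {names}")
    pidx = names.index(param)
    theta_hat = _params_to_theta(result.params)
    free = [i for i in range(len(names)) if i != pidx]

    if isinstance(data, ModulusCurve):
        omega, ln_gp, ln_gpp = data.omega, np.log(data.storage), np.log(data.loss)
        w = np.sqrt(result.config.loss_weight)

        def full_residual(theta):
            g = _modulus_levels(_theta_to_params(theta), omega)
            rp = np.log(np.maximum(g.real, 1e-300)) - ln_gp
            rpp = np.log(np.maximum(g.imag, 1e-300)) - ln_gpp
            return np.concatenate([rp, w * rpp])

    else:
        pos = data.times > 0
        t, ln_j = data.times[pos], np.log(data.compliance[pos])

        def full_residual(theta):
            model = _creep_levels(_theta_to_params(theta), t)
            return np.log(np.maximum(model, 1e-300)) - ln_j

    rows = []
    for mult in grid:
        theta = theta_hat.copy()
        theta[pidx] += np.log(mult)

        def reduced(th_free, fixed=theta[pidx]):
            th = np.empty_like(theta_hat)
            th[free] = th_free
            th[pidx] = fixed
            return full_residual(th)

        sol = least_squares(reduced, theta[free], method="trf", ftol=1e-12, xtol=1e-14)
        rows.append(
            {
                "parameter": param,
                "multiplier": float(mult),
                "value": float(np.exp(theta[pidx])),
                "loss": float(2.0 * sol.cost),
            }
        )
    table = pd.DataFrame(rows)
    span = np.log10(grid.max() / grid.min())
    n_res = result.residuals.size
    floor = max(float(result.loss), n_res * noise_scale**2)
    change = float(table.loss.max() - table.loss.min())
    table.attrs["flat"] = bool(span >= 1.0 and change < 0.01 * floor)
    return table
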