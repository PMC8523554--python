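"""Power-law analysis of rheology curves.

Covers log-log power-law fitting of creep and modulus curves, the
exponent--stiffness relation

    alpha = -log(1/J0)/log(1/tau0) + log(j0)/log(tau0),

where ``J0`` is the compliance at t = 1 s and ``(tau0, j0)`` the common
intersection point of the creep curves ``J(t) = j0 (t/tau0)**alpha``,
master-curve regression of exponent versus log-stiffness, deterministic
parameter sweeps, and Lissajous stress--strain ellipses under sinusoidal
load.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations
from typing import Literal, Sequence, Union

import numpy as np
import pandas as pd

from .model import (
    CreepCurve,
    HierParams,
    ModulusCurve,
    ValidationError,
    complex_modulus_values,
    creep_compliance,
    local_exponent,
)

__all__ = [
    "PowerLawFit",
    "StiffnessExponentPoint",
    "LissajousCurve",
    "MasterCurveFit",
    "ParallelCurvesError",
    "fit_power_law",
    "intercept_term",
    "predict_alpha",
    "estimate_intersection",
    "master_curve",
    "sweep_exponents",
    "lissajous",
    "lissajous_area",
]


class ParallelCurvesError(RuntimeError):
    """Fitted log-log lines are parallel within tolerance; no common
    intersection point exists.  Carries the common slope."""

    def __init__(self, common_slope: float):
        self.common_slope = common_slope
        super().__init__(
            "fitted lines are parallel within tolerance (slope spread < 0.01); "
            f"the power-law exponent is the common slope {common_slope:.4f}"
        )


@dataclass(frozen=True)
class PowerLawFit:
    """Power law ``J(t) = j0 * (t / tau0)**alpha`` fitted on a log-log
    window.  ``rms_residual`` is in natural-log units."""

    exponent: float
    prefactor: float
    timescale: float
    fit_window: tuple
    rms_residual: float
    n_points: int

    def __post_init__(self):
        if not np.isfinite(self.exponent):
            raise ValidationError("exponent must be finite")
        if self.prefactor <= 0 or self.timescale <= 0:
            raise ValidationError("prefactor and timescale must be > 0")

    def __call__(self, t):
        return self.prefactor * (np.asarray(t, dtype=float) / self.timescale) ** self.exponent


@dataclass(frozen=True)
class StiffnessExponentPoint:
    """One synthetic cell: stiffness 1/J(1 s) (or G' at 1 rad/s) in Pa and
    its power-law exponent."""

    stiffness: float
    exponent: float

    def __post_init__(self):
        if not (np.isfinite(self.stiffness) and self.stiffness > 0):
            raise ValidationError("stiffness must be finite and > 0")
        if not (np.isfinite(self.exponent) and 0.0 < self.exponent < 1.0):
            raise ValidationError("exponent must lie in (0, 1)")


@dataclass(frozen=True)
class LissajousCurve:
    """One steady-state stress--strain cycle under sinusoidal stress."""

    stress: np.ndarray
    strain: np.ndarray
    omega: float
    stress_amplitude: float

    def __post_init__(self):
        sig = np.asarray(self.stress, dtype=float)
        eps = np.asarray(self.strain, dtype=float)
        if sig.shape != eps.shape or sig.ndim != 1 or sig.size < 3:
            raise ValidationError("stress and strain must be equal-length 1-d arrays")
        if not (np.isclose(sig[0], sig[-1]) and np.isclose(eps[0], eps[-1])):
            raise ValidationError("the cycle must be closed (first point = last point)")
        object.__setattr__(self, "stress", sig)
        object.__setattr__(self, "strain", eps)


@dataclass(frozen=True)
class MasterCurveFit:
    """Least-squares line ``alpha = slope * log10(stiffness) + intercept``."""

    slope: float
    intercept: float
    rms_residual: float
    span_decades: float
    narrow_span: bool


# ---------------------------------------------------------------------------
# Power-law fitting
# ---------------------------------------------------------------------------


def _curve_xy(curve):
    if isinstance(curve, CreepCurve):
        return curve.times, curve.compliance, "time_s"
    if isinstance(curve, ModulusCurve):
        return curve.omega, curve.magnitude, "omega_rad_per_s"
    raise ValidationError("curve must be a CreepCurve or ModulusCurve")


def fit_power_law(
    curve: Union[CreepCurve, ModulusCurve],
    window: tuple = None,
    timescale: float = 1.0,
) -> PowerLawFit:
    """Ordinary least squares of log ordinate on log abscissa.

    For a :class:`ModulusCurve` the ordinate is the modulus magnitude
    ``|G*|``.  The exponent is the slope; the prefactor ``j0`` is reported
    at the reference ``timescale`` (1 s unless an intersection timescale
    is supplied, e.g. from :func:`estimate_intersection`).
    """
    x, y, xname = _curve_xy(curve)
    if window is None:
        mask = np.ones_like(x, dtype=bool)
        window = (float(x[0]), float(x[-1]))
    else:
        lo, hi = float(window[0]), float(window[1])
        if not lo < hi:
            raise ValidationError("window must satisfy min < max")
        mask = (x >= lo) & (x <= hi)
    if mask.sum() < 3:
        raise ValidationError(
            f"need at least 3 in-window points, found {int(mask.sum())} "
            f"({xname} window {window})"
        )
    bad = np.flatnonzero(y[mask] <= 0)
    if bad.size:
        rows = np.flatnonzero(mask)[bad]
        raise ValidationError(
            f"non-positive ordinate values at rows {rows.tolist()}"
        )
    if timescale <= 0:
        raise ValidationError("timescale must be > 0")
    lx = np.log(x[mask] / timescale)
    ly = np.log(y[mask])
    slope, logj0 = np.polyfit(lx, ly, 1)
    resid = ly - (slope * lx + logj0)
    return PowerLawFit(
        exponent=float(slope),
        prefactor=float(np.exp(logj0)),
        timescale=float(timescale),
        fit_window=(float(window[0]), float(window[1])),
        rms_residual=float(np.sqrt(np.mean(resid**2))),
        n_points=int(mask.sum()),
    )


# ---------------------------------------------------------------------------
# Exponent--stiffness relation
# ---------------------------------------------------------------------------


def intercept_term(j0: float, tau0: float) -> float:
    """The intercept ``log(j0)/log(tau0)`` of the exponent--stiffness
    relation.  The ratio is independent of the log base (natural logs are
    used internally)."""
    if j0 <= 0 or tau0 <= 0:
        raise ValidationError("j0 and tau0 must be > 0")
    if tau0 == 1.0:
        raise ValidationError("tau0 = 1 s makes the relation singular (log(tau0) = 0)")
    return float(np.log(j0) / np.log(tau0))


def predict_alpha(J0_inverse: float, j0: float, tau0: float) -> float:
    """Exponent predicted from the stiffness ``1/J0`` (compliance at 1 s):

    ``alpha = -log(1/J0)/log(1/tau0) + log(j0)/log(tau0)``.

    Algebraically the exact inverse of ``J0 = j0 * tau0**(-alpha)``.
    """
    if J0_inverse <= 0:
        raise ValidationError("stiffness 1/J0 must be > 0")
    base = intercept_term(j0, tau0)
    return float(-np.log(J0_inverse) / np.log(1.0 / tau0) + base)


def estimate_intersection(fits: Sequence[PowerLawFit], slope_tol: float = 0.01):
    """Common intersection point ``(tau0, j0)`` of fitted log-log lines,
    estimated as the median of all pairwise line intersections.

    If the lines are parallel within ``slope_tol`` (slope spread), there
    is no intersection — mirrors the high-stiffness regime where creep
    curves become parallel — and :class:`ParallelCurvesError` is raised
    carrying the common slope.
    """
    if len(fits) < 2:
        raise ValidationError("need at least two fits to intersect")
    slopes = np.array([f.exponent for f in fits])
    # lines in log-log space: log J = a_i * log(t/tau_i) + log j_i
    icepts = np.array([np.log(f.prefactor) - f.exponent * np.log(f.timescale) for f in fits])
    if slopes.max() - slopes.min() < slope_tol:
        raise ParallelCurvesError(common_slope=float(np.mean(slopes)))
    lts, ljs = [], []
    for i, j in combinations(range(len(fits)), 2):
        da = slopes[i] - slopes[j]
        if abs(da) < slope_tol:
            continue
        lt = (icepts[j] - icepts[i]) / da
        lts.append(lt)
        ljs.append(slopes[i] * lt + icepts[i])
    tau0 = float(np.exp(np.median(lts)))
    j0 = float(np.exp(np.median(ljs)))
    return tau0, j0


def master_curve(points: Sequence[StiffnessExponentPoint]) -> MasterCurveFit:
    """Least-squares master curve ``alpha`` versus ``log10(stiffness)``.

    Requires >= 3 points; a stiffness span below one decade is flagged
    (and warned about) but the fit is still returned.  Identical stiffness
    values are a degenerate design and raise.
    """
    if len(points) < 3:
        raise ValidationError("need at least 3 points for a master curve")
    s = np.array([p.stiffness for p in points])
    a = np.array([p.exponent for p in points])
    span = float(np.log10(s.max() / s.min()))
    if span == 0.0:
        raise ValidationError("identical stiffness values: degenerate design")
    narrow = span < 1.0
    if narrow:
        warnings.warn(
            f"stiffness span is only {span:.2f} decades (< 1); "
            "master-curve slope may be poorly constrained",
            stacklevel=2,
        )
    slope, intercept = np.polyfit(np.log10(s), a, 1)
    resid = a - (slope * np.log10(s) + intercept)
    return MasterCurveFit(
        slope=float(slope),
        intercept=float(intercept),
        rms_residual=float(np.sqrt(np.mean(resid**2))),
        span_decades=span,
        narrow_span=narrow,
    )


# ---------------------------------------------------------------------------
# Parameter sweeps
# ---------------------------------------------------------------------------

_PARAM_NAMES = ("E1", "E2", "E3", "eta")


def _apply_param(base: HierParams, name: str, value: float) -> HierParams:
    if name == "eta":
        return HierParams(base.stiffness, value)
    if (
        name.startswith("E")
        and name[1:].isdigit()
        and 1 <= int(name[1:]) <= base.n_levels
    ):
        return base.with_stiffness(int(name[1:]), value)
    raise ValidationError(
        f"unknown parameter {name!r}; valid names: E1..E{base.n_levels}, eta"
    )


def sweep_exponents(
    base: HierParams,
    vary: str,
    grid,
    eval_at: float,
    stiffness_time: float = 1.0,
) -> pd.DataFrame:
    """Deterministic sweep of one model parameter.

    ``grid`` holds multipliers applied to the base value of ``vary``.
    For each value the table records the parameter value, the stiffness
    ``1/J(stiffness_time)`` and the analytic local exponent at time
    ``eval_at``.  A warning is issued when ``eval_at`` is not well beyond
    the relaxation time (the exponent is then pre-asymptotic).
    """
    grid = np.atleast_1d(np.asarray(grid, dtype=float))
    if np.any(grid <= 0):
        raise ValidationError("grid multipliers must be > 0")
    if vary == "eta":
        base_value = base.viscosity
    else:
        _apply_param(base, vary, 1.0)  # validates the name
        base_value = base.stiffness[int(vary[1:]) - 1]
    if eval_at < 100.0 * base.relaxation_time:
        warnings.warn(
            "eval_at is below ~100 tau; the local exponent is pre-asymptotic",
            stacklevel=2,
        )
    rows = []
    for mult in grid:
        value = base_value * mult
        p = _apply_param(base, vary, value)
        j1s = creep_compliance(p, [stiffness_time]).compliance[0]
        rows.append(
            {
                "parameter": vary,
                "value": value,
                "multiplier": mult,
                "stiffness_pa": 1.0 / j1s,
                "exponent": local_exponent(p, eval_at),
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Lissajous ellipses
# ---------------------------------------------------------------------------


def lissajous(
    params: HierParams,
    omega: float,
    sigma0: float,
    n_points: int = 256,
) -> LissajousCurve:
    """Steady-state stress--strain cycle under ``sigma = sigma0 sin(wt)``.

    The strain is ``eps(t) = sigma0 |J*| sin(wt - delta)`` with
    ``J* = 1/G*`` and ``delta`` the loss angle; the parametric curve is a
    centred ellipse whose enclosed area ``pi sigma0**2 J''`` is the energy
    dissipated per cycle.
    """
    if omega <= 0 or sigma0 <= 0:
        raise ValidationError("omega and sigma0 must be > 0")
    if n_points < 16:
        raise ValidationError("n_points must be >= 16")
    g = complex_modulus_values(params, [omega])[0]
    jstar = 1.0 / g
    delta = np.angle(g)
    phase = np.linspace(0.0, 2.0 * np.pi, int(n_points) + 1)
    stress = sigma0 * np.sin(phase)
    strain = sigma0 * np.abs(jstar) * np.sin(phase - delta)
    # close exactly despite floating-point drift in sin(2*pi)
    stress[-1] = stress[0]
    strain[-1] = strain[0]
    return LissajousCurve(
        stress=stress, strain=strain, omega=float(omega), stress_amplitude=float(sigma0)
    )


def lissajous_area(curve: LissajousCurve) -> float:
    """Enclosed (dissipated-energy) area of the cycle by the shoelace
    formula; equals ``pi * sigma0**2 * J''`` analytically."""
    x, y = curve.strain, curve.stress
    return float(abs(0.5 * np.sum(x[:-1] * y[1:] - x[1:] * y[:-1])))
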