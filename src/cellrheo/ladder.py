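"""Finite spring--dashpot ladder networks as a brute-force oracle.

The closed-form hierarchy of :mod:`cellrheo.model` is the infinite-depth
limit of a ladder network with springs along the struts and dashpots on
the rungs.  This module evaluates *finite* ladders by three independent
routes so the closed forms can be validated by methods with uncorrelated
failure modes:

1. Laplace-domain continued fractions (``ladder_modulus``), optionally
   accelerated to the infinite-depth limit by iterated Aitken (Shanks)
   extrapolation of the depth convergents;
2. numerical inverse Laplace transforms (``invert_laplace``, Stehfest and
   fixed-Talbot);
3. direct stiff ODE integration of the ladder's node displacements under
   step stress (``ladder_creep_ode``).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Callable, Literal, Sequence, Union

import numpy as np
from scipy.integrate import solve_ivp

from .model import CreepCurve, HierParams, ValidationError

__all__ = [
    "Element",
    "spring",
    "dashpot",
    "LadderSpec",
    "LaplaceFunction",
    "CalibrationError",
    "IntegrationError",
    "ladder_modulus",
    "ladder_compliance_transform",
    "calibrate_topology",
    "invert_laplace",
    "ladder_creep_ode",
]


class CalibrationError(RuntimeError):
    """No candidate ladder topology reproduced the closed-form limits."""


class IntegrationError(RuntimeError):
    """The ladder creep ODE could not be integrated."""


@dataclass(frozen=True)
class Element:
    """A single mechanical element: spring (Pa) or dashpot (Pa*s)."""

    kind: Literal["spring", "dashpot"]
    value: float

    def __post_init__(self):
        if self.kind not in ("spring", "dashpot"):
            raise ValidationError(f"unknown element kind {self.kind!r}")
        if not (np.isfinite(self.value) and self.value > 0):
            raise ValidationError("element constant must be finite and > 0")

    def impedance(self, s):
        """Laplace-domain modulus contribution: E for a spring, eta*s for
        a dashpot."""
        return self.value if self.kind == "spring" else self.value * s


def spring(stiffness: float) -> Element:
    return Element("spring", float(stiffness))


def dashpot(viscosity: float) -> Element:
    return Element("dashpot", float(viscosity))


def _broadcast(elements, depth: int, name: str):
    if elements is None:
        return None
    if isinstance(elements, Element):
        return (elements,) * depth
    elems = tuple(elements)
    if len(elems) != depth:
        raise ValidationError(f"{name} must have one element per stage")
    if not all(isinstance(e, Element) for e in elems):
        raise ValidationError(f"{name} entries must be Element instances")
    return elems


@dataclass(frozen=True)
class LadderSpec:
    """A finite ladder of ``depth`` stages.

    Each stage consists of a rung element in parallel with a branch made
    of a strut element in series with the next stage.  ``entry_element``
    selects which element the load meets first: ``"rung"`` (stage = rung
    parallel to [strut in series with the rest]) or ``"strut"`` (stage =
    strut in series with [rung parallel to the rest]).  ``terminal``
    closes the last strut: ``"rigid"`` grounds it, ``"open"`` leaves it
    dangling (the branch then carries no load).

    ``rung_elements``/``strut_elements`` may be a single :class:`Element`
    (applied to every stage) or a sequence of length ``depth``;
    ``strut_elements`` may be ``None`` for single-element chains.
    """

    depth: int
    rung_elements: Union[Element, Sequence[Element]]
    strut_elements: Union[Element, Sequence[Element], None] = None
    entry_element: Literal["rung", "strut"] = "rung"
    terminal: Literal["rigid", "open"] = "rigid"

    def __post_init__(self):
        if int(self.depth) != self.depth or self.depth < 1:
            raise ValidationError("depth must be a positive integer")
        object.__setattr__(self, "depth", int(self.depth))
        object.__setattr__(
            self, "rung_elements", _broadcast(self.rung_elements, self.depth, "rung_elements")
        )
        object.__setattr__(
            self, "strut_elements", _broadcast(self.strut_elements, self.depth, "strut_elements")
        )
        if self.rung_elements is None:
            raise ValidationError("rung_elements is required")
        if self.entry_element not in ("rung", "strut"):
            raise ValidationError("entry_element must be 'rung' or 'strut'")
        if self.terminal not in ("rigid", "open"):
            raise ValidationError("terminal must be 'rigid' or 'open'")
        if self.entry_element == "strut" and self.strut_elements is None:
            raise ValidationError("entry through the strut requires strut elements")

    @property
    def is_uniform(self) -> bool:
        return (
            len(set(self.rung_elements)) == 1
            and (self.strut_elements is None or len(set(self.strut_elements)) == 1)
        )

    @property
    def topology_tag(self) -> str:
        return f"entry={self.entry_element},terminal={self.terminal}"

    # -- JSON serialization for reproducible oracle runs -----------------

    def to_json(self) -> str:
        def elem(e):
            return None if e is None else [{"kind": x.kind, "value": x.value} for x in e]

        return json.dumps(
            {
                "depth": self.depth,
                "rung_elements": elem(self.rung_elements),
                "strut_elements": elem(self.strut_elements),
                "entry_element": self.entry_element,
                "terminal": self.terminal,
                "topology": self.topology_tag,
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "LadderSpec":
        d = json.loads(text)

        def elem(seq):
            if seq is None:
                return None
            return tuple(Element(x["kind"], x["value"]) for x in seq)

        return cls(
            depth=d["depth"],
            rung_elements=elem(d["rung_elements"]),
            strut_elements=elem(d["strut_elements"]),
            entry_element=d["entry_element"],
            terminal=d["terminal"],
        )


@dataclass(frozen=True)
class LaplaceFunction:
    """An evaluable Laplace-domain function, analytic off the non-positive
    real axis."""

    func: Callable
    name: str = "F"

    def __call__(self, s):
        return self.func(s)


# ---------------------------------------------------------------------------
# Continued-fraction modulus
# ---------------------------------------------------------------------------


def _series(a, b):
    """Series composition of two moduli (compliances add).  ``b`` may be
    ``inf`` (rigid: series(a, inf) = a) or 0 (open branch)."""
    if np.isscalar(b) and np.isinf(b):
        return a
    return a * b / (a + b)


def _stage_sequence(ladder: LadderSpec, s):
    """Yield the modulus of the depth-k sub-ladder for k = 1..depth,
    built backward from the terminal stage."""
    s = np.asarray(s, dtype=complex)
    g = np.inf if ladder.terminal == "rigid" else 0.0
    out = []
    for k in range(ladder.depth - 1, -1, -1):
        zr = ladder.rung_elements[k].impedance(s)
        zs = None if ladder.strut_elements is None else ladder.strut_elements[k].impedance(s)
        if ladder.entry_element == "rung":
            g = zr if zs is None else zr + _series(zs, g)
        else:
            g = _series(zs, zr + g)
        out.append(g)
    return out


def _shanks_limit(convergents):
    """Iterated Aitken extrapolation of a geometrically converging
    sequence; used to estimate the infinite-depth ladder limit."""
    seq = [np.asarray(c, dtype=complex) for c in convergents]
    if len(seq) >= 2:
        last, prev = seq[-1], seq[-2]
        if np.all(np.abs(last - prev) <= 1e-13 * np.abs(last)):
            return last
    while len(seq) >= 3:
        nxt = []
        for x0, x1, x2 in zip(seq, seq[1:], seq[2:]):
            d1, d2 = x1 - x0, x2 - x1
            den = d2 - d1
            with np.errstate(divide="ignore", invalid="ignore"):
                acc = x2 - np.where(den != 0, d2 * d2 / np.where(den != 0, den, 1.0), 0.0)
            nxt.append(np.where(np.abs(den) > 0, acc, x2))
        seq = nxt
    return seq[-1]


def ladder_modulus(ladder: LadderSpec, s, extrapolate: bool = False):
    """Transfer modulus of a finite ladder at complex frequency ``s``.

    Evaluated by backward continued-fraction recursion from the terminal
    element (spring impedance E, dashpot impedance eta*s, series/parallel
    composition per the ladder topology).  With ``extrapolate=True`` the
    infinite-depth limit is estimated from the last nine depth convergents
    by iterated Aitken extrapolation (uniform ladders only).

    ``s`` may be a complex scalar or array with ``Re(s) > 0`` or
    ``s = i*omega``, ``omega > 0``.
    """
    s_arr = np.asarray(s, dtype=complex)
    if s_arr.size == 0:
        raise ValidationError("s must be non-empty")
    # The ladder transfer modulus is a rational function of s whose poles
    # lie on the non-positive real axis; only that axis is excluded.
    bad = (s_arr.imag == 0) & (s_arr.real <= 0)
    if np.any(bad):
        raise ValidationError("s must lie off the non-positive real axis")
    seq = _stage_sequence(ladder, s_arr)
    if not extrapolate:
        result = seq[-1]
    else:
        if not ladder.is_uniform:
            raise ValidationError("extrapolation requires a uniform ladder")
        result = _shanks_limit(seq[-min(len(seq), 9):])
    return complex(result) if np.isscalar(s) else np.asarray(result)


def ladder_compliance_transform(ladder: LadderSpec) -> LaplaceFunction:
    """Laplace transform of the ladder's creep compliance,
    ``J^(s) = 1 / (s * G(s))``."""
    return LaplaceFunction(
        func=lambda s: 1.0 / (s * ladder_modulus(ladder, s)),
        name="ladder_creep_compliance",
    )


# ---------------------------------------------------------------------------
# Topology calibration
# ---------------------------------------------------------------------------


def calibrate_topology(target: HierParams, depth: int = 64) -> LadderSpec:
    """Find the ladder topology whose infinite-depth limit reproduces the
    1-level closed form.

    Candidate entry/terminal combinations are screened against the two
    analytic limits of the first-level modulus: ``G -> i*omega*eta`` as
    ``omega*tau -> inf`` (probed at 1e6, tolerance 1e-3) and
    ``G -> E1*sqrt(i*omega*tau)`` as ``omega*tau -> 0`` (probed at 1e-4,
    tolerance 1e-2 — the asymptote itself carries an O(sqrt(omega*tau)/2)
    finite-frequency correction there, and lower probes exceed what the
    finite-depth convergents resolve).  The first candidate matching both
    is returned; its topology is recorded on the spec.
    """
    if target.n_levels != 1:
        raise ValidationError("calibration targets the 1-level model")
    e1, eta = target.stiffness[0], target.viscosity
    tau = target.relaxation_time
    tried = []
    for entry in ("rung", "strut"):
        for terminal in ("rigid", "open"):
            cand = LadderSpec(
                depth=depth,
                rung_elements=dashpot(eta),
                strut_elements=spring(e1),
                entry_element=entry,
                terminal=terminal,
            )
            w_hi, w_lo = 1e6 / tau, 1e-4 / tau
            g_hi = ladder_modulus(cand, 1j * w_hi, extrapolate=True)
            g_lo = ladder_modulus(cand, 1j * w_lo, extrapolate=True)
            ok_hi = abs(g_hi.imag / (w_hi * eta) - 1.0) < 1e-3
            ok_lo = abs(abs(g_lo) / (e1 * np.sqrt(w_lo * tau)) - 1.0) < 1e-2
            if ok_hi and ok_lo:
                return cand
            tried.append(
                f"{cand.topology_tag}: high-freq ok={ok_hi}, low-freq ok={ok_lo}"
            )
    raise CalibrationError(
        "no ladder topology matched the closed-form limits; tried: " + "; ".join(tried)
    )


# ---------------------------------------------------------------------------
# Numerical inverse Laplace transforms
# ---------------------------------------------------------------------------


def _stehfest_weights(order: int) -> np.ndarray:
    if order % 2 or order < 2:
        raise ValidationError("Stehfest order must be a positive even integer")
    n2 = order // 2
    from math import comb, factorial

    v = np.zeros(order)
    for k in range(1, order + 1):
        acc = 0.0
        for j in range((k + 1) // 2, min(k, n2) + 1):
            acc += (
                j**n2
                * factorial(2 * j)
                / (
                    factorial(n2 - j)
                    * factorial(j)
                    * factorial(j - 1)
                    * factorial(k - j)
                    * factorial(2 * j - k)
                )
            )
        v[k - 1] = (-1) ** (k + n2) * acc
    return v


def _invert_stehfest(F, times: np.ndarray, order: int) -> np.ndarray:
    v = _stehfest_weights(order)
    ln2 = np.log(2.0)
    out = np.empty_like(times)
    for i, t in enumerate(times):
        s = ln2 * np.arange(1, order + 1) / t
        out[i] = ln2 / t * float(np.real(np.sum(v * np.asarray([F(si) for si in s]))))
    return out


def _invert_talbot(F, times: np.ndarray, m: int) -> np.ndarray:
    # Fixed Talbot contour (Abate & Valko): s(theta) = r*theta*(cot(theta)+i)
    out = np.empty_like(times)
    for i, t in enumerate(times):
        r = 2.0 * m / (5.0 * t)
        theta = np.pi * np.arange(1, m) / m
        cot = 1.0 / np.tan(theta)
        s = r * theta * (cot + 1j)
        sigma = theta + (theta * cot - 1.0) * cot
        vals = np.asarray([F(si) for si in s], dtype=complex)
        total = 0.5 * np.exp(r * t) * complex(F(complex(r)))
        total += np.sum(np.exp(t * s) * vals * (1.0 + 1j * sigma))
        out[i] = r / m * total.real
    return out


def invert_laplace(
    F,
    times,
    method: Literal["stehfest", "talbot"] = "talbot",
    order: int = 12,
    talbot_m: int = 32,
) -> np.ndarray:
    """Numerical inverse Laplace transform of ``F`` at positive times.

    ``stehfest`` (Gaver-Stehfest, default order 12 — higher orders lose
    digits in double precision) samples ``F`` on the positive real axis
    only; ``talbot`` (fixed Talbot contour) samples complex ``s`` and is
    the cross-check on smooth transforms.  ``F`` must be analytic off the
    non-positive real axis.
    """
    t = np.atleast_1d(np.asarray(times, dtype=float))
    if np.any(t <= 0) or np.any(~np.isfinite(t)):
        raise ValidationError("times must be strictly positive and finite")
    try:
        if method == "stehfest":
            return _invert_stehfest(F, t, order)
        if method == "talbot":
            return _invert_talbot(F, t, talbot_m)
    except ValidationError:
        raise
    except Exception as exc:  # propagate evaluation failures with context
        raise RuntimeError(
            f"evaluation of the Laplace-domain function failed during "
            f"{method} inversion: {exc}"
        ) from exc
    raise ValidationError(f"unknown inversion method {method!r}")


# ---------------------------------------------------------------------------
# Direct ODE creep integration
# ---------------------------------------------------------------------------


def _assemble_chain(ladder: LadderSpec):
    """Tridiagonal system for rung-node displacements of a
    dashpot-rung / spring-strut ladder under entry through the rung."""
    rungs, struts = ladder.rung_elements, ladder.strut_elements
    if ladder.entry_element != "rung" or struts is None:
        raise ValidationError(
            "ODE integration supports dashpot-rung/spring-strut ladders "
            "entered through the rung (plus single-element chains)"
        )
    if any(e.kind != "dashpot" for e in rungs) or any(e.kind != "spring" for e in struts):
        raise ValidationError(
            "ODE integration requires dashpots on the rungs and springs on the struts"
        )
    n = ladder.depth
    eta = np.array([e.value for e in rungs])
    k = np.array([e.value for e in struts])
    a = np.zeros((n, n))
    for i in range(n):
        if i > 0:
            a[i, i - 1] += k[i - 1]
            a[i, i] -= k[i - 1]
        if i < n - 1:
            a[i, i] -= k[i]
            a[i, i + 1] += k[i]
    if ladder.terminal == "rigid":
        a[n - 1, n - 1] -= k[n - 1]
    a /= eta[:, None]
    return a, eta


def ladder_creep_ode(ladder: LadderSpec, stress_amplitude: float, times) -> CreepCurve:
    """Creep compliance of a finite ladder by direct ODE integration.

    A step stress ``sigma0`` is applied at t = 0+ as a constant boundary
    force; the state vector holds the rung node displacements (zero
    initially); the resulting linear first-order system is integrated
    with a stiff solver (Radau, analytic Jacobian).  Returns
    compliance = strain / stress.
    """
    if not (np.isfinite(stress_amplitude) and stress_amplitude > 0):
        raise ValidationError("stress_amplitude must be finite and > 0")
    t = np.atleast_1d(np.asarray(times, dtype=float))
    if np.any(t <= 0):
        raise ValidationError("times must be strictly positive")

    # Single-element chains solve in closed form.
    if ladder.depth == 1 and ladder.strut_elements is None:
        e = ladder.rung_elements[0]
        j = np.full_like(t, 1.0 / e.value) if e.kind == "spring" else t / e.value
        return CreepCurve(times=t, compliance=j)

    a, eta = _assemble_chain(ladder)
    forcing = np.zeros(ladder.depth)
    forcing[0] = stress_amplitude / eta[0]

    def rhs(_, y):
        return a @ y + forcing

    sol = solve_ivp(
        rhs,
        (0.0, float(t[-1])),
        np.zeros(ladder.depth),
        method="Radau",
        t_eval=t,
        jac=lambda *_: a,
        rtol=1e-10,
        atol=1e-14 * stress_amplitude / np.min(
            [e.value for e in ladder.strut_elements]
        ),
    )
    if not sol.success:
        eig = np.linalg.eigvals(a)
        nz = np.abs(eig[np.abs(eig) > 1e-300])
        ratio = nz.max() / nz.min() if nz.size else np.inf
        raise IntegrationError(
            f"stiff integration failed: {sol.message} "
            f"(eigenvalue stiffness ratio ~ {ratio:.3g})"
        )
    strain = sol.y[0]
    return CreepCurve(times=t, compliance=strain / stress_amplitude)
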