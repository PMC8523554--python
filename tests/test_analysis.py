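"""Power-law fits, exponent-stiffness relation, sweeps, Lissajous."""

import numpy as np
import pytest

from cellrheo import (
    CreepCurve,
    HierParams,
    ModulusCurve,
    ParallelCurvesError,
    StiffnessExponentPoint,
    ValidationError,
    complex_modulus_values,
    creep_compliance,
    estimate_intersection,
    fit_power_law,
    intercept_term,
    lissajous,
    lissajous_area,
    local_exponent,
    master_curve,
    predict_alpha,
    sweep_exponents,
)

from conftest import log_grid

# Experimentally reported intersection point of cell creep curves
J0_EXP, TAU0_EXP = 5.59e-7, 5.5e-13


# ---------------------------------------------------------------------------
# fit_power_law
# ---------------------------------------------------------------------------


def test_exact_power_law_recovered_to_machine_precision():
    t = log_grid(1e-1, 1e3, 20)
    fit = fit_power_law(CreepCurve(t, 2.0 * t**0.3))
    assert fit.exponent == pytest.approx(0.3, abs=1e-12)
    assert fit.prefactor == pytest.approx(2.0, rel=1e-12)
    assert fit.rms_residual < 1e-12


def test_level1_long_time_window_gives_half(cytoplasm, tau):
    t = log_grid(1e2 * tau, 1e4 * tau, 30)
    fit = fit_power_law(creep_compliance(cytoplasm, t))
    assert fit.exponent == pytest.approx(0.5, abs=0.01)


def test_constant_curve_gives_zero_exponent():
    c = CreepCurve(np.array([1.0, 2.0, 4.0]), np.full(3, 5.0))
    assert fit_power_law(c).exponent == pytest.approx(0.0, abs=1e-12)


def test_modulus_curve_magnitude_is_fitted(cytoplasm, tau):
    w = log_grid(1e-8 / tau, 1e-6 / tau, 12)
    g = complex_modulus_values(cytoplasm, w)
    curve = ModulusCurve(w, g.real, g.imag)
    fit = fit_power_law(curve)
    assert fit.exponent == pytest.approx(0.5, abs=0.01)


def test_window_with_too_few_points_rejected():
    t = log_grid(1.0, 100.0, 10)
    c = CreepCurve(t, t**0.4)
    with pytest.raises(ValidationError, match="3 in-window"):
        fit_power_law(c, window=(1.0, 1.1))


def test_fit_agrees_with_analytic_exponent_at_window_midpoint(cell3, tau):
    """Sub-decade window fits track the analytic local slope."""
    for lo in (1e1, 1e3, 1e5):
        t = log_grid(lo * tau, 10 * lo * tau, 12)
        fit = fit_power_law(creep_compliance(cell3, t))
        mid = np.sqrt(t[0] * t[-1])
        assert fit.exponent == pytest.approx(local_exponent(cell3, mid), abs=0.02)


# ---------------------------------------------------------------------------
# Exponent-stiffness relation
# ---------------------------------------------------------------------------


def test_intercept_term_reported_experimental_values():
    assert intercept_term(J0_EXP, TAU0_EXP) == pytest.approx(0.51, abs=5e-3)


def test_intercept_term_trivial_identities():
    assert intercept_term(0.37, 0.37) == pytest.approx(1.0)
    assert intercept_term(1.0, 2.5) == pytest.approx(0.0)


def test_intercept_term_singular_at_unit_timescale():
    with pytest.raises(ValidationError):
        intercept_term(1e-6, 1.0)


def test_predict_alpha_round_trip():
    """predict_alpha inverts J0 = j0 * tau0**(-alpha) exactly."""
    for alpha_true in (0.1, 0.3, 0.5):
        J0 = J0_EXP * TAU0_EXP ** (-alpha_true)
        assert predict_alpha(1.0 / J0, J0_EXP, TAU0_EXP) == pytest.approx(
            alpha_true, abs=1e-12
        )


def test_predict_alpha_unit_stiffness_reduces_to_intercept():
    assert predict_alpha(1.0, J0_EXP, TAU0_EXP) == pytest.approx(
        intercept_term(J0_EXP, TAU0_EXP)
    )


def test_predict_alpha_linear_decreasing_in_log_stiffness():
    s = np.logspace(1, 5, 9)
    a = np.array([predict_alpha(x, J0_EXP, TAU0_EXP) for x in s])
    assert np.all(np.diff(a) < 0)
    # exactly linear in log10(s) with negative slope
    coef = np.polyfit(np.log10(s), a, 1)
    assert coef[0] < 0
    assert np.max(np.abs(a - np.polyval(coef, np.log10(s)))) < 1e-12


# ---------------------------------------------------------------------------
# Intersection estimation
# ---------------------------------------------------------------------------


def test_intersection_recovered_from_exact_lines():
    t = log_grid(1e-2, 1e4, 25)
    tau0, j0 = 3.7e-5, 2.2e-4
    fits = [
        fit_power_law(CreepCurve(t, j0 * (t / tau0) ** a)) for a in (0.15, 0.3, 0.45)
    ]
    tau0_est, j0_est = estimate_intersection(fits)
    assert tau0_est == pytest.approx(tau0, rel=1e-8)
    assert j0_est == pytest.approx(j0, rel=1e-8)


def test_parallel_lines_refused_with_common_slope():
    t = log_grid(1.0, 1e3, 15)
    fits = [fit_power_law(CreepCurve(t, a * t**0.31)) for a in (1e-3, 2e-3, 4e-3)]
    with pytest.raises(ParallelCurvesError) as exc:
        estimate_intersection(fits)
    assert exc.value.common_slope == pytest.approx(0.31, abs=1e-6)


# ---------------------------------------------------------------------------
# Master curve
# ---------------------------------------------------------------------------


def test_master_curve_exact_recovery_from_relation():
    s = np.logspace(1, 4, 8)
    pts = [
        StiffnessExponentPoint(x, predict_alpha(x, J0_EXP, TAU0_EXP)) for x in s
    ]
    mc = master_curve(pts)
    assert mc.slope == pytest.approx(-1.0 / np.log10(1.0 / TAU0_EXP), rel=1e-6)
    assert mc.intercept == pytest.approx(intercept_term(J0_EXP, TAU0_EXP), rel=1e-6)
    assert mc.rms_residual < 1e-12


def test_master_curve_identical_stiffness_rejected():
    pts = [StiffnessExponentPoint(100.0, a) for a in (0.2, 0.3, 0.4)]
    with pytest.raises(ValidationError):
        master_curve(pts)


def test_master_curve_narrow_span_warns_but_fits():
    pts = [
        StiffnessExponentPoint(s, 0.4 - 0.05 * i)
        for i, s in enumerate((100.0, 150.0, 220.0))
    ]
    with pytest.warns(UserWarning, match="span"):
        mc = master_curve(pts)
    assert mc.narrow_span


def test_model_population_master_curve_slope_negative(hasm):
    """Sweeping E2 produces the solidification law: alpha falls as
    stiffness rises.  The exponent is probed at an experimental
    timescale (10 s), where the upper levels are partially engaged and
    E2 controls both stiffness and slope; at asymptotically long times
    every cell sits on the same 0.125 plateau and the law is invisible."""
    table = sweep_exponents(hasm, "E2", np.logspace(-2, 2, 9), eval_at=10.0)
    pts = [
        StiffnessExponentPoint(s, a)
        for s, a in zip(table.stiffness_pa, table.exponent)
    ]
    assert master_curve(pts).slope < 0


# ---------------------------------------------------------------------------
# Parameter sweeps
# ---------------------------------------------------------------------------


def test_level2_sweep_exponent_range(cell2, tau):
    table = sweep_exponents(cell2, "E2", np.logspace(-4, 4, 17), eval_at=1e6 * tau)
    assert table.exponent.min() >= 0.25 - 1e-3
    assert table.exponent.max() <= 0.5 + 0.01


def test_level3_joint_sweep_range_and_lower_limit(cell3, tau):
    alphas = []
    for m2 in np.logspace(-4, 4, 5):
        base = cell3.with_stiffness(2, 100.0 * m2)
        table = sweep_exponents(base, "E3", np.logspace(-4, 4, 5), eval_at=1e12 * tau)
        alphas.extend(table.exponent)
    alphas = np.array(alphas)
    assert alphas.min() >= 0.125 - 1e-3
    assert alphas.min() == pytest.approx(0.125, abs=0.01)
    assert alphas.max() <= 0.5 + 0.01


def test_sweep_unknown_parameter_lists_valid_names(cell2, tau):
    with pytest.raises(ValidationError, match="E1..E2, eta"):
        sweep_exponents(cell2, "E9", [1.0], eval_at=1e6 * tau)


def test_sweep_warns_when_preasymptotic(cell2, tau):
    with pytest.warns(UserWarning, match="pre-asymptotic"):
        sweep_exponents(cell2, "E2", [1.0], eval_at=tau)


# ---------------------------------------------------------------------------
# Lissajous ellipses
# ---------------------------------------------------------------------------


def test_lissajous_closed_and_centered(cytoplasm, tau):
    curve = lissajous(cytoplasm, 1.0 / tau, sigma0=10.0, n_points=512)
    assert curve.stress[0] == curve.stress[-1]
    assert curve.strain[0] == curve.strain[-1]
    # centered, symmetric ellipse: mean zero, symmetric extremes
    assert abs(np.mean(curve.stress[:-1])) < 1e-12
    assert abs(np.mean(curve.strain[:-1])) < 1e-12
    assert np.max(curve.strain) == pytest.approx(-np.min(curve.strain), rel=1e-6)


def test_lissajous_area_matches_loss_compliance(cytoplasm, tau):
    sigma0, omega = 10.0, 1.0 / tau
    curve = lissajous(cytoplasm, omega, sigma0, n_points=4096)
    g = complex_modulus_values(cytoplasm, [omega])[0]
    j_loss = abs((1.0 / g).imag)
    assert lissajous_area(curve) == pytest.approx(
        np.pi * sigma0**2 * j_loss, rel=1e-4
    )


def test_lissajous_area_vanishes_toward_elastic_limit():
    """The loss angle halves per level at low frequency, so the
    normalised ellipse area sin(delta) ~ sin(pi alpha / 2) shrinks
    toward the degenerate straight line of the elastic limit."""
    sigma0 = 1.0
    normalised = []
    for n in (1, 2, 3):
        p = HierParams([100.0] * n, viscosity=3e4)
        omega = 1e-8 / p.relaxation_time
        curve = lissajous(p, omega, sigma0, n_points=2048)
        strain_amp = np.max(np.abs(curve.strain))
        area = lissajous_area(curve) / (np.pi * sigma0 * strain_amp)
        normalised.append(area)
        assert area == pytest.approx(np.sin(np.pi * 2.0**-n / 2.0), rel=0.06)
    assert normalised[0] > normalised[1] > normalised[2]


def test_lissajous_validation():
    p = HierParams([100.0], 3e4)
    with pytest.raises(ValidationError):
        lissajous(p, -1.0, 1.0)
    with pytest.raises(ValidationError):
        lissajous(p, 1.0, 1.0, n_points=8)
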