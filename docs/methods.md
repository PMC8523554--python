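# Methods

## Model

A cell is idealised as an `n`-level self-similar hierarchy. Level 1 is the
cytoplasm: an infinite ladder with springs of stiffness `E₁` (Pa) on the
struts and dashpots of viscosity `η` (Pa·s) on the rungs, giving the
relaxation time `τ = η/E₁`. Each higher level embeds the previous one as a
building block behind a spring (`E₂`: microtubules along the load
direction; `E₃`: transverse expansion of cytoskeleton and cytoplasm). The
level-k creep compliance obeys the recursion

    J₁(t)   = (−1 + √(1 + 4t/τ)) / (2E₁),
    J_{k+1} = (−1 + √(1 + 4E_{k+1} J_k)) / (2E_{k+1}),

and the complex modulus

    G₁(ω)   = E₁ (1 + √(1 + 4(iωτ)⁻¹)) / (2(iωτ)⁻¹),
    G_{k+1} = (G_k + √(G_k² + 4E_{k+1} G_k)) / 2.

Assumptions: linear viscoelasticity (step and sinusoidal loads superpose),
one shared viscosity entering only through level 1, and perfect
self-similarity within a level. Levels beyond three follow the same
recursion; that is an extrapolation beyond the three-level cell picture
and is flagged as such in the API docs.

The closed forms are `s ↔ 1/t` approximants of the exact ladder dynamics,
not exact Laplace inversions: inverting the exact compliance transform
`Ĵ(s) = (−1+√(1+4/(sτ)))/(2E₁s)` numerically reproduces the same `t^0.5`
long-time exponent but an amplitude larger by `2/√π ≈ 1.128` (the inverse
of `s^{−3/2}` is `2√(t/π)`, while the approximant substitutes `s → 1/t`).
The ladder oracle quantifies this: exponents are exact, prefactors are
approximate at the ~13% level in the deep power-law regime.

## Numerical choices

- **Rationalized recursion.** `J_{k+1} = 2J_k/(1+√(1+4E_{k+1}J_k))` is
  used instead of the textbook form; identical analytically, but finite as
  `E_{k+1} → 0`, so degenerate levels reduce exactly to the level below.
- **Principal complex square root.** For `ω > 0` the radicand
  `1 + 4(iωτ)⁻¹` has real part ≥ 1 and the per-level radicand stays in the
  right half-plane, so the principal branch is continuous; this is
  asserted numerically (no jumps in `log G` on a 10⁴-point grid over 16
  decades) rather than assumed.
- **Analytic local exponents.** `d log J/d log t` and `d log|G|/d log ω`
  are propagated through the recursion by the chain rule; a
  finite-difference probe agrees to 10⁻⁴.
- **Ladder oracle.** The topology (dashpot on the rung in parallel with a
  spring strut in series with the next stage) is *discovered* by
  `calibrate_topology`, which screens entry/terminal candidates against
  the two analytic limits `G → iωη` (high frequency) and `G → E₁√(iωτ)`
  (low frequency), rather than hard-coded; the chosen topology is
  serialized with every `LadderSpec`. A finite depth-`N` ladder converges
  to the self-similar fixed point like `(1 − 2√(ωτ))^N` at low frequency,
  so the infinite-depth limit is estimated from the last nine depth
  convergents by iterated Aitken (Shanks) extrapolation — the standard
  limit estimator for geometrically converging continued fractions —
  reaching ~10⁻⁹ relative agreement with the closed form over
  `ωτ ∈ [10⁻³, 10³]` at depth 64.
- **Inverse Laplace transforms.** Gaver–Stehfest (order 12; higher orders
  lose digits in double precision) sampling only real `s`, and fixed
  Talbot (32 nodes) sampling a complex contour, provide two inversion
  routes with uncorrelated failure modes. Contracts: `1/s → 1` to 10⁻⁸,
  `1/s² → t` to 10⁻⁶ relative.
- **Ladder creep ODE.** Rung-node displacements under a constant boundary
  stress from `t = 0⁺` form a linear tridiagonal system (a discretised
  diffusion chain — the origin of the `t^0.5` law), integrated with Radau
  and an analytic Jacobian at `rtol = 10⁻¹⁰`. With a rigid terminal the
  finite chain saturates at `t ≈ τ(2N/π)²`; the depth-64 window checks
  stay below that.
- **Fitting.** Residuals are `ln G′`/`ln G″` (equal weight by default) or
  `ln J`, because rheology data span decades and model agreement is
  judged on log axes. Parameters are optimised as logs (positivity,
  natural multiplicative jitter). Trust-region reflective least squares
  with `ftol 10⁻¹⁰`, `gtol 10⁻⁸`; multistart initials: `E₁` from the
  storage minimum, `η` from high-frequency `G″/ω`, upper levels from the
  geometric mean of the storage range, jittered by `exp(N(0,1))` per
  start, seeded. Identifiability profiles re-optimise the remaining
  parameters on a multiplier grid; a profile is "flat" when the loss
  moves by <1% of the larger of the fitted loss and a 5%-noise-level
  loss over at least a decade.
- **Eq-relation conventions.** The exponent–stiffness relation uses
  natural logs internally; both of its terms are base-invariant ratios.
  The reference stiffness is `1/J(1 s)` for time-domain data and `G′` at
  `ω = 1 rad/s` for frequency-domain data; readers accept Hz with the
  explicit conversion `ω = 2πf` since experimental reports mix both
  conventions. The intersection point `(τ₀, j₀)` is user-supplied or
  estimated as the median of pairwise intersections of fitted log-log
  lines; when slopes agree within 0.01 the estimate is refused and the
  common slope reported instead (the high-stiffness regime, where creep
  curves are parallel and the relation no longer holds).

## Synthetic data

Generators emulate microrheology acquisition: log-spaced grids (default
30 points over `ω ∈ [10⁻², 10²]` rad/s and `t ∈ [10⁻¹, 10⁴]` s, matching
typical experimental windows), multiplicative log-normal noise (default
`σ_log = 0.05`, independent between storage and loss channels), all seeded
through `numpy.random.default_rng`. They do *not* emulate instrument
artifacts (inertia, tool compliance, drift), slow cellular remodelling, or
active (non-thermal) fluctuations — passing tests therefore demonstrate
correctness of the pipeline on model-faithful data, not robustness to
every pathology of real rheometer output.

Study conditions used by the recovery tests: an HASM-like 3-level cell
with `E₁ = E₂ = E₃ = 100 Pa` (the tabulated cytoplasm stiffness) and
`η = 1.41 Pa·s` (the experimentally measured cytoplasmic viscosity),
sampled at 30 points over `ω ∈ [1, 10⁴]` rad/s — four decades that span
both the power-law regime and the level-engagement knees, chosen so all
parameters are identifiable. Population sweeps probe the exponent at an
experimental timescale (10 s): at asymptotically long times every cell
sits on the same `2⁻ⁿ` plateau and the exponent–stiffness law is
invisible; point-wise the exponent is not even monotone in `E₂` (a very
stiff second level starts disengaging the third), so the law is asserted
as the population trend it is.

Drug-treatment presets encode directions only (histamine: `E₁` down,
`E₂`/`E₃` up; DBcAMP and cytochalasin D: `E₂`/`E₃` down), for generating
qualitative scenario populations — they are not fitted values.

## Acceptance quantities

`scripts/acceptance.py` evaluates closed forms on 41-point log grids and
reports midpoint central-difference log–log slopes: level-2 creep slope on
`t/τ ∈ [10⁷, 10⁹]` (→ 0.2513, approaching the 0.25 asymptote like
`(τ/t)^{1/4}`), level-3 creep slope on `t/τ ∈ [10¹¹, 10¹³]` (→ 0.1270),
the slope of `|G₃|` around `ωτ = 10⁻⁸` (→ 0.1317; the 2⁻³ asymptote is
approached like `(ωτ)^{1/8}`, so residual pre-asymptotic bias remains even
there), and the exponent-relation intercept at the reported intersection
point (→ 0.5100). All are deterministic; the `--seed` flag exists for
interface uniformity.

## Known limitations

- Prefactors of the closed forms deviate from the exact ladder dynamics
  (see above); exponents and their ranges are exact.
- The estimator is original to this package; published fits of this model
  report parameters but not algorithmic detail, so numerical agreement
  with any specific published fit is not claimed.
- `E₂`/`E₃` are effective network stiffnesses, not material moduli of
  single filaments; no geometry enters the model.
- No uncertainty quantification beyond profile likelihoods (bootstrap is
  future work).
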