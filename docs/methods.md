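# Methods

`caplung` implements a fractional-order compartmental model of lung-cancer
dynamics and the analysis/treatment stack built on top of it. This note
documents the models, the numerics, and the design decisions taken where
the problem was genuinely open.

## The models

**Base model.** Three coupled Caputo fractional differential equations of
order α ∈ (0, 1] describe lung cancer cells N(t), immune cells I(t) and
disseminated (metastatic) cancer cells P(t), in units of cells and days:

    D^α N = λN(1 − N/K) − μNP − β₁NI
    D^α I = φ₁I₀ + φ₂N² − φ₃I − β₂IP
    D^α P = γNP − δP − β₃IP

λ is the intrinsic tumour growth rate (1/day), K the carrying capacity of
the lung tissue (cells), μ the metastatic seeding rate (1/(cell·day)), γ
and δ the proliferation and death rates of the disseminated pool, β₁–β₃
interaction coefficients, and φ₁–φ₃ growth-factor effects. φ₁I₀ is a
*constant* immune source: I₀ is the baseline immune count (a parameter,
stored as `I_baseline`), not the evolving state. α < 1 introduces a
power-law memory kernel — the rate of change depends on the entire history
of the state, which is the model's device for long-range cellular memory;
α = 1 recovers the classical ODE system.

**Combined therapy.** The therapy variant adds a surgically-removed pool
T(t) and a Heaviside-delayed treatment: after the delay τ, the metastatic
pool is drained at rate ε₁NP + ε₂IP and surgery transfers ε₃P into T,
which clears at rate ε₄. The feedback variant (used for closed-loop
dosing) additionally depletes N and I directly by the same treatment
terms; the distinction between the two variants is preserved exactly.

The treatment efficacies ε₁..ε₄ are not part of the published constant
list. The shipped preset derives them from the two otherwise-unused
printed scalars: ε₁ = ε₂ = ε₄ = θ = 0.5, ε₃ = η = 0.7. They are labelled
as derived in the preset and trivially replaceable.

**Stem-cell (k) model.** A six-compartment mass-action system in cancer
stem cells C, progenitors Pk, supporting cells S, effector/environment E,
normal cells Nk and an immune compartment Ik, with rate constants k₁..k₁₄.
Only its steady-state equations are stated in the source material; the
dynamics here are the unique mass-action system whose zero set reproduces
them (each steady-state expression read as the Caputo derivative of its
compartment). k₁₃ and k₁₄ have no printed values; the package defaults
both to 0.1 and labels them non-source. The steady state factorises in
closed form — Nk\* = k₁₁/k₁₂ always, Pk\* = k₅C\*/k₆, Ik\* = k₁₃Pk\*/k₁₄,
and C\* is 0 or pinned by the supporting/effector balance — so the solver
enumerates branches and Newton-polishes, accepting only residuals ≤ 1e-8.

## The fractional solver

`fde_engine.solve_fde` implements the Adams–Bashforth–Moulton
predictor–corrector for Caputo problems (the method behind MATLAB's
`fde12`): fractional Adams–Bashforth prediction from the rectangle
product-integration rule, one fractional Adams–Moulton correction from the
piecewise-linear rule, full O(n²) memory. Design choices:

- **Full memory by default.** The Caputo operator is non-local; a
  short-memory window is available (`memory_window`) but off, because
  truncation changes the solution of any genuinely fractional problem.
- **One corrector iteration per step** (the `fde12` convention),
  configurable.
- **One shared α per vector problem.** The study simulates one order at a
  time; the printed α₁, α₂ are alternative scenario values, not
  per-component orders.
- **Uniform grid only**; a horizon that is not a multiple of h is snapped
  to the nearest multiple with a warning.
- **Exogenous input** u(t) (the dosage signal) is sampled at grid points
  and held constant within a step.
- **Classical limit specialisation.** At α = 1 the scheme reduces exactly
  to the Euler-predict/trapezoid-correct PECE pair, and the solver then
  sums it *incrementally* (y_{n+1} = y_n + local increment) instead of
  re-assembling y₀ + full quadrature. The from-scratch form freezes the
  quadrature error committed during sharp transients into the state (the
  error can only relax through the f-feedback), which poisons small late-
  time states; the incremental form lets the dynamics damp it, and runs in
  O(n). For α < 1 the non-local form is the method and is kept verbatim.
- **Failure policy.** A non-finite rhs value aborts with the step index
  and state in the exception payload; states are never clipped. The first
  negativity crossing of a trajectory is reported by the run layer, not
  silently altered.

Verification: the one-parameter Mittag-Leffler function E_α(z) (the
solution kernel of linear Caputo equations) is evaluated by partial sums
with past-the-hump stopping, switching to extended precision (mpmath) once
the alternating-series cancellation — of magnitude exp(|z|^(1/α)) — would
erode double precision; stated absolute accuracy ≤ 1e-10. The solver is
checked against E_α(−t^α... ) solutions at α ∈ {0.5, 0.7, 0.9}, against
exp at α = 1, and for empirical convergence order ≥ 1 under step halving
(the scheme's theoretical order is 1 + α).

### Stability of the explicit scheme on the printed preset

The printed parameter set with N₀ = 3000 produces an immune surge
φ₂N² ≈ 3.6e5 cells/day: I rises to ~5.9e3 within 0.1 day, and the
transient Jacobian rates reach ~3e2/day (dominated by β₃I on the P
equation, and up to ~3e3/day with treatment active at full efficacy). An
explicit predictor–corrector is stable only while h·rate stays below ≈ 2,
so the printed step h = 2⁻⁶ is *outside* the stability region — the
iteration overflows within ~15 steps, for this implementation and for any
faithful re-implementation of the named scheme. The true solution is
benign (N and P collapse, I peaks and decays slowly), as an implicit
reference (Radau) confirms. Package policy: the preset stores the printed
step verbatim; quantitative α = 1 comparisons run at h = 2⁻¹⁰–2⁻¹¹, and
fractional demonstrations use gentle initial states (small tumour burden)
where the printed step is stable. Runs at an unstable step fail loudly.

The α = 1 classical-limit check compares against an adaptive Radau
solution at rtol 1e-11 and measures the state-norm relative deviation
max_t ‖Δy(t)‖∞ / ‖y_ref(t)‖∞ — the standard mixed-relative metric at
state scale; at h = 2⁻¹¹ it is ≈ 2e-4 over [0, 50].

## Equilibria, stability, reproduction numbers

Steady states come from closed-form branch reduction — the tumour-free
state (0, φ₁I₀/φ₃, 0); the P = 0 family via a quadratic in N; the positive
branch via I = (γN − δ)/β₃ and P = (λ(1 − N/K) − β₁I)/μ with the remaining
scalar equation bracketed in N — plus a seeded multistart Newton search
(log-uniform starts on [1e-2, K], default seed 20230801). Every candidate
is Newton-polished and accepted only with rhs residual ≤ 1e-8; residual
verification, not the printed algebra (which contains a transcription
error in the I(N) relation), is the arbiter.

For the printed parameter set the positive branch has **no root**: the
only stable equilibrium is the tumour-free state (0, 270, 0) (eigenvalues
−2.4, −0.01, −10.8). The global-stability construction (sum-of-squares
Lyapunov function V = Σ(xᵢ − xᵢ\*)²) is therefore verified numerically
against that state: trajectories from small tumour burdens settle into a
monotone decay of V for ≥ 99% of steps after the transient.

Local stability uses the analytic Jacobian, the cubic characteristic
polynomial in both the source's sign convention (−x³ + T₁x² + T₂x + T₃)
and monic form, the Routh–Hurwitz conditions (a₁ > 0, a₃ > 0,
a₁a₂ − a₃ > 0), the source-literal minors M₁–M₃, and companion-matrix
eigenvalues as the independent arbiter; "marginal" means the largest real
part lies within 1e-9 of zero.

**Reproduction number and coefficient.** At the disease-free state
E₀ = (K, 0, 0), R₀ = β₁φ₁/(λ₁μ) and R_c = β₂γφ₂/(λ₁μφ₃), with λ₁ the
dominant eigenvalue of J(E₀). Two ambiguities in the source are surfaced,
not resolved:

1. the printed J(E₀) (zero (1,2)/(2,1) entries, corner −δ) differs from
   the analytic Jacobian at E₀ (corner γK − δ, which is *positive* for the
   printed rates); both are computed (`jacobian_mode`);
2. the dominant-eigenvalue rule is unstated; both max-real-part (default)
   and max-modulus are computed, and the ratio always uses the real part
   of the selected eigenvalue so R₀ and R_c are real.

Together with the two printed φ sets this yields the interpretation table
(`interpretation_table`). For the printed parameters every eigenvalue of
the printed J(E₀) has negative real part, so λ₁ < 0 and both ratios are
negative under every interpretation; the default interpretation gives
|R₀| = 3.0 and |R_c| = 28.0, and no interpretation reproduces the
published 2.6 / 0.22 pair to two significant figures. The table exists
precisely to make that discrepancy inspectable.

## Sensitivity analysis

The normalized sensitivity coefficient S_i = ∂ln f/∂ln k_i (elasticity) is
approximated with the 1% rule ε = 0.01·θ. When the functional stays
positive the difference is taken in log space (a log-log secant slope),
which is the exact discretisation of the definition and renders power-law
elasticities — the +1/−1/0 pattern of Nk\* = k₁₁/k₁₂ — exact at any ε; the
ratio form (∂f/∂k)(k/f) is used otherwise, and forward differences are
available as a compatibility mode. Steady-state functionals evaluate the
root directly rather than simulating to large time. Trajectory
sensitivities difference two `solve_fde` runs on identical grids.

The published steady-state sensitivity table and the printed ∂C/∂k_i
values are shipped as frozen *display* fixtures only: the table reports
nonzero sensitivities for parameters the closed-form steady state is
independent of (and zeros where the closed form gives ±1), and the
trajectory values lack an evaluation time and the k₁₃/k₁₄ values, so
neither can serve as a test oracle.

## Optimal therapy and feedback dosing

**Pontryagin sweep.** The combined-therapy problem minimises
J = ∫₀^tf (w₁N + w₂I + w₃P − w₄T) dt over a bounded dosage u(t) ∈ [0,
u_max] scaling (ε₁, ε₂, ε₃) multiplicatively (the dosage-to-efficacy map
is an explicit, replaceable policy; the admissible set is a box because
the source states none). The first-order conditions are the textbook ones
for these dynamics and this cost — H = integrand + λᵀf, costates
λ' = −∂H/∂x with λ(tf) = 0 — solved by forward–backward sweeping: forward
state integration (through the fractional engine; α = 1 by default, the
order the source's own feedback procedure adopts — a fractional adjoint
system is out of scope), backward RK4 costate integration with linear
state interpolation, bang-bang control target from the u-linear
Hamiltonian's switching function (previous value kept on numerically zero
switching), relaxed update, and objective backtracking so accepted
iterates never increase J. Convergence is sup-norm control change ≤ tol,
with a secondary stop when J has stagnated to 1e-11 relative (bang-bang
switch points can chatter by one grid cell indefinitely). The
published costate/state system for this problem is not internally
consistent (its state equations read dN/dt = μψ₁ etc., and the Hamiltonian
carries ψ-bearing terms with no matching dynamics); it is reproduced in
the appendix below verbatim and never executed. Likewise the closed-form
state expressions and the u₁–u₄ integrating factors of the feedback
section contradict the stated dynamics and are excluded from execution.

On the printed preset the sweep converges immediately to u ≡ 0 with J
equal to the uncontrolled objective: the metastatic pool is extinct long
before the treatment delay τ = 5 days, so treatment cannot improve the
objective — the honest optimum is "nothing left to treat". The test suite
therefore also exercises a synthetic, non-stiff scenario (documented in
`tests/conftest.py`) whose metastatic pool stays active; there the sweep
reduces J by more than half with a bang-bang dosage profile.

**PID dosing loop.** The closed loop repeats: simulate the feedback model
at the current dosage over the horizon, compute the end-of-horizon error
e = N_target − N(tf), update the dosage with a discrete PID law
(proportional on e, trapezoidal integral over the cycle history,
backward-difference derivative; the cycle is the sampling interval) and
clamp to [0, u_max]. Two departures from the source's sketch were
required to make the loop well-posed: (i) *reverse action* — the dosage
correction is subtracted, because with nonnegative gains the direct form
moves the dosage the wrong way whenever dosage lowers tumour burden; a
`direction="direct"` mode covers regimes where clearing metastases
releases N from suppression and the response runs the other way; (ii)
*anti-windup* — the integral accumulator freezes during cycles whose
dosage sat on a bound. Gains are plant-scale dependent; the defaults
(Kp = 0.5, Ki = 0.2, Kd = 0) are tuned for unit-gain plants and verified
on the scalar internal-model check x' = −x + u.

**W/V auxiliaries.** The wound-healing and VEGF trajectories are
trapezoidal quadratures of stated costate combinations using the second
φ set; the φ₃'ψ₂ term is implemented exactly as printed even though it
plausibly duplicates φ₁'ψ₂ by typo.

## Reproducibility

All dynamics are deterministic; randomness enters only through the
multistart equilibrium seed. Every CLI run emits a config hash sufficient
to reproduce it; CSV/JSON writers round-trip floats at 15+ significant
digits. Problem sizes used by the shipped checks: horizons of 30–50 days
at steps 2⁻¹⁰–2⁻¹¹ for α = 1 comparisons, 400 days at 2⁻⁶ for the gentle
fractional Lyapunov run, 1 day at 2⁻⁸ for solver-accuracy checks.

## What the synthetic scenarios do and do not show

The two synthetic test scenarios (`mild_therapy`, `mild_dosing`) exist
because the printed preset makes both control problems degenerate. They
emulate a slower, non-stiff tumour with persistent metastasis so that
treatment has something to act on. They share the model's structure but
not its printed rates, so tests passing on them demonstrate the
correctness of the control machinery — monotone objective descent,
transversality, PID convergence — not any clinical property of the
published parameterisation, and nothing here is clinical dosing guidance.

## Known limitations

- Explicit solver only: stiff configurations demand small steps; there is
  no implicit fractional integrator (out of scope).
- The fractional sweep uses classical adjoints; PMP for genuinely
  fractional orders (right-sided Caputo costates) is not implemented.
- Riemann–Liouville initial conditions, variable/distributed orders, and
  parameter fitting to data are out of scope.
- The Matignon stability sector |arg λ| > απ/2 for fractional orders is
  strictly larger than the classical half-plane; the package follows the
  source in applying the classical Routh–Hurwitz criterion, which is the
  conservative direction.

## Appendix: the published costate system (not executed)

For reference, the source's first-order conditions as printed (state
equations left, costate equations right, verbatim structure):

    dN/dt = μψ₁                     dψ₁/dt = −w₁ − λ(1 − 2N/K) + β₁I − 2φ₂N + θ(t−τ)ε₁P + μψ₁
    dI/dt = −β₁ψ₂ − φ₃ψ₂ − β₂ψ₅     dψ₂/dt = −w₂ + β₁N − φ₁ − β₂P − θ(t−τ)ε₂P − β₃P + μψ₁
            − β₃ψ₇ − θ(t−τ)ε₂ψ₉     ... (ψ₃–ψ₁₀ analogous)
    dT/dt = ε₄ψ₁₀

These equations do not follow from the stated Hamiltonian by ∂H/∂ψ and
−∂H/∂x, and the state equations do not reduce to the therapy dynamics;
the implementation uses the textbook conditions instead (see above).
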