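# caplung

Fractional-order (Caputo) modelling of lung-cancer dynamics: a reusable
implementation of a tumour–immune–metastasis compartmental model together
with the analysis and treatment-design stack built on it.

The package is aimed at modellers in mathematical oncology and
epidemiology-style dynamical analysis who want a tested, scriptable
version of this model family: integrate it at any order α ∈ (0, 1], find
and classify its steady states, compute reproduction quantities, measure
parameter sensitivities, and design treatment schedules by optimal
control or closed-loop PID dosing.

## The model

Lung cancer cells N(t), immune cells I(t) and disseminated (metastatic)
cells P(t) evolve under a Caputo derivative of order α:

    D^α N = λN(1 − N/K) − μNP − β₁NI
    D^α I = φ₁I₀ + φ₂N² − φ₃I − β₂IP
    D^α P = γNP − δP − β₃IP

with logistic tumour growth (rate λ, capacity K), immune kill β₁,
metastatic seeding μ, and a constant immune source φ₁I₀. α < 1 gives the
dynamics a power-law memory; α = 1 is the classical ODE limit. A
combined-therapy extension adds a Heaviside-delayed treatment (efficacies
ε₁–ε₄, delay τ) and a surgically-removed pool T(t); a six-compartment
stem-cell model (rate constants k₁–k₁₄) supports the sensitivity
analysis. See `docs/methods.md` for the full account.

What the package computes:

- **`fde_engine`** — Adams–Bashforth–Moulton predictor–corrector for
  Caputo initial-value problems (full memory, O(n²)), with a
  Mittag-Leffler series oracle for verification.
- **`models`** — right-hand sides and validated parameter containers for
  the four model families; frozen presets of the published constants.
- **`equilibria_stability`** — steady states (closed-form branches +
  seeded multistart, residual-verified), Routh–Hurwitz stability with
  eigenvalue arbitration, numeric Lyapunov traces, and the reproduction
  number R₀ = β₁φ₁/(λ₁μ) and coefficient R_c = β₂γφ₂/(λ₁μφ₃) with a full
  interpretation table over the ambiguities in their definition.
- **`sensitivity`** — normalized sensitivity coefficients (elasticities)
  of steady states and trajectories by the 1% finite-difference rule.
- **`control`** — Pontryagin forward–backward sweep for combined-therapy
  optimization, and a closed-loop PID dosing procedure.
- **`cli_io`** — presets, config-hashable reproducible runs, CSV/JSON
  serialisation, and the `caplung` command-line tool
  (`simulate`, `stability-report`, `sensitivity`, `optimize`, `dose`,
  `presets`).

## Worked example

```python
import numpy as np
from caplung.cli_io import load_preset
from caplung import equilibria_stability as eqs
from caplung.fde_engine import FDEProblem, solve_fde
from caplung.models import make_base_fde_rhs

preset = load_preset("paper2023")          # the published constant list

for e in eqs.find_equilibria(preset.base, n_starts=40, seed=20230801):
    print(f"{e.kind:26s} state={np.round(e.state, 6)}  residual={e.residual:.2e}")

rep = eqs.reproduction_numbers(preset.base)
print(f"lambda1 = {rep.lambda1.real:.4g}   R0 = {rep.R0:.4g}   Rc = {rep.Rc:.4g}")

grid = solve_fde(FDEProblem(order=0.9, rhs=make_base_fde_rhs(preset.base),
                            initial_state=[5.0, 350.0, 1.0],
                            t0=0.0, t_final=400.0, step=2.0**-6))
print("state at t=400:", np.round(grid.states[-1], 4))
```

prints

```
tumor-free-with-immunity   state=[  0. 270.   0.]  residual=4.44e-16
other                      state=[-0.0000e+00 -2.5000e-02 -1.0801e+04]  residual=4.19e-22
lambda1 = -0.01   R0 = -3   Rc = -28
state at t=400: [1.000000e-03 2.812895e+02 0.000000e+00]
```

Reading the output: under the published rates the only biologically
admissible equilibrium is the *tumour-free state with immunity* —
N = P = 0 with the immune level settled at φ₁I₀/φ₃ = 270 cells — and it
is locally stable; the second root has negative components and is
reported but not biological. The disease-free Jacobian's dominant
eigenvalue is negative (λ₁ = −0.01), so the reproduction ratios come out
negative: |R₀| = 3.0, |R_c| = 28.0 (the interpretation table in
`eqs.interpretation_table` enumerates every reading of these formulas —
see `docs/methods.md` for why no reading reproduces the published
2.6/0.22). The α = 0.9 simulation from a small tumour burden confirms the
picture: after 400 days the tumour compartments are extinct and the
immune level is relaxing toward 270 (fractional memory makes the final
approach algebraically slow, hence 281 rather than 270 at day 400).

The same analyses from the shell:

```sh
caplung presets
caplung stability-report --preset paper2023 --out stability.json
caplung sensitivity --model kmodel --out sens.csv
caplung simulate --preset paper2023 --variant base --alpha 0.9 --t-final 50 --h 0.001
```

A note on step sizes: the published step h = 2⁻⁶ is outside the explicit
scheme's stability region for the published initial state (the immune
surge drives transient rates of ~300/day), so quantitative α = 1 runs use
h ≤ 2⁻¹⁰; the solver fails loudly, never silently, on an unstable step.
`docs/methods.md` has the analysis.

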