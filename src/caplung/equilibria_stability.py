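"""Steady states, local stability, Lyapunov traces and reproduction numbers.

Steady states of the base (N, I, P) model come from closed-form branch
reduction plus seeded multistart root finding, each candidate polished by
Newton iteration and accepted only if the rhs residual is at machine-level
(max-norm <= 1e-8).

Local stability is assessed classically: the analytic Jacobian, the cubic
characteristic polynomial (kept in both the source's sign convention
``-x^3 + T1 x^2 + T2 x + T3`` and monic form), the Routh-Hurwitz
conditions, and companion-matrix eigenvalues as the independent arbiter.

The reproduction number R0 = beta1*phi1/(lambda1*mu) and reproduction
coefficient Rc = beta2*gamma*phi2/(lambda1*mu*phi3) are evaluated from the
dominant eigenvalue lambda1 of the Jacobian at the disease-free state
E0 = (K, 0, 0).  Two ambiguities are surfaced rather than resolved:
the printed J(E0) differs from the analytic Jacobian at E0 (its (1,2)
entry is zero and its (3,3) entry is -delta instead of gamma*K - delta),
and the dominant-eigenvalue rule is unstated.  Both Jacobian modes, both
dominance rules and both printed phi sets are therefore computed in an
interpretation table (:func:`interpretation_table`).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .fde_engine import SolutionGrid
from .models import BaseModelParams, base_rhs

__all__ = [
    "Equilibrium",
    "StabilityReport",
    "ReproductionReport",
    "LyapunovTrace",
    "find_equilibria",
    "jacobian_base",
    "routh_hurwitz_cubic",
    "stability_report",
    "lyapunov_trace",
    "reproduction_numbers",
    "reproduction_from_lambda1",
    "interpretation_table",
    "dfe_jacobian",
]

RESIDUAL_TOL = 1e-8
MARGINAL_BAND = 1e-9


@dataclass(frozen=True)
class Equilibrium:
    """An accepted steady state with its rhs residual and a label."""

    state: np.ndarray
    residual: float
    kind: str  # disease-free | tumor-free-with-immunity | positive | other


@dataclass
class StabilityReport:
    jacobian: np.ndarray
    char_coeffs: Tuple[float, float, float]        # (T1, T2, T3), -x^3 + T1 x^2 + T2 x + T3
    monic_coeffs: Tuple[float, float, float]       # (a1, a2, a3), x^3 + a1 x^2 + a2 x + a3
    minors: Tuple[float, float, float]             # source-literal M1, M2, M3
    eigenvalues: np.ndarray
    verdict: str                                   # stable | unstable | marginal


@dataclass
class ReproductionReport:
    dfe: np.ndarray
    jacobian_dfe: np.ndarray
    char_coeffs_dfe: Tuple[float, float, float]    # printed-form (a, b, c)
    lambda1: complex
    R0: float
    Rc: float
    interpretation: dict = field(default_factory=dict)


@dataclass
class LyapunovTrace:
    V: np.ndarray
    monotone_fraction: float
    settle_index: Optional[int]       # first index after which dV <= 0 throughout


# ---------------------------------------------------------------------------
# equilibria


def jacobian_base(params: BaseModelParams, state) -> np.ndarray:
    """Analytic Jacobian of :func:`caplung.models.base_rhs`."""
    N, I, P = state
    p = params
    return np.array([
        [p.lam - 2.0 * p.lam * N / p.K - p.mu * P - p.beta1 * I, -p.beta1 * N, -p.mu * N],
        [2.0 * p.phi2 * N, -p.phi3 - p.beta2 * P, -p.beta2 * I],
        [p.gamma * P, -p.beta3 * P, p.gamma * N - p.delta - p.beta3 * I],
    ])


def _newton_polish(params: BaseModelParams, x0: np.ndarray, iters: int = 50) -> Optional[np.ndarray]:
    x = np.asarray(x0, dtype=float).copy()
    for _ in range(iters):
        f = base_rhs(x, params)
        if not np.all(np.isfinite(f)):
            return None
        if np.max(np.abs(f)) < 1e-13 * max(1.0, np.max(np.abs(x))):
            break
        J = jacobian_base(params, x)
        try:
            step = np.linalg.solve(J, f)
        except np.linalg.LinAlgError:
            return None
        x = x - step
    return x if np.all(np.isfinite(x)) else None


def _classify(params: BaseModelParams, state: np.ndarray) -> str:
    N, I, P = state
    scale = params.K
    near0 = lambda v: abs(v) < 1e-6 * scale
    if near0(P) and near0(N) and I > 0:
        return "tumor-free-with-immunity"
    if near0(P) and near0(I) and abs(N - params.K) < 1e-6 * scale:
        return "disease-free"
    if N > 0 and I > 0 and P > 0:
        return "positive"
    return "other"


def _positive_branch_residual(params: BaseModelParams, N: float) -> float:
    """Immune-equation residual along the positive branch.

    For P != 0: I = (gamma*N - delta)/beta3 (from gamma*N - delta - beta3*I = 0);
    for N != 0: P = (lam*(1 - N/K) - beta1*I)/mu.  The remaining equation is
    phi1*I0 + phi2*N^2 - phi3*I - beta2*I*P = 0.
    """
    p = params
    I = (p.gamma * N - p.delta) / p.beta3
    P = (p.lam * (1.0 - N / p.K) - p.beta1 * I) / p.mu
    return p.phi1 * p.I_baseline + p.phi2 * N * N - p.phi3 * I - p.beta2 * I * P


def find_equilibria(
    params: BaseModelParams,
    n_starts: int = 40,
    seed: int = 20230801,
) -> List[Equilibrium]:
    """All steady states of the base model found by branches + multistart.

    Closed-form candidates: the tumour-free state (0, phi1*I0/phi3, 0); the
    P = 0 family where N solves a quadratic; and the positive branch where
    I and P are eliminated and the remaining scalar equation in N is
    bracketed on (delta/gamma, K].  A seeded multistart Newton search
    (log-uniform starts over [1e-2, K]) backstops the algebra.  Candidates
    are Newton-polished, verified (residual <= 1e-8) and deduplicated.
    """
    if n_starts < 1:
        raise ValueError("n_starts must be >= 1")
    p = params
    candidates: List[np.ndarray] = []

    candidates.append(np.array([0.0, p.phi1 * p.I_baseline / p.phi3, 0.0]))

    # P = 0, N != 0: lam*(1 - N/K) = beta1*I with I = (phi1*I0 + phi2*N^2)/phi3
    #   -> (beta1*phi2/phi3) N^2 + (lam/K) N + (beta1*phi1*I0/phi3 - lam) = 0
    qa = p.beta1 * p.phi2 / p.phi3
    qb = p.lam / p.K
    qc = p.beta1 * p.phi1 * p.I_baseline / p.phi3 - p.lam
    roots = np.roots([qa, qb, qc]) if qa != 0.0 else ([-qc / qb] if qb != 0 else [])
    for r in roots:
        if np.isreal(r) and 0.0 < r.real <= 2.0 * p.K:
            N = float(r.real)
            candidates.append(np.array([N, (p.phi1 * p.I_baseline + p.phi2 * N * N) / p.phi3, 0.0]))

    # positive branch: bracket the scalar residual in N
    if p.gamma > 0 and p.beta3 > 0 and p.mu > 0:
        lo = p.delta / p.gamma + 1e-9 * p.K
        grid = np.linspace(lo, p.K, 2001)
        vals = np.array([_positive_branch_residual(p, N) for N in grid])
        sign_flips = np.where(np.sign(vals[:-1]) * np.sign(vals[1:]) < 0)[0]
        for i in sign_flips:
            N = brentq(lambda x: _positive_branch_residual(p, x), grid[i], grid[i + 1], xtol=1e-12)
            I = (p.gamma * N - p.delta) / p.beta3
            P = (p.lam * (1.0 - N / p.K) - p.beta1 * I) / p.mu
            candidates.append(np.array([N, I, P]))

    rng = np.random.default_rng(seed)
    starts = 10.0 ** rng.uniform(-2.0, np.log10(p.K), size=(n_starts, 3))
    candidates.extend(starts)

    accepted: List[Equilibrium] = []
    for cand in candidates:
        x = _newton_polish(p, cand)
        if x is None:
            continue
        res = float(np.max(np.abs(base_rhs(x, p))))
        if res > RESIDUAL_TOL:
            continue
        if any(np.allclose(x, e.state, rtol=1e-6, atol=1e-6 * p.K) for e in accepted):
            continue
        accepted.append(Equilibrium(state=x, residual=res, kind=_classify(p, x)))
    if not accepted:
        import warnings

        warnings.warn("no equilibrium converged from any start", stacklevel=2)
    return accepted


# ---------------------------------------------------------------------------
# Routh-Hurwitz


def routh_hurwitz_cubic(char_coeffs: Sequence[float], convention: str = "monic") -> StabilityReport:
    """Stability of a cubic from its coefficients.

    ``convention="monic"`` expects (a1, a2, a3) of x^3 + a1 x^2 + a2 x + a3;
    ``convention="T"`` expects (T1, T2, T3) of -x^3 + T1 x^2 + T2 x + T3,
    which is normalised by a_i = -T_i.  Stability holds iff a1 > 0, a3 > 0
    and a1*a2 - a3 > 0.  The source-literal Routh minors M1 = 1,
    M2 = T3 - T1*T2, M3 = (T2*T3 - T1^2*T3)/T1 are reported alongside.
    Eigenvalues of the companion matrix arbitrate marginal cases
    (|max real part| < 1e-9).
    """
    coeffs = [float(c) for c in char_coeffs]
    if len(coeffs) != 3:
        raise ValueError("need exactly three cubic coefficients")
    if convention == "T":
        T1, T2, T3 = coeffs
        a1, a2, a3 = -T1, -T2, -T3
    elif convention == "monic":
        a1, a2, a3 = coeffs
        T1, T2, T3 = -a1, -a2, -a3
    else:
        raise ValueError("convention must be 'monic' or 'T'")

    minors = (1.0, T3 - T1 * T2, (T2 * T3 - T1 ** 2 * T3) / T1 if T1 != 0 else np.nan)
    eigs = np.roots([1.0, a1, a2, a3])
    max_re = float(np.max(eigs.real))
    if abs(max_re) < MARGINAL_BAND:
        verdict = "marginal"
    elif max_re < 0:
        verdict = "stable"
    else:
        verdict = "unstable"
    return StabilityReport(
        jacobian=np.empty((0, 0)),
        char_coeffs=(T1, T2, T3),
        monic_coeffs=(a1, a2, a3),
        minors=minors,
        eigenvalues=eigs,
        verdict=verdict,
    )


def stability_report(params: BaseModelParams, state) -> StabilityReport:
    """Full local-stability report at a state: Jacobian, cubic, verdict."""
    J = jacobian_base(params, state)
    # char poly of J: det(J - x I) = -x^3 + T1 x^2 + T2 x + T3
    monic = np.poly(J)  # [1, c1, c2, c3] of x^3 + c1 x^2 + ...
    rep = routh_hurwitz_cubic(tuple(monic[1:]), convention="monic")
    rep.jacobian = J
    rep.eigenvalues = np.linalg.eigvals(J)
    max_re = float(np.max(rep.eigenvalues.real))
    rep.verdict = ("marginal" if abs(max_re) < MARGINAL_BAND
                   else "stable" if max_re < 0 else "unstable")
    return rep


# ---------------------------------------------------------------------------
# Lyapunov


def lyapunov_trace(trajectory: SolutionGrid, equilibrium: Equilibrium) -> LyapunovTrace:
    """Sum-of-squares Lyapunov function V(t) = sum_i (x_i(t) - x_i*)^2.

    Reports the fraction of grid steps with dV <= 0 and the first index
    after which dV <= 0 holds for every subsequent step (None if it never
    settles).
    """
    x_star = np.asarray(equilibrium.state, dtype=float)
    if trajectory.states.shape[1] != x_star.shape[0]:
        raise ValueError("trajectory and equilibrium dimensions differ")
    V = np.sum((trajectory.states - x_star) ** 2, axis=1)
    dV = np.diff(V)
    if dV.size == 0:
        return LyapunovTrace(V=V, monotone_fraction=1.0, settle_index=0)
    ok = dV <= 0.0
    frac = float(np.mean(ok))
    settle: Optional[int]
    if ok.all():
        settle = 0
    else:
        last_bad = int(np.max(np.nonzero(~ok)[0]))
        settle = last_bad + 1 if last_bad + 1 < dV.size else None
    return LyapunovTrace(V=V, monotone_fraction=frac, settle_index=settle)


# ---------------------------------------------------------------------------
# reproduction number / coefficient


def dfe_jacobian(params: BaseModelParams, mode: str = "paper-literal") -> np.ndarray:
    """Jacobian at the disease-free state E0 = (K, 0, 0).

    ``"paper-literal"`` assembles the printed matrix
    [[-lam, 0, -mu*K], [0, -phi3, 0], [gamma*K, 0, -delta]] (its zero (1,2)
    and (2,1) entries and -delta corner differ from the analytic partial
    derivatives); ``"derived"`` evaluates the analytic Jacobian at E0.
    """
    p = params
    if mode == "paper-literal":
        return np.array([
            [-p.lam, 0.0, -p.mu * p.K],
            [0.0, -p.phi3, 0.0],
            [p.gamma * p.K, 0.0, -p.delta],
        ])
    if mode == "derived":
        return jacobian_base(p, (p.K, 0.0, 0.0))
    raise ValueError("mode must be 'paper-literal' or 'derived'")


def _dominant_eigenvalue(J: np.ndarray, dominance: str) -> complex:
    eigs = np.linalg.eigvals(J)
    if dominance == "max-real-part":
        return eigs[int(np.argmax(eigs.real))]
    if dominance == "max-modulus":
        return eigs[int(np.argmax(np.abs(eigs)))]
    raise ValueError("dominance must be 'max-real-part' or 'max-modulus'")


def reproduction_from_lambda1(params: BaseModelParams, lambda1: float) -> Tuple[float, float]:
    """R0 and Rc for a given dominant-eigenvalue value (real part)."""
    p = params
    if p.mu <= 0 or p.phi3 <= 0:
        raise ValueError("mu and phi3 must be positive")
    if abs(lambda1) < 1e-12:
        raise ZeroDivisionError("lambda1 is zero within tolerance; R0/Rc undefined")
    R0 = p.beta1 * p.phi1 / (lambda1 * p.mu)
    Rc = p.beta2 * p.gamma * p.phi2 / (lambda1 * p.mu * p.phi3)
    return R0, Rc


def reproduction_numbers(
    params: BaseModelParams,
    dominance: str = "max-real-part",
    jacobian_mode: str = "paper-literal",
) -> ReproductionReport:
    """Reproduction number and coefficient from the disease-free Jacobian.

    The ratio uses the real part of the selected dominant eigenvalue, so
    R0 and Rc are always real.  The printed-form characteristic
    coefficients a = lam + phi3 + delta + gamma*K, b = gamma*K*(lam + phi3
    + delta), c = phi3*delta*mu*K are reported verbatim for reference.
    """
    p = params
    dfe = np.array([p.K, 0.0, 0.0])
    J = dfe_jacobian(p, jacobian_mode)
    lam1 = _dominant_eigenvalue(J, dominance)
    R0, Rc = reproduction_from_lambda1(p, float(lam1.real))
    a = p.lam + p.phi3 + p.delta + p.gamma * p.K
    b = p.gamma * p.K * (p.lam + p.phi3 + p.delta)
    c = p.phi3 * p.delta * p.mu * p.K
    return ReproductionReport(
        dfe=dfe,
        jacobian_dfe=J,
        char_coeffs_dfe=(a, b, c),
        lambda1=lam1,
        R0=R0,
        Rc=Rc,
        interpretation={"dominance": dominance, "jacobian_mode": jacobian_mode},
    )


def interpretation_table(
    params: BaseModelParams,
    alt_phis: Tuple[float, float, float],
    jacobian_modes: Sequence[str] = ("paper-literal",),
) -> pd.DataFrame:
    """R0/Rc over every documented interpretation of the printed formulas.

    Rows: (phi set) x (dominance rule) x (jacobian mode).  ``alt_phis`` is
    the second printed (phi1, phi2, phi3) triple.  The default covers the
    4-way table (two phi sets x two dominance rules) on the printed
    Jacobian; pass ``jacobian_modes=("paper-literal", "derived")`` to probe
    the Jacobian discrepancy as well.
    """
    rows = []
    phi_sets = {
        "set1": (params.phi1, params.phi2, params.phi3),
        "set2": tuple(alt_phis),
    }
    for phi_name, (f1, f2, f3) in phi_sets.items():
        pp = params.replace(phi1=f1, phi2=f2, phi3=f3)
        for mode in jacobian_modes:
            for dom in ("max-real-part", "max-modulus"):
                rep = reproduction_numbers(pp, dominance=dom, jacobian_mode=mode)
                rows.append({
                    "phi_set": phi_name,
                    "jacobian_mode": mode,
                    "dominance": dom,
                    "lambda1_real": float(rep.lambda1.real),
                    "R0": rep.R0,
                    "Rc": rep.Rc,
                })
    return pd.DataFrame(rows)
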