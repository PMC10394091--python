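"""Normalized sensitivity coefficients of steady states and trajectories.

The elasticity S_i = d ln f / d ln k_i = (df/dk_i) * (k_i / f) is
approximated by finite differences with perturbation eps = 0.01 * theta
(1% of the parameter value).  Central differences are the default; the
forward-difference form is available as an exact-compatibility mode.
When the functional stays positive the difference is taken in log space
(a log-log slope), which renders power-law elasticities — the +/-1
closed forms of the steady state — exact at any perturbation size.

Steady-state functionals of the six-compartment stem-cell model evaluate
the root directly (:func:`kmodel_steady_state`) rather than simulating to
large time, which is both faster and exact; a simulate-to-T mode exists
via :func:`trajectory_sensitivity`.

``TABLE2_SENSITIVITIES`` and ``PRINTED_DC_DK`` are frozen display
fixtures reproducing the source's printed tables for side-by-side
comparison.  They are internally inconsistent with the source's own
steady-state algebra (nonzero entries for parameters the closed form is
independent of, zeros where it gives +/-1) and are therefore never used
as oracles.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Callable, Optional

import numpy as np

from .fde_engine import FDEProblem, solve_fde
from .models import KModelParams, kmodel_rhs, make_kmodel_fde_rhs

__all__ = [
    "SensitivityRecord",
    "kmodel_steady_state",
    "normalized_sensitivity",
    "trajectory_sensitivity",
    "TABLE2_SENSITIVITIES",
    "PRINTED_DC_DK",
]

# frozen display fixture: printed steady-state sensitivity table (not an oracle)
TABLE2_SENSITIVITIES = {
    "k1": -0.01920601, "k2": -0.04182639, "k3": -0.02508897, "k4": -0.01293607,
    "k5": 0.04312616, "k6": 0.0, "k7": 0.0, "k8": 0.0, "k9": 0.0,
    "k10": -0.01293607, "k11": 0.0, "k12": 0.0, "k13": -0.04312616,
    "k14": 0.0, "alpha": 0.0,
}

# frozen display fixture: printed trajectory sensitivities dC/dk_i (evaluation
# time and k13/k14 values unstated in the source; comparison only)
PRINTED_DC_DK = {
    "k1": 0.7849, "k2": -1.3074, "k3": -0.9993, "k4": -0.4045, "k5": -1.2924,
    "k6": 0.0, "k7": 0.0, "k8": -1.4679, "k9": -0.4191, "k10": 0.0,
    "k11": 0.0, "k12": 0.0, "alpha": -6.0878,
}


@dataclass(frozen=True)
class SensitivityRecord:
    parameter: str
    coefficient: float
    method: str            # central-FD | forward-FD | analytic
    epsilon: float
    functional: str
    alternative: Optional[float] = None   # the other FD estimate, when it differs


# ---------------------------------------------------------------------------
# steady state of the stem-cell model


def kmodel_steady_state(params: KModelParams, branch: str = "nontrivial") -> np.ndarray:
    """Steady state (C, Pk, S, E, Nk, Ik) of the stem-cell model.

    The zero set factorises: Nk = k11/k12 always; Pk = k5*C/k6 and
    Ik = k13*Pk/k14 follow C; and C is either 0 (trivial branch) or pinned
    by a supporting/effector balance: with S != 0, C = k7/k8 and
    k3*S + k4*E = k1 - k2 with E = 0 (E != 0 would force the incompatible
    C = k9/k10); symmetrically for the effector branch.  Branches are
    enumerated, then Newton-polished against :func:`kmodel_rhs`; the
    returned state has residual <= 1e-8.

    ``branch``: "nontrivial" (default; falls back to trivial when no
    admissible nontrivial branch exists) or "trivial" (C = 0).
    """
    k = params
    for name in ("k12", "k14", "k8", "k10"):
        if getattr(k, name) <= 0:
            raise ValueError(f"{name} must be positive to define the steady state")
    if k.k6 <= 0:
        raise ValueError("k6 must be positive to define the steady state")

    Nk = k.k11 / k.k12

    def assemble(C: float, S: float, E: float) -> np.ndarray:
        Pk = k.k5 * C / k.k6
        Ik = k.k13 * Pk / k.k14
        return np.array([C, Pk, S, E, Nk, Ik])

    candidates = []
    if branch != "trivial":
        growth = k.k1 - k.k2
        # supporting-cell branch: S != 0 -> C = k7/k8, E = 0, S from balance
        if k.k3 > 0 and growth >= 0:
            candidates.append(assemble(k.k7 / k.k8, growth / k.k3, 0.0))
        # effector branch: E != 0 -> C = k9/k10, S = 0, E from balance
        if k.k4 > 0 and growth >= 0:
            candidates.append(assemble(k.k9 / k.k10, 0.0, growth / k.k4))
        # fully free branch: growth exactly balanced with S = E = 0
        if abs(growth) < 1e-14:
            candidates.append(assemble(k.k7 / k.k8, 0.0, 0.0))
    candidates.append(assemble(0.0, 0.0, 0.0))

    for cand in candidates:
        x = _newton_kmodel(k, cand)
        if x is not None:
            res = float(np.max(np.abs(kmodel_rhs(x, k))))
            if res <= 1e-8:
                return x
    raise RuntimeError(
        "no steady-state branch converged; the implicit balance "
        "k1 - k2 = k3*S + k4*E failed for these rate constants"
    )


def _kmodel_jacobian(k: KModelParams, x: np.ndarray) -> np.ndarray:
    C, Pk, S, E, Nk, Ik = x
    return np.array([
        [k.k1 - k.k2 - k.k3 * S - k.k4 * E, 0, -k.k3 * C, -k.k4 * C, 0, 0],
        [k.k5, -k.k6, 0, 0, 0, 0],
        [-k.k8 * S, 0, k.k7 - k.k8 * C, 0, 0, 0],
        [-k.k10 * E, 0, 0, k.k9 - k.k10 * C, 0, 0],
        [0, 0, 0, 0, -k.k12, 0],
        [0, k.k13, 0, 0, 0, -k.k14],
    ])


def _newton_kmodel(k: KModelParams, x0: np.ndarray, iters: int = 30) -> Optional[np.ndarray]:
    x = x0.copy()
    for _ in range(iters):
        f = kmodel_rhs(x, k)
        if np.max(np.abs(f)) < 1e-13 * max(1.0, np.max(np.abs(x))):
            return x
        try:
            x = x - np.linalg.solve(_kmodel_jacobian(k, x), f)
        except np.linalg.LinAlgError:
            return None
        if not np.all(np.isfinite(x)):
            return None
    return x if np.max(np.abs(kmodel_rhs(x, k))) <= 1e-8 else None


# ---------------------------------------------------------------------------
# finite-difference elasticities


def normalized_sensitivity(
    functional: Callable[[object], float],
    param_name: str,
    params,
    mode: str = "central",
    rel_eps: float = 0.01,
    functional_name: str = "",
) -> SensitivityRecord:
    """Elasticity of ``functional(params)`` w.r.t. one parameter.

    ``functional`` maps a parameter container to a scalar; the container
    must support dataclasses.replace.  eps = rel_eps * theta (the source's
    1% rule).  The record carries the other difference scheme's estimate
    whenever the two disagree by more than 1e-3.
    """
    theta = getattr(params, param_name)
    if theta == 0:
        raise ValueError(f"{param_name} is zero; the 1% perturbation rule is undefined")
    f0 = functional(params)
    if f0 == 0:
        raise ZeroDivisionError(f"functional vanishes at {param_name}={theta}; "
                                "normalization undefined")
    eps = rel_eps * theta
    f_plus = functional(replace(params, **{param_name: theta + eps}))
    f_minus = functional(replace(params, **{param_name: theta - eps}))
    if f0 > 0 and f_plus > 0 and f_minus > 0:
        # elasticity is a log-log slope; differencing in log space is exact
        # for power-law dependence (the +/-1 closed forms) at any eps
        s_central = (np.log(f_plus) - np.log(f_minus)) / (np.log(theta + eps) - np.log(theta - eps))
        s_forward = (np.log(f_plus) - np.log(f0)) / (np.log(theta + eps) - np.log(theta))
    else:
        s_central = (f_plus - f_minus) / (2 * eps) * theta / f0
        s_forward = (f_plus - f0) / eps * theta / f0
    main, other, method = (
        (s_central, s_forward, "central-FD") if mode == "central"
        else (s_forward, s_central, "forward-FD")
    )
    return SensitivityRecord(
        parameter=param_name,
        coefficient=float(main),
        method=method,
        epsilon=eps,
        functional=functional_name or getattr(functional, "__name__", "functional"),
        alternative=float(other) if abs(main - other) > 1e-3 else None,
    )


def trajectory_sensitivity(
    rhs_factory: Callable[[object], Callable],
    param_name: str,
    t_eval: float,
    params,
    initial_state,
    component: int = 0,
    alpha: Optional[float] = None,
    h: float = 2.0 ** -6,
    mode: str = "central",
    rel_eps: float = 0.01,
    normalized: bool = False,
) -> SensitivityRecord:
    """Finite-difference sensitivity of one trajectory component at t_eval.

    ``rhs_factory(params)`` builds the FDE rhs (e.g.
    :func:`caplung.models.make_kmodel_fde_rhs`).  Both perturbed problems
    are solved on identical grids with :func:`caplung.fde_engine.solve_fde`.
    ``normalized=True`` returns the elasticity instead of the raw
    derivative.
    """
    theta = getattr(params, param_name)
    if theta == 0:
        raise ValueError(f"{param_name} is zero; use an absolute perturbation instead")
    eps = rel_eps * theta
    alpha_val = alpha if alpha is not None else getattr(params, "alpha", 1.0)

    def run(p) -> float:
        prob = FDEProblem(order=alpha_val, rhs=rhs_factory(p),
                          initial_state=initial_state, t0=0.0, t_final=t_eval, step=h)
        grid = solve_fde(prob)
        return float(grid.states[-1, component])

    f_plus = run(replace(params, **{param_name: theta + eps}))
    if mode == "central":
        f_minus = run(replace(params, **{param_name: theta - eps}))
        deriv = (f_plus - f_minus) / (2 * eps)
        method = "central-FD"
    else:
        deriv = (f_plus - run(params)) / eps
        method = "forward-FD"
    coeff = deriv
    if normalized:
        f0 = run(params)
        if f0 == 0:
            raise ZeroDivisionError("trajectory component vanishes; normalization undefined")
        coeff = deriv * theta / f0
    return SensitivityRecord(
        parameter=param_name,
        coefficient=float(coeff),
        method=method,
        epsilon=eps,
        functional=f"component {component} at t={t_eval}",
    )
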