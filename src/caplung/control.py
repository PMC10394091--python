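"""Treatment optimization and closed-loop PID dosing.

Two control layers sit on top of the combined-therapy model:

* an open-loop optimal-control problem — minimise the therapy cost
  J = int_0^tf (w1*N + w2*I + w3*P - w4*T) dt over a bounded dosage
  u(t) in [0, u_max] that scales the treatment efficacies (eps1, eps2,
  eps3) multiplicatively — solved by the Pontryagin forward-backward
  sweep: forward state integration with the current control, backward
  costate integration of lambda' = -dH/dx with the zero terminal
  (transversality) condition, then a relaxed control update from the
  Hamiltonian's u-slope.  The Hamiltonian is linear in u, so the pointwise
  minimiser is bang-bang with the switching function
  theta(t-tau) * [lambda_P * (-(eps1*N*P + eps2*I*P)) + lambda_T * eps3*P];
  relaxation plus objective backtracking keeps accepted iterates
  non-increasing in J.

* a closed-loop dosing procedure — repeat: simulate the treatment horizon
  at the current dosage, compare end-of-horizon tumour burden N(t_f) with
  a target, and adjust the dosage with a discrete PID law until the error
  is inside a tolerance band.  Dosage lowers tumour burden, so the loop
  applies the PID correction with reverse action (dosage is increased
  when N(t_f) overshoots the target); the integral term is frozen while
  the dosage sits on a bound (anti-windup).

The costate equations are the classical (order-1) adjoint system, matching
the source procedure's own choice of alpha = 1 for the control horizon;
the forward state solve still goes through the fractional engine so any
order in (0, 1] can be explored.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, List, Optional, Sequence, Tuple

import numpy as np
from scipy.integrate import cumulative_trapezoid, trapezoid

from .fde_engine import FDEProblem, SolutionGrid, solve_fde
from .models import TherapyParams, heaviside_delay, make_feedback_fde_rhs, make_therapy_fde_rhs

__all__ = [
    "ControlWeights",
    "PIDGains",
    "CostateTrajectory",
    "ControlSolution",
    "DosingHistory",
    "objective_value",
    "pid_update",
    "feedback_dosing_loop",
    "forward_backward_sweep",
    "auxiliary_WV",
]


@dataclass(frozen=True)
class ControlWeights:
    """Objective weights (w1, w2, w3, w4): burden of N, I, P and credit for T."""

    w1: float
    w2: float
    w3: float
    w4: float

    def __post_init__(self):
        if min(self.w1, self.w2, self.w3, self.w4) < 0:
            raise ValueError("weights must be nonnegative")

    def as_signed_vector(self) -> np.ndarray:
        return np.array([self.w1, self.w2, self.w3, -self.w4])


@dataclass(frozen=True)
class PIDGains:
    """PID configuration for the dosing loop.

    ``N_target`` is the desired end-of-horizon cancer-cell count,
    ``tolerance`` the absolute stopping band on the tracking error, and
    ``max_cycles`` the loop bound.  Gains are nonnegative; the dosing loop
    applies them with reverse action.
    """

    Kp: float
    Ki: float
    Kd: float
    N_target: float = 0.0
    tolerance: float = 1.0
    max_cycles: int = 50

    def __post_init__(self):
        if min(self.Kp, self.Ki, self.Kd) < 0:
            raise ValueError("gains must be nonnegative")
        if self.tolerance <= 0:
            raise ValueError("tolerance must be positive")
        if self.max_cycles < 1:
            raise ValueError("max_cycles must be >= 1")


@dataclass
class CostateTrajectory:
    """Adjoint trajectory; terminal row is zero by transversality."""

    times: np.ndarray
    costates: np.ndarray

    @property
    def transversality_residual(self) -> float:
        return float(np.max(np.abs(self.costates[-1])))


@dataclass
class ControlSolution:
    states: SolutionGrid
    costates: CostateTrajectory
    control: np.ndarray
    objective: float
    iterations: List[dict] = field(default_factory=list)
    converged: bool = False


@dataclass
class DosingHistory:
    records: List[dict] = field(default_factory=list)
    termination: str = "max_cycles"   # converged | max_cycles | failed

    @property
    def final_dosage(self) -> float:
        return self.records[-1]["dosage"]

    @property
    def final_error(self) -> float:
        return self.records[-1]["error"]


# ---------------------------------------------------------------------------
# objective and PID primitives


def objective_value(traj: SolutionGrid, weights: ControlWeights) -> float:
    """Composite-trapezoid value of int (w1*N + w2*I + w3*P - w4*T) dt."""
    if traj.states.shape[1] != 4:
        raise ValueError("objective expects a 4-state (N, I, P, T) trajectory")
    integrand = traj.states @ weights.as_signed_vector()
    return float(trapezoid(integrand, traj.times))


def pid_update(error_history: Sequence[float], gains: PIDGains, dt: float) -> float:
    """Discrete PID output from a sampled error history.

    u = Kp * e_now + Ki * trapezoid(e) + Kd * (e_now - e_prev)/dt; the
    derivative term is zero when only one sample exists.
    """
    e = np.asarray(error_history, dtype=float)
    if e.size < 1:
        raise ValueError("need at least one error sample")
    if dt <= 0:
        raise ValueError("dt must be positive")
    prop = gains.Kp * e[-1]
    integ = gains.Ki * (trapezoid(e, dx=dt) if e.size > 1 else 0.0)
    deriv = gains.Kd * ((e[-1] - e[-2]) / dt if e.size > 1 else 0.0)
    return float(prop + integ + deriv)


# ---------------------------------------------------------------------------
# closed-loop dosing


def feedback_dosing_loop(
    params: TherapyParams,
    initial_state,
    gains: PIDGains,
    t_final: float = 30.0,
    h: float = 2.0 ** -6,
    alpha: float = 1.0,
    u0: float = 1.0,
    u_max: float = 10.0,
    direction: str = "reverse",
) -> DosingHistory:
    """Adjust the treatment dosage until N(t_f) tracks the target.

    Each cycle simulates the feedback model with efficacies scaled by the
    current dosage, evaluates e = N_target - N(t_f) and applies the PID
    correction: u = clamp(u0 -/+ PID(e-history), 0, u_max).  The default
    ``direction="reverse"`` subtracts the correction, appropriate when
    dosage lowers the end-of-horizon tumour burden; ``"direct"`` adds it,
    for regimes where clearing metastases releases N from suppression and
    dosage raises N(t_f).  The per-cycle sampling interval of the PID is
    one cycle.  Anti-windup: the integral accumulator is frozen during
    cycles whose dosage was clamped.  Deterministic throughout.
    """
    if direction not in ("reverse", "direct"):
        raise ValueError("direction must be 'reverse' or 'direct'")
    sign = -1.0 if direction == "reverse" else 1.0
    history = DosingHistory()
    u = float(u0)
    errors: List[float] = []
    integral = 0.0
    clamped_prev = False
    for cycle in range(1, gains.max_cycles + 1):
        rhs = make_feedback_fde_rhs(params.scaled(u))
        problem = FDEProblem(order=alpha, rhs=rhs, initial_state=initial_state,
                             t0=0.0, t_final=t_final, step=h)
        try:
            grid = solve_fde(problem)
        except Exception as exc:  # noqa: BLE001 - history up to failure is returned
            history.termination = f"failed: {exc}"
            return history
        n_end = float(grid.states[-1, 0])
        e = gains.N_target - n_end
        if errors and not clamped_prev:
            integral += 0.5 * (e + errors[-1])      # trapezoid, dt = 1 cycle
        errors.append(e)
        p_term = gains.Kp * e
        i_term = gains.Ki * integral
        d_term = gains.Kd * (e - errors[-2]) if len(errors) > 1 else 0.0
        history.records.append({
            "cycle": cycle, "dosage": u, "N_end": n_end, "error": e,
            "P": p_term, "I": i_term, "D": d_term,
        })
        if abs(e) <= gains.tolerance:
            history.termination = "converged"
            return history
        u_raw = u0 + sign * (p_term + i_term + d_term)
        u_new = min(max(u_raw, 0.0), u_max)
        clamped_prev = u_new != u_raw
        u = u_new
    history.termination = "max_cycles"
    return history


# ---------------------------------------------------------------------------
# Pontryagin forward-backward sweep


def _therapy_state_jacobian(y: np.ndarray, t: float, p: TherapyParams, u: float) -> np.ndarray:
    """d f / d state for the therapy model with dosage-scaled efficacies."""
    N, I, P, T = y
    b = p.base
    th = heaviside_delay(t, p.tau)
    e1, e2, e3 = u * p.eps1, u * p.eps2, u * p.eps3
    return np.array([
        [b.lam - 2 * b.lam * N / b.K - b.mu * P - b.beta1 * I, -b.beta1 * N, -b.mu * N, 0.0],
        [2 * b.phi2 * N, -b.phi3 - b.beta2 * P, -b.beta2 * I, 0.0],
        [th * (-e1 * P) + b.gamma * P, -b.beta3 * P - th * e2 * P,
         b.gamma * N - b.delta - b.beta3 * I - th * (e1 * N + e2 * I), 0.0],
        [0.0, 0.0, th * e3, -p.eps4],
    ])


def _backward_costates(
    times: np.ndarray,
    states: np.ndarray,
    u: np.ndarray,
    params: TherapyParams,
    weights: ControlWeights,
) -> np.ndarray:
    """RK4 backward integration of lambda' = -(w + J^T lambda), lambda(tf) = 0."""
    n = len(times) - 1
    h = times[1] - times[0]
    w = weights.as_signed_vector()
    lam = np.zeros((n + 1, 4))

    def slope(i_lo: int, frac: float, lam_vec: np.ndarray) -> np.ndarray:
        # interpolate state/control linearly inside the step
        y = (1 - frac) * states[i_lo] + frac * states[min(i_lo + 1, n)]
        uu = (1 - frac) * u[i_lo] + frac * u[min(i_lo + 1, n)]
        t = times[i_lo] + frac * h
        J = _therapy_state_jacobian(y, t, params, uu)
        return -(w + J.T @ lam_vec)

    for i in range(n, 0, -1):
        # integrate from t_i down to t_{i-1}; RK4 with step -h
        l0 = lam[i]
        k1 = slope(i - 1, 1.0, l0)
        k2 = slope(i - 1, 0.5, l0 - 0.5 * h * k1)
        k3 = slope(i - 1, 0.5, l0 - 0.5 * h * k2)
        k4 = slope(i - 1, 0.0, l0 - h * k3)
        lam[i - 1] = l0 - (h / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4)
    return lam


def _switching_function(
    times: np.ndarray, states: np.ndarray, costates: np.ndarray, params: TherapyParams
) -> np.ndarray:
    """dH/du on the grid: H is linear in the dosage scale u."""
    N, I, P = states[:, 0], states[:, 1], states[:, 2]
    th = np.array([heaviside_delay(t, params.tau) for t in times])
    return th * (
        costates[:, 2] * (-(params.eps1 * N * P + params.eps2 * I * P))
        + costates[:, 3] * params.eps3 * P
    )


def forward_backward_sweep(
    params: TherapyParams,
    weights: ControlWeights,
    initial_state,
    t_final: float = 30.0,
    h: float = 2.0 ** -6,
    alpha: float = 1.0,
    u_max: float = 1.0,
    relaxation: float = 0.5,
    tol: float = 1e-4,
    max_iter: int = 40,
    max_backtracks: int = 8,
) -> ControlSolution:
    """Iterative Pontryagin solution of the combined-therapy problem.

    Starts from u = 0 (no treatment).  Each sweep: forward state solve at
    the current control, backward costate solve with zero terminal
    condition, bang-bang target from the switching function (pointwise
    minimiser of the u-linear Hamiltonian; the previous value is kept on
    near-zero switching), relaxed update, and objective backtracking so
    accepted iterates never increase J.  Convergence: sup-norm control
    change <= tol.

    Raises RuntimeError with the iteration log attached if every
    backtracked step still increases the objective.
    """

    def forward(u_grid: np.ndarray) -> SolutionGrid:
        rhs = make_therapy_fde_rhs(params)
        problem = FDEProblem(order=alpha, rhs=rhs, initial_state=initial_state,
                             t0=0.0, t_final=t_final, step=h)
        grid = solve_fde(problem, input_signal=u_grid)
        grid.metadata["columns"] = ["N", "I", "P", "T"]
        return grid

    n_pts = int(round(t_final / h)) + 1
    u = np.zeros(n_pts)
    traj = forward(u)
    J = objective_value(traj, weights)
    log: List[dict] = [{"iteration": 0, "J": J, "relaxation": None}]
    costates = np.zeros((n_pts, 4))
    converged = False

    for it in range(1, max_iter + 1):
        costates = _backward_costates(traj.times, traj.states, u, params, weights)
        phi = _switching_function(traj.times, traj.states, costates, params)
        u_target = np.where(phi < 0, u_max, 0.0)
        # keep the previous control where the switching function is
        # numerically indistinguishable from zero (singular/inactive arcs)
        dead = np.abs(phi) < 1e-12 * (1.0 + np.max(np.abs(phi)))
        u_target[dead] = u[dead]

        r = relaxation
        accepted = False
        for _ in range(max_backtracks + 1):
            u_new = (1 - r) * u + r * u_target
            traj_new = forward(u_new)
            J_new = objective_value(traj_new, weights)
            if J_new <= J + 1e-12 * (1 + abs(J)):
                accepted = True
                break
            r *= 0.5
        if not accepted:
            err = RuntimeError(
                f"sweep diverged at iteration {it}: objective increases for "
                f"all {max_backtracks + 1} relaxation factors"
            )
            err.iteration_log = log  # type: ignore[attr-defined]
            raise err
        du = float(np.max(np.abs(u_new - u)))
        dJ = abs(J - J_new)
        u, traj, J = u_new, traj_new, J_new
        log.append({"iteration": it, "J": J, "relaxation": r, "du": du})
        if du <= tol:
            converged = True
            break
        # secondary stop: bang-bang switch points can chatter by one grid
        # cell forever while J is fully converged
        recent = [entry["J"] for entry in log[-3:]]
        if len(recent) == 3 and max(recent) - min(recent) <= 1e-11 * (1 + abs(J)) and dJ <= 1e-11 * (1 + abs(J)):
            converged = True
            break

    return ControlSolution(
        states=traj,
        costates=CostateTrajectory(times=traj.times, costates=costates),
        control=u,
        objective=J,
        iterations=log,
        converged=converged,
    )


# ---------------------------------------------------------------------------
# auxiliary growth-factor / wound-healing trajectories


def auxiliary_WV(
    costates: CostateTrajectory,
    control_phis: Sequence[float],
    eps1: float,
    eps3: float,
    W0: float = 100.0,
    V0: float = 50.0,
) -> Tuple[np.ndarray, np.ndarray]:
    """Wound-healing W(t) and VEGF V(t) from a 10-column costate trajectory.

    W(t) = W0 + int (psi10 - eps3*psi6) ds and
    V(t) = V0 + int (phi1'*psi2 + phi2'*psi5 + phi3'*psi2 + phi4'*psi7
    - eps1*psi9) ds by composite trapezoid, using the second phi set
    (phi1'..phi4').  The phi3'*psi2 term is implemented exactly as printed
    in the source even though it plausibly duplicates phi1'*psi2 by typo.
    """
    psi = np.asarray(costates.costates, dtype=float)
    if psi.shape[1] != 10:
        raise ValueError("auxiliary_WV expects 10 costate columns psi1..psi10")
    f1, f2, f3, f4 = control_phis[:4]
    t = costates.times
    w_integrand = psi[:, 9] - eps3 * psi[:, 5]
    v_integrand = f1 * psi[:, 1] + f2 * psi[:, 4] + f3 * psi[:, 1] + f4 * psi[:, 6] - eps1 * psi[:, 8]
    W = W0 + np.concatenate([[0.0], cumulative_trapezoid(w_integrand, t)])
    V = V0 + np.concatenate([[0.0], cumulative_trapezoid(v_integrand, t)])
    return W, V
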