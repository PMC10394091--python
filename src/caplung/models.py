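"""Right-hand sides and parameter containers for the lung-cancer models.

Four model families share this module:

* the base tumour-immune-metastasis system in (N, I, P) — lung cancer
  cells, immune cells and disseminated (metastatic) cancer cells:

      D^a N = lam*N*(1 - N/K) - mu*N*P - beta1*N*I
      D^a I = phi1*I0 + phi2*N^2 - phi3*I - beta2*I*P
      D^a P = gamma*N*P - delta*P - beta3*I*P

* the combined-therapy extension (N, I, P, T) where a Heaviside-delayed
  treatment removes disseminated cells and T tracks surgically removed
  tumour cells;

* the feedback variant used for closed-loop dosing, identical to the
  therapy model except that the treatment term also depletes N and I
  directly;

* a six-compartment cancer-stem-cell model (C, Pk, S, E, Nk, Ik) with
  mass-action rate constants k1..k14, used for sensitivity analysis.  The
  source material only states its steady-state equations; the dynamics
  here are the unique mass-action system whose zero set reproduces them —
  each steady-state expression is read as the Caputo derivative of its
  compartment.

``phi1*I0`` in the immune equation is a constant source term: ``I0``
(stored as ``I_baseline``) is the baseline immune count, not the evolving
state.

Negative-state policy: the rhs functions are pure arithmetic and never
clip; trajectories are integrated as-is and the first nonnegativity
violation can be located with :func:`first_negative_crossing`.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field, fields, replace
from pathlib import Path
from typing import Optional, Sequence, Tuple

import numpy as np

__all__ = [
    "BaseModelParams",
    "TherapyParams",
    "KModelParams",
    "SimulationPreset",
    "heaviside_delay",
    "base_rhs",
    "therapy_rhs",
    "feedback_rhs",
    "kmodel_rhs",
    "make_base_fde_rhs",
    "make_therapy_fde_rhs",
    "make_feedback_fde_rhs",
    "make_kmodel_fde_rhs",
    "first_negative_crossing",
]


def _load_flat_mapping(source) -> dict:
    """Flat key-value mapping from a dict, JSON or YAML file/text."""
    if isinstance(source, dict):
        return dict(source)
    path = Path(source)
    text = path.read_text() if path.exists() else str(source)
    try:
        data = json.loads(text)
    except json.JSONDecodeError:
        import yaml

        data = yaml.safe_load(text)
    if not isinstance(data, dict):
        raise ValueError("parameter config must be a flat key-value mapping")
    return data


class _ConfigLoadable:
    """from_dict / from_file with unknown-key rejection for param containers."""

    @classmethod
    def from_dict(cls, data: dict):
        names = {f.name for f in fields(cls)}
        unknown = set(data) - names
        if unknown:
            raise ValueError(
                f"unknown parameter keys for {cls.__name__}: {sorted(unknown)}"
            )
        return cls(**data)

    @classmethod
    def from_file(cls, path):
        return cls.from_dict(_load_flat_mapping(path))

    def to_dict(self) -> dict:
        return asdict(self)

    def replace(self, **kwargs):
        return replace(self, **kwargs)


@dataclass(frozen=True)
class BaseModelParams(_ConfigLoadable):
    """Rate constants of the base (N, I, P) model.

    Units: rates are per day; ``K`` is cells; ``mu`` is per (cell * day);
    ``alpha`` is the dimensionless Caputo order in (0, 1].
    ``I_baseline`` is the constant immune baseline I0 multiplying phi1.
    """

    lam: float
    K: float
    mu: float
    gamma: float
    delta: float
    beta1: float
    beta2: float
    beta3: float
    phi1: float
    phi2: float
    phi3: float
    I_baseline: float
    alpha: float = 1.0

    def __post_init__(self):
        for name in ("lam", "mu", "gamma", "delta", "beta1", "beta2", "beta3",
                     "phi1", "phi2", "phi3", "I_baseline"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        if self.K <= 0:
            raise ValueError("K must be positive")
        if not 0.0 < self.alpha <= 1.0:
            raise ValueError("alpha must lie in (0, 1]")


@dataclass(frozen=True)
class TherapyParams(_ConfigLoadable):
    """Treatment/surgery efficacies eps1..eps4 and delay tau on top of base params."""

    base: BaseModelParams
    eps1: float
    eps2: float
    eps3: float
    eps4: float
    tau: float

    def __post_init__(self):
        for name in ("eps1", "eps2", "eps3", "eps4", "tau"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")

    @classmethod
    def from_dict(cls, data: dict):
        data = dict(data)
        base = data.pop("base", None)
        if isinstance(base, dict):
            base = BaseModelParams.from_dict(base)
        names = {f.name for f in fields(cls)} - {"base"}
        unknown = set(data) - names
        if unknown:
            raise ValueError(f"unknown parameter keys for TherapyParams: {sorted(unknown)}")
        return cls(base=base, **data)

    def scaled(self, dosage: float) -> "TherapyParams":
        """Efficacies eps1..eps3 scaled multiplicatively by a dosage factor.

        The dosage-to-efficacy map is a policy choice (the source never
        states one); multiplicative scaling with dosage 1 = nominal is the
        default and can be replaced by building params directly.
        """
        return replace(self, eps1=self.eps1 * dosage, eps2=self.eps2 * dosage,
                       eps3=self.eps3 * dosage)


@dataclass(frozen=True)
class KModelParams(_ConfigLoadable):
    """Rate constants k1..k14 of the six-compartment stem-cell model."""

    k1: float
    k2: float
    k3: float
    k4: float
    k5: float
    k6: float
    k7: float
    k8: float
    k9: float
    k10: float
    k11: float
    k12: float
    k13: float
    k14: float
    alpha: float = 1.0

    def __post_init__(self):
        for f in fields(self):
            if f.name != "alpha" and getattr(self, f.name) < 0:
                raise ValueError(f"{f.name} must be nonnegative")
        if not 0.0 < self.alpha <= 1.0:
            raise ValueError("alpha must lie in (0, 1]")


@dataclass(frozen=True)
class SimulationPreset:
    """Named bundle of every constant a reproducible run needs.

    ``control_phis`` is the second, independent phi set (phi1'..phi10')
    used only by the control-auxiliary computations; the base-model phi1-3
    live in ``base``.  ``theta_scalar`` and ``eta`` are stored verbatim
    from the source constant list; they enter no equation directly, but the
    preset's treatment efficacies are derived from them (eps1 = eps2 =
    eps4 = theta_scalar, eps3 = eta).
    """

    name: str
    base: BaseModelParams
    therapy: TherapyParams
    kparams: KModelParams
    initial_state: Tuple[float, float, float]          # (N0, I0, P0)
    T0: float
    W0: float
    V0: float
    k_initial: Tuple[float, float, float, float, float, float]  # (C, Pk, S, E, Nk, Ik)
    control_phis: Tuple[float, ...]                    # phi1'..phi10'
    theta_scalar: float
    eta: float
    alphas: Tuple[float, ...]
    t0: float
    t_final: float
    h: float

    @property
    def therapy_initial_state(self) -> np.ndarray:
        return np.array([*self.initial_state, self.T0])

    def to_dict(self) -> dict:
        return asdict(self)


def heaviside_delay(t: float, tau: float) -> float:
    """Unit step theta(t - tau): 0 before the delay, 1 from t = tau on.

    The boundary theta(0) = 1 means treatment is active at exactly t = tau.
    """
    return 1.0 if t >= tau else 0.0


def base_rhs(state, params: BaseModelParams) -> np.ndarray:
    """Derivatives of the base (N, I, P) model."""
    N, I, P = state
    p = params
    dN = p.lam * N * (1.0 - N / p.K) - p.mu * N * P - p.beta1 * N * I
    dI = p.phi1 * p.I_baseline + p.phi2 * N * N - p.phi3 * I - p.beta2 * I * P
    dP = p.gamma * N * P - p.delta * P - p.beta3 * I * P
    return np.array([dN, dI, dP])


def therapy_rhs(state, t: float, params: TherapyParams) -> np.ndarray:
    """Combined-therapy model: treatment drains P, surgery fills T.

    N and I follow the base dynamics; after the delay tau the treatment
    removes disseminated cells at rate eps1*N*P + eps2*I*P and surgery
    transfers eps3*P into the removed pool T, which clears at rate eps4.
    """
    N, I, P, T = state
    p = params
    dN, dI, dP = base_rhs((N, I, P), p.base)
    th = heaviside_delay(t, p.tau)
    dP -= th * (p.eps1 * N * P + p.eps2 * I * P)
    dT = th * p.eps3 * P - p.eps4 * T
    return np.array([dN, dI, dP, dT])


def feedback_rhs(state, t: float, params: TherapyParams) -> np.ndarray:
    """Feedback-control variant: treatment also depletes N and I directly.

    Identical to :func:`therapy_rhs` except for the additional
    ``-theta(t-tau)*eps1*N*P`` term in the N equation and
    ``-theta(t-tau)*eps2*I*P`` term in the I equation.
    """
    N, I, P, T = state
    p = params
    out = therapy_rhs(state, t, params)
    th = heaviside_delay(t, p.tau)
    out[0] -= th * p.eps1 * N * P
    out[1] -= th * p.eps2 * I * P
    return out


def kmodel_rhs(state, params: KModelParams) -> np.ndarray:
    """Six-compartment stem-cell model derivatives.

    Compartments: C cancer stem cells, Pk progenitor cells, S supporting
    cells, E effector/environment, Nk normal cells, Ik immune compartment.
    """
    C, Pk, S, E, Nk, Ik = state
    k = params
    dC = k.k1 * C - k.k2 * C - k.k3 * C * S - k.k4 * C * E
    dPk = k.k5 * C - k.k6 * Pk
    dS = k.k7 * S - k.k8 * C * S
    dE = k.k9 * E - k.k10 * C * E
    dNk = k.k11 - k.k12 * Nk
    dIk = k.k13 * Pk - k.k14 * Ik
    return np.array([dC, dPk, dS, dE, dNk, dIk])


# -- adapters onto the FDE engine's rhs(t, y, u) contract ------------------

def make_base_fde_rhs(params: BaseModelParams):
    def base_model(t, y, u=None):
        return base_rhs(y, params)
    return base_model


def make_therapy_fde_rhs(params: TherapyParams):
    """Therapy rhs closure; exogenous input u (if given) scales eps1..eps3."""
    def therapy_model(t, y, u=None):
        p = params if u is None else params.scaled(u)
        return therapy_rhs(y, t, p)
    return therapy_model


def make_feedback_fde_rhs(params: TherapyParams):
    def feedback_model(t, y, u=None):
        p = params if u is None else params.scaled(u)
        return feedback_rhs(y, t, p)
    return feedback_model


def make_kmodel_fde_rhs(params: KModelParams):
    def kmodel(t, y, u=None):
        return kmodel_rhs(y, params)
    return kmodel


def first_negative_crossing(states: np.ndarray) -> Optional[Tuple[int, int]]:
    """(row, column) of the first negative entry in a trajectory, or None.

    Used to monitor the nonnegativity invariant without clipping: a
    violation is reported, never silently altered.
    """
    neg = np.argwhere(np.asarray(states) < 0.0)
    if neg.size == 0:
        return None
    row = neg[:, 0].min()
    col = neg[neg[:, 0] == row][:, 1].min()
    return int(row), int(col)
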