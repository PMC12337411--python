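"""Closed-form four-state transcription/splicing/degradation kinetics.

The underlying two-species ODE per gene is

    du/dt = alpha - beta * u
    ds/dt = beta * u - gamma * s

with transcription rate ``alpha`` switched off at a gene-specific switching
time ``t_switch``. Cells occupy one of four transcriptional states:

    k=1 induction           (alpha > 0, t in [0, t_switch])
    k=2 induction steady    (t -> inf limit of induction)
    k=3 repression          (alpha = 0, t in [t_switch, t_max])
    k=4 repression steady   (t -> inf limit of repression: both species 0)

All functions are vectorised and accept either NumPy arrays or autodiff
``Tensor`` objects (the training loop differentiates through them).
Velocity is the instantaneous rate of change of spliced abundance,
``v = beta * u - gamma * s``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._autodiff import Tensor, exp, expm1

__all__ = [
    "KineticParams",
    "transcription_rate",
    "predict_unspliced",
    "predict_spliced",
    "velocity",
    "induction_u",
    "induction_s",
    "repression_u",
    "repression_s",
    "switch_point",
]

#: minimum allowed |beta - gamma|; the spliced closed form divides by it
BETA_GAMMA_EPS = 1e-6

INDUCTION, INDUCTION_SS, REPRESSION, REPRESSION_SS = 1, 2, 3, 4


@dataclass
class KineticParams:
    """Per-gene kinetic rates and noise scales.

    Parameters may be scalars or length-G arrays. ``alpha1`` is the induction
    transcription rate; in the (default) constant-rate mode ``alpha0`` and
    ``lambda_alpha`` are unused. ``t_max`` fixes the global time scale shared
    across genes; ``t_switch`` must lie strictly inside (0, t_max).
    ``c_state`` scales the observation noise per state (repression steady
    state is modelled as much tighter).
    """

    alpha1: np.ndarray
    beta: np.ndarray
    gamma: np.ndarray
    t_switch: np.ndarray
    t_max: float = 20.0
    sigma_u: np.ndarray | None = None
    sigma_s: np.ndarray | None = None
    alpha0: np.ndarray | None = None
    lambda_alpha: np.ndarray | None = None
    time_dependent: bool = False
    c_state: tuple = (1.0, 1.0, 1.0, 0.1)

    def __post_init__(self):
        for name in ("alpha1", "beta", "gamma", "t_switch"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        if np.any(self.alpha1 <= 0) or np.any(self.beta <= 0) or np.any(self.gamma <= 0):
            raise ValueError("kinetic rates alpha1, beta, gamma must be strictly positive")
        if np.any(np.abs(self.beta - self.gamma) <= BETA_GAMMA_EPS):
            raise ValueError(
                f"|beta - gamma| must exceed {BETA_GAMMA_EPS}; the spliced closed form "
                "is singular at beta == gamma"
            )
        if np.any(self.t_switch <= 0) or np.any(self.t_switch >= self.t_max):
            raise ValueError("t_switch must lie in (0, t_max)")
        if self.time_dependent and (self.alpha0 is None or self.lambda_alpha is None):
            raise ValueError("time-dependent mode requires alpha0 and lambda_alpha")

    @property
    def n_genes(self) -> int:
        return int(np.broadcast(self.alpha1, self.beta, self.gamma, self.t_switch).size)


def _alpha_at(t, p: KineticParams):
    """Effective transcription rate during induction (constant by default)."""
    if not p.time_dependent:
        return p.alpha1
    return p.alpha1 - (p.alpha1 - p.alpha0) * exp(-p.lambda_alpha * t)


def transcription_rate(t, k: int, p: KineticParams):
    """Transcription rate alpha^(k)(t): active in induction states, 0 after."""
    if np.any(np.asarray(t.data if isinstance(t, Tensor) else t) < 0):
        raise ValueError("time must be non-negative")
    if k in (REPRESSION, REPRESSION_SS):
        return np.zeros_like(np.asarray(t, dtype=float) * np.ones_like(p.alpha1))
    return _alpha_at(t, p) * np.ones_like(np.asarray(t, dtype=float))


# --------------------------------------------------------------------- branches
def induction_u(t, alpha, beta):
    """Unspliced abundance on the induction branch, u(0)=0."""
    return (alpha / beta) * (1.0 - exp(-beta * t))


def _dexp(tau, beta, gamma):
    """(e^{-gamma tau} - e^{-beta tau}) / (gamma - beta), stably.

    Written as e^{-beta tau} expm1(-(gamma-beta) tau) / (gamma-beta), which
    has a removable singularity at gamma = beta (limit tau e^{-beta tau})
    and stays accurate and differentiable for small rate differences. An
    exactly (or near-) zero difference is nudged to +-1e-12, well inside
    float64 accuracy of the limit.
    """
    d = gamma - beta
    dd = d.data if isinstance(d, Tensor) else np.asarray(d, dtype=float)
    tiny = 1e-12
    adj = np.where(np.abs(dd) < tiny,
                   np.where(dd >= 0, tiny - dd, -tiny - dd), 0.0)
    if np.any(adj != 0):
        d = d + adj
    return exp(-beta * tau) * expm1(-d * tau) / d


def induction_s(t, alpha, beta, gamma):
    """Spliced abundance on the induction branch, s(0)=0."""
    return (alpha / gamma) * (1.0 - exp(-gamma * t)) + alpha * _dexp(t, beta, gamma)


def repression_u(tau, u0, beta):
    """Unspliced abundance a time ``tau`` after the switch, from u0."""
    return u0 * exp(-beta * tau)


def repression_s(tau, u0, s0, beta, gamma):
    """Spliced abundance a time ``tau`` after the switch, from (u0, s0)."""
    return s0 * exp(-gamma * tau) - beta * u0 * _dexp(tau, beta, gamma)


def switch_point(p: KineticParams):
    """(u, s) at the switching time: initial condition of the repression branch."""
    alpha = _alpha_at(p.t_switch, p) if p.time_dependent else p.alpha1
    u0 = induction_u(p.t_switch, alpha, p.beta)
    s0 = induction_s(p.t_switch, alpha, p.beta, p.gamma)
    return u0, s0


# ------------------------------------------------------------------- public API
def _check_time(t, k, p):
    tarr = np.asarray(t.data if isinstance(t, Tensor) else t, dtype=float)
    if np.any(tarr < 0):
        raise ValueError("time must be non-negative")
    if k == REPRESSION and np.any(tarr < p.t_switch - 1e-12):
        raise ValueError("repression branch requires t >= t_switch")


def predict_unspliced(t, k: int, p: KineticParams):
    """Expected unspliced abundance at latent time ``t`` in state ``k``."""
    _check_time(t, k, p)
    alpha = _alpha_at(t, p)
    if k == INDUCTION:
        return induction_u(t, alpha, p.beta)
    if k == INDUCTION_SS:
        return (p.alpha1 / p.beta) * np.ones_like(np.asarray(t, dtype=float))
    if k == REPRESSION:
        u0, _ = switch_point(p)
        return repression_u(t - p.t_switch, u0, p.beta)
    if k == REPRESSION_SS:
        return np.zeros_like(np.asarray(t, dtype=float) * np.ones_like(p.beta))
    raise ValueError(f"unknown state {k}")


def predict_spliced(t, k: int, p: KineticParams):
    """Expected spliced abundance at latent time ``t`` in state ``k``."""
    _check_time(t, k, p)
    alpha = _alpha_at(t, p)
    if k == INDUCTION:
        return induction_s(t, alpha, p.beta, p.gamma)
    if k == INDUCTION_SS:
        return (p.alpha1 / p.gamma) * np.ones_like(np.asarray(t, dtype=float))
    if k == REPRESSION:
        u0, s0 = switch_point(p)
        return repression_s(t - p.t_switch, u0, s0, p.beta, p.gamma)
    if k == REPRESSION_SS:
        return np.zeros_like(np.asarray(t, dtype=float) * np.ones_like(p.beta))
    raise ValueError(f"unknown state {k}")


def velocity(t, k: int, p: KineticParams):
    """RNA velocity v = beta * u(t,k) - gamma * s(t,k).

    At both steady states the balance beta u = gamma s holds identically
    (beta alpha/beta = gamma alpha/gamma = alpha, resp. 0 = 0), so those
    branches return exact zeros rather than round-off residue.
    """
    if k in (INDUCTION_SS, REPRESSION_SS):
        return np.zeros_like(np.asarray(t, dtype=float) * np.ones_like(p.beta))
    return p.beta * predict_unspliced(t, k, p) - p.gamma * predict_spliced(t, k, p)
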