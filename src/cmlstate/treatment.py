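"""Treatment forces and diffusion schedules for the state-transition model.

Two interventions are modeled on top of the disease landscape ``U_p``:

* **TOTO** (Tet-off -> Tet-on): complete genetic silencing of the
  oncogenic signal from ``t_on`` onward.  The treatment force is a
  constant-in-time multiple of the gradient difference between the
  disease-shaped cubic and the healthy linear gradient,

      dU_TOTO/dx = a (x - c2) (x^2 + c1 (c5 - x) - c5 x - 1)

  which is identically the factored form of
  ``a (x-c1)(x-c2)(x-c5) - a (x-c2)``.

* **TKI** (tyrosine kinase inhibitor, nilotinib): protein-level
  inhibition dosed over ``[t_on, t_off]``.  The gradient difference of
  the two cubic approximations collapses to the quadratic

      dU_TKI/dx = a (c3 - c5) (x - c1) (x - c2)

  and after dosing ends the force decays exponentially with the drug
  elimination rate ``lam`` (per week, from the nilotinib half-life).

Diffusion is piecewise constant: one plateau switch for TOTO
(pre/on) and two for TKI (pre/on/post).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, asdict

import numpy as np

from .potentials import PotentialModel

__all__ = [
    "NILOTINIB_LAMBDA_PER_WEEK",
    "TreatmentSchedule",
    "toto_gradient",
    "tki_gradient",
    "treatment_force",
    "diffusion_value",
    "circuit_treatment",
]

# Nilotinib elimination half-life is about 17 h; on a weekly time unit
# lambda = ln 2 / (17/168) per week.
NILOTINIB_LAMBDA_PER_WEEK = float(np.log(2.0) / (17.0 / 168.0))


@dataclass
class TreatmentSchedule:
    """Timing, strength and diffusion plateaus of one treatment arm.

    ``kind`` is "none", "TOTO" or "TKI".  ``gamma`` is the treatment
    response strength (1.1 for TOTO, 1.4 for TKI).  ``t_on`` is the week
    treatment starts (default 6); ``t_off`` the week TKI dosing ends
    (default 10, i.e. four weeks of dosing).  ``lam`` is the post-dosing
    force decay rate per week.  ``beta_pre/on/post`` are the diffusion
    plateaus in state-space units^2 per week.
    """

    kind: str = "none"
    gamma: float = 1.0
    t_on: float = 6.0
    t_off: float = 10.0
    lam: float = NILOTINIB_LAMBDA_PER_WEEK
    beta_pre: float = 0.05
    beta_on: float = 0.05
    beta_post: float = 0.05

    def __post_init__(self):
        if self.kind not in ("none", "TOTO", "TKI"):
            raise ValueError(f"unknown treatment kind {self.kind!r}")
        if min(self.beta_pre, self.beta_on, self.beta_post) <= 0:
            raise ValueError("diffusion plateaus must be positive")
        if self.lam < 0:
            raise ValueError("decay rate lam must be nonnegative")
        if self.kind == "TKI" and not self.t_on < self.t_off:
            raise ValueError("TKI schedule requires t_on < t_off")
        if self.gamma <= 0:
            raise ValueError("gamma must be positive")

    # convenience constructors with the fitted defaults
    @classmethod
    def toto(cls, gamma=1.1, t_on=6.0, **kw) -> "TreatmentSchedule":
        return cls(kind="TOTO", gamma=gamma, t_on=t_on, **kw)

    @classmethod
    def tki(cls, gamma=1.4, t_on=6.0, t_off=10.0, **kw) -> "TreatmentSchedule":
        return cls(kind="TKI", gamma=gamma, t_on=t_on, t_off=t_off, **kw)

    @classmethod
    def none(cls, beta=0.05) -> "TreatmentSchedule":
        return cls(kind="none", beta_pre=beta, beta_on=beta, beta_post=beta)

    def force(self, potential: PotentialModel, x, t):
        return treatment_force(self, potential, x, t)

    def diffusion(self, t):
        return diffusion_value(self, t)

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)

    @classmethod
    def from_json(cls, text: str) -> "TreatmentSchedule":
        return cls(**json.loads(text))


def _require_points(potential: PotentialModel, labels):
    if len(potential.critical_points) < max(labels):
        raise ValueError(
            f"potential of kind {potential.kind!r} lacks critical points "
            f"c{max(labels)}; a quintic landscape is required")


def toto_gradient(x, potential: PotentialModel):
    """Gradient of the TOTO transformation potential.

    Difference between the disease cubic ``a (x-c1)(x-c2)(x-c5)`` and the
    healthy linear gradient ``a (x-c2)``; equals the factored quadratic
    form ``a (x-c2)(x^2 + c1 (c5-x) - c5 x - 1)`` identically.
    """
    _require_points(potential, (1, 2, 5))
    a = potential.a
    c1, c2, c5 = potential.c(1), potential.c(2), potential.c(5)
    x = np.asarray(x, dtype=float)
    out = a * (x - c2) * (x * x + c1 * (c5 - x) - c5 * x - 1.0)
    return out if out.ndim else float(out)


def tki_gradient(x, potential: PotentialModel):
    """Gradient of the TKI transformation potential.

    ``a (c3-c5)(x-c1)(x-c2)`` — the difference of the disease cubic
    ``a (x-c1)(x-c2)(x-c5)`` and the normal cubic ``a (x-c1)(x-c2)(x-c3)``.
    Degenerate (identically zero) when c3 == c5.
    """
    _require_points(potential, (1, 2, 3, 5))
    a = potential.a
    c1, c2, c3, c5 = (potential.c(i) for i in (1, 2, 3, 5))
    if c3 == c5:
        warnings.warn("c3 == c5: TKI gradient is identically zero")
    x = np.asarray(x, dtype=float)
    out = a * (c3 - c5) * (x - c1) * (x - c2)
    return out if out.ndim else float(out)


def treatment_force(schedule: TreatmentSchedule, potential: PotentialModel,
                    x, t):
    """Treatment force F(x, t) for a schedule.

    Zero before ``t_on`` (Heaviside switch-on).  TOTO applies
    ``gamma * dU_TOTO/dx`` constant in time from ``t_on``; TKI applies
    ``gamma * dU_TKI/dx`` during dosing and decays it as
    ``exp(-lam (t - t_off))`` afterwards, continuous at ``t_off``.
    """
    x = np.asarray(x, dtype=float)
    if schedule.kind == "none" or t < schedule.t_on:
        out = np.zeros_like(x)
        return out if out.ndim else 0.0
    if schedule.kind == "TOTO":
        return schedule.gamma * toto_gradient(x, potential)
    # TKI
    amp = schedule.gamma
    if t > schedule.t_off:
        amp *= np.exp(-schedule.lam * (t - schedule.t_off))
    return amp * tki_gradient(x, potential)


def diffusion_value(schedule: TreatmentSchedule, t):
    """Diffusion coefficient R(t): piecewise-constant plateaus.

    TOTO switches pre -> on at ``t_on``; TKI switches pre -> on at
    ``t_on`` and on -> post at ``t_off``.  "none" stays at ``beta_pre``.
    """
    if schedule.kind == "none" or t < schedule.t_on:
        return schedule.beta_pre
    if schedule.kind == "TOTO":
        return schedule.beta_on
    if t <= schedule.t_off:
        return schedule.beta_on
    return schedule.beta_post


def circuit_treatment(params, kind: str, s_fraction: float = 0.4,
                      gamma: float | None = None):
    """Transform circuit parameters into their treated counterpart.

    TOTO sets the signal to zero and applies the treatment response
    modifier gamma = 1.1 to the regulated transcriptome production rates;
    TKI reduces the signal to ``s_fraction * s_max`` and applies
    gamma = 1.4.  The returned parameter set can be analyzed with
    :func:`cmlstate.potentials.find_critical_points`.
    """
    if kind == "TOTO":
        g = 1.1 if gamma is None else gamma
        return params.with_(s=0.0, gamma_circuit=g)
    if kind == "TKI":
        g = 1.4 if gamma is None else gamma
        return params.with_(s=s_fraction * params.s_max, gamma_circuit=g)
    raise ValueError(f"unknown treatment kind {kind!r}")
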