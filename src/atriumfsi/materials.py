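"""Fibre-reinforced hyperelastic atrial wall material with active tension.

Passive response is an invariant-based, transversely isotropic exponential
model with a logarithmic volumetric penalty,

    W = a/(2b) {exp[b(I1-3)] - 1} + a1/(2 b1) {exp[b1 (I4-1)^2] - 1}
        + beta/4 log^2(I3),

where I1 = tr(C), I3 = det(C), I4 = e.(C e), C = F^T F.  Fibres support
extension only: the fibre term is switched off whenever I4 < 1.  The first
Piola-Kirchhoff stress carries an extra (non-variational) term
-a exp[b(I1-3)] F^{-T} so that the stress vanishes identically at F = I:

    P = a e^{b(I1-3)} F - a e^{b(I1-3)} F^{-T}
        + 2 a1 (I4-1) e^{b1 (I4-1)^2} F e x e + beta log(I3) F^{-T}.

Active contraction adds P_act = J T F (e x e) with
T = T_active(t) [1 + gamma (lambda - 1)], lambda = sqrt(I4), driven by a
smooth non-negative periodic activation profile T_active(t) that peaks in
late diastole.

Moduli are given in kPa at the interface and converted to CGS internally.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .units import kpa
from .fe import DeformationState

__all__ = [
    "PassiveParams",
    "ActiveParams",
    "ActivationProfile",
    "passive_energy",
    "passive_stress",
    "active_stress",
    "activation_profile",
]


@dataclass(frozen=True)
class PassiveParams:
    """Passive material constants (a, a1, beta in kPa; b, b1 dimensionless)."""

    a: float = 8.0
    b: float = 5.57
    a1: float = 6.0
    b1: float = 4.06
    beta: float = 500.0

    def __post_init__(self):
        for name in ("a", "b", "a1", "b1", "beta"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @property
    def a_cgs(self):
        return kpa(self.a)

    @property
    def a1_cgs(self):
        return kpa(self.a1)

    @property
    def beta_cgs(self):
        return kpa(self.beta)


@dataclass(frozen=True)
class ActivationProfile:
    """Smooth single-bump periodic activation (squared-sine window).

    T_active(t) = peak * sin^2(pi (t - onset)/duration) inside the window,
    0 outside; periodic with the cycle length.  Defaults place the bump in
    late diastole of a 0.8 s cycle whose origin is the start of ventricular
    systole (systole [0, 0.30), early/mid/late diastole thereafter).
    """

    peak: float = 56.2          # kPa
    onset: float = 0.64         # s, within the cycle
    duration: float = 0.16      # s
    cycle: float = 0.8          # s

    def __call__(self, t):
        t = np.asarray(t, dtype=float)
        tau = np.mod(t - self.onset, self.cycle)
        inside = tau < self.duration
        val = np.where(inside, np.sin(np.pi * tau / self.duration) ** 2, 0.0)
        out = self.peak * val
        return out if out.ndim else float(out)

    @property
    def peak_time(self):
        return (self.onset + 0.5 * self.duration) % self.cycle


@dataclass(frozen=True)
class ActiveParams:
    """Active-tension parameters: stretch sensitivity gamma and T_active(t)."""

    gamma: float = 4.9
    profile: ActivationProfile = field(default_factory=ActivationProfile)

    def __post_init__(self):
        if self.profile.peak < 0:
            raise ValueError("activation peak must be non-negative")


def activation_profile(t, active_params: ActiveParams):
    """T_active at time t (kPa)."""
    return active_params.profile(t)


# ------------------------------------------------------------------ passive


def _check_state(state: DeformationState):
    if state.I4 is None:
        raise ValueError("mesh has no fibre directions; I4 undefined")
    if not (np.all(np.isfinite(state.I1)) and np.all(np.isfinite(state.I4))):
        raise ValueError("non-finite invariants")
    if np.any(state.J <= 0):
        raise ValueError("J <= 0: degenerate deformation state")


def passive_energy(state: DeformationState, params: PassiveParams) -> np.ndarray:
    """Strain-energy density W per quadrature point (dyn/cm^2)."""
    _check_state(state)
    a, b = params.a_cgs, params.b
    a1, b1 = params.a1_cgs, params.b1
    beta = params.beta_cgs
    I1, I3, I4 = state.I1, state.I3, state.I4
    W = a / (2 * b) * (np.exp(b * (I1 - 3.0)) - 1.0)
    ext = I4 > 1.0  # tension-only fibre contribution
    Wf = a1 / (2 * b1) * (np.exp(b1 * (I4 - 1.0) ** 2) - 1.0)
    W = W + np.where(ext, Wf, 0.0)
    W = W + beta / 4.0 * np.log(I3) ** 2
    return W


def passive_stress(state: DeformationState, params: PassiveParams,
                   fibre: np.ndarray | None = None) -> np.ndarray:
    """Modified first Piola-Kirchhoff stress per quadrature point.

    `fibre` overrides the mesh fibre field (E, d); normally taken from the
    mesh that produced `state` via :func:`stress_for_mesh` callers.
    """
    _check_state(state)
    a, b = params.a_cgs, params.b
    a1, b1 = params.a1_cgs, params.b1
    beta = params.beta_cgs
    F, I1, I3, I4 = state.F, state.I1, state.I3, state.I4
    Finv = np.linalg.inv(F)
    FinvT = np.swapaxes(Finv, -1, -2)
    expb = np.exp(b * (I1 - 3.0))[..., None, None]
    P = a * expb * F - a * expb * FinvT
    P = P + (beta * np.log(I3))[..., None, None] * FinvT
    if fibre is None:
        raise ValueError("fibre directions required for the fibre stress term")
    ext = I4 > 1.0
    coef = np.where(ext, 2 * a1 * (I4 - 1.0) * np.exp(b1 * (I4 - 1.0) ** 2), 0.0)
    Fe = np.einsum("eqdg,eg->eqd", F, fibre)
    # (F e) x e  ->  outer product mapping reference fibre direction
    P = P + coef[..., None, None] * np.einsum("eqd,eg->eqdg", Fe, fibre)
    return P


# ------------------------------------------------------------------- active


def active_stress(state: DeformationState, active_params: ActiveParams, t,
                  fibre: np.ndarray) -> np.ndarray:
    """Additive active first PK stress  P = J T F (e x e).

    T = T_active(t) [1 + gamma (lambda - 1)] with lambda = sqrt(I4).
    Zero tensor whenever T_active(t) = 0 (e.g. the AF scenario).
    """
    if state.I4 is None and fibre is None:
        raise ValueError("fibre directions required")
    Ta = kpa(activation_profile(t, active_params))
    if Ta == 0.0:
        return np.zeros_like(state.F)
    lam = np.sqrt(state.I4)
    if not np.all(np.isfinite(lam)):
        raise ValueError("non-finite fibre stretch")
    T = Ta * (1.0 + active_params.gamma * (lam - 1.0))
    Fe = np.einsum("eqdg,eg->eqd", state.F, fibre)
    return (state.J * T)[..., None, None] * np.einsum(
        "eqd,eg->eqdg", Fe, fibre
    )
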