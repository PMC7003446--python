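"""Constitutive model: passive energy/stress, active tension, activation."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from atriumfsi.fe import DeformationState
from atriumfsi.materials import (
    PassiveParams, ActiveParams, ActivationProfile,
    passive_energy, passive_stress, active_stress, activation_profile,
)
from atriumfsi.units import kpa


def make_state(F, fibre):
    """DeformationState from an explicit stack of deformation gradients."""
    F = np.asarray(F, float)
    if F.ndim == 2:
        F = F[None, None]
    J = np.linalg.det(F)
    d = F.shape[-1]
    I1 = np.einsum("eqij,eqij->eq", F, F) + (3 - d)
    Fe = np.einsum("eqij,ej->eqi", F, fibre)
    I4 = np.einsum("eqi,eqi->eq", Fe, Fe)
    return DeformationState(chi=None, F=F, J=J, I1=I1, I3=J**2, I4=I4,
                            degenerate=np.any(J <= 0, axis=1))


def scalar_energy(F, e, p: PassiveParams):
    """Independent scalar evaluation of the strain-energy density."""
    C = F.T @ F
    d = F.shape[0]
    I1 = np.trace(C) + (3 - d)
    I3 = np.linalg.det(C)
    I4 = e @ C @ e
    W = p.a_cgs / (2 * p.b) * (np.exp(p.b * (I1 - 3)) - 1)
    if I4 > 1.0:
        W += p.a1_cgs / (2 * p.b1) * (np.exp(p.b1 * (I4 - 1) ** 2) - 1)
    W += p.beta_cgs / 4 * np.log(I3) ** 2
    return W


def random_states(n, d=3, seed=0, spread=0.08):
    """Random deformation gradients with J in about [0.9, 1.1]."""
    rng = np.random.default_rng(seed)
    Fs, es = [], []
    while len(Fs) < n:
        F = np.eye(d) + spread * rng.normal(size=(d, d))
        J = np.linalg.det(F)
        if 0.9 <= J <= 1.1:
            e = rng.normal(size=d)
            es.append(e / np.linalg.norm(e))
            Fs.append(F)
    return np.array(Fs)[:, None], np.array(es)


def test_energy_zero_at_identity():
    e = np.array([[1.0, 0.0, 0.0]])
    state = make_state(np.eye(3), e)
    assert passive_energy(state, PassiveParams()) == pytest.approx(0.0, abs=1e-14)


def test_compressed_fibre_contributes_no_energy():
    # I4 < 1 (fibre shortened): fibre term must vanish exactly
    e = np.array([[1.0, 0.0, 0.0]])
    lam = 0.9
    F = np.diag([lam, 1 / np.sqrt(lam), 1 / np.sqrt(lam)])  # J = 1
    p = PassiveParams()
    W = passive_energy(make_state(F, e), p)
    p_nofib = PassiveParams(a=p.a, b=p.b, a1=1e-12, b1=p.b1, beta=p.beta)
    W_nofib = passive_energy(make_state(F, e), p_nofib)
    assert W == pytest.approx(W_nofib, rel=1e-12)


def test_uniaxial_fibre_stretch_matches_independent_evaluation():
    e = np.array([[1.0, 0.0, 0.0]])
    lam = 1.1
    F = np.diag([lam, 1 / np.sqrt(lam), 1 / np.sqrt(lam)])  # isochoric
    p = PassiveParams()
    W = passive_energy(make_state(F, e), p)
    assert W == pytest.approx(scalar_energy(F, e[0], p), rel=1e-12)


def test_stress_zero_at_identity():
    e = np.array([[0.6, 0.8, 0.0]])
    P = passive_stress(make_state(np.eye(3), e), PassiveParams(), fibre=e)
    assert np.abs(P).max() < 1e-12


def test_compressed_fibre_term_omitted_from_stress():
    e = np.array([[1.0, 0.0, 0.0]])
    lam = 0.95
    F = np.diag([lam, 1 / np.sqrt(lam), 1 / np.sqrt(lam)])
    p = PassiveParams()
    P = passive_stress(make_state(F, e), p, fibre=e)
    p_nofib = PassiveParams(a=p.a, b=p.b, a1=1e-12, b1=p.b1, beta=p.beta)
    P2 = passive_stress(make_state(F, e), p_nofib, fibre=e)
    assert np.allclose(P, P2, rtol=1e-12)


def test_stress_equals_energy_gradient_plus_modification():
    """FD oracle over >= 100 random states with J in [0.9, 1.1]."""
    p = PassiveParams(a=8.0, b=5.57, a1=6.0, b1=4.06, beta=500.0)
    Fs, es = random_states(120, seed=42)
    state = make_state(Fs, es)
    P = passive_stress(state, p, fibre=es)
    FinvT = np.swapaxes(np.linalg.inv(Fs), -1, -2)
    P_mod = -p.a_cgs * np.exp(p.b * (state.I1 - 3))[..., None, None] * FinvT
    eps = 1e-7
    for k in range(len(Fs)):
        F = Fs[k, 0]
        e = es[k]
        P_fd = np.zeros((3, 3))
        for i in range(3):
            for j in range(3):
                Fp = F.copy()
                Fp[i, j] += eps
                Fm = F.copy()
                Fm[i, j] -= eps
                P_fd[i, j] = (scalar_energy(Fp, e, p)
                              - scalar_energy(Fm, e, p)) / (2 * eps)
        expect = P_fd + P_mod[k, 0]
        scale = max(np.abs(expect).max(), 1.0)
        assert np.allclose(P[k, 0], expect, atol=2e-6 * scale), k


@pytest.mark.parametrize("seed", [1, 2, 3])
def test_objectivity_under_rotation(seed):
    """P(R F) = R P(F) for the passive and active parts."""
    from scipy.spatial.transform import Rotation
    rng = np.random.default_rng(seed)
    R = Rotation.random(random_state=seed).as_matrix()
    F = np.eye(3) + 0.08 * rng.normal(size=(3, 3))
    if np.linalg.det(F) <= 0:
        F = np.eye(3) + 0.02 * rng.normal(size=(3, 3))
    e = rng.normal(size=3)
    e = (e / np.linalg.norm(e))[None, :]
    p = PassiveParams()
    P1 = passive_stress(make_state(R @ F, e), p, fibre=e)[0, 0]
    P2 = R @ passive_stress(make_state(F, e), p, fibre=e)[0, 0]
    assert np.allclose(P1, P2, atol=1e-8 * max(np.abs(P2).max(), 1))
    act = ActiveParams(profile=ActivationProfile(peak=50.0))
    t = act.profile.peak_time
    A1 = active_stress(make_state(R @ F, e), act, t, fibre=e)[0, 0]
    A2 = R @ active_stress(make_state(F, e), act, t, fibre=e)[0, 0]
    assert np.allclose(A1, A2, atol=1e-8 * max(np.abs(A2).max(), 1))


def test_fibre_stress_monotone_in_stretch():
    e = np.array([[1.0, 0.0, 0.0]])
    p = PassiveParams()
    prev = -np.inf
    for lam in np.linspace(1.0, 1.3, 16):
        F = np.diag([lam, 1 / np.sqrt(lam), 1 / np.sqrt(lam)])
        P = passive_stress(make_state(F, e), p, fibre=e)[0, 0]
        s11 = P[0, 0]
        assert s11 >= prev - 1e-9
        prev = s11


# ------------------------------------------------------------------ active


def test_active_zero_when_unactivated():
    e = np.array([[1.0, 0.0, 0.0]])
    act = ActiveParams(profile=ActivationProfile(peak=56.2, onset=0.64,
                                                 duration=0.16))
    F = np.diag([1.2, 1.0, 1.0 / 1.2])
    A = active_stress(make_state(F, e), act, t=0.2, fibre=e)  # systole
    assert np.abs(A).max() == 0.0
    af = ActiveParams(profile=ActivationProfile(peak=0.0))
    A = active_stress(make_state(F, e), af, t=af.profile.peak_time, fibre=e)
    assert np.abs(A).max() == 0.0


def test_active_tension_scaling_with_stretch():
    e = np.array([[1.0, 0.0, 0.0]])
    act = ActiveParams(gamma=4.9, profile=ActivationProfile(peak=56.2))
    t = act.profile.peak_time
    Ta = kpa(activation_profile(t, act))
    # lambda = 1: P = J T_active F e x e -> component (0,0) = T_active
    A = active_stress(make_state(np.eye(3), e), act, t, fibre=e)[0, 0]
    assert A[0, 0] == pytest.approx(Ta, rel=1e-12)
    assert np.abs(A - np.diag([Ta, 0, 0])).max() < 1e-9 * Ta
    # lambda = 1.1 at J = 1: T = 1.49 T_active
    lam = 1.1
    F = np.diag([lam, 1 / np.sqrt(lam), 1 / np.sqrt(lam)])
    A = active_stress(make_state(F, e), act, t, fibre=e)[0, 0]
    assert A[0, 0] == pytest.approx(1.49 * Ta * lam, rel=1e-9)


def test_activation_profile_shape():
    prof = ActivationProfile(peak=56.2, onset=0.64, duration=0.16, cycle=0.8)
    assert prof(prof.peak_time) == pytest.approx(56.2, rel=1e-12)
    ts = np.linspace(0, 0.8, 801)
    vals = prof(ts)
    assert (vals >= 0).all()
    # zero through systole (first 0.3 s of the cycle)
    assert np.abs(vals[ts <= 0.3]).max() == 0.0
    assert np.trapezoid(vals, ts) > 0
    # periodic wrap
    assert prof(0.7) == pytest.approx(prof(0.7 + 0.8), rel=1e-12)


@settings(max_examples=25, deadline=None)
@given(lam=st.floats(0.95, 1.25), peak=st.floats(0.0, 100.0))
def test_active_tension_formula_property(lam, peak):
    e = np.array([[1.0, 0.0, 0.0]])
    act = ActiveParams(gamma=4.9, profile=ActivationProfile(peak=peak))
    t = act.profile.peak_time
    F = np.diag([lam, 1.0, 1.0])
    A = active_stress(make_state(F, e), act, t, fibre=e)
    Ta = kpa(peak)
    expect = np.linalg.det(F) * Ta * (1 + 4.9 * (lam - 1)) * lam
    if peak == 0.0:
        assert np.abs(A).max() == 0.0
    else:
        assert A[0, 0, 0, 0] == pytest.approx(expect, rel=1e-9)


def test_invalid_parameters_rejected():
    with pytest.raises(ValueError):
        PassiveParams(a=-1.0)
    with pytest.raises(ValueError):
        ActiveParams(profile=ActivationProfile(peak=-5.0))
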