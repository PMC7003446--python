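"""Regularized-delta transfer identities and the coupled FSI loop."""

import numpy as np
import pytest

from atriumfsi.grid import StaggeredGrid, BoundarySpec, FluidProperties
from atriumfsi.kernels import KernelSpec
from atriumfsi.coupling import (spread, interpolate, Transfer, FSISystem,
                                PointOutsideDomainError)
from atriumfsi.geometry import build_ring_2d
from atriumfsi.materials import PassiveParams
from atriumfsi.metrics import polygon_area, kinetic_energy, dissipation_rate

FAMILIES = ["ib4", "ib3", "bspline6"]


@pytest.mark.parametrize("family", FAMILIES)
def test_partition_of_unity_and_first_moment(family):
    k = KernelSpec(family)
    rng = np.random.default_rng(0)
    s = rng.uniform(10, 20, 500)
    base, w = k.weights_1d(s)
    assert np.abs(w.sum(axis=1) - 1.0).max() < 1e-13
    offs = np.arange(k.support_cells)
    moment = ((base[:, None] + offs[None, :] - s[:, None]) * w).sum(axis=1)
    assert np.abs(moment).max() < 1e-12


@pytest.mark.parametrize("family", FAMILIES)
def test_linear_field_interpolated_exactly(family):
    g = StaggeredGrid.make((4.0, 4.0), (32, 32))
    xu, yu = np.meshgrid(*g.face_coords(0), indexing="ij")
    xv, yv = np.meshgrid(*g.face_coords(1), indexing="ij")
    g.u[0] = 0.5 + xu - 2 * yu
    g.u[1] = 2 * yv - 0.5 * xv
    rng = np.random.default_rng(1)
    pts = rng.uniform(1.0, 3.0, (400, 2))
    U = interpolate(g, pts, family)
    assert np.abs(U[:, 0] - (0.5 + pts[:, 0] - 2 * pts[:, 1])).max() < 1e-12
    assert np.abs(U[:, 1] - (2 * pts[:, 1] - 0.5 * pts[:, 0])).max() < 1e-12


def test_uniform_field_everywhere():
    g = StaggeredGrid.make((4.0, 4.0), (16, 16))
    g.u[0][:] = 1.0
    pts = np.array([[2.0, 2.0], [1.3, 2.7]])
    U = interpolate(g, pts)
    assert np.allclose(U, [[1.0, 0.0], [1.0, 0.0]], atol=1e-14)


def test_spread_conserves_force_to_round_off():
    g = StaggeredGrid.make((4.0, 4.0), (32, 32))
    rng = np.random.default_rng(2)
    pts = rng.uniform(1.0, 3.0, (1000, 2))
    F = rng.normal(size=(1000, 2))
    f = spread(F, pts, g)
    for c in range(2):
        total = f[c].sum() * g.h**2
        assert abs(total - F[:, c].sum()) <= 1e-12 * abs(F[:, c]).sum()


def test_single_point_force_sums_to_one():
    g = StaggeredGrid.make((4.0, 4.0), (32, 32))
    f = spread(np.array([[1.0, 0.0]]), np.array([[1.77, 2.13]]), g)
    assert f[0].sum() * g.h**2 == pytest.approx(1.0, abs=1e-14)
    assert abs(f[1]).max() == 0.0


def test_spread_interpolate_adjointness_power_identity():
    g = StaggeredGrid.make((4.0, 4.0), (32, 32))
    rng = np.random.default_rng(3)
    g.u[0] = rng.normal(size=g.face_shape(0))
    g.u[1] = rng.normal(size=g.face_shape(1))
    pts = rng.uniform(0.8, 3.2, (600, 2))
    F = rng.normal(size=(600, 2))
    f = spread(F, pts, g)
    U = interpolate(g, pts)
    lhs = sum(float((fc * uc).sum()) for fc, uc in zip(f, g.u)) * g.h**2
    rhs = float((F * U).sum())
    assert abs(lhs - rhs) <= 1e-12 * abs(rhs)


def test_transfer_identities_in_3d():
    g = StaggeredGrid(origin=np.zeros(3), n=np.array([12, 12, 12]), h=0.25)
    rng = np.random.default_rng(4)
    pts = rng.uniform(0.8, 2.2, (200, 3))
    F = rng.normal(size=(200, 3))
    f = spread(F, pts, g)
    for c in range(3):
        assert abs(f[c].sum() * g.h**3 - F[:, c].sum()) \
            <= 1e-11 * abs(F[:, c]).sum()
    for c in range(3):
        coords = np.meshgrid(*g.face_coords(c), indexing="ij")
        g.u[c] = 1.0 + 2.0 * coords[0] - coords[2]
    U = interpolate(g, pts)
    for c in range(3):
        exact = 1.0 + 2.0 * pts[:, 0] - pts[:, 2]
        assert np.abs(U[:, c] - exact).max() < 1e-11


def test_point_outside_box_is_hard_error():
    g = StaggeredGrid.make((4.0, 4.0), (16, 16))
    with pytest.raises(PointOutsideDomainError):
        interpolate(g, np.array([[5.0, 1.0]]))


# ----------------------------------------------------------- coupled tests


def _ring_system(n, stretch=1.05, dt=4e-4):
    g = StaggeredGrid.make((4.0, 4.0), (n, n))
    seg = max(int(2 * np.pi / (0.4 * g.h)), 32)
    mesh = build_ring_2d(radius=1.0 / stretch, thickness=0.12, n_seg=seg,
                         centre=(2, 2))
    c = np.array([2.0, 2.0])
    chi = c + (mesh.nodes - c) * stretch
    sys_ = FSISystem(
        grid=g, props=FluidProperties(), bc=BoundarySpec(2), mesh=mesh,
        passive={"ring": PassiveParams(a=2.0, b=5.57, a1=2.0, b1=4.06,
                                       beta=50.0)},
        chi=chi,
    )
    return sys_, mesh, dt


def test_rest_state_stays_at_rest():
    g = StaggeredGrid.make((4.0, 4.0), (24, 24))
    mesh = build_ring_2d(radius=1.0, thickness=0.12, n_seg=64, centre=(2, 2))
    sys_ = FSISystem(
        grid=g, props=FluidProperties(), bc=BoundarySpec(2), mesh=mesh,
        passive={"ring": PassiveParams()},
    )
    for _ in range(20):
        sys_.step(5e-4)
    assert g.max_speed() < 1e-9
    assert np.abs(sys_.chi - mesh.nodes).max() < 1e-9


@pytest.mark.parametrize("scheme", ["midpoint", "euler"])
def test_pressurised_ring_conserves_area(scheme):
    """Stretched immersed ring: enclosed area drift < 1% over the run."""
    sys_, mesh, dt = _ring_system(32)
    loop = mesh.meta["mid_loop"]
    a0 = polygon_area(sys_.chi[loop])
    while sys_.time < 0.12:
        sys_.step(dt, scheme=scheme)
    a1 = polygon_area(sys_.chi[loop])
    assert abs(a1 - a0) / a0 < 0.01


def test_ring_equilibrium_error_decreases_under_refinement():
    errs = []
    for n, dt in ((16, 4e-4), (32, 4e-4)):
        sys_, mesh, _ = _ring_system(n, dt=dt)
        loop = mesh.meta["mid_loop"]
        a0 = polygon_area(sys_.chi[loop])
        while sys_.time < 0.15:
            sys_.step(dt)
        a1 = polygon_area(sys_.chi[loop])
        r = np.linalg.norm(sys_.chi[loop] - np.array([2.0, 2.0]), axis=1)
        errs.append((abs(a1 - a0) / a0, abs(r.mean() - 1.0)))
    assert errs[1][0] < errs[0][0]   # area conservation improves
    assert errs[1][1] < errs[0][1]   # equilibrium-radius error improves


def test_energy_bookkeeping_with_spread_forces():
    """dKE/dt + D balances the spread-force power on a resolved flow."""
    n = 32
    L = np.pi
    g = StaggeredGrid.make((L, L), (n, n))
    bc = BoundarySpec(2)
    props = FluidProperties(mu=0.05)
    # dense Lagrangian cloud carrying a smooth solenoidal force that
    # vanishes at the walls
    ds = 0.5 * g.h
    xs = np.arange(ds / 2, L, ds)
    X, Y = np.meshgrid(xs, xs, indexing="ij")
    pts = np.column_stack([X.ravel(), Y.ravel()])
    A = 40.0
    Fx = A * np.sin(pts[:, 0]) ** 2 * np.sin(2 * pts[:, 1]) * ds**2
    Fy = -A * np.sin(2 * pts[:, 0]) * np.sin(pts[:, 1]) ** 2 * ds**2
    F = np.column_stack([Fx, Fy])
    tr = Transfer(g, pts)
    from atriumfsi.projection import momentum_step_and_project
    mask = np.ones((n, n), bool)
    dt = 2e-3
    solver = None
    ke0 = kinetic_energy(g, mask, props.rho)
    P_int = D_int = P_abs = 0.0
    for k in range(300):
        amp = np.sin(2 * np.pi * k * dt / 0.5)
        f = tr.spread(F * amp)
        solver = momentum_step_and_project(g, props, bc, f=f, dt=dt,
                                           t=k * dt, limited=False,
                                           solver=solver)
        power = float((F * amp * tr.interpolate()).sum())
        P_int += power * dt
        P_abs += abs(power) * dt
        D_int += dissipation_rate(g, mask, props.mu) * dt
    ke1 = kinetic_energy(g, mask, props.rho)
    residual = (ke1 - ke0) + D_int - P_int
    assert abs(residual) / P_abs < 0.05


def test_instability_detector_aborts():
    """An unstable configuration aborts with a diagnostic, never NaN-loops."""
    from atriumfsi.coupling import InstabilityError
    from atriumfsi.advection import CFLError
    sys_, mesh, _ = _ring_system(16, stretch=1.4)  # violently stretched
    with pytest.raises((InstabilityError, FloatingPointError, CFLError,
                        PointOutsideDomainError, ValueError)):
        for _ in range(2000):
            sys_.step(5e-3)  # far beyond the stable step
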