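"""Haemodynamic metric operators against closed forms and brute force."""

import numpy as np
import pytest
import trimesh

from atriumfsi.grid import StaggeredGrid
from atriumfsi.fe import kinematics
from atriumfsi.metrics import (
    kinetic_energy, dissipation_rate, cell_center_velocity,
    enclosed_volume, polygon_area, planar_ring_area,
    volume_accounting, stroke_from_components,
    principal_strain, fibre_strain, segment_patch, orifice_trace,
    pathlines, residence_time, stagnation_fraction, chamber_mask,
)

from conftest import quad_block


# --------------------------------------------------------------- energetics


def _grid(n=16, L=2.0):
    return StaggeredGrid.make((L, L), (n, n))


def test_kinetic_energy_zero_and_uniform():
    g = _grid()
    mask = np.ones(tuple(g.n), bool)
    assert kinetic_energy(g, mask, rho=1.0) == 0.0
    g.u[0][:] = 3.0
    V = g.extents.prod()
    assert kinetic_energy(g, mask, rho=2.0) == pytest.approx(
        0.5 * 2.0 * 9.0 * V, rel=1e-12)


def test_kinetic_energy_matches_direct_sum_on_random_field():
    rng = np.random.default_rng(0)
    g = _grid()
    g.u[0] = rng.normal(size=g.face_shape(0))
    g.u[1] = rng.normal(size=g.face_shape(1))
    mask = rng.random(tuple(g.n)) > 0.4
    uc = cell_center_velocity(g)
    expect = 0.0
    for i in range(g.n[0]):
        for j in range(g.n[1]):
            if mask[i, j]:
                expect += 0.5 * (uc[i, j, 0] ** 2 + uc[i, j, 1] ** 2) * g.h**2
    got = kinetic_energy(g, mask, rho=1.0)
    assert got == pytest.approx(expect, rel=1e-12)


def test_dissipation_closed_forms():
    g = _grid()
    mask = np.ones(tuple(g.n), bool)
    g.u[0][:] = 5.0
    assert dissipation_rate(g, mask, mu=0.04) == pytest.approx(0.0, abs=1e-12)
    # simple shear u = (gdot*y, 0): D = mu gdot^2 V
    gdot = 1.7
    yu = np.meshgrid(*g.face_coords(0), indexing="ij")[1]
    g.u[0] = gdot * yu
    g.u[1][:] = 0.0
    V = g.extents.prod()
    assert dissipation_rate(g, mask, mu=0.3) == pytest.approx(
        0.3 * gdot**2 * V, rel=1e-10)


def test_dissipation_nonnegative_for_random_fields():
    rng = np.random.default_rng(1)
    g = _grid()
    mask = np.ones(tuple(g.n), bool)
    for _ in range(5):
        g.u[0] = rng.normal(size=g.face_shape(0))
        g.u[1] = rng.normal(size=g.face_shape(1))
        assert dissipation_rate(g, mask, mu=0.1) >= 0.0


def test_empty_mask_rejected():
    g = _grid()
    with pytest.raises(ValueError):
        kinetic_energy(g, np.zeros(tuple(g.n), bool))


# ------------------------------------------------------------------ volumes


def test_enclosed_volume_of_unit_sphere():
    ico = trimesh.creation.icosphere(subdivisions=3)
    v = enclosed_volume(ico.vertices, ico.faces)
    # inscribed polyhedron: ~0.9% deficit at this refinement
    assert v == pytest.approx(4 * np.pi / 3, rel=1.5e-2)
    assert v == pytest.approx(ico.volume, rel=1e-12)  # trimesh cross-check
    # translation invariance
    v2 = enclosed_volume(ico.vertices + [10.0, -4.0, 2.5], ico.faces)
    assert v2 == pytest.approx(v, rel=1e-12)


def test_enclosed_volume_agrees_with_voxel_oracle():
    ico = trimesh.creation.icosphere(subdivisions=3)
    verts = ico.vertices * 1.3
    v = enclosed_volume(verts, ico.faces)
    h = 2.8 / 96
    xs = np.arange(-1.4 + h / 2, 1.4, h)
    X, Y, Z = np.meshgrid(xs, xs, xs, indexing="ij")
    # voxel counting against the analytic sphere the mesh approximates
    inside = X**2 + Y**2 + Z**2 < 1.3**2
    v_vox = inside.sum() * h**3
    assert abs(v - v_vox) / v_vox < 0.01


def test_open_surface_rejected():
    ico = trimesh.creation.icosphere(subdivisions=2)
    with pytest.raises(ValueError):
        enclosed_volume(ico.vertices, ico.faces[:-3])


def test_polygon_and_ring_area():
    th = np.linspace(0, 2 * np.pi, 200, endpoint=False)
    poly = np.column_stack([2 * np.cos(th), 3 * np.sin(th)])
    assert polygon_area(poly) == pytest.approx(6 * np.pi, rel=1e-3)
    ring = np.column_stack([np.cos(th), np.sin(th), 0 * th + 5.0])
    assert planar_ring_area(ring) == pytest.approx(np.pi, rel=1e-3)


# -------------------------------------------------------- volume accounting


@pytest.mark.parametrize("conduit, emptying, regurgitant, stroke", [
    (46.5, 58.0, 6.0, 98.5),
    (64.1, 28.1, 7.1, 85.1),
    (47.9, 81.7, 38.1, 91.5),
])
def test_stroke_volume_identity(conduit, emptying, regurgitant, stroke):
    """Signed sum of conduit + emptying - regurgitant components."""
    assert stroke_from_components(conduit, emptying, regurgitant) == \
        pytest.approx(stroke, abs=1e-12)


def test_volume_accounting_zero_flux():
    t = np.linspace(0, 0.8, 161)
    out = volume_accounting(t, np.full_like(t, 50.0), np.zeros_like(t),
                            sys_start=0.0, sys_end=0.3, cycle=0.8)
    for key in ("stroke", "conduit", "emptying", "regurgitant"):
        assert out[key] == pytest.approx(0.0, abs=1e-12)


def test_volume_accounting_identity_on_synthetic_traces():
    """stroke = conduit + emptying - regurgitant holds by construction."""
    t = np.linspace(0, 0.8, 801)
    vol = 60 + 8 * np.sin(2 * np.pi * t / 0.8)
    q = 120 * np.maximum(np.sin(2 * np.pi * (t - 0.3) / 0.8), 0) \
        - 30 * np.exp(-((t - 0.1) / 0.05) ** 2)
    out = volume_accounting(t, vol, q, sys_start=0.0, sys_end=0.3, cycle=0.8)
    assert out["stroke"] == pytest.approx(
        out["conduit"] + out["emptying"] - out["regurgitant"], rel=1e-12)
    assert out["regurgitant"] > 0
    with pytest.raises(ValueError):
        volume_accounting(t[:100], vol[:100], q[:100], 0.0, 0.3, 0.8)


# ------------------------------------------------------------------ strains


def test_principal_strain_identity_and_uniaxial():
    mesh = quad_block(2, 2)
    st = kinematics(mesh, mesh.nodes)
    eps1, mean = principal_strain(st, mesh)
    assert np.allclose(eps1, 0.0, atol=1e-13) and mean == pytest.approx(0.0, abs=1e-13)
    lam = 1.15
    st = kinematics(mesh, mesh.nodes @ np.diag([lam, 1.0]))
    eps1, mean = principal_strain(st, mesh)
    assert np.allclose(eps1, 0.5 * (lam**2 - 1), rtol=1e-12)


def test_principal_strain_matches_closed_form_eigenvalue():
    # 2x2 closed-form oracle: lam_max = tr/2 + sqrt((tr/2)^2 - det)
    mesh = quad_block(2, 2)
    rng = np.random.default_rng(4)
    A = np.eye(2) + 0.2 * rng.normal(size=(2, 2))
    st = kinematics(mesh, mesh.nodes @ A.T)
    eps1, _ = principal_strain(st, mesh)
    E = 0.5 * (A.T @ A - np.eye(2))
    tr2 = np.trace(E) / 2
    lam_max = tr2 + np.sqrt(tr2**2 - np.linalg.det(E))
    assert np.allclose(eps1, lam_max, rtol=1e-12)


def test_fibre_strain_values_and_rotation_invariance():
    mesh = quad_block(2, 2, fibre=(1.0, 0.0))
    st = kinematics(mesh, mesh.nodes)
    fs, mean = fibre_strain(st, mesh)
    assert np.allclose(fs, 0.0, atol=1e-13)
    lam = 1.2
    st = kinematics(mesh, mesh.nodes @ np.diag([lam, 1.0]))
    fs, mean = fibre_strain(st, mesh)
    assert np.allclose(fs, lam - 1, rtol=1e-12)
    th = 0.7
    R = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
    st = kinematics(mesh, mesh.nodes @ (R @ np.diag([lam, 1.0])).T)
    fs, _ = fibre_strain(st, mesh)
    assert np.allclose(fs, lam - 1, rtol=1e-12)


# ------------------------------------------------------------ patch traces


def test_orifice_trace_uniform_flow():
    g = _grid(n=32, L=4.0)
    g.u[1][:] = -2.0  # downward
    pts, w, nrm = segment_patch((1.0, 2.0), (3.0, 2.0), 16)
    if nrm[1] > 0:
        nrm = -nrm
    mean, flux = orifice_trace(g, pts, w, nrm)
    assert mean == pytest.approx(2.0, rel=1e-12)
    assert flux == pytest.approx(2.0 * 2.0, rel=1e-12)  # U * length
    # tangential flow contributes nothing
    g.u[1][:] = 0.0
    g.u[0][:] = 5.0
    mean, flux = orifice_trace(g, pts, w, nrm)
    assert abs(flux) < 1e-12


def test_orifice_flux_additive_over_partitions():
    rng = np.random.default_rng(5)
    g = _grid(n=32, L=4.0)
    g.u[0] = rng.normal(size=g.face_shape(0))
    g.u[1] = rng.normal(size=g.face_shape(1))
    a, b, c = (1.0, 2.0), (2.0, 2.0), (3.0, 2.0)
    full = orifice_trace(g, *segment_patch(a, c, 64))[1]
    left = orifice_trace(g, *segment_patch(a, b, 32))[1]
    right = orifice_trace(g, *segment_patch(b, c, 32))[1]
    assert full == pytest.approx(left + right, rel=1e-9)


# ---------------------------------------------------------------- pathlines


def test_pathlines_uniform_flow_straight():
    U = np.array([3.0, -1.0])

    def sampler(t, pts):
        return np.tile(U, (len(pts), 1))

    seeds = np.array([[0.0, 0.0], [1.0, 1.0]])
    ps = pathlines(sampler, seeds, t0=0.0, t1=0.5, dt=0.01)
    assert np.allclose(ps.positions[:, -1], seeds + 0.5 * U, atol=1e-12)


def test_pathlines_solid_body_rotation_circle():
    om = 2.0

    def sampler(t, pts):
        return np.column_stack([-om * pts[:, 1], om * pts[:, 0]])

    seeds = np.array([[1.0, 0.0]])
    T = np.pi / om  # half revolution
    ps = pathlines(sampler, seeds, t0=0.0, t1=T, dt=T / 400)
    assert np.allclose(ps.positions[0, -1], [-1.0, 0.0], atol=1e-6)
    r = np.linalg.norm(ps.positions[0], axis=1)
    assert np.abs(r - 1.0).max() < 1e-6


def test_pathlines_seed_outside_domain_rejected():
    def sampler(t, pts):
        return np.zeros_like(pts)
    with pytest.raises(ValueError):
        pathlines(sampler, [[5.0, 0.0]], 0.0, 1.0, 0.1,
                  domain=(np.zeros(2), np.ones(2)))


def test_residence_time_definitions():
    def sampler(t, pts):
        return np.tile([1.0, 0.0], (len(pts), 1))

    region = lambda pts: pts[:, 0] < 1.0  # noqa: E731
    # both particles exit after exactly their transit time
    seeds = np.array([[0.0, 0.0], [0.5, 0.0]])
    ps = pathlines(sampler, seeds, 0.0, 2.0, 0.005)
    frt, ok = residence_time(ps, region)
    assert ok
    assert frt == pytest.approx(0.75, abs=0.01)  # mean of 1.0 and 0.5
    # zero flow: no particle exits -> undefined flag
    ps2 = pathlines(lambda t, p: np.zeros_like(p), seeds, 0.0, 1.0, 0.01)
    frt2, ok2 = residence_time(ps2, region)
    assert not ok2 and frt2 is None


def test_stagnation_fraction_constructed_fields():
    speed = np.zeros((10, 10))
    region = np.ones((10, 10), bool)
    assert stagnation_fraction(speed, region, 10.0) == 100.0
    speed[:] = 50.0
    assert stagnation_fraction(speed, region, 10.0) == 0.0
    speed[:5] = 1.0  # half below threshold
    assert stagnation_fraction(speed, region, 10.0) == 50.0
    with pytest.raises(ValueError):
        stagnation_fraction(speed, np.zeros((10, 10), bool))


def test_chamber_mask_matches_polygon():
    g = _grid(n=20, L=2.0)
    th = np.linspace(0, 2 * np.pi, 100, endpoint=False)
    poly = np.column_stack([1.0 + 0.6 * np.cos(th), 1.0 + 0.6 * np.sin(th)])
    mask = chamber_mask(g, poly)
    frac = mask.sum() * g.h**2 / (np.pi * 0.36)
    assert frac == pytest.approx(1.0, abs=0.08)
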