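"""Synthetic idealized left-atrium and valve geometry.

A parametric stand-in for the patient CT anatomy: a superellipsoidal
thin-walled main chamber carrying four cylindrical pulmonary-vein (PV)
stubs, a tapered appendage (LAA) pouch, and a mitral-valve (MV) annulus
opening at the inferior pole.  The generator is calibrated so that the
enclosed main-chamber cavity volume, the appendage cavity volume, the
orifice areas and the mean wall thickness hit the target values of the
idealized anatomy (chamber 107.3 mL, appendage 12.6 mL, appendage orifice
4.6 cm^2, PV orifices 2.5/2.0/1.8/2.5 cm^2, mean wall thickness 1.5 mm);
calibration is deterministic fixed-point iteration on the cap angles, the
global scale and the pouch length.

The wall is extruded outward along the surface normal into two element
layers (>= 2 elements transmurally) of linear tetrahedra.  A 2D
chamber-with-flaps testbed and a plain elastic ring are provided for fast
coupled-dynamics work.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import trimesh

from .fe import StructureMesh
from .metrics import enclosed_volume, planar_ring_area

__all__ = [
    "GeometryParams", "ThicknessField", "TestbedParams", "ValveAssembly",
    "build_idealized_la", "nonuniform_thickness_field", "build_valve",
    "build_2d_testbed", "build_ring_2d", "cavity_volume", "audit_la_mesh",
]


def _unit(v):
    v = np.asarray(v, float)
    return v / np.linalg.norm(v)


# ------------------------------------------------------------------ params


@dataclass(frozen=True)
class GeometryParams:
    """Parameters of the idealized LA generator (lengths cm, areas cm^2).

    Axis convention: +z superior, +x anterior, +y leftward (patient left).
    """

    chamber_semi_axes: tuple = (3.6, 2.9, 2.455)
    superellipse_exponent: float = 2.0
    chamber_volume_ml: float = 107.3
    appendage_volume_ml: float = 12.6
    pv_areas: tuple = (("rspv", 2.5), ("ripv", 2.0), ("lspv", 1.8), ("lipv", 2.5))
    pv_axes: tuple = (
        ("rspv", (-0.40, -0.60, 0.69)),
        ("ripv", (-0.62, -0.60, -0.10)),
        ("lspv", (-0.40, 0.60, 0.69)),
        ("lipv", (-0.62, 0.60, -0.10)),
    )
    pv_length: float = 1.2
    laa_axis: tuple = (0.70, 0.55, 0.45)
    laa_orifice_area: float = 4.6
    laa_bulge: float = 0.35
    annulus_axis: tuple = (0.0, 0.0, -1.0)
    annulus_radius: float = 1.5
    # wall thickness (mm); mode: 'nonuniform' | 'uniform'
    thickness_mode: str = "nonuniform"
    mean_thickness_mm: float = 1.5
    uniform_thickness_mm: float = 1.5
    posterior_amp: float = 0.6
    superior_amp: float = 0.4
    # valve
    leaflet_length_anterior: float = 2.0
    leaflet_length_posterior: float = 1.2
    chordae_depth: float = 2.3
    chordae_radius: float = 0.8
    mvr_offset: float = 2.8
    # discretization
    subdivisions: int = 4
    n_wall_layers: int = 2
    seed: int = 0


# -------------------------------------------------------- surface building


class _Surface:
    """Mutable triangulated surface with per-face component labels."""

    def __init__(self, verts, faces, label):
        self.verts = np.asarray(verts, float)
        self.faces = np.asarray(faces, np.int64)
        self.label = np.asarray([label] * len(self.faces), dtype=object)
        self.rings: dict[str, np.ndarray] = {}


def _superellipsoid_radius(dirs, semi, n):
    """Radial scale t so that t*dirs lies on |x/a|^n+|y/b|^n+|z/c|^n = 1."""
    s = np.sum(np.abs(dirs / np.asarray(semi)) ** n, axis=1)
    return s ** (-1.0 / n)


def _boundary_loop(faces, cand):
    """Ordered boundary-vertex loop restricted to candidate vertices.

    Boundary edges are edges used by exactly one kept face; the directed
    walk follows the face winding.
    """
    cand = set(int(c) for c in cand)
    dir_edges = {}
    und = {}
    for f in faces:
        for a, b in ((f[0], f[1]), (f[1], f[2]), (f[2], f[0])):
            key = (min(a, b), max(a, b))
            und[key] = und.get(key, 0) + 1
    nxt = {}
    for f in faces:
        for a, b in ((f[0], f[1]), (f[1], f[2]), (f[2], f[0])):
            key = (min(a, b), max(a, b))
            if und[key] == 1 and a in cand and b in cand:
                nxt[int(a)] = int(b)
    if not nxt:
        raise ValueError("no boundary loop found at orifice")
    start = next(iter(nxt))
    loop = [start]
    cur = nxt[start]
    while cur != start:
        loop.append(cur)
        cur = nxt.get(cur)
        if cur is None or len(loop) > len(nxt) + 1:
            raise ValueError("orifice boundary is not a simple loop")
    return np.asarray(loop, np.int64)


def _cut_orifice(surf: _Surface, name, axis, alpha, surf_point):
    """Open a circular hole of cap angle alpha about `axis`.

    Removes fully-inside faces, projects the remaining in-cap vertices
    onto the cap boundary circle, and records the ordered ring loop.
    """
    axis = _unit(axis)
    d = surf.verts / np.linalg.norm(surf.verts, axis=1, keepdims=True)
    cosang = d @ axis
    inside = cosang > math.cos(alpha)
    face_in = inside[surf.faces]
    # remove faces touching the cap; boundary vertices (just outside) are
    # pulled inward onto the ring circle, which cannot invert kept faces
    removed = np.any(face_in, axis=1)
    boundary = np.unique(surf.faces[removed][~face_in[removed]])
    surf.faces = surf.faces[~removed]
    surf.label = surf.label[~removed]
    referenced = np.zeros(len(surf.verts), dtype=bool)
    referenced[surf.faces.ravel()] = True
    ring_cand = boundary[referenced[boundary]]
    if len(ring_cand) < 6:
        raise ValueError(f"orifice {name!r}: cap angle too small for the mesh")
    loop = _boundary_loop(surf.faces, ring_cand)
    # azimuth basis about the axis
    ref = np.array([1.0, 0.0, 0.0])
    if abs(ref @ axis) > 0.9:
        ref = np.array([0.0, 1.0, 0.0])
    e1 = _unit(ref - (ref @ axis) * axis)
    e2 = np.cross(axis, e1)
    w = d[loop]
    phi = np.arctan2(w @ e2, w @ e1)
    new_dir = (
        math.cos(alpha) * axis[None, :]
        + math.sin(alpha) * (np.cos(phi)[:, None] * e1[None, :]
                             + np.sin(phi)[:, None] * e2[None, :])
    )
    surf.verts[loop] = surf_point(new_dir)
    # orient counterclockwise about the outward axis
    q = surf.verts[loop] - surf.verts[loop].mean(axis=0)
    va = 0.5 * np.cross(q, np.roll(q, -1, axis=0)).sum(axis=0)
    if va @ axis < 0:
        loop = loop[::-1]
        phi = phi[::-1]
    surf.rings[name] = loop
    surf.rings[name + "__frame"] = (axis, e1, e2, np.unwrap(phi))


def _cap_faces(verts, ring, extra_vert_store):
    """Fan triangulation closing a ring; appends the centroid vertex."""
    c = verts[ring].mean(axis=0)
    cid = len(verts) + len(extra_vert_store)
    extra_vert_store.append(c)
    m = len(ring)
    return np.array([[cid, ring[j], ring[(j + 1) % m]] for j in range(m)])


def _patch_volume(verts, faces_list):
    faces = np.concatenate(faces_list)
    return abs(enclosed_volume(verts, faces))


def _chamber_capped_volume(surf: _Surface, orifices):
    extra = []
    caps = []
    for name in orifices:
        caps.append(_cap_faces(surf.verts, surf.rings[name], extra))
    verts = np.vstack([surf.verts] + [np.asarray(extra)])
    chamber_faces = surf.faces[surf.label == "chamber"]
    return _patch_volume(verts, [chamber_faces] + caps)


def _build_chamber_surface(params: GeometryParams, scale, alphas):
    semi = np.asarray(params.chamber_semi_axes) * scale
    nexp = params.superellipse_exponent
    base = trimesh.creation.icosphere(subdivisions=params.subdivisions)
    dirs = base.vertices / np.linalg.norm(base.vertices, axis=1, keepdims=True)

    def surf_point(ds):
        return ds * _superellipsoid_radius(ds, semi, nexp)[:, None]

    verts = surf_point(dirs)
    surf = _Surface(verts, base.faces, "chamber")
    for name, axis in _orifice_axes(params).items():
        _cut_orifice(surf, name, axis, alphas[name], surf_point)
    return surf


def _orifice_axes(params: GeometryParams):
    axes = {name: _unit(ax) for name, ax in params.pv_axes}
    axes["laa"] = _unit(params.laa_axis)
    axes["annulus"] = _unit(params.annulus_axis)
    return axes


def _orifice_targets(params: GeometryParams):
    t = dict(params.pv_areas)
    t["laa"] = params.laa_orifice_area
    t["annulus"] = math.pi * params.annulus_radius**2
    return t


def _ring_area(surf: _Surface, name):
    return planar_ring_area(surf.verts[surf.rings[name]])


def _calibrate_chamber(params: GeometryParams):
    """Fixed-point calibration of the global scale and cap angles."""
    targets = _orifice_targets(params)
    semi = np.asarray(params.chamber_semi_axes)
    rmean = semi.mean()
    alphas = {n: math.sqrt(a / math.pi) / rmean for n, a in targets.items()}
    scale = 1.0
    surf = None
    for _ in range(8):
        surf = _build_chamber_surface(params, scale, alphas)
        ok = True
        for name, target in targets.items():
            area = _ring_area(surf, name)
            ratio = target / area
            if abs(ratio - 1.0) > 2e-3:
                ok = False
            alphas[name] *= math.sqrt(ratio)
        vol = _chamber_capped_volume(surf, targets.keys())
        vratio = params.chamber_volume_ml / vol
        if abs(vratio - 1.0) > 2e-3:
            ok = False
        scale *= vratio ** (1.0 / 3.0)
        if ok:
            break
    surf = _build_chamber_surface(params, scale, alphas)
    return surf, scale, alphas


# --------------------------------------------------- appendage and PV stubs


def _ring_frame(surf: _Surface, name):
    axis, e1, e2, phis = surf.rings[name + "__frame"]
    ring = surf.rings[name]
    centre = surf.verts[ring].mean(axis=0)
    rel = surf.verts[ring] - centre
    radius = float(np.linalg.norm(
        rel - (rel @ axis)[:, None] * axis, axis=1).mean())
    axial_extent = float((rel @ axis).max())
    return ring, axis, e1, e2, phis, centre, radius, axial_extent


def _append_rings(surf: _Surface, base_ring, ring_pts_list, label,
                  close_tip=False, tip_point=None):
    """Attach a tube of rings (strip-triangulated) to an existing ring."""
    m = len(base_ring)
    prev = np.asarray(base_ring)
    new_faces = []
    for pts in ring_pts_list:
        start = len(surf.verts)
        surf.verts = np.vstack([surf.verts, pts])
        cur = np.arange(start, start + m)
        for j in range(m):
            jn = (j + 1) % m
            new_faces.append([prev[j], prev[jn], cur[j]])
            new_faces.append([cur[j], prev[jn], cur[jn]])
        prev = cur
    if close_tip:
        tid = len(surf.verts)
        surf.verts = np.vstack([surf.verts, tip_point[None, :]])
        for j in range(m):
            jn = (j + 1) % m
            new_faces.append([prev[j], prev[jn], tid])
        prev = None
    new_faces = np.asarray(new_faces, np.int64)
    surf.faces = np.vstack([surf.faces, new_faces])
    surf.label = np.concatenate([surf.label,
                                 np.asarray([label] * len(new_faces), object)])
    return prev  # ids of the last open ring (None if closed)


def _laa_ring_points(centre, axis, e1, e2, phis, r_eq, d0, L, bulge,
                     n_rings=10):
    out = []
    for i in range(1, n_rings):
        s = i / n_rings
        rho = r_eq * math.sqrt(1.0 - s) * (1.0 + bulge * s)
        c = centre + axis * (d0 + (L - d0) * s)
        pts = c[None, :] + rho * (np.cos(phis)[:, None] * e1[None, :]
                                  + np.sin(phis)[:, None] * e2[None, :])
        out.append(pts)
    return out


def _attach_appendage(surf: _Surface, params: GeometryParams):
    ring, axis, e1, e2, phis, centre, r_eq, dmax = _ring_frame(surf, "laa")
    d0 = dmax + 0.15  # clear the (non-planar) orifice ring
    # pouch volume is ~linear in its free length: fixed-point calibration
    L = d0 + 2.5
    for _ in range(3):
        rings = _laa_ring_points(centre, axis, e1, e2, phis, r_eq, d0, L,
                                 params.laa_bulge)
        tip = centre + axis * L
        vol = _pouch_volume(surf.verts[ring], rings, tip, phis)
        L = d0 + (L - d0) * params.appendage_volume_ml / vol
    rings = _laa_ring_points(centre, axis, e1, e2, phis, r_eq, d0, L,
                             params.laa_bulge)
    tip = centre + axis * L
    _append_rings(surf, ring, rings, "laa", close_tip=True, tip_point=tip)
    return L


def _pouch_volume(base_pts, rings, tip, phis):
    m = len(base_pts)
    verts = np.vstack([base_pts] + rings + [tip[None, :]])
    faces = []
    nr = len(rings)
    for i in range(nr):
        a0, b0 = m * i, m * (i + 1)
        for j in range(m):
            jn = (j + 1) % m
            faces.append([a0 + j, a0 + jn, b0 + j])
            faces.append([b0 + j, a0 + jn, b0 + jn])
    tid = m * (nr + 1)
    a0 = m * nr
    for j in range(m):
        faces.append([a0 + j, a0 + (j + 1) % m, tid])
    # close the base with a fan
    c = base_pts.mean(axis=0)
    verts = np.vstack([verts, c[None, :]])
    cid = len(verts) - 1
    for j in range(m):
        faces.append([cid, (j + 1) % m, j])
    return _patch_volume(verts, [np.asarray(faces, np.int64)])


def _attach_pv_tubes(surf: _Surface, params: GeometryParams):
    rims = {}
    straight_faces = {}
    for name, _ in params.pv_areas:
        ring, axis, e1, e2, phis, centre, r_eq, dmax = _ring_frame(surf, name)
        r_t = math.sqrt(dict(params.pv_areas)[name] / math.pi)
        n_r = 4
        d0 = dmax + 0.15
        pts_list = []
        for i in range(1, n_r + 1):
            c = centre + axis * (d0 + params.pv_length * (i - 1) / (n_r - 1))
            pts = c[None, :] + r_t * (np.cos(phis)[:, None] * e1[None, :]
                                      + np.sin(phis)[:, None] * e2[None, :])
            pts_list.append(pts)
        f0 = len(surf.faces)
        rim = _append_rings(surf, ring, pts_list, "pv_" + name)
        rims[name] = rim
        m = len(ring)
        straight_faces[name] = np.arange(f0 + 2 * m, len(surf.faces))
        surf.rings["rim_" + name] = rim
        surf.rings["rim_" + name + "__frame"] = surf.rings[name + "__frame"]
    return rims, straight_faces


# -------------------------------------------------------- thickness field


class ThicknessField:
    """Wall thickness map t(x) over the atrial surface (cm internally).

    Nonuniform mode: thicker posterior (-x) and superior (+z) walls,
    calibrated so the area-weighted mean over the reference surface equals
    ``mean_mm``; minimum bounded below by 0.55 * mean.  Uniform mode:
    constant value.
    """

    def __init__(self, mode, mean_mm, centre, calib_verts=None,
                 calib_areas=None, posterior_amp=0.6, superior_amp=0.4):
        self.mode = mode
        self.mean_mm = float(mean_mm)
        self.centre = np.asarray(centre, float)
        self.posterior_amp = posterior_amp
        self.superior_amp = superior_amp
        self._scale = 1.0
        self._calib_verts = calib_verts
        self._calib_areas = calib_areas
        if mode == "nonuniform":
            if calib_verts is None:
                raise ValueError("nonuniform mode needs a calibration surface")
            raw = self._raw(calib_verts)
            mean_raw = float(np.sum(raw * calib_areas) / np.sum(calib_areas))
            self._scale = (mean_mm * 0.1) / mean_raw  # mm -> cm

    def _raw(self, pts):
        d = pts - self.centre
        d = d / np.linalg.norm(d, axis=1, keepdims=True)
        post = 0.5 * (1.0 + np.tanh((-d[:, 0] - 0.25) / 0.25))
        sup = 0.5 * (1.0 + np.tanh((d[:, 2] - 0.25) / 0.25))
        return 1.0 + self.posterior_amp * post + self.superior_amp * sup

    def __call__(self, pts):
        pts = np.atleast_2d(np.asarray(pts, float))
        if self.mode == "uniform":
            return np.full(len(pts), self.mean_mm * 0.1)
        t = self._scale * self._raw(pts)
        return np.maximum(t, 0.55 * self.mean_mm * 0.1)

    def area_weighted_mean_mm(self, verts=None, areas=None) -> float:
        """Area-weighted mean thickness (mm) over a surface (default: the
        calibration surface)."""
        if verts is None:
            verts, areas = self._calib_verts, self._calib_areas
        t = self(verts)
        return 10.0 * float(np.sum(t * areas) / np.sum(areas))

    def min_over(self, verts=None) -> float:
        if verts is None:
            verts = self._calib_verts
        return float(self(verts).min())


def _vertex_areas(verts, faces):
    tri = verts[faces]
    a = 0.5 * np.linalg.norm(
        np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0]), axis=1)
    va = np.zeros(len(verts))
    np.add.at(va, faces.ravel(), np.repeat(a / 3.0, 3))
    return va


def nonuniform_thickness_field(params: GeometryParams | None = None,
                               surface=None) -> ThicknessField:
    """Default non-uniform wall thickness map, calibrated to the mean.

    If no surface is supplied, the default chamber surface is generated
    for calibration.  ``surface`` is (verts, faces) of the wall
    mid/endocardial surface.
    """
    params = params or GeometryParams()
    if params.thickness_mode == "uniform":
        return ThicknessField("uniform", params.uniform_thickness_mm,
                              np.zeros(3))
    if surface is None:
        surf, _, _ = _calibrate_chamber(params)
        _attach_appendage(surf, params)
        verts, faces = surf.verts, surf.faces[np.isin(surf.label,
                                                      ["chamber", "laa"])]
    else:
        verts, faces = surface
    va = _vertex_areas(verts, faces)
    used = va > 0
    return ThicknessField(
        "nonuniform", params.mean_thickness_mm, centre=np.zeros(3),
        calib_verts=verts[used], calib_areas=va[used],
        posterior_amp=params.posterior_amp, superior_amp=params.superior_amp,
    )


# ------------------------------------------------------------- LA assembly


def build_idealized_la(params: GeometryParams | None = None) -> StructureMesh:
    """Generate the idealized LA wall mesh (linear tetrahedra, 2 layers).

    Returns a StructureMesh whose meta carries the inner (endocardial)
    surface, per-face component labels, ordered orifice rings, orifice
    axes, measured calibration values and the thickness field.  Fibre
    directions are left unset; see :mod:`atriumfsi.fibres`.
    """
    params = params or GeometryParams()
    surf, scale, alphas = _calibrate_chamber(params)
    laa_len = _attach_appendage(surf, params)
    rims, straight = _attach_pv_tubes(surf, params)

    # thickness over chamber+appendage; PV stubs use the same field
    wall_faces = surf.faces[np.isin(surf.label, ["chamber", "laa"])]
    tfield = (nonuniform_thickness_field(params, (surf.verts, wall_faces))
              if params.thickness_mode == "nonuniform"
              else ThicknessField("uniform", params.uniform_thickness_mm,
                                  np.zeros(3)))

    verts = surf.verts
    faces = surf.faces
    nv = len(verts)
    tm = trimesh.Trimesh(vertices=verts, faces=faces, process=False)
    normals = np.array(tm.vertex_normals)
    # smooth the extrusion direction so that sharp junction creases
    # (chamber/tube, chamber/pouch) cannot fold the offset shells
    adj_a = faces[:, [0, 1, 2]].ravel()
    adj_b = faces[:, [1, 2, 0]].ravel()
    for _ in range(6):
        acc = normals.copy()
        np.add.at(acc, adj_a, normals[adj_b])
        np.add.at(acc, adj_b, normals[adj_a])
        nn = np.linalg.norm(acc, axis=1, keepdims=True)
        normals = acc / np.maximum(nn, 1e-30)
    # exact radial normals on the straight PV tube rings
    axes = _orifice_axes(params)
    for name, _ in params.pv_areas:
        ax = axes[name]
        ring, axis, e1, e2, phis, centre, _, _ = _ring_frame(surf, name)
        tube_ids = np.unique(surf.faces[straight[name]].ravel())
        rel = verts[tube_ids] - centre
        rad = rel - (rel @ ax)[:, None] * ax
        nr = np.linalg.norm(rad, axis=1, keepdims=True)
        good = nr[:, 0] > 1e-9
        normals[tube_ids[good]] = rad[good] / nr[good]

    t_vert = tfield(verts)
    n_layers = params.n_wall_layers

    def make_shells(factor):
        off = normals * (t_vert * factor)[:, None]
        return [verts + off * (k / n_layers) for k in range(n_layers + 1)]

    # local offset relaxation: shrink the extrusion at vertices whose
    # prisms fold (concave junction creases) until all tets are positive
    factor = np.ones(nv)
    fa, fb, fc = faces[:, 0], faces[:, 1], faces[:, 2]
    for _ in range(30):
        shells = make_shells(factor)
        nodes = np.vstack(shells)
        bad_verts = set()
        for l in range(n_layers):
            ob, ot = l * nv, (l + 1) * nv
            A, B, C = nodes[fa + ot], nodes[fb + ot], nodes[fc + ot]
            a2, b2, c2 = nodes[fa + ob], nodes[fb + ob], nodes[fc + ob]

            def vol(p, q, r, s):
                return np.einsum("ij,ij->i", np.cross(q - p, r - p), s - p)
            bad = (vol(a2, b2, c2, C) <= 0) | (vol(a2, b2, C, B) <= 0) \
                | (vol(a2, B, C, A) <= 0)
            if bad.any():
                bad_verts.update(faces[bad].ravel())
        if not bad_verts:
            break
        ids = np.fromiter(bad_verts, np.int64)
        factor[ids] *= 0.8
    else:  # pragma: no cover
        raise RuntimeError("wall extrusion could not be made fold-free")

    conn = []
    region = []
    parent_face = []
    layer_of = []
    for l in range(n_layers):
        off_b, off_t = l * nv, (l + 1) * nv
        for fi, (a, b, c) in enumerate(faces):
            A, B, C = a + off_t, b + off_t, c + off_t
            a2, b2, c2 = a + off_b, b + off_b, c + off_b
            conn.extend([[a2, b2, c2, C], [a2, b2, C, B], [a2, B, C, A]])
            lab = surf.label[fi]
            region.extend([lab] * 3)
            parent_face.extend([fi] * 3)
            layer_of.extend([l] * 3)
    conn = np.asarray(conn, np.int64)
    region = np.asarray(region, dtype=object)

    mesh = StructureMesh(nodes=nodes, elem_type="tet4", conn=conn,
                         region=region)
    # guard: positive reference volumes (raises otherwise)
    mesh.element_volumes()

    # markers
    node_sets = {}
    for name in list(dict(params.pv_areas)) + ["laa", "annulus"]:
        ring = surf.rings[name]
        node_sets[name + "_ring"] = np.asarray(ring)
    for name, rim in rims.items():
        ids = np.concatenate([rim + k * nv for k in range(n_layers + 1)])
        node_sets["rim_" + name] = ids
    ann_ring = surf.rings["annulus"]
    dirs = verts / np.linalg.norm(verts, axis=1, keepdims=True)
    ann_ax = axes["annulus"]
    housing_band = np.where(dirs @ ann_ax > math.cos(2.2 * alphas["annulus"]))[0]
    node_sets["housing"] = np.concatenate(
        [housing_band + k * nv for k in range(n_layers + 1)])
    mesh.node_sets = node_sets

    elem_sets = {}
    for lab in np.unique(region):
        elem_sets[str(lab)] = np.where(region == lab)[0]
    mesh.elem_sets = elem_sets

    mesh.meta.update(
        surface_nv=nv,
        surface_faces=faces,
        surface_face_label=surf.label,
        surface_normals=normals,
        rings={k: v for k, v in surf.rings.items() if not k.endswith("__frame")},
        ring_frames={k[:-7]: v for k, v in surf.rings.items()
                     if k.endswith("__frame")},
        axes=axes,
        chamber_centre=np.zeros(3),
        scale=scale,
        cap_alphas=alphas,
        laa_length=laa_len,
        thickness_field=tfield,
        parent_face=np.asarray(parent_face),
        layer_of=np.asarray(layer_of),
        params=params,
    )
    mesh.meta["chamber_volume_ml"] = cavity_volume(mesh, "chamber")
    mesh.meta["appendage_volume_ml"] = cavity_volume(mesh, "appendage")
    mesh.meta["orifice_areas"] = {
        name: planar_ring_area(verts[surf.rings[name]])
        for name in _orifice_targets(params)
    }
    return mesh


def orifice_area(mesh: StructureMesh, name: str) -> float:
    """Planar area (cm^2) of an orifice marker ring patch."""
    ring = mesh.meta["rings"][name]
    return planar_ring_area(mesh.nodes[ring])


def cavity_volume(mesh: StructureMesh, component: str = "chamber",
                  positions: np.ndarray | None = None) -> float:
    """Enclosed cavity volume (mL) by divergence-theorem surface integral.

    component 'chamber': endocardial chamber patch capped across all six
    orifice rings; 'appendage': the pouch capped at its orifice.
    """
    nv = mesh.meta["surface_nv"]
    verts = (mesh.nodes if positions is None else positions)[:nv]
    faces = mesh.meta["surface_faces"]
    labels = mesh.meta["surface_face_label"]
    rings = mesh.meta["rings"]
    if component == "chamber":
        patch = faces[labels == "chamber"]
        cap_names = [k for k in rings if not k.startswith("rim_")]
        flip = False
    elif component == "appendage":
        patch = faces[labels == "laa"]
        cap_names = ["laa"]
        flip = True  # cap must face away from the pouch, toward the chamber
    else:
        raise ValueError(f"unknown component {component!r}")
    extra = []
    caps = [_cap_faces(verts, rings[n], extra) for n in cap_names]
    if flip:
        caps = [c[:, ::-1] for c in caps]
    allverts = np.vstack([verts] + [np.asarray(extra)])
    return _patch_volume(allverts, [patch] + caps)


def audit_la_mesh(mesh: StructureMesh) -> dict:
    """Watertightness / positive-volume / marker-completeness audit."""
    nv = mesh.meta["surface_nv"]
    verts = mesh.nodes[:nv]
    faces = mesh.meta["surface_faces"]
    rings = mesh.meta["rings"]
    extra = []
    caps = [_cap_faces(verts, rings[n], extra)
            for n in rings if n.startswith("rim_") or n == "annulus"]
    allverts = np.vstack([verts] + [np.asarray(extra)])
    closed = trimesh.Trimesh(vertices=allverts,
                             faces=np.vstack([faces] + caps),
                             process=False)
    vols = mesh.element_volumes()
    expected_sets = ({n + "_ring" for n, _ in GeometryParams().pv_areas}
                     | {"laa_ring", "annulus_ring", "housing"})
    return {
        "watertight": bool(closed.is_watertight),
        "min_element_volume": float(vols.min()),
        "n_elements": mesh.n_elems,
        "markers_complete": expected_sets.issubset(mesh.node_sets.keys()),
        "regions_complete": bool(np.all([r is not None for r in mesh.region])),
    }


# ------------------------------------------------------------------- valve


@dataclass
class ValveAssembly:
    """Two-leaflet parametric mitral valve with chordae tethers."""

    verts: np.ndarray          # leaflet surface vertices
    faces: np.ndarray          # triangles
    leaflet_of: np.ndarray     # per-face label: 'anterior' | 'posterior'
    annulus_ids: np.ndarray    # fixed attachment nodes (s = 0 rows)
    free_edge_ids: np.ndarray  # free-edge nodes (s = 1 rows)
    chordae_origins: np.ndarray   # (10, 3)
    chordae_nodes: np.ndarray     # free-edge node attached to each origin's chord
    chordae_rest: np.ndarray
    variant: str = "normal"
    offset: float = 0.0


def build_valve(params: GeometryParams | None = None,
                variant: str = "normal") -> ValveAssembly:
    """Build the simplified two-leaflet valve and its 10 chordae origins.

    variant 'mvr' displaces the chordae origins toward the atrium by
    ``params.mvr_offset``, which lifts the rest free edge past the annulus
    plane (leaflet prolapse).
    """
    params = params or GeometryParams()
    if variant not in ("normal", "mvr"):
        raise ValueError("variant must be 'normal' or 'mvr'")
    # annulus ring: circle of the configured radius in the cap plane
    surf, scale, alphas = _calibrate_chamber(params)
    ring, axis, e1, e2, phis, centre, r_ann, _ = _ring_frame(surf, "annulus")
    down = axis  # annulus axis points inferior (out of the chamber)

    offset = params.mvr_offset if variant == "mvr" else 0.0
    cl_angles = np.array([90.0, 45.0, 0.0, -45.0, -90.0])
    origins = []
    for base in (0.0, 180.0):
        for da in cl_angles:
            th = math.radians(base + da * 0.35)
            p = (centre + down * params.chordae_depth
                 + params.chordae_radius * (math.cos(th) * e1 + math.sin(th) * e2))
            origins.append(p - down * offset)
    origins = np.asarray(origins)

    spans = {"anterior": (math.radians(-65), math.radians(65),
                          params.leaflet_length_anterior),
             "posterior": (math.radians(115), math.radians(245),
                           params.leaflet_length_posterior)}
    verts = []
    faces = []
    leaflet_of = []
    ann_ids = []
    free_ids = []
    n_th, n_s = 17, 6
    for name, (th0, th1, L) in spans.items():
        ths = np.linspace(th0, th1, n_th)
        base_row = len(verts)
        for i, th in enumerate(ths):
            rp = centre + r_ann * (math.cos(th) * e1 + math.sin(th) * e2)
            cluster = origins[:5].mean(axis=0) if math.cos(th) >= 0 \
                else origins[5:].mean(axis=0)
            d = _unit(cluster - rp)
            for j in range(n_s):
                s = j / (n_s - 1)
                verts.append(rp + s * L * d)
                if j == 0:
                    ann_ids.append(len(verts) - 1)
                if j == n_s - 1:
                    free_ids.append(len(verts) - 1)
        for i in range(n_th - 1):
            for j in range(n_s - 1):
                v00 = base_row + i * n_s + j
                v01 = v00 + 1
                v10 = base_row + (i + 1) * n_s + j
                v11 = v10 + 1
                faces.append([v00, v10, v11])
                faces.append([v00, v11, v01])
                leaflet_of.extend([name, name])
    verts = np.asarray(verts)
    faces = np.asarray(faces, np.int64)
    free_ids = np.asarray(free_ids)

    # each chorda attaches to the free-edge node nearest its origin
    chordae_nodes = []
    for o in origins:
        dist = np.linalg.norm(verts[free_ids] - o, axis=1)
        chordae_nodes.append(free_ids[int(np.argmin(dist))])
    chordae_nodes = np.asarray(chordae_nodes)
    rest = np.linalg.norm(verts[chordae_nodes] - origins, axis=1)

    return ValveAssembly(
        verts=verts, faces=faces, leaflet_of=np.asarray(leaflet_of, object),
        annulus_ids=np.asarray(ann_ids), free_edge_ids=free_ids,
        chordae_origins=origins, chordae_nodes=chordae_nodes,
        chordae_rest=rest, variant=variant, offset=offset,
    )


# --------------------------------------------------------------- 2D pieces


def build_ring_2d(radius=1.0, thickness=0.16, n_seg=96, n_layers=2,
                  centre=(0.0, 0.0)) -> StructureMesh:
    """Closed elastic ring (quad4, circumferential fibres) for FSI tests."""
    cx, cy = centre
    th = 2 * np.pi * np.arange(n_seg) / n_seg
    nodes = []
    for l in range(n_layers + 1):
        r = radius - thickness / 2 + thickness * l / n_layers
        nodes.append(np.column_stack([cx + r * np.cos(th), cy + r * np.sin(th)]))
    nodes = np.vstack(nodes)
    conn = []
    for l in range(n_layers):
        for j in range(n_seg):
            jn = (j + 1) % n_seg
            # radial-then-tangential order keeps the Jacobian positive
            conn.append([l * n_seg + j, (l + 1) * n_seg + j,
                         (l + 1) * n_seg + jn, l * n_seg + jn])
    fib = np.column_stack([-np.sin(th), np.cos(th)])
    fibre = np.vstack([fib] * n_layers)
    fibre = fibre / np.linalg.norm(fibre, axis=1, keepdims=True)
    mesh = StructureMesh(nodes=nodes, elem_type="quad4",
                         conn=np.asarray(conn), fibre=fibre,
                         region=np.asarray(["ring"] * n_seg * n_layers, object))
    mid = n_layers // 2
    mesh.meta["mid_loop"] = np.arange(mid * n_seg, (mid + 1) * n_seg)
    mesh.meta["centre"] = np.asarray(centre, float)
    mesh.meta["radius"] = radius
    return mesh


@dataclass(frozen=True)
class TestbedParams:
    """2D chamber-with-flaps testbed (fast coupled-dynamics geometry)."""

    __test__ = False  # not a test case, despite the name

    domain: tuple = (6.4, 8.0)
    n_cells: tuple = (48, 60)
    centre: tuple = (3.2, 4.6)
    rx: float = 1.7
    ry: float = 1.5
    wall_thickness: float = 0.10      # cm, chamber-wall mean
    thickness_mode: str = "nonuniform"   # 'nonuniform' | 'uniform'
    thickness_factor: float = 1.0     # uniform value = factor * mean
    thickness_amp: float = 0.45
    pv_gaps: tuple = ((62.0, 80.0), (100.0, 118.0))   # degrees
    mv_gap: tuple = (254.0, 286.0)
    leaflet_length: float = 0.62
    leaflet_thickness: float = 0.08
    rigid_thickness: float = 0.10
    chordae_depth: float = 1.25       # below the annulus plane
    chordae_spread: float = 0.20
    mvr_offset: float = 0.0           # toward-LA shift of chordae origins
    n_wall_layers: int = 2
    ds_factor: float = 0.45           # node spacing = ds_factor * h
    baffle_top_y: float = 7.0         # seals the PV plenum from the ambient
    baffle_bottom_y: float = 1.6      # seals the LV plenum from the ambient


def _arc_strip(centre, rx, ry, th0, th1, thickness_fn, n_layers, ds):
    """Quad strip along an ellipse arc with transmural layers."""
    cx, cy = centre
    # approximate arc length
    tt = np.linspace(th0, th1, 200)
    pts = np.column_stack([rx * np.cos(tt), ry * np.sin(tt)])
    arclen = np.sum(np.linalg.norm(np.diff(pts, axis=0), axis=1))
    nseg = max(int(np.ceil(arclen / ds)), 4)
    th = np.linspace(th0, th1, nseg + 1)
    mid = np.column_stack([cx + rx * np.cos(th), cy + ry * np.sin(th)])
    # outward normal of the ellipse
    nrm = np.column_stack([ry * np.cos(th), rx * np.sin(th)])
    nrm /= np.linalg.norm(nrm, axis=1, keepdims=True)
    tvals = thickness_fn(th)
    nodes = []
    for l in range(n_layers + 1):
        off = (-0.5 + l / n_layers) * tvals
        nodes.append(mid + nrm * off[:, None])
    nodes = np.vstack(nodes)
    npt = nseg + 1
    conn = []
    for l in range(n_layers):
        for j in range(nseg):
            conn.append([l * npt + j, l * npt + j + 1,
                         (l + 1) * npt + j + 1, (l + 1) * npt + j])
    tang = np.column_stack([-rx * np.sin(th), ry * np.cos(th)])
    tang /= np.linalg.norm(tang, axis=1, keepdims=True)
    fib_seg = 0.5 * (tang[:-1] + tang[1:])
    fib_seg /= np.linalg.norm(fib_seg, axis=1, keepdims=True)
    fibre = np.vstack([fib_seg] * n_layers)
    midline = np.arange((n_layers // 2) * npt, (n_layers // 2) * npt + npt)
    return np.asarray(nodes), np.asarray(conn, np.int64), fibre, midline


def _straight_strip(p0, p1, thickness, n_layers, ds, lateral=None):
    """Quad strip along a straight segment."""
    p0 = np.asarray(p0, float)
    p1 = np.asarray(p1, float)
    L = np.linalg.norm(p1 - p0)
    nseg = max(int(np.ceil(L / ds)), 2)
    s = np.linspace(0, 1, nseg + 1)
    mid = p0[None, :] + s[:, None] * (p1 - p0)[None, :]
    tang = (p1 - p0) / L
    nrm = np.array([-tang[1], tang[0]]) if lateral is None \
        else _unit(np.asarray(lateral, float))
    nodes = []
    for l in range(n_layers + 1):
        off = (-0.5 + l / n_layers) * thickness
        nodes.append(mid + nrm[None, :] * off)
    nodes = np.vstack(nodes)
    npt = nseg + 1
    conn = []
    for l in range(n_layers):
        for j in range(nseg):
            conn.append([l * npt + j, l * npt + j + 1,
                         (l + 1) * npt + j + 1, (l + 1) * npt + j])
    fibre = np.tile(tang, (n_layers * nseg, 1))
    return nodes, np.asarray(conn, np.int64), fibre, npt


def _fix_orientation(nodes, conn):
    """Ensure counterclockwise quads (positive reference areas)."""
    q = nodes[conn]
    area2 = np.zeros(len(conn))
    for k in range(4):
        a = q[:, k]
        b = q[:, (k + 1) % 4]
        area2 += a[:, 0] * b[:, 1] - b[:, 0] * a[:, 1]
    flip = area2 < 0
    conn[flip] = conn[flip][:, ::-1]
    return conn


def build_2d_testbed(params: TestbedParams | None = None) -> StructureMesh:
    """Assemble the 2D chamber + PV channels + valve testbed mesh.

    Regions: 'chamber' (active atrial wall), 'leaflet' (valve flaps),
    'rigid' (tether-constrained channel walls).  Node sets: 'tether'
    (rigid walls + housing/junction nodes), 'chordae_tips'.  Meta carries
    the ordered chamber midline loop, orifice segments, chordae origins
    and the domain box.
    """
    params = params or TestbedParams()
    h = params.domain[0] / params.n_cells[0]
    ds = params.ds_factor * h
    cx, cy = params.centre
    rx, ry = params.rx, params.ry
    nl = params.n_wall_layers

    tbar = params.wall_thickness * params.thickness_factor
    if params.thickness_mode == "nonuniform":
        amp = params.thickness_amp

        def tfun(th):
            raw = 1.0 + amp * np.sin(th)
            return tbar * raw / 1.0  # mean of raw over [0,2pi) is 1
    else:
        def tfun(th):
            return np.full_like(np.asarray(th, float), tbar)

    d2r = math.radians
    (g1a, g1b), (g2a, g2b) = params.pv_gaps
    mva, mvb = params.mv_gap

    all_nodes = []
    all_conn = []
    all_fibre = []
    all_region = []
    node_off = 0
    sets = {"tether": [], "chordae_tips": []}
    mid_loop_parts = []

    def add_piece(nodes, conn, fibre, region):
        nonlocal node_off
        conn = conn + node_off
        all_nodes.append(nodes)
        all_conn.append(conn)
        all_fibre.append(fibre)
        all_region.extend([region] * len(conn))
        off0 = node_off
        node_off += len(nodes)
        return off0

    # chamber arcs in theta order starting after PV gap 1
    arcs = [(d2r(g1b), d2r(g2a)), (d2r(g2b), d2r(mva)),
            (d2r(mvb), d2r(g1a) + 2 * np.pi)]
    arc_ends = []
    for th0, th1 in arcs:
        nodes, conn, fibre, midline = _arc_strip(
            (cx, cy), rx, ry, th0, th1, tfun, nl, ds)
        off = add_piece(nodes, conn, fibre, "chamber")
        mid_loop_parts.append(midline + off)
        arc_ends.append((off + 0, off + midline[-1]))  # first node id, last mid id

    # ellipse points of the gap edges
    def ep(deg):
        t = d2r(deg)
        return np.array([cx + rx * math.cos(t), cy + ry * math.sin(t)])

    margin = 0.02  # keep rigid strips strictly inside the box
    top = params.domain[1] - margin
    # PV channels: vertical rigid walls from each gap edge to the top face
    for deg in (g1a, g1b, g2a, g2b):
        p = ep(deg)
        nodes, conn, fibre, npt = _straight_strip(
            p, np.array([p[0], top]), params.rigid_thickness, 1, ds,
            lateral=(1.0, 0.0))
        off = add_piece(nodes, conn, fibre, "rigid")
        sets["tether"].extend(range(off, off + len(nodes)))

    # LV channel: vertical rigid walls from the MV gap edges to the bottom
    pmv_l, pmv_r = ep(mva), ep(mvb)
    for p in (pmv_l, pmv_r):
        nodes, conn, fibre, npt = _straight_strip(
            np.array([p[0], p[1]]), np.array([p[0], margin]),
            params.rigid_thickness, 1, ds, lateral=(1.0, 0.0))
        off = add_piece(nodes, conn, fibre, "rigid")
        sets["tether"].extend(range(off, off + len(nodes)))

    # baffles: horizontal rigid strips sealing the bottom (LV) pressure
    # plenum; the ambient region vents through the top (PV) face and so
    # tracks the pulmonary-vein pressure, a pericardial-like reference
    ov = 0.06  # overlap into channel walls
    yb = params.baffle_bottom_y
    for x0, x1 in ((margin, pmv_l[0] + ov),
                   (pmv_r[0] - ov, params.domain[0] - margin)):
        nodes, conn, fibre, npt = _straight_strip(
            np.array([x0, yb]), np.array([x1, yb]),
            params.rigid_thickness, 1, ds, lateral=(0.0, 1.0))
        off = add_piece(nodes, conn, fibre, "rigid")
        sets["tether"].extend(range(off, off + len(nodes)))

    # leaflets: flaps hanging from the MV gap edges in the open (diastolic)
    # rest position, angled off the outflow channel walls so the grid can
    # resolve the flow behind them; reverse (systolic) flow swings them shut
    tilt = 0.55
    leaflet_node_range = [node_off, node_off]
    for p, sign in ((pmv_l, +1.0), (pmv_r, -1.0)):
        d = _unit(np.array([sign * tilt, -1.0]))
        end = p + d * params.leaflet_length
        nodes, conn, fibre, npt = _straight_strip(
            p, end, params.leaflet_thickness, 1, ds)
        off = add_piece(nodes, conn, fibre, "leaflet")
        # root nodes (attachment) are tethered to the annulus
        sets["tether"].extend([off + 0, off + npt])
        tip_node = off + npt - 1
        sets["chordae_tips"].append(tip_node)
    leaflet_node_range[1] = node_off

    # housing: chamber arc terminal nodes near every gap edge (leaflets
    # excluded so they can hinge freely at their roots)
    nodes_all = np.vstack(all_nodes)
    leaflet_lo = leaflet_node_range[0]
    gap_pts = [ep(d) for d in (g1a, g1b, g2a, g2b, mva, mvb)]
    for gp in gap_pts:
        near = np.where(np.linalg.norm(nodes_all - gp, axis=1) < 0.22)[0]
        sets["tether"].extend(n for n in near.tolist() if n < leaflet_lo)

    conn_all = np.vstack(all_conn)
    conn_all = _fix_orientation(nodes_all, conn_all)
    fibre_all = np.vstack(all_fibre)
    fibre_all /= np.linalg.norm(fibre_all, axis=1, keepdims=True)
    mesh = StructureMesh(
        nodes=nodes_all, elem_type="quad4", conn=conn_all, fibre=fibre_all,
        region=np.asarray(all_region, object),
    )
    mesh.node_sets = {
        "tether": np.unique(np.asarray(sets["tether"], np.int64)),
        "chordae_tips": np.asarray(sets["chordae_tips"], np.int64),
    }
    mesh.elem_sets = {lab: np.where(mesh.region == lab)[0]
                      for lab in ("chamber", "leaflet", "rigid")}
    # ordered midline loop (theta-ascending across the three arcs)
    mesh.meta["mid_loop"] = np.concatenate(mid_loop_parts)
    mesh.meta["domain"] = np.asarray(params.domain)
    mesh.meta["n_cells"] = np.asarray(params.n_cells)
    mesh.meta["mv_segment"] = (pmv_l.copy(), pmv_r.copy())
    mesh.meta["pv_segments"] = ((ep(g1a), ep(g1b)), (ep(g2a), ep(g2b)))
    origins0 = np.array(
        [[pmv_l[0] + params.chordae_spread, pmv_l[1] - params.chordae_depth],
         [pmv_r[0] - params.chordae_spread, pmv_r[1] - params.chordae_depth]])
    origins = origins0.copy()
    origins[:, 1] += params.mvr_offset  # MVR: displaced toward the atrium
    mesh.meta["chordae_origins"] = origins
    mesh.meta["chordae_origins_normal"] = origins0
    mesh.meta["params"] = params
    return mesh
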