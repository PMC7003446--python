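"""Rule-based atrial fibre architecture.

The atrial wall is partitioned into six sections -- left PVs, right PVs,
septopulmonary, Bachmann, appendage (LAA) and MV-plane -- and each section
receives a wall-tangent unit fibre direction by a geometric rule:

* LPV / RPV : circumferential about the respective vein axis;
* LAA       : circumferential about the appendage central axis;
* MV-plane  : parallel to the annulus plane (a band above the annulus);
* Bachmann  : circumferential about the chamber's superior-inferior axis
              on the anterior wall, which blends naturally into the
              annulus-parallel direction;
* septopulmonary : oblique (default 45 deg) between the meridional
              roof-to-septum direction and the circumferential direction.

There is no transmural rotation: every element stack through the wall
carries the same direction.  A nearest-neighbour transfer between meshes
is provided for mapping fibres onto a coarsened mesh.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .fe import StructureMesh

__all__ = ["SECTIONS", "FibreField", "partition_sections", "assign_fibres",
           "map_fibres_nn"]

SECTIONS = ("lpv", "rpv", "septopulmonary", "bachmann", "laa", "mv_plane")

_LEFT_PVS = ("lspv", "lipv")
_RIGHT_PVS = ("rspv", "ripv")


def _unit_rows(v):
    n = np.linalg.norm(v, axis=-1, keepdims=True)
    if np.any(n < 1e-12):
        raise ValueError("degenerate direction (zero vector) in fibre rule")
    return v / n


@dataclass
class FibreField:
    """Per-element unit fibre vectors with their section labels."""

    e: np.ndarray          # (E, d) unit vectors
    section: np.ndarray    # (E,) labels from SECTIONS
    normal: np.ndarray     # (E, d) wall surface normal used for tangency


def _require_markers(mesh: StructureMesh):
    for key in ("axes", "rings", "surface_faces", "surface_nv", "parent_face",
                "cap_alphas"):
        if key not in mesh.meta:
            raise ValueError(f"mesh lacks marker metadata {key!r}; "
                             "generate it with build_idealized_la")


def partition_sections(mesh: StructureMesh,
                       pv_collar: float = 2.0,
                       mv_band: float = 2.0) -> np.ndarray:
    """Assign each wall element to one of the six fibre sections.

    PV sections are geodesic collars of `pv_collar` times the orifice cap
    angle around each vein; the MV-plane section is the band within
    `mv_band` times the annulus cap angle; the pouch is LAA; the anterior
    remainder is Bachmann and the posterior/superior remainder
    septopulmonary.
    """
    _require_markers(mesh)
    axes = mesh.meta["axes"]
    alphas = mesh.meta["cap_alphas"]
    centre = mesh.meta.get("chamber_centre", np.zeros(mesh.dim))
    # label by parent surface facet so that transmural element stacks
    # always agree; facet centroids on the endocardial surface
    nv = mesh.meta["surface_nv"]
    faces = mesh.meta["surface_faces"]
    fc = mesh.nodes[:nv][faces].mean(axis=1)
    d_face = _unit_rows(fc - centre)
    d = d_face[mesh.meta["parent_face"]]
    region = mesh.region
    labels = np.empty(mesh.n_elems, dtype=object)

    for i in range(mesh.n_elems):
        comp = region[i]
        if comp == "laa":
            labels[i] = "laa"
            continue
        if comp.startswith("pv_"):
            labels[i] = "lpv" if comp[3:] in _LEFT_PVS else "rpv"
            continue
        labels[i] = None
    chamber = np.array([lab is None for lab in labels])
    dc = d[chamber]
    lab_c = np.empty(chamber.sum(), dtype=object)
    # MV-plane band around the annulus
    ann_ax = axes["annulus"]
    in_mv = dc @ ann_ax > np.cos(mv_band * alphas["annulus"])
    lab_c[in_mv] = "mv_plane"
    # PV collars
    for name in _LEFT_PVS + _RIGHT_PVS:
        sec = "lpv" if name in _LEFT_PVS else "rpv"
        in_c = (dc @ axes[name] > np.cos(pv_collar * alphas[name])) & \
            (lab_c == None)  # noqa: E711
        lab_c[in_c] = sec
    # LAA collar joins the appendage section
    in_laa = (dc @ axes["laa"] > np.cos(1.5 * alphas["laa"])) & \
        (lab_c == None)  # noqa: E711
    lab_c[in_laa] = "laa"
    rest = lab_c == None  # noqa: E711
    anterior = dc[:, 0] > 0.15
    lab_c[rest & anterior] = "bachmann"
    lab_c[rest & ~anterior] = "septopulmonary"
    labels[chamber] = lab_c
    return labels


def assign_fibres(mesh: StructureMesh, labels: np.ndarray | None = None,
                  oblique_deg: float = 45.0) -> FibreField:
    """Construct the rule-based fibre field and attach it to the mesh.

    All directions are projected onto the wall tangent plane; elements
    stacked transmurally over the same surface facet receive identical
    vectors (no transmural rotation).  PV-stub elements use the exact
    cylinder frame, so their fibres are exactly orthogonal to both the
    vein axis and the radial surface normal.
    """
    _require_markers(mesh)
    if labels is None:
        labels = partition_sections(mesh)
    axes = mesh.meta["axes"]
    centre = mesh.meta.get("chamber_centre", np.zeros(mesh.dim))
    nv = mesh.meta["surface_nv"]
    faces = mesh.meta["surface_faces"]
    verts = mesh.nodes[:nv]
    parent = mesh.meta["parent_face"]

    # per-face geometry (shared by the transmural element stack)
    fc = verts[faces].mean(axis=1)                      # face centroids
    fn = np.cross(verts[faces[:, 1]] - verts[faces[:, 0]],
                  verts[faces[:, 2]] - verts[faces[:, 0]])
    fn = _unit_rows(fn)

    # exact radial normals + frames for PV stubs
    region = mesh.region
    elem_face = parent
    pos = fc[elem_face]
    nrm = fn[elem_face].copy()
    e = np.zeros_like(pos)
    zhat = -np.asarray(axes["annulus"], float)          # superior direction

    ring_centres = {}
    for name in mesh.meta["rings"]:
        ring_centres[name] = verts[mesh.meta["rings"][name]].mean(axis=0)

    for i in range(mesh.n_elems):
        sec = labels[i]
        comp = region[i]
        p = pos[i]
        n = nrm[i]
        if comp.startswith("pv_"):
            name = comp[3:]
            ax = axes[name]
            rel = p - ring_centres[name]
            r = rel - (rel @ ax) * ax
            rl = np.linalg.norm(r)
            if rl < 1e-9:
                raise ValueError(f"degenerate tube frame in element {i}")
            r /= rl
            nrm[i] = r                                  # exact radial normal
            e[i] = np.cross(ax, r)
            continue
        if sec == "laa":
            ax = axes["laa"]
            rel = p - ring_centres["laa"]
            raw = np.cross(ax, rel - (rel @ ax) * ax)
        elif sec in ("lpv", "rpv"):
            name = min((nm for nm in (_LEFT_PVS if sec == "lpv" else _RIGHT_PVS)),
                       key=lambda nm: -((p - centre) @ axes[nm]))
            raw = np.cross(axes[name], p - ring_centres[name])
        elif sec == "mv_plane":
            raw = np.cross(axes["annulus"], n)
        elif sec == "bachmann":
            raw = np.cross(zhat, p - centre)
        elif sec == "septopulmonary":
            circ = np.cross(zhat, p - centre)
            circ = circ - (circ @ n) * n
            merid = zhat - (zhat @ n) * n
            cl, ml = np.linalg.norm(circ), np.linalg.norm(merid)
            if cl < 1e-9 or ml < 1e-9:
                raise ValueError(f"degenerate roof frame in element {i}")
            ang = np.deg2rad(oblique_deg)
            raw = np.cos(ang) * merid / ml + np.sin(ang) * circ / cl
        else:  # pragma: no cover
            raise ValueError(f"unknown section {sec!r}")
        raw = raw - (raw @ n) * n                       # wall-tangent
        rl = np.linalg.norm(raw)
        if rl < 1e-9:
            raise ValueError(f"degenerate fibre direction in element {i}")
        e[i] = raw / rl
    e = _unit_rows(e)
    field = FibreField(e=e, section=np.asarray(labels, object), normal=nrm)
    mesh.fibre = e
    mesh.meta["fibre_section"] = field.section
    mesh.meta["fibre_normal"] = nrm
    return field


def map_fibres_nn(source_mesh: StructureMesh, source_fibres: np.ndarray,
                  target_mesh: StructureMesh) -> np.ndarray:
    """Nearest-neighbour fibre transfer between overlapping meshes.

    Each target element inherits the fibre of the source element whose
    centroid is nearest to its own; unit norm is preserved.
    """
    source_fibres = np.asarray(source_fibres, float)
    if len(source_fibres) == 0 or source_mesh.n_elems == 0:
        raise ValueError("empty source mesh")
    tree = cKDTree(source_mesh.element_centroids())
    _, idx = tree.query(target_mesh.element_centroids(), k=1)
    out = source_fibres[idx]
    return _unit_rows(out)
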