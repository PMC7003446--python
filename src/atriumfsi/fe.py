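"""Lagrangian finite elements for thin-walled immersed structures.

Elements are standard isoparametric low-order continua: 4-node bilinear
quadrilaterals (2D), 4-node linear tetrahedra and 8-node trilinear
hexahedra (3D).  In 2D the kinematics are plane strain: the out-of-plane
stretch is 1, so the invariants reduce to I1 = tr(C) + 1, I3 = det(C) and
F = I gives (I1, I3, I4) = (3, 1, 1) exactly as in 3D.

The Lagrangian force density follows the weak form

    int F . V dX = - int P : grad_X V dX   for all test functions V,

assembled with nodal lumping of the reference measure, which is the form
needed by the regularized-delta spreading operator.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import numpy as np

__all__ = [
    "StructureMesh",
    "DeformationState",
    "kinematics",
    "force_density",
    "assemble_energy",
    "DegenerateElementError",
]


class DegenerateElementError(RuntimeError):
    """Raised when an element has non-positive Jacobian (J <= 0)."""


# ---------------------------------------------------------------- quadrature

_G = 1.0 / np.sqrt(3.0)


def _quad_rule(elem_type: str):
    """Return (reference points, weights) for the element family."""
    if elem_type == "tet4":
        return np.array([[0.25, 0.25, 0.25]]), np.array([1.0 / 6.0])
    if elem_type == "quad4":
        pts = np.array([[sx * _G, sy * _G] for sx in (-1, 1) for sy in (-1, 1)])
        return pts, np.ones(4)
    if elem_type == "hex8":
        pts = np.array(
            [[sx * _G, sy * _G, sz * _G]
             for sx in (-1, 1) for sy in (-1, 1) for sz in (-1, 1)]
        )
        return pts, np.ones(8)
    raise ValueError(f"unknown element type {elem_type!r}")


def _shape(elem_type: str, xi: np.ndarray):
    """Shape functions N (nq, k) and reference gradients dN (nq, k, d)."""
    if elem_type == "tet4":
        r, s, t = xi[:, 0], xi[:, 1], xi[:, 2]
        N = np.stack([1 - r - s - t, r, s, t], axis=1)
        dN = np.broadcast_to(
            np.array([[-1.0, -1.0, -1.0], [1, 0, 0], [0, 1, 0], [0, 0, 1]]),
            (len(xi), 4, 3),
        ).copy()
        return N, dN
    if elem_type == "quad4":
        r, s = xi[:, 0], xi[:, 1]
        corners = np.array([[-1, -1], [1, -1], [1, 1], [-1, 1]], dtype=float)
        N = np.stack(
            [(1 + cr * r) * (1 + cs * s) / 4 for cr, cs in corners], axis=1
        )
        dN = np.empty((len(xi), 4, 2))
        for a, (cr, cs) in enumerate(corners):
            dN[:, a, 0] = cr * (1 + cs * s) / 4
            dN[:, a, 1] = cs * (1 + cr * r) / 4
        return N, dN
    if elem_type == "hex8":
        r, s, t = xi[:, 0], xi[:, 1], xi[:, 2]
        corners = np.array(
            [[-1, -1, -1], [1, -1, -1], [1, 1, -1], [-1, 1, -1],
             [-1, -1, 1], [1, -1, 1], [1, 1, 1], [-1, 1, 1]], dtype=float
        )
        N = np.stack(
            [(1 + cr * r) * (1 + cs * s) * (1 + ct * t) / 8
             for cr, cs, ct in corners], axis=1
        )
        dN = np.empty((len(xi), 8, 3))
        for a, (cr, cs, ct) in enumerate(corners):
            dN[:, a, 0] = cr * (1 + cs * s) * (1 + ct * t) / 8
            dN[:, a, 1] = cs * (1 + cr * r) * (1 + ct * t) / 8
            dN[:, a, 2] = ct * (1 + cr * r) * (1 + cs * s) / 8
        return N, dN
    raise ValueError(f"unknown element type {elem_type!r}")


# -------------------------------------------------------------------- mesh


@dataclass
class StructureMesh:
    """Reference configuration of an immersed elastic structure.

    nodes      : (N, d) reference coordinates X, cm
    elem_type  : 'quad4' | 'tet4' | 'hex8'
    conn       : (E, k) connectivity
    fibre      : (E, d) per-element unit fibre direction e
    region     : (E,) per-element region label (str)
    node_sets  : named node index sets (markers: rims, annulus, tethers, ...)
    elem_sets  : named element index sets
    meta       : free-form geometric metadata (axes, rings, surfaces, ...)
    """

    nodes: np.ndarray
    elem_type: str
    conn: np.ndarray
    fibre: np.ndarray | None = None
    region: np.ndarray | None = None
    node_sets: dict = field(default_factory=dict)
    elem_sets: dict = field(default_factory=dict)
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.nodes = np.asarray(self.nodes, dtype=float)
        self.conn = np.asarray(self.conn, dtype=np.int64)
        if self.region is None:
            self.region = np.array(["default"] * self.n_elems, dtype=object)
        else:
            self.region = np.asarray(self.region, dtype=object)
        if self.fibre is not None:
            self.fibre = np.asarray(self.fibre, dtype=float)
            nrm = np.linalg.norm(self.fibre, axis=1)
            if not np.allclose(nrm, 1.0, atol=1e-9):
                raise ValueError("fibre directions must be unit vectors")
        self._cache = None

    # -- basic properties ---------------------------------------------------
    @property
    def dim(self) -> int:
        return self.nodes.shape[1]

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_elems(self) -> int:
        return len(self.conn)

    # -- precomputed quadrature data ----------------------------------------
    def _quad_data(self):
        """Reference-gradient and weight tables, computed once.

        Returns (gradN (E, nq, k, d), w (E, nq), N (nq, k)).
        """
        if self._cache is None:
            xi, wq = _quad_rule(self.elem_type)
            N, dN = _shape(self.elem_type, xi)           # (nq,k), (nq,k,d)
            Xe = self.nodes[self.conn]                    # (E,k,d)
            # J0[e,q,i,j] = d X_i / d xi_j
            J0 = np.einsum("ekd,qkj->eqdj", Xe, dN)
            detJ = np.linalg.det(J0)
            if np.any(detJ <= 0):
                bad = np.where(np.any(detJ <= 0, axis=1))[0]
                raise DegenerateElementError(
                    f"non-positive reference Jacobian in elements {bad[:10]}"
                )
            Jinv = np.linalg.inv(J0)                      # (E,nq,d,d)
            gradN = np.einsum("qkj,eqjd->eqkd", dN, Jinv)
            w = detJ * wq[None, :]
            self._cache = (gradN, w, N)
        return self._cache

    def element_volumes(self) -> np.ndarray:
        """Reference measure of each element (area in 2D)."""
        _, w, _ = self._quad_data()
        return w.sum(axis=1)

    def nodal_measure(self) -> np.ndarray:
        """Lumped reference measure M_a = int N_a dX per node."""
        _, w, N = self._quad_data()
        contrib = w[:, :, None] * N[None, :, :]           # (E,nq,k)
        M = np.zeros(self.n_nodes)
        np.add.at(M, self.conn, contrib.sum(axis=1))
        return M

    def element_centroids(self) -> np.ndarray:
        return self.nodes[self.conn].mean(axis=1)

    def transform(self, R: np.ndarray | None = None, t: np.ndarray | None = None):
        """Return a rigidly transformed copy (rotates stored axes/fibres)."""
        R = np.eye(self.dim) if R is None else np.asarray(R, float)
        t = np.zeros(self.dim) if t is None else np.asarray(t, float)
        out = StructureMesh(
            nodes=self.nodes @ R.T + t,
            elem_type=self.elem_type,
            conn=self.conn.copy(),
            fibre=None if self.fibre is None else self.fibre @ R.T,
            region=self.region.copy(),
            node_sets={k: np.array(v) for k, v in self.node_sets.items()},
            elem_sets={k: np.array(v) for k, v in self.elem_sets.items()},
            meta=dict(self.meta),
        )
        # rotate vector-valued metadata; translate positional entries
        def _rot(val, key=""):
            if isinstance(val, np.ndarray) and val.ndim == 1 \
                    and len(val) == self.dim and val.dtype.kind == "f":
                positional = key.endswith(("centre", "point", "origin"))
                return R @ val + (t if positional else 0.0)
            if isinstance(val, dict):
                return {k: _rot(v, k) for k, v in val.items()}
            if isinstance(val, tuple):
                return tuple(_rot(v) for v in val)
            return val
        for key in list(out.meta.keys()):
            out.meta[key] = _rot(out.meta[key], key)
        return out


# --------------------------------------------------------------- kinematics


@dataclass
class DeformationState:
    """Per-quadrature-point kinematics of a deformed structure."""

    chi: np.ndarray        # (N, d) current nodal positions
    F: np.ndarray          # (E, nq, d, d) deformation gradient
    J: np.ndarray          # (E, nq) det F
    I1: np.ndarray         # (E, nq) tr(C) (+1 in plane strain)
    I3: np.ndarray         # (E, nq) det(C) == J^2
    I4: np.ndarray | None  # (E, nq) fibre stretch squared, if fibres set
    degenerate: np.ndarray  # (E,) True where any qp has J <= 0


def kinematics(mesh: StructureMesh, chi: np.ndarray) -> DeformationState:
    """Evaluate F, J and the invariants I1, I3, I4 at every quadrature point."""
    chi = np.asarray(chi, dtype=float)
    if chi.shape != mesh.nodes.shape:
        raise ValueError("chi must be conformal with mesh.nodes")
    gradN, _, _ = mesh._quad_data()
    xe = chi[mesh.conn]                                   # (E,k,d)
    F = np.einsum("ekd,eqkg->eqdg", xe, gradN)            # (E,nq,d,d)
    J = np.linalg.det(F)
    C_tr = np.einsum("eqdg,eqdg->eq", F, F)               # tr(F^T F)
    d = mesh.dim
    I1 = C_tr + (3 - d)                                   # plane strain in 2D
    I3 = J**2
    I4 = None
    if mesh.fibre is not None:
        Fe = np.einsum("eqdg,eg->eqd", F, mesh.fibre)     # F e
        I4 = np.einsum("eqd,eqd->eq", Fe, Fe)
    return DeformationState(
        chi=chi, F=F, J=J, I1=I1, I3=I3, I4=I4,
        degenerate=np.any(J <= 0.0, axis=1),
    )


# ------------------------------------------------------------ force density


def force_density(mesh: StructureMesh, P: np.ndarray,
                  return_measure: bool = False):
    """Nodal Lagrangian forces from a per-quadrature first PK stress.

    Computes G_a = -sum_e sum_q w_q P_q : grad_X N_a, the weak-form nodal
    force (units dyn); with nodal lumping the Lagrangian force *density* is
    G_a / M_a where M_a is the lumped reference measure.

    P : (E, nq, d, d) first Piola-Kirchhoff stress per quadrature point.
    """
    gradN, w, _ = mesh._quad_data()
    P = np.asarray(P, dtype=float)
    if P.shape != gradN.shape[:2] + (mesh.dim, mesh.dim):
        raise ValueError(
            f"stress shape {P.shape} does not match mesh quadrature "
            f"{gradN.shape[:2] + (mesh.dim, mesh.dim)}"
        )
    if not np.all(np.isfinite(P)):
        raise ValueError("non-finite stress")
    # contribution to node a: -w * P . gradN_a
    contrib = -np.einsum("eq,eqdg,eqkg->ekd", w, P, gradN)
    G = np.zeros_like(mesh.nodes)
    np.add.at(G, mesh.conn, contrib)
    if return_measure:
        return G, mesh.nodal_measure()
    return G


def assemble_energy(mesh: StructureMesh, W: np.ndarray) -> float:
    """Total elastic energy from a per-quadrature energy density W (E, nq)."""
    _, w, _ = mesh._quad_data()
    return float(np.sum(w * W))
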