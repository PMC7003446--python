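"""Lagrangian-Eulerian transfer and the explicit FSI time loop.

`spread` pushes nodal structure forces onto the Eulerian face grids as a
body-force density; `interpolate` evaluates the face-centred velocity at
structure points.  Both use the same tensor-product regularized delta
kernel, so they are exact adjoints: the power identity

    sum_faces f . u h^d  ==  sum_nodes F . U

holds to round-off, and total force is conserved by the partition of
unity.  `FSISystem.step` advances the coupled system with an explicit
midpoint scheme: forces from the current configuration drive a half fluid
step, the structure moves to the midpoint, and midpoint forces drive the
full step.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from .grid import StaggeredGrid, BoundarySpec, FluidProperties
from .kernels import get_kernel, KernelSpec
from .projection import PressureSolver, momentum_step_and_project
from .fe import StructureMesh, kinematics
from .materials import ActiveParams, passive_stress, active_stress

__all__ = ["spread", "interpolate", "FSISystem", "TetherSet", "SpringSet",
           "InstabilityError", "PointOutsideDomainError"]


class InstabilityError(RuntimeError):
    """Coupled-system energy blow-up detected; the run is aborted."""


class PointOutsideDomainError(ValueError):
    """A structure point left the Eulerian box."""


def _component_weights(grid: StaggeredGrid, chi: np.ndarray, c: int,
                       kernel: KernelSpec):
    """Stencil (bases, weights) of every point on component-c's face grid."""
    d = grid.dim
    bases, weights = [], []
    for a in range(d):
        off = 0.0 if a == c else 0.5  # face grids are cell-centred off-axis
        s = (chi[:, a] - grid.origin[a]) / grid.h - off
        b, w = kernel.weights_1d(s)
        bases.append(b)
        weights.append(w)
    return bases, weights


def _check_points(grid: StaggeredGrid, chi: np.ndarray, kernel: KernelSpec,
                  bc: BoundarySpec | None = None):
    lo = grid.origin
    hi = grid.origin + grid.extents
    out = np.where(np.any((chi < lo) | (chi > hi), axis=1))[0]
    if len(out):
        raise PointOutsideDomainError(
            f"{len(out)} structure point(s) outside the box, first ids {out[:5]}"
        )
    flagged = np.zeros(len(chi), dtype=bool)
    margin = kernel.half_support * grid.h
    if bc is not None:
        for a in range(grid.dim):
            for side, edge in ((-1, lo[a]), (+1, hi[a])):
                face = "xyz"[a] + ("-" if side < 0 else "+")
                if bc.kind(face) == "pressure":
                    near = np.abs(chi[:, a] - edge) < margin
                    flagged |= near
    return flagged


class Transfer:
    """Precomputed spread/interpolate plan for one structure configuration.

    The tensor-product kernel stencil (flat grid indices and weights) is
    built once per (grid, positions) pair and shared by the adjoint pair
    of operators, which guarantees the discrete power identity exactly.
    """

    def __init__(self, grid: StaggeredGrid, chi, kernel="ib4",
                 bc: BoundarySpec | None = None):
        kernel = get_kernel(kernel)
        chi = np.asarray(chi, float)
        _check_points(grid, chi, kernel, bc)
        self.grid = grid
        self.kernel = kernel
        self.n_points = len(chi)
        d = grid.dim
        supp = kernel.support_cells
        self._plans = []
        for c in range(d):
            bases, weights = _component_weights(grid, chi, c, kernel)
            shape = grid.face_shape(c)
            idx_rows, w_rows = [], []
            if d == 2:
                for ka in range(supp):
                    ia = np.clip(bases[0] + ka, 0, shape[0] - 1)
                    wa = weights[0][:, ka]
                    for kb in range(supp):
                        ib = np.clip(bases[1] + kb, 0, shape[1] - 1)
                        idx_rows.append(ia * shape[1] + ib)
                        w_rows.append(wa * weights[1][:, kb])
            else:
                for ka in range(supp):
                    ia = np.clip(bases[0] + ka, 0, shape[0] - 1)
                    wa = weights[0][:, ka]
                    for kb in range(supp):
                        ib = np.clip(bases[1] + kb, 0, shape[1] - 1)
                        wab = wa * weights[1][:, kb]
                        for kc in range(supp):
                            ic = np.clip(bases[2] + kc, 0, shape[2] - 1)
                            idx_rows.append((ia * shape[1] + ib) * shape[2] + ic)
                            w_rows.append(wab * weights[2][:, kc])
            self._plans.append((np.asarray(idx_rows), np.asarray(w_rows), shape))

    def spread(self, F_nodal: np.ndarray):
        """Nodal forces (dyn) -> Eulerian force density on the face grids."""
        g = self.grid
        scale = 1.0 / g.h**g.dim
        out = []
        for c, (idx, w, shape) in enumerate(self._plans):
            vals = w * (F_nodal[:, c] * scale)[None, :]
            acc = np.bincount(idx.ravel(), weights=vals.ravel(),
                              minlength=int(np.prod(shape)))
            out.append(acc.reshape(shape))
        return out

    def interpolate(self, u=None) -> np.ndarray:
        """Face-centred velocity -> velocities at the structure points."""
        u = self.grid.u if u is None else u
        U = np.empty((self.n_points, self.grid.dim))
        for c, (idx, w, shape) in enumerate(self._plans):
            U[:, c] = np.einsum("kp,kp->p", u[c].ravel()[idx], w)
        return U


def spread(F_nodal: np.ndarray, chi: np.ndarray, grid: StaggeredGrid,
           kernel="ib4", bc: BoundarySpec | None = None):
    """Spread nodal forces (dyn) to Eulerian face force densities (dyn/cm^d).

    f(x) = sum_a F_a delta_h(x - chi_a);  conserves total force exactly:
    sum_cells f h^d == sum_a F_a per component.
    """
    return Transfer(grid, chi, kernel, bc).spread(np.asarray(F_nodal, float))


def interpolate(grid: StaggeredGrid, chi: np.ndarray, kernel="ib4",
                bc: BoundarySpec | None = None) -> np.ndarray:
    """Interpolate the face-centred velocity to structure points (cm/s)."""
    return Transfer(grid, chi, kernel, bc).interpolate()


# ------------------------------------------------------- auxiliary forces


@dataclass
class TetherSet:
    """Stiff penalty tethers pinning nodes to (possibly moving) targets.

    target(t) -> (len(nodes), d) positions; force = kappa (target - chi).
    kappa is a force per unit length per node (dyn/cm).
    """

    nodes: np.ndarray
    target: Callable[[float], np.ndarray]
    kappa: float

    def force(self, chi: np.ndarray, t: float, out: np.ndarray,
              ramp: float = 1.0):
        out[self.nodes] += ramp * self.kappa * (self.target(t) - chi[self.nodes])

    def max_violation(self, chi: np.ndarray, t: float) -> float:
        d = self.target(t) - chi[self.nodes]
        return float(np.linalg.norm(d, axis=1).max()) if len(self.nodes) else 0.0


@dataclass
class SpringSet:
    """Tension-only nonlinear springs (chordae) from nodes to moving origins.

    origins(t) -> (n_springs, d); spring i connects structure node
    nodes[i] to origins(t)[i].  Force magnitude k * max(0, L - L0) with a
    stiffening quadratic term k2 * max(0, L - L0)^2.
    """

    nodes: np.ndarray
    origins: Callable[[float], np.ndarray]
    rest_length: np.ndarray
    k: float
    k2: float = 0.0

    def force(self, chi: np.ndarray, t: float, out: np.ndarray,
              ramp: float = 1.0):
        org = self.origins(t)
        dvec = org - chi[self.nodes]
        L = np.linalg.norm(dvec, axis=1)
        ext = np.maximum(L - self.rest_length, 0.0)
        mag = ramp * (self.k * ext + self.k2 * ext**2)
        with np.errstate(invalid="ignore", divide="ignore"):
            unit = np.where(L[:, None] > 1e-14, dvec / np.maximum(L, 1e-14)[:, None], 0.0)
        out[self.nodes] += mag[:, None] * unit


# --------------------------------------------------------------- FSI loop


@dataclass
class FSISystem:
    """Coupled Eulerian fluid + Lagrangian structure state and stepper."""

    grid: StaggeredGrid
    props: FluidProperties
    bc: BoundarySpec
    mesh: StructureMesh
    passive: dict                      # region label -> PassiveParams
    active: ActiveParams | None = None
    active_regions: tuple = ()
    kernel: KernelSpec | str = "ib4"
    tethers: list = field(default_factory=list)
    springs: list = field(default_factory=list)
    limited: bool = True
    gravity: tuple | None = None
    time: float = 0.0
    ramp: Callable[[float], float] | None = None   # scales tether/spring/BC drive
    chi: np.ndarray = None
    _solver: PressureSolver | None = None

    def __post_init__(self):
        if self.chi is None:
            self.chi = self.mesh.nodes.copy()
        self.kernel = get_kernel(self.kernel)
        self._solver = PressureSolver(self.grid, self.bc)
        self._last_ke = None
        # restrict FE assembly to the regions that carry a material;
        # tether-only (rigid) pieces need no elastic stress
        sel = np.isin(self.mesh.region, list(self.passive.keys()))
        if sel.all():
            self._elastic = self.mesh
        else:
            self._elastic = StructureMesh(
                nodes=self.mesh.nodes, elem_type=self.mesh.elem_type,
                conn=self.mesh.conn[sel],
                fibre=None if self.mesh.fibre is None else self.mesh.fibre[sel],
                region=self.mesh.region[sel],
            )

    # -- structure forces ---------------------------------------------------
    def structure_force(self, chi: np.ndarray, t: float) -> np.ndarray:
        """Total nodal force (dyn): elastic + active + tethers + chordae."""
        mesh = self._elastic
        state = kinematics(mesh, chi)
        E = mesh.n_elems
        nq = state.F.shape[1]
        d = mesh.dim
        P = np.zeros((E, nq, d, d))
        for label, params in self.passive.items():
            sel = mesh.region == label
            if not np.any(sel):
                continue
            sub = _SubState(state, sel)
            P[sel] = passive_stress(sub, params, fibre=mesh.fibre[sel])
            if self.active is not None and label in self.active_regions:
                P[sel] += active_stress(sub, self.active, t,
                                        fibre=mesh.fibre[sel])
        from .fe import force_density
        G = force_density(mesh, P)
        r = self.ramp(t) if self.ramp is not None else 1.0
        for tset in self.tethers:
            tset.force(chi, t, G, ramp=r)
        for sset in self.springs:
            sset.force(chi, t, G, ramp=1.0)
        return G

    # -- time stepping ------------------------------------------------------
    def _fluid_step(self, f, dt, t):
        momentum_step_and_project(
            self.grid, self.props, self.bc, f=f, dt=dt, t=t,
            limited=self.limited, solver=self._solver,
        )

    def step(self, dt: float, scheme: str = "midpoint"):
        """Advance the coupled state by dt (explicit midpoint by default)."""
        t = self.time
        if scheme == "euler":
            G = self.structure_force(self.chi, t)
            tr = Transfer(self.grid, self.chi, self.kernel, self.bc)
            self._fluid_step(tr.spread(G), dt, t)
            self.chi = self.chi + dt * tr.interpolate()
        elif scheme == "midpoint":
            u0 = [uc.copy() for uc in self.grid.u]
            p0 = self.grid.p.copy()
            # half step
            G = self.structure_force(self.chi, t)
            tr = Transfer(self.grid, self.chi, self.kernel, self.bc)
            self._fluid_step(tr.spread(G), 0.5 * dt, t)
            chi_half = self.chi + 0.5 * dt * tr.interpolate()
            # full step with midpoint forces
            self.grid.u = u0
            self.grid.p = p0
            G = self.structure_force(chi_half, t + 0.5 * dt)
            tr = Transfer(self.grid, chi_half, self.kernel, self.bc)
            self._fluid_step(tr.spread(G), dt, t + 0.5 * dt)
            self.chi = self.chi + dt * tr.interpolate()
        else:
            raise ValueError(f"unknown scheme {scheme!r}")
        self.time = t + dt
        ke = self.grid.kinetic_energy(self.props.rho)
        if self._last_ke is not None and ke > 10.0 * self._last_ke \
                and ke > 1e-8:
            raise InstabilityError(
                f"kinetic energy grew {ke / max(self._last_ke, 1e-300):.1f}x "
                f"in one step at t={self.time:.5f}"
            )
        self._last_ke = ke

    def log_line(self) -> str:
        return (f"t={self.time:.6f} max|u|={self.grid.max_speed():.4g} "
                f"max|div|={np.abs(self.grid.divergence()).max():.3g}")


class _SubState:
    """View of a DeformationState restricted to an element subset."""

    def __init__(self, state, sel):
        self.chi = state.chi
        self.F = state.F[sel]
        self.J = state.J[sel]
        self.I1 = state.I1[sel]
        self.I3 = state.I3[sel]
        self.I4 = None if state.I4 is None else state.I4[sel]
        self.degenerate = state.degenerate[sel]
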