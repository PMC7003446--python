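"""Incompressible momentum step with pressure projection (2D MAC grid).

One step of

    rho (du/dt + u.grad u) = -grad p + mu lap u + f,   div u = 0,

is advanced explicitly (PPM advection, explicit diffusion) and projected
onto the divergence-free space by a pressure Poisson solve.  The
non-incremental form is used so that prescribed pressures on open patches
are realised directly by the pressure field.  The Poisson system is built
once per (grid, boundary-kind) pair and solved with a cached sparse LU
factorisation, so the discrete divergence after projection is at the level
of round-off.
"""

from __future__ import annotations

import numpy as np
import scipy.sparse as sp
from scipy.sparse.linalg import splu

from .grid import StaggeredGrid, BoundarySpec, FluidProperties
from .advection import advective_term, laplacian

__all__ = ["PressureSolver", "momentum_step_and_project"]


class PressureSolver:
    """Cached sparse LU solver for the MAC pressure Poisson equation."""

    def __init__(self, grid: StaggeredGrid, bc: BoundarySpec):
        if grid.dim != 2:
            raise NotImplementedError("the flow solver operates on 2D grids")
        bc.validate()
        self.nx, self.ny = int(grid.n[0]), int(grid.n[1])
        self.h = grid.h
        self.bc = bc
        self._dirichlet = len(bc.open_faces()) > 0
        self._build()

    def _idx(self, i, j):
        return i * self.ny + j

    def _build(self):
        nx, ny, h = self.nx, self.ny, self.h
        N = nx * ny
        rows, cols, vals = [], [], []
        # bkind[axis][side]
        kinds = {(0, -1): self.bc.kind("x-"), (0, +1): self.bc.kind("x+"),
                 (1, -1): self.bc.kind("y-"), (1, +1): self.bc.kind("y+")}
        diag = np.zeros(N)
        for i in range(nx):
            for j in range(ny):
                me = self._idx(i, j)
                for axis, side in kinds:
                    ii, jj = i, j
                    if axis == 0:
                        ii += side
                    else:
                        jj += side
                    inside = 0 <= ii < nx and 0 <= jj < ny
                    if inside:
                        rows.append(me)
                        cols.append(self._idx(ii, jj))
                        vals.append(1.0)
                        diag[me] -= 1.0
                    else:
                        kind = kinds[(axis, side)]
                        if kind == "periodic":
                            rows.append(me)
                            cols.append(self._idx(ii % nx, jj % ny))
                            vals.append(1.0)
                            diag[me] -= 1.0
                        elif kind == "pressure":
                            # ghost p = 2 p_b - p_c: (p_ghost - p_c)/h^2
                            diag[me] -= 2.0
                        # wall: homogeneous Neumann, neighbour dropped
        rows.extend(range(N))
        cols.extend(range(N))
        vals.extend(diag)
        A = sp.csr_matrix((vals, (rows, cols)), shape=(N, N)) / h**2
        if not self._dirichlet:
            # singular (all Neumann/periodic): pin p at cell (0,0)
            A = A.tolil()
            A[0, :] = 0.0
            A[0, 0] = 1.0
            A = A.tocsr()
        self._lu = splu(A.tocsc())

    def boundary_pressures(self, t: float):
        out = {}
        for face in ("x-", "x+", "y-", "y+"):
            if self.bc.kind(face) == "pressure":
                out[face] = self.bc.pressure(face, t)
        return out

    def solve(self, rhs: np.ndarray, t: float) -> np.ndarray:
        """Solve lap p = rhs with the configured BCs at time t."""
        nx, ny, h = self.nx, self.ny, self.h
        b = rhs.copy()
        for face, pb in self.boundary_pressures(t).items():
            if face == "x-":
                b[0, :] -= 2.0 * pb / h**2
            elif face == "x+":
                b[-1, :] -= 2.0 * pb / h**2
            elif face == "y-":
                b[:, 0] -= 2.0 * pb / h**2
            elif face == "y+":
                b[:, -1] -= 2.0 * pb / h**2
        b = b.ravel()
        if not self._dirichlet:
            b = b - b.mean()
            b[0] = 0.0
        p = self._lu.solve(b)
        return p.reshape(nx, ny)


def _apply_wall_normal(grid: StaggeredGrid, bc: BoundarySpec):
    """Zero the normal velocity on wall faces."""
    u, v = grid.u
    if bc.kind("x-") == "wall":
        u[0, :] = 0.0
    if bc.kind("x+") == "wall":
        u[-1, :] = 0.0
    if bc.kind("y-") == "wall":
        v[:, 0] = 0.0
    if bc.kind("y+") == "wall":
        v[:, -1] = 0.0


def _sync_periodic(grid: StaggeredGrid, bc: BoundarySpec):
    u, v = grid.u
    if bc.is_periodic(0):
        u[-1, :] = u[0, :]
    if bc.is_periodic(1):
        v[:, -1] = v[:, 0]


def momentum_step_and_project(
    grid: StaggeredGrid,
    props: FluidProperties,
    bc: BoundarySpec,
    f=None,
    dt: float = None,
    t: float = 0.0,
    limited: bool = True,
    solver: PressureSolver | None = None,
    advect: bool = True,
    rk2: bool = False,
) -> PressureSolver:
    """Advance grid.u, grid.p in place by one explicit step of size dt.

    f is an optional pair of face-centred body-force arrays (dyn/cm^3);
    boundary pressures are evaluated at t + dt.  With rk2=True a midpoint
    two-stage step is taken (second-order in time, two pressure solves).
    Returns the (possibly newly created) PressureSolver so callers can
    reuse the factorisation.
    """
    if dt is None or dt <= 0:
        raise ValueError("dt must be positive")
    if solver is None:
        solver = PressureSolver(grid, bc)
    rho, mu = props.rho, props.mu
    if rk2:
        u0 = [uc.copy() for uc in grid.u]
        momentum_step_and_project(grid, props, bc, f=f, dt=0.5 * dt, t=t,
                                  limited=limited, solver=solver,
                                  advect=advect, rk2=False)
        adv = advective_term(grid, bc, dt=dt, limited=limited) if advect \
            else [0.0, 0.0]
        lap = laplacian(grid, bc)
        for c in range(2):
            fc = 0.0 if f is None else f[c]
            grid.u[c] = u0[c] + dt * (
                -adv[c] + (mu / rho) * lap[c] + fc / rho
            )
        _apply_wall_normal(grid, bc)
        _sync_periodic(grid, bc)
        rhs = (rho / dt) * grid.divergence()
        p = solver.solve(rhs, t + dt)
        grid.p = p
        _pressure_correct(grid, bc, solver, p, dt, rho, t)
        grid.check_finite()
        return solver
    adv = advective_term(grid, bc, dt=dt, limited=limited) if advect \
        else [0.0, 0.0]
    lap = laplacian(grid, bc)
    for c in range(2):
        fc = 0.0 if f is None else f[c]
        grid.u[c] = grid.u[c] + dt * (
            -adv[c] + (mu / rho) * lap[c] + fc / rho
        )
    _apply_wall_normal(grid, bc)
    _sync_periodic(grid, bc)

    rhs = (rho / dt) * grid.divergence()
    p = solver.solve(rhs, t + dt)
    grid.p = p
    _pressure_correct(grid, bc, solver, p, dt, rho, t)
    grid.check_finite()
    return solver


def _pressure_correct(grid, bc, solver, p, dt, rho, t):
    u, v = grid.u
    h = grid.h
    # interior faces
    u[1:-1, :] -= dt / rho * (p[1:, :] - p[:-1, :]) / h
    v[:, 1:-1] -= dt / rho * (p[:, 1:] - p[:, :-1]) / h
    # boundary faces
    pb = solver.boundary_pressures(t + dt)
    if bc.kind("x-") == "pressure":
        u[0, :] -= dt / rho * 2.0 * (p[0, :] - pb["x-"]) / h
    if bc.kind("x+") == "pressure":
        u[-1, :] -= dt / rho * 2.0 * (pb["x+"] - p[-1, :]) / h
    if bc.kind("y-") == "pressure":
        v[:, 0] -= dt / rho * 2.0 * (p[:, 0] - pb["y-"]) / h
    if bc.kind("y+") == "pressure":
        v[:, -1] -= dt / rho * 2.0 * (pb["y+"] - p[:, -1]) / h
    if bc.is_periodic(0):
        u[0, :] -= dt / rho * (p[0, :] - p[-1, :]) / h
        u[-1, :] = u[0, :]
    if bc.is_periodic(1):
        v[:, 0] -= dt / rho * (p[:, 0] - p[:, -1]) / h
        v[:, -1] = v[:, 0]
    _apply_wall_normal(grid, bc)
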