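"""Fixed Cartesian staggered (MAC) grid for the Eulerian fluid state.

Velocity components live on cell faces, pressure at cell centres, body
force on faces.  The container is dimension-generic (2D/3D); the
Navier-Stokes solver itself (see :mod:`atriumfsi.projection`) operates on
2D grids, which is the desk-scale regime every coupled computation here
runs in.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["StaggeredGrid", "FluidProperties", "BoundarySpec"]

_FACES_2D = ("x-", "x+", "y-", "y+")
_FACES_3D = ("x-", "x+", "y-", "y+", "z-", "z+")


@dataclass(frozen=True)
class FluidProperties:
    """Newtonian fluid: density rho (g/cm^3), dynamic viscosity mu (g/cm/s)."""

    rho: float = 1.0
    mu: float = 0.04

    def __post_init__(self):
        if self.rho <= 0 or self.mu <= 0:
            raise ValueError("rho and mu must be positive")


class BoundarySpec:
    """Per-box-face boundary condition.

    Each face of the computational box carries exactly one condition:

    - ``("wall",)``                 no-slip rigid wall
    - ``("pressure", p)``           open patch with prescribed normal
                                    traction; ``p`` is a number (dyn/cm^2)
                                    or a callable ``p(t)``
    - ``("periodic",)``             periodic pair (both opposing faces)
    """

    def __init__(self, dim: int = 2, default: str = "wall"):
        self.dim = dim
        faces = _FACES_2D if dim == 2 else _FACES_3D
        self._conds = {f: (default,) for f in faces}

    @classmethod
    def periodic(cls, dim: int = 2) -> "BoundarySpec":
        bc = cls(dim)
        for f in bc._conds:
            bc._conds[f] = ("periodic",)
        return bc

    def set_wall(self, face: str):
        self._check(face)
        self._conds[face] = ("wall",)
        return self

    def set_pressure(self, face: str, p):
        self._check(face)
        self._conds[face] = ("pressure", p)
        return self

    def set_periodic_axis(self, axis: int):
        ax = "xyz"[axis]
        self._conds[ax + "-"] = ("periodic",)
        self._conds[ax + "+"] = ("periodic",)
        return self

    def _check(self, face: str):
        if face not in self._conds:
            raise KeyError(f"unknown face {face!r}")

    def kind(self, face: str) -> str:
        return self._conds[face][0]

    def pressure(self, face: str, t: float = 0.0) -> float:
        cond = self._conds[face]
        if cond[0] != "pressure":
            raise ValueError(f"face {face!r} is not an open pressure patch")
        p = cond[1]
        return float(p(t)) if callable(p) else float(p)

    def validate(self):
        for ax in range(self.dim):
            a = "xyz"[ax]
            lo, hi = self.kind(a + "-"), self.kind(a + "+")
            if ("periodic" in (lo, hi)) and lo != hi:
                raise ValueError(f"periodic axis {a} must be periodic on both faces")
        return self

    def is_periodic(self, axis: int) -> bool:
        return self.kind("xyz"[axis] + "-") == "periodic"

    def open_faces(self):
        return [f for f, c in self._conds.items() if c[0] == "pressure"]

    def __repr__(self):
        return f"BoundarySpec({self._conds})"


@dataclass
class StaggeredGrid:
    """MAC-grid Eulerian state.

    origin : (d,) lower corner of the box, cm
    n      : (d,) number of cells per axis
    h      : uniform grid spacing, cm
    u      : list of d face-centred velocity arrays; component c has shape
             n + e_c (one extra layer of faces along its own axis), cm/s
    p      : (n) cell-centred pressure, dyn/cm^2
    f      : list of d face-centred body-force arrays, dyn/cm^3
    """

    origin: np.ndarray
    n: np.ndarray
    h: float
    u: list = field(default=None)
    p: np.ndarray = field(default=None)
    f: list = field(default=None)

    def __post_init__(self):
        self.origin = np.asarray(self.origin, dtype=float)
        self.n = np.asarray(self.n, dtype=int)
        if self.h <= 0:
            raise ValueError("h must be positive")
        d = self.dim
        if self.u is None:
            self.u = [np.zeros(self.face_shape(c)) for c in range(d)]
        if self.p is None:
            self.p = np.zeros(tuple(self.n))
        if self.f is None:
            self.f = [np.zeros(self.face_shape(c)) for c in range(d)]

    @classmethod
    def make(cls, extents, n, origin=None):
        """Build from box extents (d,) and cell counts (d,); h must be uniform."""
        extents = np.asarray(extents, dtype=float)
        n = np.asarray(n, dtype=int)
        h = extents[0] / n[0]
        if not np.allclose(extents / n, h, rtol=1e-12):
            raise ValueError("box extents and cell counts imply non-uniform h")
        origin = np.zeros(len(n)) if origin is None else np.asarray(origin, float)
        return cls(origin=origin, n=n, h=h)

    @property
    def dim(self) -> int:
        return len(self.n)

    @property
    def extents(self) -> np.ndarray:
        return self.n * self.h

    def face_shape(self, c: int):
        s = self.n.copy()
        s[c] += 1
        return tuple(s)

    def cell_centers(self):
        axes = [self.origin[a] + (np.arange(self.n[a]) + 0.5) * self.h
                for a in range(self.dim)]
        return np.meshgrid(*axes, indexing="ij")

    def face_coords(self, c: int):
        """1D coordinate arrays of component-c face positions, per axis."""
        out = []
        for a in range(self.dim):
            if a == c:
                out.append(self.origin[a] + np.arange(self.n[a] + 1) * self.h)
            else:
                out.append(self.origin[a] + (np.arange(self.n[a]) + 0.5) * self.h)
        return out

    def max_speed(self) -> float:
        return max(float(np.abs(uc).max()) for uc in self.u)

    def divergence(self) -> np.ndarray:
        """Discrete cell-centred divergence of u."""
        div = np.zeros(tuple(self.n))
        for c in range(self.dim):
            uc = self.u[c]
            hi = [slice(None)] * self.dim
            lo = [slice(None)] * self.dim
            hi[c] = slice(1, None)
            lo[c] = slice(0, -1)
            div += (uc[tuple(hi)] - uc[tuple(lo)]) / self.h
        return div

    def kinetic_energy(self, rho: float = 1.0) -> float:
        """Total 1/2 rho |u|^2 over the box (face-based trapezoidal sum)."""
        ke = 0.0
        for c in range(self.dim):
            uc = self.u[c] ** 2
            w = np.ones(uc.shape)
            end = [slice(None)] * self.dim
            for bnd in (0, -1):
                end[c] = bnd
                w[tuple(end)] = 0.5
                end[c] = slice(None)
            ke += 0.5 * rho * float(np.sum(w * uc)) * self.h**self.dim
        return ke

    def copy(self) -> "StaggeredGrid":
        return StaggeredGrid(
            origin=self.origin.copy(), n=self.n.copy(), h=self.h,
            u=[uc.copy() for uc in self.u], p=self.p.copy(),
            f=[fc.copy() for fc in self.f],
        )

    def check_finite(self):
        if not np.all(np.isfinite(self.p)):
            raise FloatingPointError("NaN/Inf in pressure field")
        for c in range(self.dim):
            if not np.all(np.isfinite(self.u[c])):
                raise FloatingPointError(f"NaN/Inf in velocity component {c}")
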