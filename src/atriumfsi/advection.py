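"""High-resolution upwind advection on the 2D MAC grid.

The advective term u . grad(u) is evaluated in advective form with
piecewise-parabolic (PPM) interface reconstruction: fourth-order interface
interpolation, optional Colella-Woodward monotonization, and upwind
selection of the interface state by the sign of the advecting velocity.
Unlimited reconstruction is better than second-order accurate on smooth
fields; the limited variant is the robust default inside coupled runs.

Ghost layers encode the boundary conditions: periodic wrap, no-slip
reflection at walls, zero tangential velocity and linear normal
extrapolation at open (pressure) patches.
"""

from __future__ import annotations

import numpy as np

from .grid import StaggeredGrid, BoundarySpec

__all__ = ["advective_term", "CFLError", "extended_components", "laplacian"]

_NG = 4  # ghost layers


class CFLError(RuntimeError):
    """Advective CFL number exceeds the stability bound (dt too large)."""


# ------------------------------------------------------------ ghost filling


def _fill_axis(Qm, L, a, c, bc: BoundarySpec, ng=_NG):
    """Fill ghost rows of Qm (axis moved to front, rows ng..ng+L-1 valid).

    a: the axis being extended; c: the component the array belongs to.
    """
    ax = "xyz"[a]
    normal = a == c
    for side, kind in (("-", bc.kind(ax + "-")), ("+", bc.kind(ax + "+"))):
        if kind == "periodic":
            period = L - 1 if normal else L
            for k in range(ng):
                if side == "-":
                    Qm[ng - 1 - k] = Qm[ng - 1 - k + period]
                else:
                    Qm[ng + L + k] = Qm[ng + L + k - period]
        elif kind == "wall":
            if normal:
                # odd reflection through the boundary face (value 0 there)
                for k in range(ng):
                    if side == "-":
                        Qm[ng - 1 - k] = -Qm[ng + 1 + k]
                    else:
                        Qm[ng + L + k] = -Qm[ng + L - 2 - k]
            else:
                # no-slip: zero at the wall, located between rows
                for k in range(ng):
                    if side == "-":
                        Qm[ng - 1 - k] = -Qm[ng + k]
                    else:
                        Qm[ng + L + k] = -Qm[ng + L - 1 - k]
        elif kind == "pressure":
            if normal:
                # open patch: linear extrapolation of the normal component
                for k in range(ng):
                    if side == "-":
                        Qm[ng - 1 - k] = (k + 2) * Qm[ng] - (k + 1) * Qm[ng + 1]
                    else:
                        Qm[ng + L + k] = (
                            (k + 2) * Qm[ng + L - 1] - (k + 1) * Qm[ng + L - 2]
                        )
            else:
                # zero tangential velocity on the patch
                for k in range(ng):
                    if side == "-":
                        Qm[ng - 1 - k] = -Qm[ng + k]
                    else:
                        Qm[ng + L + k] = -Qm[ng + L - 1 - k]
        else:  # pragma: no cover
            raise ValueError(f"unknown boundary kind {kind!r}")


def extended_components(grid: StaggeredGrid, bc: BoundarySpec, ng=_NG):
    """Velocity components padded by ng ghost layers on every axis."""
    if grid.dim != 2:
        raise NotImplementedError("advection is implemented for 2D grids")
    out = []
    for c in range(2):
        qc = grid.u[c]
        Q = np.zeros((qc.shape[0] + 2 * ng, qc.shape[1] + 2 * ng))
        Q[ng:-ng, ng:-ng] = qc
        for a in range(2):
            Qm = np.moveaxis(Q, a, 0)
            _fill_axis(Qm, qc.shape[a], a, c, bc, ng)
        out.append(Q)
    return out


# ----------------------------------------------------------- PPM derivative


def _monotonize(qL, qR, q0):
    d = qR - qL
    six = d * (q0 - 0.5 * (qL + qR))
    ext = (qR - q0) * (q0 - qL) <= 0.0
    qL2 = np.where(ext, q0, np.where(six > d * d / 6.0, 3 * q0 - 2 * qR, qL))
    qR2 = np.where(ext, q0, np.where(six < -d * d / 6.0, 3 * q0 - 2 * qL, qR))
    return qL2, qR2


def _ppm_deriv(qext, wext, L, h, limited, w_margin):
    """Upwind w * dq/dx along axis 0.

    qext : rows 0..L+2*_NG-1, centre i at row i+_NG
    wext : advecting velocity at the same points, margin `w_margin` rows
    Returns rows i = 0..L-1.
    """
    q = qext
    m = w_margin
    # interface i-1/2 for i = -1..L+1  (index mi = i+1)
    qhat = (7.0 * (q[2:L + 5] + q[3:L + 6]) - (q[1:L + 4] + q[4:L + 7])) / 12.0
    # cells j = -1..L (index cj = j+1)
    qLc = qhat[0:L + 2]
    qRc = qhat[1:L + 3]
    if limited:
        q0c = q[3:L + 5]
        qLc, qRc = _monotonize(qLc, qRc, q0c)
        wf = 0.5 * (wext[m - 1:m + L] + wext[m:m + L + 1])
        qface = np.where(
            wf > 0, qRc[0:L + 1],
            np.where(wf < 0, qLc[1:L + 2], 0.5 * (qRc[0:L + 1] + qLc[1:L + 2])),
        )
    else:
        # unlimited reconstruction is continuous across the interface
        qface = qhat[1:L + 2]
    w0 = wext[m:m + L]
    return w0 * (qface[1:L + 1] - qface[0:L]) / h


# ------------------------------------------------------------------ driver


def advective_term(grid: StaggeredGrid, bc: BoundarySpec, dt: float | None = None,
                   limited: bool = True):
    """Return [adv_x, adv_y] = u . grad(u) on the velocity face grids.

    If dt is given, refuse when the advective CFL number max|u| dt / h
    exceeds 0.5.
    """
    bc.validate()
    if dt is not None:
        cfl = grid.max_speed() * dt / grid.h
        if cfl > 0.5 + 1e-12:
            raise CFLError(
                f"advective CFL {cfl:.3f} > 0.5 (max|u|={grid.max_speed():.3g}, "
                f"dt={dt:.3g}, h={grid.h:.3g}); reduce dt"
            )
    nx, ny = grid.n
    h = grid.h
    Uext, Vext = extended_components(grid, bc)
    ng = _NG

    adv_u = np.zeros((nx + 1, ny))
    adv_v = np.zeros((nx, ny + 1))

    # --- u du/dx: along axis 0 of the u grid, self-advection
    q = Uext[:, ng:ng + ny]
    adv_u += _ppm_deriv(q, q, nx + 1, h, limited, w_margin=ng)

    # --- v du/dy: advecting velocity = v averaged to u points
    m = 2
    W = 0.25 * (
        Vext[ng - 1:ng + nx, ng - m:ng + ny + m]
        + Vext[ng:ng + nx + 1, ng - m:ng + ny + m]
        + Vext[ng - 1:ng + nx, ng - m + 1:ng + ny + m + 1]
        + Vext[ng:ng + nx + 1, ng - m + 1:ng + ny + m + 1]
    )
    q = np.moveaxis(Uext[ng:ng + nx + 1, :], 1, 0)
    w = np.moveaxis(W, 1, 0)
    adv_u += np.moveaxis(_ppm_deriv(q, w, ny, h, limited, w_margin=m), 0, 1)

    # --- u dv/dx: advecting velocity = u averaged to v points
    W = 0.25 * (
        Uext[ng - m:ng + nx + m, ng - 1:ng + ny]
        + Uext[ng - m + 1:ng + nx + m + 1, ng - 1:ng + ny]
        + Uext[ng - m:ng + nx + m, ng:ng + ny + 1]
        + Uext[ng - m + 1:ng + nx + m + 1, ng:ng + ny + 1]
    )
    q = Vext[:, ng:ng + ny + 1]
    adv_v += _ppm_deriv(q, W, nx, h, limited, w_margin=m)

    # --- v dv/dy: self-advection
    q = np.moveaxis(Vext[ng:ng + nx, :], 1, 0)
    adv_v += np.moveaxis(_ppm_deriv(q, q, ny + 1, h, limited, w_margin=ng), 0, 1)

    return [adv_u, adv_v]


def laplacian(grid: StaggeredGrid, bc: BoundarySpec):
    """Five-point Laplacian of each velocity component with BC ghosts."""
    nx, ny = grid.n
    h2 = grid.h**2
    Uext, Vext = extended_components(grid, bc, ng=1)
    out = []
    for Q in (Uext, Vext):
        lap = (
            Q[2:, 1:-1] + Q[:-2, 1:-1] + Q[1:-1, 2:] + Q[1:-1, :-2]
            - 4.0 * Q[1:-1, 1:-1]
        ) / h2
        out.append(lap)
    return out
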