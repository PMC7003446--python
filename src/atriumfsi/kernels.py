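"""Regularized delta-function kernels of the immersed boundary method.

All kernels are tensor products of a 1D weight function phi(r) satisfying
the discrete partition of unity  sum_j phi(r - j) = 1  and the first-moment
condition  sum_j (r - j) phi(r - j) = 0  for every shift r, which makes
interpolation exact on constant and linear fields.

Families:
  "ib4"      classical 4-point IB kernel (default; support 4 cells)
  "ib3"      3-point kernel of Roma-Peskin-Berger (support 3 cells)
  "bspline6" quintic cardinal B-spline (support 6 cells, C^4 smooth)
"""

from __future__ import annotations

import numpy as np

__all__ = ["KernelSpec", "get_kernel"]


def _phi_ib4(r):
    r = np.abs(r)
    out = np.zeros_like(r)
    m1 = r < 1.0
    m2 = (r >= 1.0) & (r < 2.0)
    out[m1] = (3.0 - 2.0 * r[m1] + np.sqrt(1.0 + 4.0 * r[m1] - 4.0 * r[m1] ** 2)) / 8.0
    out[m2] = (5.0 - 2.0 * r[m2] - np.sqrt(-7.0 + 12.0 * r[m2] - 4.0 * r[m2] ** 2)) / 8.0
    return out


def _phi_ib3(r):
    r = np.abs(r)
    out = np.zeros_like(r)
    m1 = r < 0.5
    m2 = (r >= 0.5) & (r < 1.5)
    out[m1] = (1.0 + np.sqrt(1.0 - 3.0 * r[m1] ** 2)) / 3.0
    out[m2] = (5.0 - 3.0 * r[m2] - np.sqrt(-3.0 * (1.0 - r[m2]) ** 2 + 1.0)) / 6.0
    return out


def _phi_bspline6(r):
    # centred cardinal quintic B-spline M_6(r), support |r| < 3
    r = np.abs(r)
    out = np.zeros_like(r)
    for c, shift in ((1.0, 3.0), (-6.0, 2.0), (15.0, 1.0), (-20.0, 0.0)):
        out += c * np.maximum(shift - r, 0.0) ** 5
    return out / 120.0


_FAMILIES = {
    "ib4": (_phi_ib4, 2),       # (phi, half-support in cells)
    "ib3": (_phi_ib3, 2),       # offsets -1..2 cover support 1.5
    "bspline6": (_phi_bspline6, 3),
}


class KernelSpec:
    """A regularized delta kernel: family name + 1D weight evaluation."""

    def __init__(self, family: str = "ib4"):
        if family not in _FAMILIES:
            raise ValueError(
                f"unknown kernel family {family!r}; choose from {sorted(_FAMILIES)}"
            )
        self.family = family
        self.phi, self.half_support = _FAMILIES[family]

    @property
    def support_cells(self) -> int:
        return 2 * self.half_support

    def weights_1d(self, s: np.ndarray):
        """Per-point stencil weights.

        s : (P,) positions in grid-index units on some component grid.
        Returns (base (P,) int, w (P, support)) such that grid index
        base + k carries weight w[:, k].
        """
        s = np.asarray(s, dtype=float)
        base = np.floor(s).astype(np.int64) - (self.half_support - 1)
        offs = np.arange(self.support_cells)
        r = s[:, None] - (base[:, None] + offs[None, :])
        return base, self.phi(r)

    def __repr__(self):
        return f"KernelSpec({self.family!r})"


def get_kernel(spec) -> KernelSpec:
    if isinstance(spec, KernelSpec):
        return spec
    return KernelSpec(spec)
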