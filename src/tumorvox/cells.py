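"""Tumor-cell invasion operator F_c: overflow-driven diffusion of live cells.

Within each voxel, necrotic cells (tumor and host) stay put and live tumor
cells up to the voxel's remaining maximum capacity ``M_max`` stay as well;
only the live tumor cells in excess of that capacity invade the neighboring
voxels, dislocating live host cells, in proportion to the reflecting-boundary
cell matrix ``T_c``.  In vector form::

    s1 = s(M_max * 1 - nc - nn)      # room left over necrotic occupants
    s2 = min(l, s1)                  # live tumor cells that may remain
    l' = s2 + T_c @ (l - s2)

with ``s(x) = max(x, 0)`` elementwise.  Because ``T_c`` is column-stochastic,
total live tumor mass is conserved and no mass leaves the lattice; when no
voxel overflows the operator is the identity.  Receiving voxels may
transiently exceed ``M_max``; the excess is resolved on the next application.
Cell counts are continuous nonnegative reals (fractional populations are
meaningful throughout the model; nothing is rounded).
"""

from __future__ import annotations

import numpy as np

from .matrices import TransitionMatrix

__all__ = ["apply_cell_diffusion"]


def apply_cell_diffusion(
    l: np.ndarray,
    nc: np.ndarray,
    nn: np.ndarray,
    T_c: TransitionMatrix,
    M_max: float,
) -> np.ndarray:
    """Return the live-tumor-cell vector after one invasion step.

    ``nc`` and ``nn`` are untouched: necrotic cells do not invade.
    """
    if np.any(l < 0) or np.any(nc < 0) or np.any(nn < 0):
        raise ValueError("cell-count vectors must be nonnegative")
    if T_c.boundary_mode != "neumann_reflecting":
        raise ValueError("cell diffusion requires the reflecting-boundary matrix")
    s1 = np.maximum(M_max - nc - nn, 0.0)
    s2 = np.minimum(l, s1)
    overflow = l - s2
    if not np.any(overflow > 0):
        return l.copy()
    return s2 + T_c.mat @ overflow
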