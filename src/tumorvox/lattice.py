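"""Voxel-grid geometry.

The simulated tissue is a cubic lattice of N x N x N voxels, each a cube of
edge ``delta_s`` (mm), evolving with time step ``delta_tau`` (s).  Voxels are
addressed by 1-based integer triads ``(i, j, k)`` and mapped to 1-based linear
indices by ``L(i, j, k) = i + (j - 1) N + (k - 1) N**2``, so that every state
vector of the simulator is a flat array of length ``N**3`` in L order.

Every voxel falls into one of four boundary categories, determined by how many
of the up-to-26 Chebyshev-distance-1 neighbors lie inside the lattice:
interior voxels have 26 neighbors, face voxels 17, edge voxels 11 and vertex
(corner) voxels 7.  Neighbors are further classified by whether they share a
face, an edge or only a vertex with the center voxel.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "LatticeSpec",
    "NeighborSet",
    "linear_index",
    "inverse_linear_index",
    "neighbors",
    "boundary_category",
    "OFFSETS",
    "offset_class",
]

#: The 26 neighbor offsets, grouped implicitly by class; fixed canonical order.
OFFSETS: tuple[tuple[int, int, int], ...] = tuple(
    d for d in itertools.product((-1, 0, 1), repeat=3) if d != (0, 0, 0)
)


def offset_class(d: tuple[int, int, int]) -> str:
    """Classify a unit offset as ``face``, ``edge`` or ``vertex`` (or ``self``)."""
    n = sum(1 for c in d if c != 0)
    return {0: "self", 1: "face", 2: "edge", 3: "vertex"}[n]


@dataclass(frozen=True)
class LatticeSpec:
    """Geometry and discretization of the cubic voxel grid.

    Parameters
    ----------
    N : int
        Lattice side in voxels (>= 3).
    delta_s : float
        Voxel edge length in mm.
    delta_tau : float
        Time step in seconds.
    """

    N: int
    delta_s: float
    delta_tau: float

    def __post_init__(self) -> None:
        if self.N < 3:
            raise ValueError(f"N must be >= 3, got {self.N}")
        if self.delta_s <= 0:
            raise ValueError("delta_s must be positive")
        if self.delta_tau <= 0:
            raise ValueError("delta_tau must be positive")

    @property
    def n_voxels(self) -> int:
        return self.N**3


@dataclass
class NeighborSet:
    """In-lattice neighbors of a voxel, classified by shared face/edge/vertex."""

    face: list = field(default_factory=list)
    edge: list = field(default_factory=list)
    vertex: list = field(default_factory=list)

    @property
    def total(self) -> int:
        return len(self.face) + len(self.edge) + len(self.vertex)


def _check_in_lattice(v: tuple[int, int, int], N: int) -> None:
    i, j, k = v
    if not (1 <= i <= N and 1 <= j <= N and 1 <= k <= N):
        raise ValueError(f"voxel {v} outside 1..{N} lattice")


def linear_index(v: tuple[int, int, int], N: int) -> int:
    """Map a 1-based voxel triad to its 1-based linear index.

    ``L(i, j, k) = i + (j - 1) N + (k - 1) N**2``; a bijection onto 1..N^3.
    """
    _check_in_lattice(v, N)
    i, j, k = v
    return i + (j - 1) * N + (k - 1) * N**2


def inverse_linear_index(idx: int, N: int) -> tuple[int, int, int]:
    """Inverse of :func:`linear_index`: 1-based linear index -> voxel triad."""
    if not 1 <= idx <= N**3:
        raise ValueError(f"linear index {idx} outside 1..{N ** 3}")
    z = idx - 1
    i = z % N
    j = (z // N) % N
    k = z // N**2
    return (i + 1, j + 1, k + 1)


def neighbors(v: tuple[int, int, int], spec: LatticeSpec) -> NeighborSet:
    """All in-lattice voxels at Chebyshev distance 1 from ``v``, classified.

    Lists are returned sorted by linear index so that downstream matrix
    assembly is deterministic.
    """
    N = spec.N
    _check_in_lattice(v, N)
    i, j, k = v
    out = NeighborSet()
    for d in OFFSETS:
        w = (i + d[0], j + d[1], k + d[2])
        if all(1 <= c <= N for c in w):
            getattr(out, offset_class(d)).append(w)
    for lst in (out.face, out.edge, out.vertex):
        lst.sort(key=lambda w: linear_index(w, N))
    return out


def boundary_category(v: tuple[int, int, int], spec: LatticeSpec) -> str:
    """Return ``interior``, ``face``, ``edge`` or ``vertex``.

    The category counts how many coordinates of ``v`` lie on the lattice
    surface (0, 1, 2 or 3), which is consistent with neighbor counts
    26/17/11/7 respectively.
    """
    N = spec.N
    _check_in_lattice(v, N)
    on_surface = sum(1 for c in v if c == 1 or c == N)
    return {0: "interior", 1: "face", 2: "edge", 3: "vertex"}[on_surface]


# --- vectorized helpers used by matrix assembly -----------------------------


def boundary_mask(N: int) -> np.ndarray:
    """Boolean array (length N^3, L order) marking lattice-surface voxels."""
    idx = np.arange(N**3)
    i = idx % N
    j = (idx // N) % N
    k = idx // N**2
    return (
        (i == 0) | (i == N - 1) | (j == 0) | (j == N - 1) | (k == 0) | (k == N - 1)
    )


def coords_0based(N: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """0-based (i, j, k) coordinate arrays for all voxels in L order."""
    idx = np.arange(N**3)
    return idx % N, (idx // N) % N, idx // N**2
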