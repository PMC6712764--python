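"""Sparse N^3 x N^3 transition matrices for chemical and cellular diffusion.

Chemical species (oxygen, glucose) evolve by ``q_{t+dt} = T q_t`` under
time-independent Dirichlet boundaries: each interior or near-boundary row
gathers ``Pr(A<-A) q(A) + sum_i Pr(B_i->A) q(B_i)`` from the pooled isotropic
kernel, while each lattice-surface row is an identity row, holding the
boundary value fixed.  Because the kernel is renormalized so that
``p_self + 6 p_face + 12 p_edge + 8 p_vertex = 1`` exactly, every row sums to
one and a spatially uniform field is an exact fixed point.

Live tumor cells diffuse under a reflecting (homogeneous Neumann) boundary:
for each source voxel the probabilities toward its in-lattice neighbors are
renormalized to sum to one, the self term is dropped (only overflow cells
move), and the result is stored column-wise, making the cell matrix
column-stochastic with a zero diagonal — no cell mass ever leaves the lattice.

To emulate the short-time stochastic variability of in-vivo chemical fields,
columns of the chemical matrices that lie inside or near the tumor are
periodically perturbed: each nonzero entry is scaled by ``exp(eps * u)`` with
``u ~ Uniform(-1, 1)`` and the column rescaled to its original sum, which
preserves both the column sum and (for the order-of-magnitude-separated
kernel entries and ``eps <= 0.5``) the rank order of the entries; a post-check
redraws any violating column.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np
import scipy.sparse as sp

from .lattice import OFFSETS, LatticeSpec, boundary_mask, coords_0based, offset_class
from .kernels import AnisotropicKernelField, IsotropicKernel

__all__ = [
    "TransitionMatrix",
    "build_chemical_matrix",
    "build_periodic_dirichlet",
    "build_cell_matrix",
    "perturb_columns",
    "ColumnPerturber",
]


@dataclass
class TransitionMatrix:
    """A sparse transition operator plus its boundary-condition tag."""

    mat: sp.spmatrix
    boundary_mode: str  # dirichlet_fixed | dirichlet_periodic | neumann_reflecting
    species: str = ""
    N: int = 0

    def __matmul__(self, q: np.ndarray) -> np.ndarray:
        return self.mat @ q

    def copy(self) -> "TransitionMatrix":
        return TransitionMatrix(self.mat.copy(), self.boundary_mode, self.species, self.N)

    def save_mtx(self, path) -> None:
        from scipy.io import mmwrite

        mmwrite(str(path), self.mat.tocoo())


def _offset_lists(N: int):
    """For each of the 27 offsets: flat source rows with all coords valid."""
    i, j, k = coords_0based(N)
    idx = np.arange(N**3)
    for d in [(0, 0, 0), *OFFSETS]:
        ii, jj, kk = i + d[0], j + d[1], k + d[2]
        ok = (ii >= 0) & (ii < N) & (jj >= 0) & (jj < N) & (kk >= 0) & (kk < N)
        yield d, idx[ok], (ii + jj * N + kk * N**2)[ok]


def build_chemical_matrix(
    kernel: IsotropicKernel, spec: LatticeSpec, species: str = ""
) -> TransitionMatrix:
    """Assemble the Dirichlet-fixed chemical diffusion matrix.

    The kernel is renormalized so interior rows sum to exactly one; boundary
    rows are unit rows selecting themselves.  Row/column placement follows the
    L linear-index mapping.
    """
    N = spec.N
    k = kernel.renormalized()
    bmask = boundary_mask(N)
    rows, cols, vals = [], [], []
    for d, center, neighbor in _offset_lists(N):
        # entry T[center, neighbor]: probability neighbor -> center; only for
        # non-boundary target rows (boundary rows become identity below).
        keep = ~bmask[center]
        p = k.class_prob(offset_class(d))
        rows.append(center[keep])
        cols.append(neighbor[keep])
        vals.append(np.full(keep.sum(), p))
    bidx = np.flatnonzero(bmask)
    rows.append(bidx)
    cols.append(bidx)
    vals.append(np.ones(bidx.size))
    mat = sp.csr_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
        shape=(N**3, N**3),
    )
    return TransitionMatrix(mat, "dirichlet_fixed", species, N)


class PeriodicDirichletOperator:
    """Chemical diffusion with a time-dependent (periodic) boundary value.

    Wraps a Dirichlet-fixed matrix; after each multiply the boundary entries
    are overwritten with ``g(step)``.
    """

    def __init__(self, base: TransitionMatrix, g: Callable[[int], float]):
        if base.boundary_mode != "dirichlet_fixed":
            raise ValueError("base must be a dirichlet_fixed matrix")
        self.base = base
        self.g = g
        self._bidx = np.flatnonzero(boundary_mask(base.N))
        self.boundary_mode = "dirichlet_periodic"

    def apply(self, q: np.ndarray, step: int) -> np.ndarray:
        out = self.base.mat @ q
        out[self._bidx] = self.g(step)
        return out


def build_periodic_dirichlet(
    base: TransitionMatrix, g: Callable[[int], float]
) -> PeriodicDirichletOperator:
    return PeriodicDirichletOperator(base, g)


def build_cell_matrix(
    kernel_field: AnisotropicKernelField, spec: LatticeSpec
) -> TransitionMatrix:
    """Assemble the reflecting-boundary cell diffusion matrix T_c.

    Column ``A`` holds ``Pr(A -> B_i)`` over the in-lattice neighbors of A,
    renormalized to sum to one; the diagonal is zero (only overflow cells
    move, so the self term is not used).  Column-stochasticity makes the
    operator mass-conserving: reflecting boundary by construction.
    """
    N = spec.N
    probs = kernel_field.kernel_at()
    rows, cols, vals = [], [], []
    colsum = np.zeros(N**3)
    for d, source, target in _offset_lists(N):
        if d == (0, 0, 0):
            continue
        p = float(probs[d])
        rows.append(target)
        cols.append(source)
        vals.append(np.full(source.size, p))
        colsum[source] += p
    if np.any(colsum <= 0):
        raise ValueError("degenerate kernel: a voxel has zero outflow probability")
    vals = [v / colsum[c] for v, c in zip(vals, cols)]
    mat = sp.csc_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
        shape=(N**3, N**3),
    )
    return TransitionMatrix(mat, "neumann_reflecting", "cells", N)


def _rank_order_preserved(old: np.ndarray, new: np.ndarray) -> bool:
    """True when every strict inequality among old entries survives in new."""
    o = np.argsort(old, kind="stable")
    so, sn = old[o], new[o]
    # strict increases in the sorted old sequence must remain increases
    inc = so[1:] > so[:-1]
    return bool(np.all(sn[1:][inc] > sn[:-1][inc]))


class ColumnPerturber:
    """Stochastic column perturbation of a transition matrix.

    Each application multiplies the nonzero entries of the *active* columns
    by independent ``exp(eps * u)`` factors, ``u ~ Uniform(-1, 1)``, and
    rescales each perturbed column to its baseline sum, so column sums and
    (given the order-of-magnitude separation of kernel entries and
    ``eps <= 0.5``) entry rank orders are preserved; a post-check redraws any
    violating column.  Perturbations are always drawn relative to the
    *baseline* entries captured at construction — repeated applications
    therefore jitter around the estimated kernel instead of performing an
    unbounded multiplicative random walk that would eventually erase the
    relative orders of magnitude.
    """

    def __init__(self, T: TransitionMatrix):
        self.T = T
        csc = T.mat.tocsc()
        csc.sum_duplicates()
        T.mat = csc
        self.baseline = csc.data.copy()
        self.indptr = csc.indptr
        ncols = csc.shape[1]
        self.colid = np.repeat(np.arange(ncols), np.diff(self.indptr))
        self.colsum = np.add.reduceat(self.baseline, self.indptr[:-1])
        self.colsum[np.diff(self.indptr) == 0] = 1.0
        # positions in (column, ascending baseline) order, for the rank check
        self.order = np.lexsort((self.baseline, self.colid))
        ob, oc = self.baseline[self.order], self.colid[self.order]
        self.check_pairs = np.flatnonzero((oc[1:] == oc[:-1]) & (ob[1:] > ob[:-1]))

    def apply(
        self,
        active: np.ndarray,
        magnitude: float,
        rng: np.random.Generator,
        max_redraws: int = 20,
    ) -> TransitionMatrix:
        if magnitude < 0:
            raise ValueError("magnitude must be nonnegative")
        if magnitude == 0 or not np.any(active):
            return self.T
        data = self.T.mat.data
        pos = active[self.colid]
        factors = np.exp(magnitude * rng.uniform(-1.0, 1.0, size=int(pos.sum())))
        new = np.where(pos, self.baseline, data)
        new[pos] = self.baseline[pos] * factors
        newsum = np.add.reduceat(new, self.indptr[:-1])
        newsum[np.diff(self.indptr) == 0] = 1.0
        scale = np.where(active, self.colsum / newsum, 1.0)
        new *= scale[self.colid]
        # rank-order post-check; redraw any violating column individually
        so = new[self.order]
        bad = ~(so[1:] > so[:-1])
        violating = np.unique(self.colid[self.order][self.check_pairs + 1][bad[self.check_pairs]])
        for col in violating:
            lo, hi = self.indptr[col], self.indptr[col + 1]
            base = self.baseline[lo:hi]
            for _ in range(max_redraws):
                u = rng.uniform(-1.0, 1.0, size=hi - lo)
                cand = base * np.exp(magnitude * u)
                cand *= base.sum() / cand.sum()
                if _rank_order_preserved(base, cand):
                    new[lo:hi] = cand
                    break
            else:
                new[lo:hi] = base
        self.T.mat.data[:] = new
        return self.T


def perturb_columns(
    T: TransitionMatrix,
    active: np.ndarray,
    magnitude: float,
    rng: np.random.Generator,
    max_redraws: int = 20,
) -> TransitionMatrix:
    """One-shot stochastic perturbation of the active columns of ``T``.

    Convenience wrapper around :class:`ColumnPerturber` with the baseline
    taken from the current matrix entries; returns ``T`` modified in place
    (on its CSC representation).  Only active columns change; each perturbed
    column keeps its sum and the rank order of its entries.
    """
    if magnitude == 0 or not np.any(active):
        if magnitude < 0:
            raise ValueError("magnitude must be nonnegative")
        return T
    return ColumnPerturber(T).apply(active, magnitude, rng, max_redraws)
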