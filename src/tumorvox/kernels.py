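"""Per-step voxel-to-neighbor transition kernels.

A particle placed uniformly at random inside a voxel performs one step of
Brownian motion over ``delta_tau``.  For isotropic diffusion with coefficient
``D`` the displacement is Gaussian with per-axis variance ``2 D delta_tau``
(the SDE ``dx = sqrt(2D) dB``); for anisotropic diffusion the displacement is
``U diag(sqrt(a l1), sqrt(a l2), sqrt(a l3)) b`` with ``b ~ N(0, delta_tau I)``,
where ``U`` holds the orthonormal eigenvectors of the diffusion tensor and
``a`` is a species-specific scale (for a scalar coefficient, ``2 D = a l``).

Binning the endpoint into the source voxel, its 26 neighbors, or "escape"
(further away) yields the transition probabilities that drive the sparse
diffusion operators.  The grid is well resolved when the escape mass is
negligible, i.e. particles diffuse at most into the neighbor shell within one
time step; :func:`check_containment` reports the residual.

Isotropic kernels pool the symmetric neighbor classes (6 face, 12 edge,
8 vertex), so they consist of essentially four numbers.  An independent
semi-analytic route is provided by :func:`analytic_isotropic_kernel`: with
independent axes, each class probability is a product of three 1-D terms
``q(d)`` (the Gaussian mass a uniformly-placed particle deposits in the bin
offset by ``d`` voxels), computed by numerical quadrature.

Internally all lengths are mm and times are seconds; diffusion coefficients
are accepted in cm^2/s (the conventional unit for tissue diffusivities).
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import integrate
from scipy.stats import norm

from .lattice import OFFSETS, LatticeSpec

__all__ = [
    "DiffusionTensor",
    "IsotropicKernel",
    "AnisotropicKernelField",
    "sample_isotropic_kernel",
    "analytic_isotropic_kernel",
    "sample_anisotropic_kernel",
    "check_containment",
]

CM2_TO_MM2 = 100.0  # 1 cm^2 = 100 mm^2

CLASS_MULTIPLICITY = {"self": 1, "face": 6, "edge": 12, "vertex": 8}


@dataclass(frozen=True)
class DiffusionTensor:
    """Diffusion ellipsoid: orthonormal eigenvectors, eigenvalues, and scale.

    The displacement over one step is ``U diag(sqrt(alpha*lam_i)) b`` with
    ``b ~ N(0, delta_tau I)``; ``alpha * lam_i`` has units mm^2/s.
    """

    U: np.ndarray
    eigenvalues: tuple[float, float, float]
    alpha: float = 1.0

    def __post_init__(self) -> None:
        U = np.asarray(self.U, dtype=float)
        if U.shape != (3, 3):
            raise ValueError("U must be 3x3")
        if not np.allclose(U.T @ U, np.eye(3), atol=1e-8):
            raise ValueError("U must be orthonormal")
        if any(l <= 0 for l in self.eigenvalues):
            raise ValueError("eigenvalues must be positive")
        if self.alpha < 0:
            raise ValueError("alpha must be nonnegative")
        object.__setattr__(self, "U", U)

    @classmethod
    def from_axis_coefficients(
        cls, U: np.ndarray, D_axes_cm2_s: tuple[float, float, float]
    ) -> "DiffusionTensor":
        """Build from per-axis scalar diffusion coefficients via ``2 D = a l``.

        Each axis coefficient ``D_i`` (cm^2/s) is converted to the product
        ``alpha * lam_i = 2 D_i`` (in mm^2/s); ``alpha`` is folded into the
        eigenvalues (stored alpha = 1).
        """
        lams = tuple(2.0 * D * CM2_TO_MM2 for D in D_axes_cm2_s)
        return cls(U=np.asarray(U, dtype=float), eigenvalues=lams, alpha=1.0)

    @classmethod
    def isotropic(cls, D_cm2_s: float) -> "DiffusionTensor":
        return cls.from_axis_coefficients(np.eye(3), (D_cm2_s,) * 3)

    def step_scales_mm(self, delta_tau: float) -> np.ndarray:
        """Per-principal-axis standard deviation (mm) of one displacement."""
        al = self.alpha * np.asarray(self.eigenvalues)
        return np.sqrt(al * delta_tau)


@dataclass
class IsotropicKernel:
    """Pooled class probabilities self/face/edge/vertex plus escape mass."""

    p_self: float
    p_face: float
    p_edge: float
    p_vertex: float
    escape: float
    n_samples: int = 0
    seed: int | None = None
    stderr: dict = field(default_factory=dict)

    @property
    def covered(self) -> float:
        """Total probability mass landing in the source voxel or its neighbors."""
        return self.p_self + 6 * self.p_face + 12 * self.p_edge + 8 * self.p_vertex

    def renormalized(self) -> "IsotropicKernel":
        """Fold the escape mass back in so the covered mass is exactly 1.

        Enforces the containment condition as an equality; a uniform field is
        then an exact fixed point of the interior diffusion stencil.
        """
        c = self.covered
        if c <= 0:
            raise ValueError("kernel has no covered mass")
        return IsotropicKernel(
            p_self=self.p_self / c,
            p_face=self.p_face / c,
            p_edge=self.p_edge / c,
            p_vertex=self.p_vertex / c,
            escape=0.0,
            n_samples=self.n_samples,
            seed=self.seed,
        )

    def class_prob(self, cls: str) -> float:
        return {
            "self": self.p_self,
            "face": self.p_face,
            "edge": self.p_edge,
            "vertex": self.p_vertex,
        }[cls]

    def to_dict(self) -> dict:
        return {
            "p_self": self.p_self,
            "p_face": self.p_face,
            "p_edge": self.p_edge,
            "p_vertex": self.p_vertex,
            "escape": self.escape,
            "n_samples": self.n_samples,
            "seed": self.seed,
        }


@dataclass
class AnisotropicKernelField:
    """Offset -> probability map for cell diffusion.

    For a spatially constant tensor (the case simulated here) one shared
    27-entry map serves every voxel; near the boundary the out-of-lattice
    entries are dropped and the remainder renormalized by the matrix builder.
    """

    probs: dict  # (di, dj, dk) -> probability, includes (0, 0, 0)
    escape: float
    n_samples: int = 0
    seed: int | None = None

    def kernel_at(self, voxel=None) -> dict:
        """Probability map for a voxel (constant field: same map everywhere)."""
        return self.probs

    @property
    def covered(self) -> float:
        return float(sum(self.probs.values()))


def _sigma_iso_mm(D_cm2_s: float, delta_tau: float) -> float:
    return math.sqrt(2.0 * D_cm2_s * CM2_TO_MM2 * delta_tau)


def _bin_offsets(end: np.ndarray, delta_s: float) -> np.ndarray:
    """Integer voxel offsets of endpoints; start voxel spans [0, delta_s)^3."""
    return np.floor(end / delta_s).astype(np.int64)


def sample_isotropic_kernel(
    D: float, spec: LatticeSpec, n_samples: int = 1_000_000, seed: int = 0
) -> IsotropicKernel:
    """Monte Carlo estimate of the isotropic transition kernel.

    Parameters
    ----------
    D : float
        Scalar diffusion coefficient in cm^2/s (must be >= 0).
    spec : LatticeSpec
        Supplies the voxel edge ``delta_s`` (mm) and time step ``delta_tau`` (s).
    n_samples : int
        Number of simulated particles.
    seed : int
        Seed for the sampling generator.

    Draws the start uniform in the source voxel, displaces by an isotropic
    Gaussian of per-axis variance ``2 D delta_tau``, bins the endpoint, and
    pools the symmetric neighbor classes.  Stores the per-class Monte Carlo
    standard errors in ``stderr``.
    """
    if D < 0:
        raise ValueError("diffusion coefficient must be nonnegative")
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    rng = np.random.default_rng(seed)
    sigma = _sigma_iso_mm(D, spec.delta_tau)
    start = rng.random((n_samples, 3)) * spec.delta_s
    end = start + rng.normal(0.0, sigma, size=(n_samples, 3)) if sigma > 0 else start
    off = _bin_offsets(end, spec.delta_s)
    in_shell = np.all(np.abs(off) <= 1, axis=1)
    moved_axes = np.count_nonzero(off, axis=1)

    counts = {"self": 0, "face": 0, "edge": 0, "vertex": 0}
    names = ["self", "face", "edge", "vertex"]
    for m in range(4):
        counts[names[m]] = int(np.count_nonzero(in_shell & (moved_axes == m)))
    n_escape = n_samples - sum(counts.values())

    probs, stderr = {}, {}
    for cls in names:
        mult = CLASS_MULTIPLICITY[cls]
        p_tot = counts[cls] / n_samples
        probs[cls] = p_tot / mult
        stderr[cls] = math.sqrt(max(p_tot * (1 - p_tot), 0.0) / n_samples) / mult
    return IsotropicKernel(
        p_self=probs["self"],
        p_face=probs["face"],
        p_edge=probs["edge"],
        p_vertex=probs["vertex"],
        escape=n_escape / n_samples,
        n_samples=n_samples,
        seed=seed,
        stderr=stderr,
    )


def _q_1d(d: int, sigma: float, delta_s: float) -> float:
    """1-D term: mass a uniform start in [0, ds) deposits in bin offset d.

    ``q(d) = (1/ds) \\int_0^{ds} [Phi((d ds + ds - x)/s) - Phi((d ds - x)/s)] dx``
    """
    if sigma == 0:
        return 1.0 if d == 0 else 0.0

    def f(x: float) -> float:
        return norm.cdf((d * delta_s + delta_s - x) / sigma) - norm.cdf(
            (d * delta_s - x) / sigma
        )

    val, _ = integrate.quad(f, 0.0, delta_s, epsabs=1e-14, epsrel=1e-12)
    return val / delta_s


def analytic_isotropic_kernel(D: float, spec: LatticeSpec) -> IsotropicKernel:
    """Deterministic quadrature reference for the isotropic kernel.

    The three axes are independent, so each class probability factorizes into
    1-D terms: ``p_self = q(0)^3``, ``p_face = q(1) q(0)^2``,
    ``p_edge = q(1)^2 q(0)``, ``p_vertex = q(1)^3`` (with ``q(1) = q(-1)`` by
    symmetry).  Used as the independent oracle for the Monte Carlo estimate.
    """
    if D < 0:
        raise ValueError("diffusion coefficient must be nonnegative")
    sigma = _sigma_iso_mm(D, spec.delta_tau)
    q0 = _q_1d(0, sigma, spec.delta_s)
    q1 = _q_1d(1, sigma, spec.delta_s)
    k = IsotropicKernel(
        p_self=q0**3,
        p_face=q1 * q0**2,
        p_edge=q1**2 * q0,
        p_vertex=q1**3,
        escape=0.0,
        n_samples=0,
        seed=None,
    )
    k.escape = max(1.0 - k.covered, 0.0)
    return k


def sample_anisotropic_kernel(
    tensor: DiffusionTensor,
    spec: LatticeSpec,
    n_samples: int = 1_000_000,
    seed: int = 0,
) -> AnisotropicKernelField:
    """Monte Carlo estimate of the anisotropic (cell) transition kernel.

    Displacement: ``U diag(sqrt(alpha lam_i)) b`` with ``b ~ N(0, dt I)``.
    For a spatially constant tensor one shared offset map serves all voxels.
    """
    rng = np.random.default_rng(seed)
    scales = tensor.step_scales_mm(spec.delta_tau)  # mm
    start = rng.random((n_samples, 3)) * spec.delta_s
    b = rng.normal(0.0, 1.0, size=(n_samples, 3))
    disp = (tensor.U @ (scales[:, None] * b.T)).T
    off = _bin_offsets(start + disp, spec.delta_s)
    in_shell = np.all(np.abs(off) <= 1, axis=1)

    probs: dict = {}
    key = (off[in_shell, 0] + 1) * 9 + (off[in_shell, 1] + 1) * 3 + (off[in_shell, 2] + 1)
    counts = np.bincount(key, minlength=27)
    for d in [(0, 0, 0), *OFFSETS]:
        probs[d] = counts[(d[0] + 1) * 9 + (d[1] + 1) * 3 + (d[2] + 1)] / n_samples
    escape = 1.0 - counts.sum() / n_samples
    return AnisotropicKernelField(
        probs=probs, escape=escape, n_samples=n_samples, seed=seed
    )


def check_containment(kernel) -> float:
    """Residual escape mass of a kernel (0 when the one-step displacement is
    fully contained in the source voxel and its 26 neighbors)."""
    return float(kernel.escape)


# --- kernel cache -----------------------------------------------------------


def _cache_key(kind: str, params: dict) -> str:
    blob = json.dumps({"kind": kind, **params}, sort_keys=True)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def cache_isotropic_kernel(
    D: float,
    spec: LatticeSpec,
    n_samples: int,
    seed: int,
    cache_dir: str | Path,
) -> IsotropicKernel:
    """Sample an isotropic kernel, memoized as JSON keyed by its parameters."""
    cache_dir = Path(cache_dir)
    cache_dir.mkdir(parents=True, exist_ok=True)
    key = _cache_key(
        "iso",
        {
            "D": D,
            "delta_s": spec.delta_s,
            "delta_tau": spec.delta_tau,
            "n": n_samples,
            "seed": seed,
        },
    )
    path = cache_dir / f"kernel_{key}.json"
    if path.exists():
        d = json.loads(path.read_text())
        return IsotropicKernel(**d)
    k = sample_isotropic_kernel(D, spec, n_samples, seed)
    payload = k.to_dict()
    path.write_text(json.dumps(payload, indent=1))
    return k
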