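"""Simulation engine: state vector, operator sequencing, runs and ensembles.

The model is a discrete-time stochastic dynamical system.  The state consists
of nine per-voxel vectors — live tumor ``l``, necrotic tumor ``nc``, necrotic
host ``nn`` (cells); oxygen ``o`` and glucose ``gl`` stocks (pmol); supply
rates ``o_b``, ``gl_b`` and their caps ``o_b_max``, ``gl_b_max`` (pmol/s) —
plus the angiogenesis switch ``sw`` and the simulation clock.  One time step
applies, in order:

1. ``F_vr``  vascular remodeling (supply rates for the coming interval),
2. ``F_pn``  metabolism-driven proliferation/necrosis,
3. ``F_o``/``F_gl``  chemical diffusion (sparse multiplies, Dirichlet),
4. ``F_c``   cell invasion, every ``kappa`` steps only (cells diffuse orders
   of magnitude more slowly than molecules),

then recomputes the angiogenesis switch and advances the clock.  On its own
cadence, the columns of the chemical matrices inside/near the tumor are
stochastically perturbed before the multiplies of that step.  All randomness
flows through a single seeded generator in a fixed order (perturbation,
vascular draws, metabolism draws), so a master seed reproduces a trajectory
bit for bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

from .cells import apply_cell_diffusion
from .kernels import (
    DiffusionTensor,
    sample_anisotropic_kernel,
    sample_isotropic_kernel,
)
from .lattice import LatticeSpec, linear_index
from .matrices import (
    ColumnPerturber,
    TransitionMatrix,
    build_cell_matrix,
    build_chemical_matrix,
)
from .metabolism import ModelParams, apply_metabolism
from .vasculature import apply_vascular_remodeling, update_switch

__all__ = [
    "SimulationState",
    "Operators",
    "default_cell_tensor",
    "build_operators",
    "init_state",
    "center_seeding",
    "step",
    "run",
    "run_ensemble",
    "RunResult",
    "EnsembleSummary",
    "save_state",
    "load_state",
]

def default_cell_tensor(
    D_principal: float = 1.5e-6, D_transverse: float = 1.5e-8
) -> DiffusionTensor:
    """Synthetic, spatially constant cell-diffusion tensor.

    The principal axis lies along (1/2, 1/2, sqrt(2)/2) with the principal
    diffusivity at the top of the reported tissue range for migrating tumor
    cells and the transverse diffusivities at the bottom, so cell invasion is
    strongly anisotropic.  Axis coefficients are in cm^2/s.
    """
    U = np.array(
        [
            [0.5, 0.5, np.sqrt(2) / 2],
            [-0.5, -0.5, np.sqrt(2) / 2],
            [np.sqrt(2) / 2, -np.sqrt(2) / 2, 0.0],
        ]
    ).T
    return DiffusionTensor.from_axis_coefficients(
        U, (D_principal, D_transverse, D_transverse)
    )


@dataclass
class SimulationState:
    """The nine per-voxel state vectors plus switch and clock."""

    l: np.ndarray
    nc: np.ndarray
    nn: np.ndarray
    o: np.ndarray
    gl: np.ndarray
    o_b: np.ndarray
    gl_b: np.ndarray
    o_b_max: np.ndarray
    gl_b_max: np.ndarray
    sw: np.ndarray
    t: float = 0.0
    step_index: int = 0
    N: int = 0
    delta_tau: float = 10.0

    def copy(self) -> "SimulationState":
        return SimulationState(
            *(getattr(self, f).copy() for f in
              ("l", "nc", "nn", "o", "gl", "o_b", "gl_b", "o_b_max", "gl_b_max", "sw")),
            t=self.t, step_index=self.step_index, N=self.N, delta_tau=self.delta_tau,
        )

    def validate(self, M: float | None = None, where: str = "") -> None:
        """Assert the state invariants; used in debug mode after operators."""
        for name in ("l", "nc", "nn", "o", "gl", "o_b_max", "gl_b_max"):
            v = getattr(self, name)
            if np.any(v < 0) or not np.all(np.isfinite(v)):
                raise AssertionError(f"{where}: {name} negative or non-finite")
        if np.any(np.abs(self.o_b) > self.o_b_max * (1 + 1e-12)):
            raise AssertionError(f"{where}: |o_b| exceeds o_b_max")
        if np.any(np.abs(self.gl_b) > self.gl_b_max * (1 + 1e-12)):
            raise AssertionError(f"{where}: |gl_b| exceeds gl_b_max")

    def total_live(self) -> float:
        return float(self.l.sum())


@dataclass
class Operators:
    """The sparse diffusion operators a simulation needs."""

    T_o: TransitionMatrix
    T_gl: TransitionMatrix
    T_c: TransitionMatrix

    def copy(self) -> "Operators":
        return Operators(self.T_o.copy(), self.T_gl.copy(), self.T_c.copy())

    def perturbers(self) -> tuple[ColumnPerturber, ColumnPerturber]:
        """Lazily built column perturbers for the two chemical matrices
        (baselines captured at first use)."""
        if not hasattr(self, "_perturbers"):
            self._perturbers = (ColumnPerturber(self.T_o), ColumnPerturber(self.T_gl))
        return self._perturbers


def build_operators(
    params: ModelParams,
    spec: LatticeSpec,
    tensor: DiffusionTensor | None = None,
    n_kernel_samples: int = 1_000_000,
    kernel_seed: int = 12345,
) -> Operators:
    """Estimate the three transition kernels and assemble the matrices.

    Kernels are Monte Carlo estimates with a fixed, documented seed so that
    operator construction is reproducible independently of the run seed.
    """
    tensor = tensor or default_cell_tensor()
    k_o = sample_isotropic_kernel(params.D_o, spec, n_kernel_samples, kernel_seed)
    k_gl = sample_isotropic_kernel(params.D_gl, spec, n_kernel_samples, kernel_seed + 1)
    k_c = sample_anisotropic_kernel(tensor, spec, n_kernel_samples, kernel_seed + 2)
    return Operators(
        T_o=build_chemical_matrix(k_o, spec, species="oxygen"),
        T_gl=build_chemical_matrix(k_gl, spec, species="glucose"),
        T_c=build_cell_matrix(k_c, spec),
    )


def center_seeding(spec: LatticeSpec, n_cells: float = 5e5):
    """Seed ``n_cells`` live tumor cells in the central voxel."""
    c = (spec.N + 1) // 2
    return [((c, c, c), n_cells)]


def init_state(
    params: ModelParams,
    spec: LatticeSpec,
    seeding: Sequence[tuple[tuple[int, int, int], float]] | None = None,
    allow_overfull_seed: bool = True,
) -> SimulationState:
    """Initial state: homogeneous normal tissue plus the seeded tumor.

    Stocks start at the blood-equilibrium quantities, supply rates at the
    host-consumption balance ``o_b = M K_o`` / ``gl_b = M K_gl``, caps at
    their normal-tissue values, and no necrosis anywhere.  By default a
    seeding above ``M_max`` in one voxel is allowed (the overflow invades at
    the first cell-diffusion step); pass ``allow_overfull_seed=False`` to
    treat it as a configuration error.
    """
    n = spec.n_voxels
    state = SimulationState(
        l=np.zeros(n),
        nc=np.zeros(n),
        nn=np.zeros(n),
        o=np.full(n, params.o0_bar),
        gl=np.full(n, params.gl0_bar),
        o_b=np.full(n, params.M * params.K_o),
        gl_b=np.full(n, params.M * params.K_gl),
        o_b_max=np.full(n, params.o_b_max0),
        gl_b_max=np.full(n, params.gl_b_max0),
        sw=np.zeros(n),
        N=spec.N,
        delta_tau=spec.delta_tau,
    )
    for voxel, count in seeding or ():
        if count < 0:
            raise ValueError("seeded cell count must be nonnegative")
        if count > params.M_max and not allow_overfull_seed:
            raise ValueError(f"seeding {count} exceeds M_max in voxel {voxel}")
        state.l[linear_index(voxel, spec.N) - 1] += count
    return state


def _tumor_vicinity(state: SimulationState) -> np.ndarray:
    """Voxels with tumor presence (l + nc > 0) or adjacent to one."""
    reached = (state.l + state.nc) > 0
    cube = reached.reshape(state.N, state.N, state.N)
    dil = ndimage.binary_dilation(cube, structure=np.ones((3, 3, 3), bool))
    return dil.reshape(-1)


def step(
    state: SimulationState,
    operators: Operators,
    params: ModelParams,
    rng: np.random.Generator,
    debug: bool = False,
) -> SimulationState:
    """Advance the state by one time step (in place)."""
    # chemical-matrix perturbation, on its cadence, before the multiplies
    if (
        params.perturb_magnitude > 0
        and state.step_index % params.perturb_period == 0
    ):
        active = _tumor_vicinity(state)
        if np.any(active):
            for pert in operators.perturbers():
                pert.apply(active, params.perturb_magnitude, rng)

    draws = rng.random((5, state.l.shape[0]))  # r1..r4 then beta, fixed order
    apply_vascular_remodeling(state, params, rng, draws=draws[:4])
    if debug:
        state.validate(where="F_vr")
    apply_metabolism(state, params, rng, beta_draws=draws[4])
    if debug:
        state.validate(where="F_pn")
    state.o = operators.T_o.mat @ state.o
    state.gl = operators.T_gl.mat @ state.gl
    if debug:
        state.validate(where="F_o/F_gl")
    if (state.step_index + 1) % params.kappa == 0:
        state.l = apply_cell_diffusion(
            state.l, state.nc, state.nn, operators.T_c, params.M_max
        )
        if debug:
            state.validate(where="F_c")
    state.sw = update_switch(state, params)
    state.t += state.delta_tau
    state.step_index += 1
    return state


def _summarize(state: SimulationState, params: ModelParams) -> dict:
    return {
        "step": state.step_index,
        "t_days": state.t / 86400.0,
        "total_live": float(state.l.sum()),
        "total_nc": float(state.nc.sum()),
        "total_nn": float(state.nn.sum()),
        "n_reached": int(np.count_nonzero(state.l + state.nc)),
        "n_hypoxic": int(np.count_nonzero(state.o < params.h_o * params.o0_bar)),
        "n_hypoglycemic": int(
            np.count_nonzero(state.gl < params.h_gl * params.gl0_bar)
        ),
    }


@dataclass
class RunResult:
    summaries: pd.DataFrame
    final_state: SimulationState


def run(
    params: ModelParams,
    spec: LatticeSpec,
    n_steps: int,
    seed: int,
    seeding: Sequence[tuple[tuple[int, int, int], float]] | None = None,
    operators: Operators | None = None,
    summary_every: int | None = None,
    callbacks: Sequence[Callable[[SimulationState], None]] = (),
    debug: bool = False,
) -> RunResult:
    """Run a single replicate for ``n_steps`` steps.

    Summaries (total populations, hypoxic/hypoglycemic voxel counts) are
    recorded at step 0 and every ``summary_every`` steps (default: once per
    simulated day).  The supplied ``operators`` are copied when chemical
    perturbation is enabled, so a shared template is never mutated.
    """
    if n_steps < 0:
        raise ValueError("n_steps must be >= 0")
    ops = operators or build_operators(params, spec)
    if params.perturb_magnitude > 0:
        ops = Operators(ops.T_o.copy(), ops.T_gl.copy(), ops.T_c)
    if summary_every is None:
        summary_every = max(int(round(86400.0 / spec.delta_tau)), 1)
    rng = np.random.default_rng(seed)
    state = init_state(params, spec, seeding)
    rows = [_summarize(state, params)]
    for _ in range(n_steps):
        step(state, ops, params, rng, debug=debug)
        if state.step_index % summary_every == 0 or state.step_index == n_steps:
            rows.append(_summarize(state, params))
            for cb in callbacks:
                cb(state)
    # drop a duplicated final row when n_steps hits the cadence exactly
    summaries = pd.DataFrame(rows).drop_duplicates(subset="step", ignore_index=True)
    return RunResult(summaries=summaries, final_state=state)


@dataclass
class EnsembleSummary:
    """Replicate-level outcomes of a stochastic ensemble."""

    final_live: np.ndarray
    seeds: list
    survival_probability: float
    conditional_mean_live: float  # NaN when no replicate survives
    per_day: pd.DataFrame
    final_states: list = field(default_factory=list)

    @property
    def sorted_final_live(self) -> np.ndarray:
        """Final live counts sorted descending (the 'skewed bar' ordering)."""
        return np.sort(self.final_live)[::-1]


def run_ensemble(
    params: ModelParams,
    spec: LatticeSpec,
    n_replicates: int,
    n_steps: int,
    base_seed: int,
    seeding: Sequence[tuple[tuple[int, int, int], float]] | None = None,
    operators: Operators | None = None,
    keep_states: bool = False,
) -> EnsembleSummary:
    """Run ``n_replicates`` independent replicates (seeds ``base_seed + i``).

    Survival probability is the fraction of replicates ending with a nonzero
    live-tumor population; the conditional mean live count averages over the
    surviving replicates only.
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    ops = operators or build_operators(params, spec)
    finals, frames, states = [], [], []
    seeds = [base_seed + i for i in range(n_replicates)]
    for i, s in enumerate(seeds):
        res = run(params, spec, n_steps, seed=s, seeding=seeding, operators=ops)
        finals.append(res.final_state.total_live())
        df = res.summaries.copy()
        df.insert(0, "replicate", i)
        frames.append(df)
        if keep_states:
            states.append(res.final_state)
    finals = np.asarray(finals)
    alive = finals > 0
    survival = float(alive.mean())
    cond_mean = float(finals[alive].mean()) if alive.any() else float("nan")
    return EnsembleSummary(
        final_live=finals,
        seeds=seeds,
        survival_probability=survival,
        conditional_mean_live=cond_mean,
        per_day=pd.concat(frames, ignore_index=True),
        final_states=states,
    )


# --- persistence ------------------------------------------------------------

_STATE_FIELDS = ("l", "nc", "nn", "o", "gl", "o_b", "gl_b", "o_b_max", "gl_b_max", "sw")


def save_state(state: SimulationState, path, params: ModelParams | None = None) -> None:
    """Write a state snapshot to HDF5 (one dataset per vector, clock attrs)."""
    import h5py

    with h5py.File(path, "w") as f:
        for name in _STATE_FIELDS:
            f.create_dataset(name, data=getattr(state, name))
        f.attrs["t"] = state.t
        f.attrs["step_index"] = state.step_index
        f.attrs["N"] = state.N
        f.attrs["delta_tau"] = state.delta_tau
        if params is not None:
            for k, v in params.to_dict().items():
                f.attrs[f"param_{k}"] = v


def load_state(path) -> SimulationState:
    import h5py

    with h5py.File(path, "r") as f:
        vecs = {name: f[name][...] for name in _STATE_FIELDS}
        return SimulationState(
            **vecs,
            t=float(f.attrs["t"]),
            step_index=int(f.attrs["step_index"]),
            N=int(f.attrs["N"]),
            delta_tau=float(f.attrs["delta_tau"]),
        )
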