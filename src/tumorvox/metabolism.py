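"""Proliferation/necrosis operator F_pn: metabolism-limited tumor growth.

Energy bookkeeping
------------------
A normal (host) cell consumes oxygen at ``K_o`` and glucose at ``K_gl``
(pmol/s).  Clean combustion (Gl + 6 O2 -> 36 ATP) and glycolysis
(Gl -> 2 ATP) fix its ATP demand at ``K_ATP = (17/3) K_o + 2 K_gl``.
A quiescent tumor cell needs the same ``K_ATP`` but may cover a fraction
``beta`` of it by glycolysis (the Warburg effect), which requires

* glucose: ``((17 beta + 1) / 36) K_ATP``  pmol/s
* oxygen:  ``((1 - beta) / 6)  K_ATP``  pmol/s

and an actively proliferating tumor cell needs ``lambda`` times as much
(``lambda > 1``).  At ``beta = 0`` the oxygen:glucose uptake ratio is 6:1 and
the combustion pathway yields 18x the ATP per glucose of glycolysis.

Per-voxel algorithm (executed every time step)
----------------------------------------------
Step 1 — host cells consume first.  The live-host count is the derived
``s(M - l - nc - nn)``.  If stock plus supply covers their demand, the
leftovers ``O_av``/``Gl_av`` go to the tumor (Case 1.1); otherwise the
surviving host count is set by the binding resource and the rest turn
necrotic (Case 1.2), leaving the binding resource exactly exhausted.

Step 2 — tumor cells.  With no tumor the voxel just stores the leftovers
(Case 2.1).  Otherwise the feasible glycolysis window is computed from the
resource-imposed bounds ``beta_ = 1 - 6 O_av / (l K_ATP dt)`` (oxygen) and
``beta^ = (36 Gl_av / (l K_ATP dt) - 1) / 17`` (glucose), intersected with
the phenotype limits ``[beta1, beta2]``.  If the intersection is empty the
voxel starves: a random ``beta~`` in ``[beta1, beta2]`` determines how many
cells the resources can keep alive; the rest become necrotic (Case 2.2.1).
If nonempty, ``beta~`` is drawn uniformly on the window and the mitosis rate
is ``a~ = min(a_o(beta~), a_gl(beta~), a_max)`` — the oxygen- and
glucose-limited rates with ``a_o`` increasing and ``a_gl`` decreasing in
``beta`` — after which populations grow by ``a~ l`` and both stocks are
decremented by quiescent plus proliferative consumption (Case 2.2.2).  The
actively proliferating count is the deterministic estimate
``a l (cc / dt)`` for cell-cycle duration ``cc``.

Populations are continuous; a voxel whose live-tumor count falls below one
cell is treated as extinct there (the remainder becomes necrotic), so that
finite ensembles have well-defined extinction events.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
from numba import njit

__all__ = [
    "ModelParams",
    "k_atp",
    "cell_needs",
    "pathway_atp_yields",
    "normal_cell_step",
    "beta_window",
    "mitosis_rate_oxygen",
    "mitosis_rate_glucose",
    "tumor_cell_step",
    "apply_metabolism",
    "rate_from_halftime_days",
    "rate_from_doubling_days",
]


def k_atp(K_o: float, K_gl: float) -> float:
    """ATP consumption rate of a normal cell, ``(17/3) K_o + 2 K_gl`` pmol/s."""
    if K_o < 0 or K_gl < 0:
        raise ValueError("consumption rates must be nonnegative")
    return (17.0 / 3.0) * K_o + 2.0 * K_gl


def cell_needs(beta: float, lambda_eff: float, K_ATP: float) -> tuple[float, float]:
    """(glucose, oxygen) uptake rates (pmol/s) of one tumor cell.

    ``beta`` is the glycolysis fraction of its ATP budget; ``lambda_eff`` is 1
    for a quiescent cell and ``lambda`` for an actively proliferating one.
    """
    if not 0.0 <= beta <= 1.0:
        raise ValueError("beta must lie in [0, 1]")
    if lambda_eff < 1.0:
        raise ValueError("lambda_eff must be >= 1")
    glucose = (17.0 * beta + 1.0) / 36.0 * lambda_eff * K_ATP
    oxygen = (1.0 - beta) / 6.0 * lambda_eff * K_ATP
    return glucose, oxygen


def pathway_atp_yields(K_ATP: float = 1.0) -> tuple[float, float]:
    """ATP produced per unit glucose by combustion and by glycolysis.

    Derived from the implemented uptake stoichiometry: at ``beta = 0`` all ATP
    comes from combustion, at ``beta = 1`` all from glycolysis; the yield is
    the ATP rate divided by the glucose uptake rate in each pure regime.
    """
    gl_comb, _ = cell_needs(0.0, 1.0, K_ATP)
    gl_glyc, _ = cell_needs(1.0, 1.0, K_ATP)
    return K_ATP / gl_comb, K_ATP / gl_glyc


def rate_from_halftime_days(days: float, delta_tau: float) -> float:
    """Per-step regression rate whose minimum halftime is ``days`` days."""
    return math.log(2.0) / (days * 86400.0 / delta_tau)


def rate_from_doubling_days(days: float, delta_tau: float) -> float:
    """Per-step expansion (or mitosis) rate whose minimum doubling time is
    ``days`` days."""
    return math.log(2.0) / (days * 86400.0 / delta_tau)


@dataclass
class ModelParams:
    """All tunable model parameters (rates in pmol/s, quantities in pmol,
    populations in cells, per-step rates dimensionless).

    Defaults follow the reference parameterization for a 2 mm voxel and a
    10 s time step: voxel capacity ``M = 8e6`` cells (``M_max = 1.02 M``),
    host consumption ``K_o = 2.5e-4`` / ``K_gl = 5e-5`` pmol/s, maximum
    mitosis rate matching a 5-day doubling time, cell cycle 24 h,
    proliferation multiplier ``lambda = 10``, glycolysis window [0.1, 0.2],
    vascular regression at a 5-day minimum halftime and expansion at a 1-day
    minimum doubling time, hypoxia/hypoglycemia thresholds at 30% / 50% of
    the normal-tissue stocks ``o0 = 1.2e3`` / ``gl0 = 4e4`` pmol, and supply
    caps ``2.8e3`` / ``560`` pmol/s.
    """

    M: float = 8e6
    M_max: float = 1.02 * 8e6
    K_o: float = 250e-6
    K_gl: float = 50e-6
    lambda_: float = 10.0
    cc: float = 86400.0
    a_max: float = 16e-6
    beta1: float = 0.1
    beta2: float = 0.2
    h_o: float = 0.30
    h_gl: float = 0.50
    o0_bar: float = 1.2e3
    gl0_bar: float = 40e3
    o_b_max0: float = 2.8e3
    gl_b_max0: float = 560.0
    v_r: float = field(default_factory=lambda: rate_from_halftime_days(5.0, 10.0))
    v_e: float = field(default_factory=lambda: rate_from_doubling_days(1.0, 10.0))
    kappa: int = 30
    perturb_period: int = 6
    perturb_magnitude: float = 0.1
    angiogenesis_enabled: bool = True
    extinction_threshold: float = 1.0
    D_o: float = 1.8e-5  # cm^2/s
    D_gl: float = 1.05e-5  # cm^2/s

    def __post_init__(self) -> None:
        if not self.M_max >= self.M > 0:
            raise ValueError("require M_max >= M > 0")
        if not 0.0 <= self.beta1 <= self.beta2 <= 1.0:
            raise ValueError("require 0 <= beta1 <= beta2 <= 1")
        if self.lambda_ <= 1.0:
            raise ValueError("lambda must be > 1")
        if not (0.0 < self.h_o < 1.0 and 0.0 < self.h_gl < 1.0):
            raise ValueError("thresholds must lie in (0, 1)")
        for name in ("K_o", "K_gl", "cc", "a_max", "o0_bar", "gl0_bar",
                     "o_b_max0", "gl_b_max0", "v_r", "v_e"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        if self.kappa < 1 or self.perturb_period < 1:
            raise ValueError("kappa and perturb_period must be >= 1")

    @property
    def K_ATP(self) -> float:
        return k_atp(self.K_o, self.K_gl)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ModelParams":
        return cls(**d)


# --- scalar per-voxel operations (reference API) ----------------------------


def _s(x: float) -> float:
    return x if x >= 0.0 else 0.0


def normal_cell_step(
    l: float,
    nc: float,
    nn: float,
    o: float,
    gl: float,
    o_b_next: float,
    gl_b_next: float,
    params: ModelParams,
    delta_tau: float,
) -> tuple[float, float, float]:
    """Step 1 for one voxel: host-cell consumption and necrosis.

    Returns ``(O_av, Gl_av, nn_next)``: the oxygen and glucose left for tumor
    cells and the updated necrotic-host count.
    """
    Ko, Kgl, M, dt = params.K_o, params.K_gl, params.M, delta_tau
    ln = _s(M - l - nc - nn)
    avail_o = o + o_b_next * dt
    avail_gl = gl + gl_b_next * dt
    O1 = avail_o - ln * Ko * dt
    Gl1 = avail_gl - ln * Kgl * dt
    if O1 >= 0.0 and Gl1 >= 0.0:
        return O1, Gl1, nn
    N_n = min(avail_o / (Ko * dt), avail_gl / (Kgl * dt))
    if N_n < 0.0:
        N_n = 0.0
    O_av = avail_o - N_n * Ko * dt
    Gl_av = avail_gl - N_n * Kgl * dt
    if O_av < 0.0:
        O_av = 0.0
    if Gl_av < 0.0:
        Gl_av = 0.0
    return O_av, Gl_av, nn + (ln - N_n)


def beta_window(
    O_av: float,
    Gl_av: float,
    l: float,
    params: ModelParams,
    delta_tau: float,
) -> tuple[float, float, bool]:
    """Resource-imposed glycolysis-fraction bounds for a voxel with ``l > 0``.

    Returns ``(beta_, beta^, feasible)`` where feasibility means the window
    ``[max(beta_, beta1), min(beta^, beta2)]`` is nonempty (boundary cases
    inclusive).
    """
    if l <= 0:
        raise ValueError("beta_window requires a positive live-tumor count")
    E = l * params.K_ATP * delta_tau
    beta_lo = 1.0 - 6.0 * O_av / E
    beta_hi = (36.0 * Gl_av / E - 1.0) / 17.0
    infeasible = (
        beta_lo > params.beta2
        or beta_hi < params.beta1
        or min(beta_hi, params.beta2) < max(beta_lo, params.beta1)
    )
    return beta_lo, beta_hi, not infeasible


def mitosis_rate_oxygen(
    beta: float, O_av: float, l: float, params: ModelParams, delta_tau: float
) -> float:
    """Oxygen-limited mitosis rate ``a_o(beta)`` (increasing in beta on [0, 1);
    negative when the available oxygen cannot even keep the cells alive)."""
    need = (1.0 - beta) / 6.0 * params.K_ATP * delta_tau
    denom = (params.lambda_ - 1.0) * l * (params.cc / delta_tau) * need
    return (O_av - l * need) / denom


def mitosis_rate_glucose(
    beta: float, Gl_av: float, l: float, params: ModelParams, delta_tau: float
) -> float:
    """Glucose-limited mitosis rate ``a_gl(beta)`` (decreasing in beta)."""
    need = (17.0 * beta + 1.0) / 36.0 * params.K_ATP * delta_tau
    denom = (params.lambda_ - 1.0) * l * (params.cc / delta_tau) * need
    return (Gl_av - l * need) / denom


def tumor_cell_step(
    l: float,
    nc: float,
    O_av: float,
    Gl_av: float,
    params: ModelParams,
    delta_tau: float,
    u: float,
) -> tuple[float, float, float, float, float, float]:
    """Step 2 for one voxel: tumor proliferation or starvation necrosis.

    ``u ~ Uniform[0, 1)`` drives the glycolysis-fraction draw (pass a fixed
    value to make the step deterministic).  Returns
    ``(l_next, nc_next, o_next, gl_next, beta_t, a_t)``.
    """
    p, dt = params, delta_tau
    if l == 0.0:
        return l, nc, O_av, Gl_av, math.nan, 0.0
    Katp, lam, ccs, amax = p.K_ATP, p.lambda_, p.cc / dt, p.a_max
    E = l * Katp * dt
    beta_lo = 1.0 - 6.0 * O_av / E
    beta_hi = (36.0 * Gl_av / E - 1.0) / 17.0
    lo = max(beta_lo, p.beta1)
    hi = min(beta_hi, p.beta2)
    infeasible = beta_lo > p.beta2 or beta_hi < p.beta1 or hi < lo
    if infeasible:
        bt = p.beta1 + u * (p.beta2 - p.beta1)
        needO = (1.0 - bt) / 6.0 * Katp * dt
        needG = (17.0 * bt + 1.0) / 36.0 * Katp * dt
        if bt != 1.0:
            Nc = min(O_av / needO, Gl_av / needG)
        else:
            Nc = Gl_av / needG
        if Nc < 0.0:
            Nc = 0.0
        o_n = O_av - Nc * needO
        gl_n = Gl_av - Nc * needG
        l_n, nc_n, a_t = Nc, nc + (l - Nc), 0.0
    else:
        bt = lo + u * (hi - lo)
        needO = (1.0 - bt) / 6.0 * Katp * dt
        needG = (17.0 * bt + 1.0) / 36.0 * Katp * dt
        denom = (lam - 1.0) * l * ccs
        if bt != 1.0:
            a_t = min((O_av - l * needO) / (denom * needO),
                      (Gl_av - l * needG) / (denom * needG), amax)
        else:
            a_t = min((Gl_av - l * needG) / (denom * needG), amax)
        prolif = (lam - 1.0) * a_t * l * ccs
        o_n = O_av - l * needO - prolif * needO
        gl_n = Gl_av - l * needG - prolif * needG
        l_n, nc_n = l + a_t * l, nc
    if o_n < 0.0:
        o_n = 0.0
    if gl_n < 0.0:
        gl_n = 0.0
    if l_n < params.extinction_threshold:
        nc_n = nc_n + l_n
        l_n = 0.0
    return l_n, nc_n, o_n, gl_n, bt, a_t


# --- compiled lattice sweep -------------------------------------------------


@njit(cache=True)
def _metabolism_sweep(
    l, nc, nn, o, gl, ob, glb, u,
    M, Ko, Kgl, Katp, lam, cc_steps, amax, b1, b2, dt, ext,
):  # pragma: no cover - exercised through apply_metabolism
    n = l.shape[0]
    for v in range(n):
        # Step 1: host cells
        ln = M - l[v] - nc[v] - nn[v]
        if ln < 0.0:
            ln = 0.0
        avail_o = o[v] + ob[v] * dt
        avail_gl = gl[v] + glb[v] * dt
        O1 = avail_o - ln * Ko * dt
        Gl1 = avail_gl - ln * Kgl * dt
        if O1 >= 0.0 and Gl1 >= 0.0:
            O_av = O1
            Gl_av = Gl1
        else:
            N_n = min(avail_o / (Ko * dt), avail_gl / (Kgl * dt))
            if N_n < 0.0:
                N_n = 0.0
            O_av = avail_o - N_n * Ko * dt
            Gl_av = avail_gl - N_n * Kgl * dt
            if O_av < 0.0:
                O_av = 0.0
            if Gl_av < 0.0:
                Gl_av = 0.0
            nn[v] = nn[v] + (ln - N_n)
        # Step 2: tumor cells
        if l[v] == 0.0:
            o[v] = O_av
            gl[v] = Gl_av
            continue
        E = l[v] * Katp * dt
        beta_lo = 1.0 - 6.0 * O_av / E
        beta_hi = (36.0 * Gl_av / E - 1.0) / 17.0
        lo = max(beta_lo, b1)
        hi = min(beta_hi, b2)
        infeasible = beta_lo > b2 or beta_hi < b1 or hi < lo
        if infeasible:
            bt = b1 + u[v] * (b2 - b1)
            needO = (1.0 - bt) / 6.0 * Katp * dt
            needG = (17.0 * bt + 1.0) / 36.0 * Katp * dt
            if bt != 1.0:
                Nc = min(O_av / needO, Gl_av / needG)
            else:
                Nc = Gl_av / needG
            if Nc < 0.0:
                Nc = 0.0
            o_n = O_av - Nc * needO
            gl_n = Gl_av - Nc * needG
            nc[v] = nc[v] + (l[v] - Nc)
            l_n = Nc
        else:
            bt = lo + u[v] * (hi - lo)
            needO = (1.0 - bt) / 6.0 * Katp * dt
            needG = (17.0 * bt + 1.0) / 36.0 * Katp * dt
            denom = (lam - 1.0) * l[v] * cc_steps
            if bt != 1.0:
                a_t = min((O_av - l[v] * needO) / (denom * needO),
                          (Gl_av - l[v] * needG) / (denom * needG), amax)
            else:
                a_t = min((Gl_av - l[v] * needG) / (denom * needG), amax)
            prolif = (lam - 1.0) * a_t * l[v] * cc_steps
            o_n = O_av - l[v] * needO - prolif * needO
            gl_n = Gl_av - l[v] * needG - prolif * needG
            l_n = l[v] + a_t * l[v]
        if o_n < 0.0:
            o_n = 0.0
        if gl_n < 0.0:
            gl_n = 0.0
        if l_n < ext:
            nc[v] = nc[v] + l_n
            l_n = 0.0
        l[v] = l_n
        o[v] = o_n
        gl[v] = gl_n


def apply_metabolism(state, params: ModelParams, rng: np.random.Generator,
                     beta_draws: np.ndarray | None = None):
    """Apply F_pn to every voxel of a simulation state (in place).

    ``state.o_b`` / ``state.gl_b`` must already hold the supply rates for the
    current interval (computed by the vascular-remodeling operator).  One
    uniform draw per voxel feeds the glycolysis-fraction choice; pass
    ``beta_draws`` to stub the randomness.
    """
    if beta_draws is None:
        beta_draws = rng.random(state.l.shape[0])
    _metabolism_sweep(
        state.l, state.nc, state.nn, state.o, state.gl,
        state.o_b, state.gl_b, beta_draws,
        params.M, params.K_o, params.K_gl, params.K_ATP, params.lambda_,
        params.cc / state.delta_tau, params.a_max, params.beta1, params.beta2,
        state.delta_tau, params.extinction_threshold,
    )
    return state
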