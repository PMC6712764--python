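"""Vascular remodeling operator F_vr: nutrient supply rates and their caps.

The local vascular network acts as a buffer: when the tissue stock of a
substance in a voxel is below (above) its constant blood-side level —
``o0_bar`` for oxygen, ``gl0_bar`` for glucose — the supply rate relaxes
upward (downward) by a random fraction of the imbalance per step::

    o_b'  = o_b  + r1 * (o0_bar  - o)  / dt      r1, r2 ~ Uniform[0, 1]
    gl_b' = gl_b + r2 * (gl0_bar - gl) / dt

Supply rates may be negative (the vasculature can absorb), but are clipped to
``[-cap, +cap]`` where the caps ``o_b_max`` / ``gl_b_max`` quantify the local
vessel density.  In tumor-free voxels the caps are constant (Case 1).  In
voxels the tumor has reached (``l + nc > 0``, Case 2) both caps evolve by the
same stochastic multiplicative factor::

    1 - f_r * r3 * v_r + sw * f_e * r4 * v_e     r3, r4 ~ Uniform[0, 1]

with occupancy-driven regression weight ``f_r = (l + nc) / M`` and expansion
weight ``f_e = (M - l - nc - nn) / M``, both sanity-clamped to [0, 1];
``v_r`` / ``v_e`` are the maximum per-step regression and expansion rates and
``sw`` is the per-voxel angiogenesis switch, set at the end of each step when
a voxel holds live tumor cells and is hypoxic (``o < h_o * o0_bar``) or
hypoglycemic (``gl < h_gl * gl0_bar``).
"""

from __future__ import annotations

import numpy as np
from numba import njit

from .metabolism import ModelParams

__all__ = ["clip", "update_switch", "apply_vascular_remodeling"]


def clip(x: float, mu: float):
    """Symmetric clamp ``B_mu``: the value of ``x`` limited to [-mu, mu]."""
    if np.any(np.asarray(mu) < 0):
        raise ValueError("mu must be nonnegative")
    return np.minimum(np.maximum(x, -mu), mu)


def update_switch(state, params: ModelParams) -> np.ndarray:
    """Recompute the per-voxel angiogenesis switch from the current fields.

    ``sw(A) = 1`` iff the voxel holds live tumor cells and either stock is
    below its hypoxia/hypoglycemia threshold.  When angiogenesis is disabled
    in the parameters the switch is identically zero.
    """
    if not params.angiogenesis_enabled:
        return np.zeros(state.sw.shape[0])
    low = (state.o < params.h_o * params.o0_bar) | (
        state.gl < params.h_gl * params.gl0_bar
    )
    return ((state.l > 0) & low).astype(np.float64)


@njit(cache=True)
def _vascular_sweep(
    l, nc, nn, o, gl, ob, glb, obm, glbm, sw,
    r1, r2, r3, r4, M, v_r, v_e, o0, gl0, dt,
):  # pragma: no cover - exercised through apply_vascular_remodeling
    n = l.shape[0]
    for v in range(n):
        if l[v] + nc[v] > 0.0:
            fr = (l[v] + nc[v]) / M
            if fr > 1.0:
                fr = 1.0
            if fr < 0.0:
                fr = 0.0
            fe = (M - l[v] - nc[v] - nn[v]) / M
            if fe > 1.0:
                fe = 1.0
            if fe < 0.0:
                fe = 0.0
            factor = 1.0 - fr * r3[v] * v_r + sw[v] * fe * r4[v] * v_e
            om = obm[v] * factor
            gm = glbm[v] * factor
            if om < 0.0:
                om = 0.0
            if gm < 0.0:
                gm = 0.0
            obm[v] = om
            glbm[v] = gm
        obv = ob[v] + r1[v] * ((o0 - o[v]) / dt)
        if obv > obm[v]:
            obv = obm[v]
        elif obv < -obm[v]:
            obv = -obm[v]
        ob[v] = obv
        glbv = glb[v] + r2[v] * ((gl0 - gl[v]) / dt)
        if glbv > glbm[v]:
            glbv = glbm[v]
        elif glbv < -glbm[v]:
            glbv = -glbm[v]
        glb[v] = glbv


def apply_vascular_remodeling(state, params: ModelParams,
                              rng: np.random.Generator,
                              draws: np.ndarray | None = None):
    """Apply F_vr to every voxel (in place): caps first, then relaxed and
    clipped supply rates for the upcoming interval.

    ``draws`` may supply a stubbed ``(4, N^3)`` array of uniforms
    (r1, r2, r3, r4 rows); by default they are drawn from ``rng``.
    """
    if draws is None:
        draws = rng.random((4, state.l.shape[0]))
    r1, r2, r3, r4 = draws
    _vascular_sweep(
        state.l, state.nc, state.nn, state.o, state.gl,
        state.o_b, state.gl_b, state.o_b_max, state.gl_b_max,
        np.asarray(state.sw, dtype=np.float64),
        r1, r2, r3, r4,
        params.M, params.v_r, params.v_e,
        params.o0_bar, params.gl0_bar, state.delta_tau,
    )
    return state
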