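"""Vascular remodeling: clipping, the angiogenesis switch, cap evolution."""

import numpy as np
import pytest

from tumorvox import ModelParams, apply_vascular_remodeling, clip, update_switch

DT = 10.0


class _State:
    delta_tau = DT


def make_state(n, p, seed=0, tumor=False):
    rng = np.random.default_rng(seed)
    st = _State()
    st.l = rng.random(n) * p.M * 1.2 if tumor else np.zeros(n)
    st.nc = rng.random(n) * p.M * 0.3 if tumor else np.zeros(n)
    st.nn = rng.random(n) * p.M * 0.3 if tumor else np.zeros(n)
    st.o = np.full(n, p.o0_bar)
    st.gl = np.full(n, p.gl0_bar)
    st.o_b = np.full(n, p.M * p.K_o)
    st.gl_b = np.full(n, p.M * p.K_gl)
    st.o_b_max = np.full(n, p.o_b_max0)
    st.gl_b_max = np.full(n, p.gl_b_max0)
    st.sw = np.zeros(n)
    return st


@pytest.mark.parametrize("x, mu, expected", [(7, 5, 5), (-7, 5, -5), (3, 5, 3),
                                             (-3, 5, -3), (0, 0, 0)])
def test_clip_piecewise(x, mu, expected):
    assert clip(x, mu) == expected


def test_clip_rejects_negative_mu():
    with pytest.raises(ValueError):
        clip(1.0, -1.0)


def test_switch_requires_tumor_and_deficit():
    p = ModelParams()
    st = make_state(4, p)
    st.l = np.array([0.0, 10.0, 10.0, 10.0])
    st.o = np.array([0.1, 0.29, 1.0, 1.0]) * p.o0_bar
    st.gl = np.array([1.0, 1.0, 0.49, 1.0]) * p.gl0_bar
    sw = update_switch(st, p)
    # no tumor -> off; hypoxic -> on; hypoglycemic -> on; satisfied -> off
    np.testing.assert_array_equal(sw, [0, 1, 1, 0])


def test_switch_forced_off_when_angiogenesis_disabled():
    p = ModelParams(angiogenesis_enabled=False)
    st = make_state(3, p)
    st.l = np.full(3, 10.0)
    st.o = np.zeros(3)
    np.testing.assert_array_equal(update_switch(st, p), 0.0)


def test_balanced_tumor_free_state_unchanged():
    p = ModelParams()
    st = make_state(50, p)
    draws = np.random.default_rng(1).random((4, 50))
    apply_vascular_remodeling(st, p, rng=None, draws=draws)
    np.testing.assert_array_equal(st.o_b, p.M * p.K_o)
    np.testing.assert_array_equal(st.gl_b, p.M * p.K_gl)
    np.testing.assert_array_equal(st.o_b_max, p.o_b_max0)  # Case 1: caps frozen


def test_fully_necrotic_voxel_regresses_at_v_r():
    """Occupancy l + nc = M with r3 stubbed to one: caps shrink by (1 - v_r)."""
    p = ModelParams()
    st = make_state(1, p)
    st.nc[0] = p.M
    draws = np.array([[0.0], [0.0], [1.0], [1.0]])
    apply_vascular_remodeling(st, p, rng=None, draws=draws)
    assert st.o_b_max[0] == pytest.approx(p.o_b_max0 * (1 - p.v_r), rel=1e-12)
    assert st.gl_b_max[0] == pytest.approx(p.gl_b_max0 * (1 - p.v_r), rel=1e-12)


def test_tumor_edge_voxel_expands_when_switch_on():
    p = ModelParams()
    st = make_state(1, p)
    st.l[0] = 0.25 * p.M
    st.sw[0] = 1.0
    draws = np.ones((4, 1))
    apply_vascular_remodeling(st, p, rng=None, draws=draws)
    fr, fe = 0.25, 0.75
    factor = 1 - fr * p.v_r + fe * p.v_e
    assert st.o_b_max[0] == pytest.approx(p.o_b_max0 * factor, rel=1e-12)


def test_occupancy_fractions_are_sanity_clamped():
    p = ModelParams()
    st = make_state(1, p)
    st.l[0] = 3.0 * p.M  # transiently overfull voxel
    draws = np.array([[0.0], [0.0], [1.0], [0.0]])
    apply_vascular_remodeling(st, p, rng=None, draws=draws)
    assert st.o_b_max[0] == pytest.approx(p.o_b_max0 * (1 - p.v_r))  # f_r -> 1


def test_supply_always_clipped_by_caps():
    p = ModelParams()
    rng = np.random.default_rng(3)
    st = make_state(500, p, tumor=True, seed=4)
    st.o = rng.random(500) * 3 * p.o0_bar
    st.gl = rng.random(500) * 3 * p.gl0_bar
    st.sw = (rng.random(500) < 0.5).astype(float)
    for _ in range(50):
        apply_vascular_remodeling(st, p, rng)
        assert np.all(np.abs(st.o_b) <= st.o_b_max + 1e-12)
        assert np.all(np.abs(st.gl_b) <= st.gl_b_max + 1e-12)
        assert np.all(st.o_b_max >= 0) and np.all(st.gl_b_max >= 0)


def test_caps_share_one_multiplicative_history():
    """o_b_max and gl_b_max stay proportional, so a single capacity rendering
    is valid for both species."""
    p = ModelParams()
    st = make_state(200, p, tumor=True, seed=5)
    rng = np.random.default_rng(6)
    for _ in range(100):
        apply_vascular_remodeling(st, p, rng)
    ratio = st.o_b_max / st.gl_b_max
    np.testing.assert_allclose(ratio, p.o_b_max0 / p.gl_b_max0, rtol=1e-9)


def test_caps_non_increasing_without_angiogenesis():
    p = ModelParams()
    st = make_state(200, p, tumor=True, seed=7)
    st.sw[:] = 0.0
    caps0 = st.o_b_max.copy()
    apply_vascular_remodeling(st, p, np.random.default_rng(8))
    assert np.all(st.o_b_max <= caps0 + 1e-15)


def oracle_voxel(l, nc, nn, o, gl, ob, glb, obm, glbm, sw, r, p, dt):
    """Independent scalar re-implementation of F_vr for one voxel."""
    r1, r2, r3, r4 = r
    if l + nc > 0:
        fr = min(max((l + nc) / p.M, 0.0), 1.0)
        fe = min(max((p.M - l - nc - nn) / p.M, 0.0), 1.0)
        factor = 1.0 - fr * r3 * p.v_r + sw * fe * r4 * p.v_e
        obm = max(obm * factor, 0.0)
        glbm = max(glbm * factor, 0.0)
    ob = min(max(ob + r1 * ((p.o0_bar - o) / dt), -obm), obm)
    glb = min(max(glb + r2 * ((p.gl0_bar - gl) / dt), -glbm), glbm)
    return ob, glb, obm, glbm


def test_vectorized_sweep_matches_scalar_oracle_exactly():
    p = ModelParams()
    n = 3000
    rng = np.random.default_rng(11)
    st = make_state(n, p, tumor=True, seed=12)
    st.l[rng.random(n) < 0.3] = 0.0
    st.nc[rng.random(n) < 0.5] = 0.0
    st.o = rng.random(n) * 2 * p.o0_bar
    st.gl = rng.random(n) * 2 * p.gl0_bar
    st.o_b = (rng.random(n) * 2 - 1) * p.o_b_max0
    st.gl_b = (rng.random(n) * 2 - 1) * p.gl_b_max0
    st.sw = (rng.random(n) < 0.5).astype(float)
    draws = rng.random((4, n))
    expect = [
        oracle_voxel(st.l[i], st.nc[i], st.nn[i], st.o[i], st.gl[i],
                     st.o_b[i], st.gl_b[i], st.o_b_max[i], st.gl_b_max[i],
                     st.sw[i], draws[:, i], p, DT)
        for i in range(n)
    ]
    apply_vascular_remodeling(st, p, rng=None, draws=draws)
    got = np.column_stack([st.o_b, st.gl_b, st.o_b_max, st.gl_b_max])
    np.testing.assert_array_equal(got, np.array(expect))
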