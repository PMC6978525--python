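"""STICS velocimetry and directional-coherence statistics."""

import numpy as np
import pandas as pd
import pytest

import difftrack as dtk
from difftrack.stics import compare_flow_fractions, directional_coherence


def _stack(data, px=0.1, dt=2.0):
    return dtk.ImageStack(np.asarray(data, float), px, dt)


# --------------------------------------------------------- immobile filter
def test_immobile_filter_static_stack_is_zero():
    stack = _stack(np.tile(np.random.default_rng(0).random((8, 8)), (25, 1, 1)))
    out = dtk.immobile_filter(stack, window=20)
    assert np.allclose(out.data, 0.0)


def test_immobile_filter_dc_invariance():
    rng = np.random.default_rng(1)
    base = rng.random((25, 8, 8))
    a = dtk.immobile_filter(_stack(base), 20).data
    b = dtk.immobile_filter(_stack(base + 123.0), 20).data
    assert np.allclose(a, b)


def test_immobile_filter_window_too_long():
    with pytest.raises(ValueError, match="exceeds stack length"):
        dtk.immobile_filter(_stack(np.zeros((5, 4, 4))), window=20)


def test_immobile_filter_preserves_moving_spot():
    T, H, W = 30, 40, 40
    rng = np.random.default_rng(2)
    background = np.tile(50 + 10 * rng.random((H, W)), (T, 1, 1))
    data = background.copy()
    for t in range(T):
        data[t, 18:22, 3 + t] += 100.0  # moving bright spot
    out = dtk.immobile_filter(_stack(data), 20).data
    # background energy (away from the spot trail) strongly suppressed
    static_region = out[:, :10, :]
    raw_static = (background[:, :10, :] - background[:, :10, :].mean()) ** 2
    assert static_region.var() < 0.05 * background[:, :10, :].var() + 1e-9
    # the moving spot survives
    assert out.max() > 50


def test_immobile_filter_fourier_mode():
    rng = np.random.default_rng(3)
    base = rng.random((10, 6, 6))
    out = dtk.immobile_filter(_stack(base), method="fourier").data
    assert np.allclose(out.mean(axis=0), 0.0, atol=1e-12)


# ------------------------------------------------------------- velocimetry
def test_stics_recovers_uniform_flow():
    # 0.5 px/frame, 0.1 um/px, 2 s -> 1.5 um/min
    stack, _ = dtk.simulate_flow_stack(("uniform", 0.025, 0.0), shape=(64, 64),
                                       n_frames=20, pixel_size=0.1,
                                       frame_interval=2.0, noise=2.0, seed=5)
    field = dtk.stics_vectors(stack, sub=8, sub_shift=2, toi=5, toi_shift=3)
    v = field[field["valid"]]
    assert len(v) / len(field) > 0.8
    frac = np.mean(np.abs(v["speed_um_min"] - 1.5) / 1.5 <= 0.1)
    assert frac >= 0.9
    # direction along +x
    ang = np.degrees(np.arctan2(v["vy_um_min"], v["vx_um_min"]))
    assert np.abs(np.median(ang)) < 5


def test_stics_zero_flow_noise_floor():
    stack, _ = dtk.simulate_flow_stack(("zero",), shape=(64, 64), n_frames=20,
                                       pixel_size=0.1, frame_interval=2.0,
                                       noise=2.0, seed=6)
    field = dtk.stics_vectors(stack, sub=8, sub_shift=2, toi=5, toi_shift=3)
    v = field[field["valid"]]
    assert v["speed_um_min"].median() < 0.15  # 10% of 1.5 um/min


def test_stics_radial_direction_accuracy():
    stack, truth = dtk.simulate_flow_stack(("radial_in", 0.02), shape=(64, 64),
                                           n_frames=20, pixel_size=0.1,
                                           frame_interval=2.0, noise=1.0, seed=7)
    field = dtk.stics_vectors(stack, sub=8, sub_shift=2, toi=5, toi_shift=3)
    v = field[field["valid"]]
    tv = truth.velocity(v[["x_um", "y_um"]].to_numpy())
    mv = v[["vx_um_min", "vy_um_min"]].to_numpy()
    norm = np.hypot(*mv.T) * np.hypot(*tv.T)
    keep = norm > 0
    cos = np.sum(mv * tv, axis=1)[keep] / norm[keep]
    ang = np.degrees(np.arccos(np.clip(cos, -1, 1)))
    assert np.median(ang) < 15


def test_stics_short_stack_warns():
    stack = _stack(np.zeros((3, 40, 40)))
    with pytest.warns(UserWarning, match="TOI"):
        field = dtk.stics_vectors(stack, toi=5)
    assert field.shape[0] == 0


# --------------------------------------------------------------- coherence
def _field(rows):
    return pd.DataFrame(rows, columns=["x_um", "y_um", "vx_um_min",
                                       "vy_um_min", "speed_um_min", "valid"])


def test_coherence_cardinal_directions():
    centroid = (0.0, 0.0)
    f = _field([
        (1.0, 0.0, -2.0, 0.0, 2.0, True),   # toward centroid -> +1
        (1.0, 0.0, 2.0, 0.0, 2.0, True),    # away -> -1
        (1.0, 0.0, 0.0, 2.0, 2.0, True),    # perpendicular -> 0
        (2.0, 0.0, 0.0, 0.0, 0.0, True),    # zero vector -> excluded
        (9.0, 9.0, 5.0, 5.0, 7.1, False),   # invalid -> excluded
    ])
    res = directional_coherence(f, centroid)
    assert res.n == 3
    assert np.allclose(np.sort(res.coherence), [-1.0, 0.0, 1.0])
    assert res.inward_fraction == pytest.approx(1 / 3)
    assert res.outward_fraction == pytest.approx(1 / 3)
    r, pdf = res.pdf(bins=10)
    assert np.sum(pdf) * 0.2 == pytest.approx(1.0)  # density normalization


def test_coherence_of_synthetic_radial_fields():
    stack_in, _ = dtk.simulate_flow_stack(("radial_in", 0.02), shape=(64, 64),
                                          n_frames=20, pixel_size=0.1,
                                          frame_interval=2.0, noise=1.0, seed=8)
    f_in = dtk.stics_vectors(stack_in, sub=8, sub_shift=2, toi=5, toi_shift=3)
    c_in = directional_coherence(f_in, (3.2, 3.2))
    assert c_in.inward_fraction >= 0.95

    stack_out, _ = dtk.simulate_flow_stack(("radial_out", 0.02), shape=(64, 64),
                                           n_frames=20, pixel_size=0.1,
                                           frame_interval=2.0, noise=1.0, seed=9)
    f_out = dtk.stics_vectors(stack_out, sub=8, sub_shift=2, toi=5, toi_shift=3)
    c_out = directional_coherence(f_out, (3.2, 3.2))
    assert c_out.outward_fraction >= 0.95

    z, p = compare_flow_fractions(c_in.inward_fraction, c_in.n,
                                  c_out.inward_fraction, c_out.n)
    assert p < 1e-3


# ------------------------------------------------------------------ z-test
def test_ztest_equal_fractions():
    z, p = compare_flow_fractions(0.2, 100, 0.2, 100)
    assert z == 0.0
    assert p == 1.0


def test_ztest_matches_hand_formula():
    f1, n1, f2, n2 = 143 / 1000, 1000, 450 / 1000, 1000
    z, p = compare_flow_fractions(f1, n1, f2, n2)
    pooled = (f1 * n1 + f2 * n2) / (n1 + n2)
    z_hand = (f1 - f2) / np.sqrt(pooled * (1 - pooled) * (1 / n1 + 1 / n2))
    from scipy.stats import norm
    p_hand = 2 * norm.sf(abs(z_hand))
    assert z == pytest.approx(z_hand, abs=1e-10)
    assert p == pytest.approx(p_hand, abs=1e-12)


def test_ztest_symmetry_and_degenerate():
    z1, p1 = compare_flow_fractions(0.1, 200, 0.3, 150)
    z2, p2 = compare_flow_fractions(0.3, 150, 0.1, 200)
    assert z1 == pytest.approx(-z2)
    assert p1 == pytest.approx(p2)
    z0, p0 = compare_flow_fractions(0.0, 50, 0.0, 70)
    assert (z0, p0) == (0.0, 1.0)
    with pytest.raises(ValueError):
        compare_flow_fractions(0.5, 0, 0.5, 10)
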