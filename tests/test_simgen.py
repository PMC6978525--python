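"""Trajectory / movie / flow generators: ground-truth statistics."""

import numpy as np
import pandas as pd
import pytest

import difftrack as dtk
from conftest import DT


def test_zero_motion_particles_are_static():
    cfg = dtk.SimConfig(state_diffusivities=[0.0], state_loc_sigma=[0.0],
                        track_length_law=("fixed", 20), n_tracks=20,
                        frames_per_burst=20, seed=1)
    tr = dtk.simulate_trackset(cfg)
    for _, g in tr.groupby("particle_id"):
        assert np.allclose(g["x_um"], g["x_um"].iloc[0])
        assert np.allclose(g["y_um"], g["y_um"].iloc[0])


def test_ensemble_msd_lag1_matches_4Ddt():
    # no blur, no noise: MSD(1) = 4 D dt
    cfg = dtk.SimConfig(state_diffusivities=[0.1], state_loc_sigma=[0.0],
                        exposure_fraction=0.0, track_length_law=("fixed", 15),
                        n_tracks=10_000, frames_per_burst=15,
                        mask=dtk.DiskMask(100.0), seed=2)
    tr = dtk.simulate_trackset(cfg)
    m = dtk.emsd(tr, 1)
    assert m["msd"].iloc[0] == pytest.approx(4 * 0.1 * DT, rel=0.02)


def test_emsd_matches_blur_noise_closed_form():
    # full closed form 4 D n dt + 4 sigma^2 - 8 R D dt for n = 1..10
    D, sigma = 0.1, 0.03
    cfg = dtk.SimConfig(state_diffusivities=[D], state_loc_sigma=[sigma],
                        track_length_law=("fixed", 15), n_tracks=8000,
                        frames_per_burst=15, mask=dtk.DiskMask(100.0), seed=3)
    tr = dtk.simulate_trackset(cfg)
    m = dtk.emsd(tr, 10)
    expected = dtk.emsd_expected(10, D, sigma, DT, R=cfg.blur_R)
    assert np.allclose(m["msd"], expected, rtol=0.05)
    assert np.all(np.diff(m["n_pairs"]) < 0)


def test_two_state_occupancy_converges_to_stationary():
    P = np.array([[0.9, 0.1], [0.1, 0.9]])
    cfg = dtk.SimConfig(state_diffusivities=[0.01, 0.1],
                        state_loc_sigma=[0.02, 0.05],
                        per_frame_transition_matrix=P,
                        initial_fractions=[1.0, 0.0],  # start far from stationary
                        track_length_law=("fixed", 400), n_tracks=200,
                        frames_per_burst=400, mask=dtk.DiskMask(20.0), seed=4)
    tr = dtk.simulate_trackset(cfg)
    occ = (tr["true_state"] == 0).mean()
    assert occ == pytest.approx(0.5, abs=0.02)


def test_seed_determinism_and_frame_contiguity():
    cfg = dict(state_diffusivities=[0.05], state_loc_sigma=[0.03],
               track_length_law=("geometric", 40.0), n_tracks=50, seed=5)
    a = dtk.simulate_trackset(dtk.SimConfig(**cfg))
    b = dtk.simulate_trackset(dtk.SimConfig(**cfg))
    pd.testing.assert_frame_equal(a, b)
    for _, g in a.groupby("particle_id"):
        assert np.all(np.diff(g["frame"]) == 1)


def test_positions_stay_inside_mask():
    mask = dtk.DiskMask(3.0)
    cfg = dtk.SimConfig(state_diffusivities=[0.5], state_loc_sigma=[0.0],
                        track_length_law=("fixed", 100), n_tracks=50,
                        frames_per_burst=100, mask=mask, seed=6)
    tr = dtk.simulate_trackset(cfg)
    assert mask.contains(tr[["x_um", "y_um"]].to_numpy()).all()


def test_cluster_states_confined_to_disks():
    cfg = dtk.SimConfig(state_diffusivities=[0.005, 0.2],
                        state_loc_sigma=[0.0, 0.0],
                        initial_fractions=[0.5, 0.5],
                        cluster_spec={0: (5, 0.2)},
                        track_length_law=("fixed", 30), n_tracks=200,
                        frames_per_burst=30, mask=dtk.DiskMask(5.0), seed=7)
    tr = dtk.simulate_trackset(cfg)
    slow = tr[tr.groupby("particle_id")["true_state"].transform("first") == 0]
    # every slow particle's spread is bounded by its cluster-disk diameter
    for _, g in slow.groupby("particle_id"):
        span = max(g["x_um"].max() - g["x_um"].min(),
                   g["y_um"].max() - g["y_um"].min())
        assert span <= 0.4 + 1e-9


def test_config_validation_errors():
    with pytest.raises(ValueError, match="configuration error"):
        dtk.SimConfig(state_diffusivities=[0.1, 0.2], state_loc_sigma=[0.03])
    with pytest.raises(ValueError, match="sum to 1"):
        dtk.SimConfig(state_diffusivities=[0.1, 0.2],
                      state_loc_sigma=[0.02, 0.03],
                      per_frame_transition_matrix=np.array([[0.5, 0.4],
                                                            [0.1, 0.9]]))
    with pytest.raises(ValueError, match="exposure_fraction"):
        dtk.SimConfig(exposure_fraction=1.5)


def test_render_empty_and_zero_photon_cases():
    empty = pd.DataFrame(columns=["particle_id", "burst", "frame", "x_um", "y_um"])
    stack = dtk.render_spot_movie(empty, 0.15, 1000, 50.0, "none")
    assert np.all(stack.data == 50.0)
    one = pd.DataFrame({"particle_id": [0], "burst": [0], "frame": [0],
                        "x_um": [1.0], "y_um": [1.0]})
    stack0 = dtk.render_spot_movie(one, 0.15, 0.0, 7.0, "none",
                                   extent=(0, 0, 2, 2))
    assert np.all(stack0.data == 7.0)


def test_render_static_emitter_centroid_matches_truth():
    x, y = 0.503, 0.748
    tr = pd.DataFrame({"particle_id": 0, "burst": 0, "frame": range(3),
                       "x_um": x, "y_um": y})
    # roomy extent: no PSF truncation at the image border
    stack = dtk.render_spot_movie(tr, 0.15, 1000, 0.0, "none",
                                  pixel_size=0.1, extent=(-1, -1, 2.5, 2.5))
    xs, ys = stack.pixel_centers()
    for frame in stack.data:
        tot = frame.sum()
        cx = (frame.sum(axis=0) * xs).sum() / tot
        cy = (frame.sum(axis=1) * ys).sum() / tot
        assert abs(cx - x) < 1e-3 * 0.1  # 1e-3 pixel
        assert abs(cy - y) < 1e-3 * 0.1


def test_render_rejects_out_of_extent_particle():
    tr = pd.DataFrame({"particle_id": [7], "burst": [0], "frame": [0],
                       "x_um": [5.0], "y_um": [5.0]})
    with pytest.raises(ValueError, match="particle 7"):
        dtk.render_spot_movie(tr, 0.15, 100, 0.0, "none", extent=(0, 0, 2, 2))


def test_flow_zero_field_frames_identical():
    stack, truth = dtk.simulate_flow_stack(("zero",), n_frames=5, noise=0.0, seed=8)
    assert np.allclose(stack.data, stack.data[0])
    assert np.all(truth.velocity(np.array([[1.0, 2.0]])) == 0)


def test_flow_integer_shift_is_exact_translation():
    # 1 px/frame: 0.05 um/s at 0.1 um/px, 2 s interval
    stack, _ = dtk.simulate_flow_stack(("uniform", 0.05, 0.0), shape=(32, 32),
                                       n_frames=4, pixel_size=0.1,
                                       frame_interval=2.0, noise=0.0, seed=9)
    for t in range(4):
        assert np.allclose(stack.data[t],
                           np.roll(stack.data[0], t, axis=1), atol=1e-6)


def test_flow_radial_truth_points_at_centroid():
    stack, truth = dtk.simulate_flow_stack(("radial_in", 0.02), shape=(32, 32),
                                           n_frames=3, pixel_size=0.1,
                                           frame_interval=2.0, seed=10)
    rng = np.random.default_rng(0)
    pts = rng.uniform(0.5, 2.7, size=(50, 2))
    pts = pts[np.hypot(*(pts - truth.center).T) > 0.3]  # outside the core
    v = truth.velocity(pts)
    to_c = np.asarray(truth.center) - pts
    cos = np.sum(v * to_c, axis=1) / (np.hypot(*v.T) * np.hypot(*to_c.T))
    assert np.allclose(cos, 1.0)


def test_flow_aliasing_warning():
    with pytest.warns(UserWarning, match="aliasing"):
        dtk.simulate_flow_stack(("uniform", 0.5, 0.0), shape=(32, 32),
                                n_frames=3, pixel_size=0.1, frame_interval=2.0,
                                seed=11)


def test_trackset_csv_roundtrip(tmp_path):
    cfg = dtk.SimConfig(n_tracks=10, seed=12, track_length_law=("fixed", 20),
                        frames_per_burst=20)
    tr = dtk.simulate_trackset(cfg)
    path = tmp_path / "tracks.csv"
    dtk.write_trackset(tr, path, header_comment="test")
    back = dtk.read_trackset(path)
    pd.testing.assert_frame_equal(tr, back[tr.columns], check_dtype=False)


def test_stack_tiff_roundtrip(tmp_path):
    stack = dtk.ImageStack(np.random.default_rng(0).poisson(50, (3, 16, 16)).astype(np.uint16),
                           pixel_size=0.1, frame_interval=DT, origin=(1.0, 2.0))
    p = tmp_path / "stack.tif"
    stack.save(p)
    back = dtk.ImageStack.load(p)
    assert np.array_equal(back.data, stack.data)
    assert back.pixel_size == stack.pixel_size
    assert back.origin == stack.origin
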