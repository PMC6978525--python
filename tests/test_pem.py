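"""EM over diffusive states: likelihood model, fitting, model selection,
fractions and transition statistics."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import multivariate_normal

import difftrack as dtk
from difftrack import pem
from conftest import DT, R_FULL, mixture_segments, single_state_segments


# ------------------------------------------------- displacement covariance
def test_covariance_zero_params_zero_matrix():
    assert np.all(pem.displacement_covariance(0.0, 0.0, DT, R_FULL) == 0)


def test_covariance_pure_brownian_diagonal():
    C = pem.displacement_covariance(0.05, 0.0, DT, R=0.0)
    assert np.allclose(np.diag(C), 2 * 0.05 * DT)
    assert np.allclose(C - np.diag(np.diag(C)), 0)


def test_covariance_arithmetic_example():
    C = pem.displacement_covariance(0.1, 9e-4, dt=0.03, R=1 / 6)
    assert C[0, 0] == pytest.approx(0.0058)
    assert C[0, 1] == pytest.approx(1.0e-4)
    # symmetric tridiagonal Toeplitz
    assert np.allclose(C, C.T)
    assert np.all(C[np.abs(np.subtract.outer(range(14), range(14))) > 1] == 0)


# ----------------------------------------------------------------- loglik
def test_segment_loglik_matches_direct_bivariate_normal():
    dx = np.array([[0.1, -0.05]])
    dy = np.array([[0.02, 0.03]])
    D, s2 = 0.05, 4e-4
    C = pem.displacement_covariance(D, s2, DT, R_FULL, n_disp=2)
    expected = (multivariate_normal.logpdf(dx[0], mean=[0, 0], cov=C)
                + multivariate_normal.logpdf(dy[0], mean=[0, 0], cov=C))
    got = pem.segment_loglik(dx, dy, D, s2, DT, R_FULL)
    assert got[0] == pytest.approx(expected)


def test_loglik_scale_equivariance_of_argmax():
    rng = np.random.default_rng(0)
    dx = rng.normal(0, 0.05, (50, 14))
    dy = rng.normal(0, 0.05, (50, 14))
    Ds = np.logspace(-3, 0, 25)
    ll = np.array([pem.segment_loglik(dx, dy, D, 0.0, DT, 0.0).sum() for D in Ds])
    c = 3.0
    ll_scaled = np.array(
        [pem.segment_loglik(c * dx, c * dy, c**2 * D, 0.0, DT, 0.0).sum()
         for D in Ds]
    )
    assert np.argmax(ll) == np.argmax(ll_scaled)


def test_loglik_prefers_generating_parameters():
    _, dx, dy = single_state_segments(0.05, 0.03, 500, seed=11)
    good = pem.segment_loglik(dx, dy, 0.05, 9e-4, DT, R_FULL)
    bad = pem.segment_loglik(dx, dy, 0.5, 9e-4, DT, R_FULL)
    assert np.mean(good > bad) >= 0.99


def test_loglik_non_positive_definite_is_minus_inf():
    # sigma2 >> D dt makes b strongly negative but stays PD; force non-PD
    ll = pem.segment_loglik(np.zeros((1, 14)), np.zeros((1, 14)),
                            0.0, 0.0, DT, R_FULL)
    assert np.isneginf(ll[0])


# --------------------------------------------------------------------- EM
def test_em_single_state_matches_pooled_cve():
    segs, dx, dy = single_state_segments(0.08, 0.03, 800, seed=12)
    model, gamma = pem.em_fit(dx, dy, 1, DT, R_FULL, seed=0)
    rec = dtk.cve_estimate_segments(segs, DT, R_FULL)
    assert model.pi[0] == pytest.approx(1.0)
    assert model.D[0] == pytest.approx(rec["D_hat"].mean(), rel=0.05)
    assert np.allclose(gamma, 1.0)


def test_em_two_state_recovery_and_posteriors():
    dx, dy, labels = mixture_segments([0.01, 0.3], [0.02, 0.08], 1000, seed=20)
    model, gamma = pem.em_fit(dx, dy, 2, DT, R_FULL, seed=1)
    assert model.K == 2
    assert np.allclose(gamma.sum(axis=1), 1.0, atol=1e-9)
    assert model.D[0] == pytest.approx(0.01, rel=0.15)
    assert model.D[1] == pytest.approx(0.3, rel=0.15)
    assert np.allclose(model.pi, [0.5, 0.5], atol=0.05)
    acc = np.mean(pem.hard_labels(gamma) == labels)
    assert acc >= 0.95
    assert np.all(np.diff(model.D) > 0)  # sorted ascending


def test_em_loglik_monotone_from_random_inits():
    dx, dy, _ = mixture_segments([0.01, 0.3], [0.02, 0.08], 300, seed=21)
    rng = np.random.default_rng(2)
    for _ in range(8):
        model, _ = pem.em_fit(
            dx, dy, 3, DT, R_FULL,
            D_init=np.sort(rng.uniform(1e-3, 1.0, 3)),
            sigma2_init=rng.uniform(1e-5, 1e-2, 3),
            pi_init=rng.dirichlet(np.ones(3)),
        )
        h = model.loglik_history
        assert np.all(np.diff(h) >= -1e-8 * np.abs(h[-1]))


def test_pem_search_single_state_selects_k1():
    _, dx, dy = single_state_segments(0.05, 0.03, 600, seed=22)
    models, best_K = pem.pem_search(dx, dy, DT, R_FULL, K_max=4,
                                    n_reinit=3, n_perturb=6, seed=3)
    assert best_K == 1
    # richer nested models fit no worse at their optimum
    for K in range(1, 4):
        assert models[K + 1].loglik >= models[K].loglik - 1e-6 * abs(models[K].loglik)


def test_pem_bic_convention():
    _, dx, dy = single_state_segments(0.05, 0.03, 200, seed=23)
    model, _ = pem.em_fit(dx, dy, 1, DT, R_FULL, seed=0)
    model.bic = pem._bic(model, dx.shape[0])
    assert model.bic == pytest.approx(-2 * model.loglik + 2 * np.log(dx.shape[0]))


# -------------------------------------------------------------- fractions
def test_population_fractions_wilson_interval():
    labels = pd.DataFrame({"burst": 0, "label": [1] * 200 + [2] * 200})
    pf = pem.population_fractions(labels, 2)
    row = pf[pf["state"] == 1].iloc[0]
    assert row["fraction"] == 0.5
    assert row["ci_low"] == pytest.approx(0.451, abs=0.001)
    assert row["ci_high"] == pytest.approx(0.549, abs=0.001)
    # fractions sum to 1 per burst
    assert pf.groupby("burst")["fraction"].sum().iloc[0] == pytest.approx(1.0)


def test_population_fractions_single_state():
    pf = pem.population_fractions(pd.DataFrame({"burst": 1, "label": [2] * 50}), 2)
    full = pf[pf["state"] == 2].iloc[0]
    assert full["fraction"] == 1.0
    assert full["ci_high"] == pytest.approx(1.0)


# ------------------------------------------------------------- transitions
def _labels_df(seg_labels_per_track, track_length):
    recs = []
    for pid, labs in enumerate(seg_labels_per_track):
        for i, lab in enumerate(labs):
            recs.append((1000 * pid + i, pid, 0, i, lab, track_length))
    return pd.DataFrame(recs, columns=["segment_id", "particle_id", "burst",
                                       "seg_index", "label", "track_length"])


def test_transitions_identity_for_constant_labels():
    labels = _labels_df([[1, 1, 1], [2, 2, 2]], track_length=45)
    tm = pem.transitions(labels, 2)
    assert np.allclose(tm.freq, np.eye(2))
    assert tm.n_pairs == 4


def test_transitions_track_length_filter():
    # 30-frame tracks (2 segments) are excluded by the > 30 frames rule
    short = _labels_df([[1, 2]], track_length=30)
    assert pem.transitions(short, 2).n_pairs == 0
    ok = _labels_df([[1, 2]], track_length=31)
    tm = pem.transitions(ok, 2)
    assert tm.n_pairs == 1
    assert tm.counts[0, 1] == 1


def test_transitions_recover_block_markov_rate():
    P = np.array([[0.8, 0.2], [0.2, 0.8]])
    cfg = dtk.SimConfig(state_diffusivities=[0.01, 0.3],
                        state_loc_sigma=[0.02, 0.08],
                        per_frame_transition_matrix=P,
                        initial_fractions=[0.5, 0.5], switch_every=15,
                        track_length_law=("fixed", 60), n_tracks=500,
                        frames_per_burst=60, mask=dtk.DiskMask(30.0), seed=24)
    tracks = dtk.simulate_trackset(cfg)
    segs = dtk.filter_and_segment(tracks)
    lab = (segs.groupby("segment_id")
           .agg(particle_id=("particle_id", "first"), burst=("burst", "first"),
                seg_index=("seg_index", "first"),
                track_length=("track_length", "first"),
                label=("true_state", "first")).reset_index())
    lab["label"] += 1
    tm = pem.transitions(lab, 2, min_track_frames=31)
    assert tm.freq[0, 1] == pytest.approx(0.2, abs=0.05)
    assert tm.freq[1, 0] == pytest.approx(0.2, abs=0.05)


def test_transitions_empty_input_warns(caplog):
    empty = _labels_df([], track_length=0)
    tm = pem.transitions(empty, 3)
    assert tm.n_pairs == 0
    assert tm.zero_rows.all()
    assert np.isnan(tm.freq).all()
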