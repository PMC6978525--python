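import numpy as np
import pandas as pd
import pytest

import difftrack as dtk

DT = 1.0 / 33.0
R_FULL = 1.0 / 6.0


def single_state_segments(D, sigma, n_segments, seed, exposure_fraction=1.0,
                          mask_radius=100.0):
    """Simulate n 15-frame single-state tracks and return (segments, dx, dy)."""
    cfg = dtk.SimConfig(
        state_diffusivities=[D],
        state_loc_sigma=[sigma],
        exposure_fraction=exposure_fraction,
        track_length_law=("fixed", 15),
        n_tracks=n_segments,
        frames_per_burst=15,
        mask=dtk.DiskMask(mask_radius),
        seed=seed,
    )
    segs = dtk.filter_and_segment(dtk.simulate_trackset(cfg))
    ids, dx, dy = dtk.segment_displacements(segs)
    return segs, dx, dy


def mixture_segments(Ds, sigmas, n_per_state, seed):
    """Segments pooled from several single-state simulations, with labels."""
    dxs, dys, labels = [], [], []
    for k, (D, s) in enumerate(zip(Ds, sigmas)):
        _, dx, dy = single_state_segments(D, s, n_per_state, seed + 13 * k)
        dxs.append(dx)
        dys.append(dy)
        labels.append(np.full(n_per_state, k + 1))
    return np.vstack(dxs), np.vstack(dys), np.concatenate(labels)


def constructed_tracks(lengths):
    """A TrackSet with one track per requested length (random-walk coords)."""
    rng = np.random.default_rng(0)
    recs = []
    for pid, L in enumerate(lengths):
        recs.append(pd.DataFrame({
            "particle_id": pid,
            "burst": 0,
            "frame": np.arange(L),
            "x_um": np.cumsum(rng.normal(0, 0.05, L)),
            "y_um": np.cumsum(rng.normal(0, 0.05, L)),
        }))
    return pd.concat(recs, ignore_index=True)


@pytest.fixture(scope="session")
def cve_benchmark_segments():
    """The 10^4-segment single-state ensemble used for estimator checks."""
    return single_state_segments(0.1, 0.03, 10_000, seed=101)
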