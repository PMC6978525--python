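"""Pair-correlation analysis of state-sorted molecule positions.

g(r) is the normalized probability of finding a second molecule at distance
r from a typical molecule: 1 under complete spatial randomness (CSR), > 1
at short r for clustered organisation. To avoid analytic edge corrections
for irregular cell contours, the CSR expectation is computed by Monte Carlo:
the same pair-count estimator is applied to a dense uniform reference point
set drawn inside the same mask, so the mask geometry cancels.

To avoid over-weighting slow molecules that contribute many segments, only
the first position of each distinct particle enters, labeled by the
majority state over its segments; states are pooled in diffusivity-adjacent
pairs ({1,2}, {3,4}, ...) before correlation.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .geometry import Mask

__all__ = ["first_positions", "pool_state_pairs", "pair_correlation"]


def first_positions(segments: pd.DataFrame, labels: pd.DataFrame) -> pd.DataFrame:
    """One point per distinct particle: its first localization, with the
    particle's majority state label (ties broken toward the slower state).

    ``segments``: SegmentSet rows; ``labels``: per-segment ``segment_id,
    label``. Returns ``particle_id, burst, x_um, y_um, label``.
    """
    if segments.shape[0] == 0:
        return pd.DataFrame(columns=["particle_id", "burst", "x_um", "y_um", "label"])
    seg = segments.merge(labels[["segment_id", "label"]], on="segment_id")
    recs = []
    for (pid, burst), grp in seg.groupby(["particle_id", "burst"], sort=True):
        first = grp.sort_values(["frame"]).iloc[0]
        seg_labels = grp.groupby("segment_id")["label"].first()
        counts = seg_labels.value_counts()
        top = counts[counts == counts.max()].index.min()  # majority, ties -> slowest
        recs.append((pid, burst, first["x_um"], first["y_um"], int(top)))
    return pd.DataFrame(recs, columns=["particle_id", "burst", "x_um", "y_um", "label"])


def pool_state_pairs(points: pd.DataFrame, K: int) -> dict[str, pd.DataFrame]:
    """Group labeled points by diffusivity-adjacent state pairs.

    K = 8 gives groups {1,2}, {3,4}, {5,6}, {7,8}; an odd K leaves the last
    state alone. Returns a dict mapping group name (e.g. ``"1-2"``) to the
    point subset; counts are conserved across groups.
    """
    groups = {}
    for lo in range(1, K + 1, 2):
        hi = min(lo + 1, K)
        name = f"{lo}-{hi}" if hi > lo else f"{lo}"
        groups[name] = points[points["label"].isin([lo, hi])].reset_index(drop=True)
    return groups


def _pair_counts(xy: np.ndarray, r_edges: np.ndarray) -> np.ndarray:
    """Unordered pair counts per annulus, closed-right convention (d <= edge)."""
    tree = cKDTree(xy)
    cum = tree.count_neighbors(tree, r_edges)  # ordered pairs incl. self
    cum = (cum - xy.shape[0]) // 2
    return np.diff(cum)


def pair_correlation(
    points: np.ndarray,
    mask: Mask,
    r_edges: np.ndarray,
    ref_factor: int = 20,
    seed: int = 0,
    label: str = "",
) -> pd.DataFrame:
    """Pair correlation g(r) inside a mask with Monte-Carlo CSR normalization.

    Parameters
    ----------
    points : (n, 2) positions in um (n >= 2), all inside the mask.
    r_edges : increasing bin edges in um.
    ref_factor : CSR reference points per data point (>= 20 recommended).

    Returns a GrCurve DataFrame ``r, g, n_pairs, valid, group`` where bins
    whose CSR expectation is zero are marked invalid.
    """
    xy = np.asarray(points, dtype=float)
    if xy.ndim != 2 or xy.shape[0] < 2:
        raise ValueError("need >= 2 points")
    r_edges = np.asarray(r_edges, dtype=float)
    if np.any(np.diff(r_edges) <= 0):
        raise ValueError("r_edges must be strictly increasing")
    n = xy.shape[0]
    rng = np.random.default_rng(seed)
    ref = mask.sample(ref_factor * n, rng)
    m = ref.shape[0]

    dd = _pair_counts(xy, r_edges)
    rr = _pair_counts(ref, r_edges)
    norm_d = n * (n - 1) / 2
    norm_r = m * (m - 1) / 2
    valid = rr > 0
    with np.errstate(divide="ignore", invalid="ignore"):
        g = np.where(valid, (dd / norm_d) / np.where(valid, rr, 1) * norm_r, np.nan)
    return pd.DataFrame(
        {
            "r": 0.5 * (r_edges[:-1] + r_edges[1:]),
            "g": g,
            "n_pairs": dd,
            "valid": valid,
            "group": label,
        }
    )
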