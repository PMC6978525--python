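"""Covariance-based diffusivity estimation and ensemble MSD.

The covariance-based estimator (CVE) recovers the diffusion coefficient of a
short trajectory without regression, and is unbiased in the presence of both
static localization noise (variance sigma^2) and motion blur (coefficient R,
1/6 for full-frame uniform exposure). Per axis, with displacements d_n over
a uniform frame interval dt:

    D_hat      = <d_n^2> / (2 dt) + <d_n d_{n+1}> / dt
    sigma2_hat = R <d_n^2> + (2R - 1) <d_n d_{n+1}>

Unbiasedness requires keeping negative estimates; they are never clipped.
The expected ensemble MSD of such a process is

    MSD(n) = 4 D n dt + 4 sigma^2 - 8 R D dt        (two dimensions)

which serves as an independent regression oracle for the CVE.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["cve_estimate", "cve_estimate_segments", "emsd", "emsd_expected",
           "compare_distributions"]

logger = logging.getLogger(__name__)

DEFAULT_R = 1.0 / 6.0


def _cve_1d(d: np.ndarray, dt: float, R: float):
    m2 = np.mean(d**2)
    m11 = np.mean(d[:-1] * d[1:]) if d.size > 1 else 0.0
    D = m2 / (2 * dt) + m11 / dt
    s2 = R * m2 + (2 * R - 1) * m11
    return D, s2


def cve_estimate(positions: np.ndarray, dt: float, R: float = DEFAULT_R):
    """CVE diffusivity of one trajectory piece.

    Parameters
    ----------
    positions : (n, 2) array of x, y in um, n >= 3.
    dt : frame interval in s.
    R : motion-blur coefficient (exposure_fraction / 6).

    Returns
    -------
    (D_hat, sigma2_hat) averaged over the two axes; D_hat may be negative.
    """
    pos = np.asarray(positions, dtype=float)
    if pos.ndim != 2 or pos.shape[1] != 2 or pos.shape[0] < 3:
        raise ValueError("need >= 3 planar positions")
    dx = np.diff(pos[:, 0])
    dy = np.diff(pos[:, 1])
    Dx, sx = _cve_1d(dx, dt, R)
    Dy, sy = _cve_1d(dy, dt, R)
    return (Dx + Dy) / 2, (sx + sy) / 2


def cve_estimate_segments(
    segments: pd.DataFrame, dt: float, R: float = DEFAULT_R
) -> pd.DataFrame:
    """Vectorized CVE over a SegmentSet; one DiffusivityRecord per segment.

    Returns a DataFrame ``segment_id, D_hat, sigma2_hat, burst``
    (+ ``particle_id, seg_index, track_length``) sorted by segment id.
    """
    from .detect_link import segment_displacements

    if segments.shape[0] == 0:
        return pd.DataFrame(columns=["segment_id", "D_hat", "sigma2_hat", "burst"])
    ids, dx, dy = segment_displacements(segments)

    def axis(d):
        m2 = np.mean(d**2, axis=1)
        m11 = np.mean(d[:, :-1] * d[:, 1:], axis=1)
        return m2 / (2 * dt) + m11 / dt, R * m2 + (2 * R - 1) * m11

    Dx, sx = axis(dx)
    Dy, sy = axis(dy)
    meta = (
        segments.groupby("segment_id", sort=True)
        .agg(
            burst=("burst", "first"),
            particle_id=("particle_id", "first"),
            seg_index=("seg_index", "first"),
            track_length=("track_length", "first"),
        )
        .reset_index()
    )
    out = pd.DataFrame(
        {"segment_id": ids, "D_hat": (Dx + Dy) / 2, "sigma2_hat": (sx + sy) / 2}
    )
    return out.merge(meta, on="segment_id").sort_values("segment_id").reset_index(drop=True)


def emsd(tracks: pd.DataFrame, max_lag: int, dt: float | None = None) -> pd.DataFrame:
    """Ensemble mean-square displacement over all particles and start frames.

    Returns a DataFrame ``lag, lag_s, msd, n_pairs``; lags above the longest
    usable track are truncated with a warning.
    """
    id_cols = [c for c in ("particle_id", "burst") if c in tracks.columns]
    groups = [g[["x_um", "y_um"]].to_numpy()
              for _, g in tracks.sort_values("frame").groupby(id_cols, sort=False)]
    longest = max((g.shape[0] for g in groups), default=0)
    if max_lag >= longest:
        warnings.warn(
            f"max_lag {max_lag} >= longest track ({longest} frames); truncating",
            stacklevel=2,
        )
        max_lag = longest - 1
    lags = np.arange(1, max_lag + 1)
    sums = np.zeros(max_lag)
    counts = np.zeros(max_lag, dtype=int)
    for g in groups:
        n = g.shape[0]
        for lag in range(1, min(n, max_lag + 1)):
            d = g[lag:] - g[:-lag]
            sums[lag - 1] += np.sum(d[:, 0] ** 2 + d[:, 1] ** 2)
            counts[lag - 1] += d.shape[0]
    with np.errstate(invalid="ignore"):
        msd = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    out = pd.DataFrame({"lag": lags, "msd": msd, "n_pairs": counts})
    if dt is not None:
        out.insert(1, "lag_s", lags * dt)
    return out


def emsd_expected(n_lags: int, D: float, sigma: float, dt: float, R: float = DEFAULT_R):
    """Closed-form 2-D MSD of blurred, noisy Brownian motion (test oracle)."""
    n = np.arange(1, n_lags + 1)
    return 4 * D * n * dt + 4 * sigma**2 - 8 * R * D * dt


def compare_distributions(
    groups,
    subset_size: int = 200,
    n_draws: int = 25,
    seed: int = 0,
):
    """Kruskal–Wallis comparison on seeded random subsets of each group.

    Large single-particle datasets make any distributional difference
    "significant"; subsampling to ``subset_size`` per group keeps the test
    honest. Each draw re-seeds an identical RNG per group so identical
    groups receive identical subsets (and thus p = 1).

    Returns a dict with ``p_median``, ``p_values`` (all draws), ``p_iqr``.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2:
        raise ValueError("need >= 2 groups")
    for g in groups:
        if g.size < subset_size:
            raise ValueError(f"group of size {g.size} smaller than subset_size {subset_size}")
    ps = []
    for d in range(n_draws):
        subs = []
        for g in groups:
            rng = np.random.default_rng([seed, d])
            idx = rng.permutation(g.size)[:subset_size]
            subs.append(g[idx])
        stacked = np.concatenate(subs)
        if np.all(stacked == stacked[0]):
            logger.warning("degenerate draw (all ties); p = 1")
            ps.append(1.0)
            continue
        try:
            _, p = stats.kruskal(*subs)
        except ValueError:
            logger.warning("degenerate draw (all ties); p = 1")
            p = 1.0
        ps.append(float(p) if np.isfinite(p) else 1.0)
    ps = np.array(ps)
    return {
        "p_median": float(np.median(ps)),
        "p_iqr": float(np.subtract(*np.percentile(ps, [75, 25]))),
        "p_values": ps,
    }
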