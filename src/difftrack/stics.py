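"""Spatio-temporal image correlation spectroscopy (STICS) velocimetry.

Local flow is measured from the lag-dependent displacement of the
spatio-temporal cross-correlation peak of small image subregions: for each
subregion and time-of-interest (TOI) window, frames tau apart are
cross-correlated and averaged; a 2-D Gaussian fit localizes the correlation
peak per tau to sub-pixel precision, and the velocity is the least-squares
slope of peak displacement versus tau. Static structure is removed
beforehand by an "immobile filter" (moving-average subtraction per pixel).

Directionality is summarized by the directional coherence: the cosine of
the angle between a flow vector and the direction from its position to the
cell centroid (+1 = inward, -1 = outward). Conditions are compared via the
inward (c > 0.9) and outward (c < -0.9) fractions with a pooled
two-proportion z-test.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage, stats

from .gaussfit import fit_gaussian_patches
from .stack import ImageStack

__all__ = [
    "immobile_filter",
    "stics_vectors",
    "directional_coherence",
    "compare_flow_fractions",
    "CoherenceResult",
]

logger = logging.getLogger(__name__)


def immobile_filter(stack: ImageStack, window: int = 20, method: str = "moving_average") -> ImageStack:
    """Remove the static image component before correlation analysis.

    ``moving_average`` subtracts each pixel's ``window``-frame moving average
    (the immobile-filter setting); ``fourier`` removes the temporal DC
    component (whole-stack mean per pixel).
    """
    data = np.asarray(stack.data, dtype=float)
    if method == "fourier":
        out = data - data.mean(axis=0, keepdims=True)
    elif method == "moving_average":
        if window > data.shape[0]:
            raise ValueError(
                f"immobile-filter window {window} exceeds stack length {data.shape[0]}"
            )
        avg = ndimage.uniform_filter1d(data, size=window, axis=0, mode="nearest")
        out = data - avg
    else:
        raise ValueError(f"unknown method {method!r}")
    return ImageStack(out, stack.pixel_size, stack.frame_interval, stack.origin,
                      dict(stack.extras))


def _fit_gauss_patches(patches: np.ndarray, n_iter: int = 25):
    """Least-squares 2-D Gaussian fits on 5x5 correlation-peak patches.

    Returns ``(x0, y0, A, ok)`` with x0, y0 the sub-pixel offsets from the
    patch centre.
    """
    x0, y0, A, _, _, ok = fit_gaussian_patches(
        patches, sigma0=1.2, max_shift=1.5, n_iter=n_iter
    )
    return x0, y0, A, ok


def _toi_correlations(tem_f, sea_f, toi, taus, margin, nfft):
    """Average cross-correlation planes per (subregion, tau).

    ``tem_f``/``sea_f``: rfft2 of zero-mean templates (sub x sub) and search
    regions (sub + 2*margin squared), padded to ``nfft``. Every shift within
    |xi|, |eta| <= margin has full template overlap, so the plane needs no
    overlap normalization and carries no window-induced bias toward zero
    shift.

    Pairs are averaged over a template set common to every tau (templates
    t in [0, toi - max_tau), searches t + tau): the random peak offset a
    finite textured window produces is then identical for all tau and is
    absorbed by the intercept of the displacement-vs-tau line fit instead
    of corrupting the velocity slope.

    Returns (n_tau, ..., 2*margin+1, 2*margin+1) planes with index
    ``margin`` = zero shift.
    """
    n_templates = max(toi - int(max(taus)), 1)
    out = []
    for tau in taus:
        acc = None
        for t in range(n_templates):
            cross = np.conj(tem_f[t]) * sea_f[t + tau]
            acc = cross if acc is None else acc + cross
        plane = np.fft.irfft2(acc / n_templates, s=(nfft, nfft))
        out.append(plane[..., : 2 * margin + 1, : 2 * margin + 1])
    return np.stack(out)


def stics_vectors(
    stack: ImageStack,
    sub: int = 8,
    sub_shift: int = 2,
    toi: int = 5,
    toi_shift: int = 3,
    max_lag: int | None = None,
    amp_threshold_factor: float = 2.0,
) -> pd.DataFrame:
    """Local flow vectors from spatio-temporal correlation of subregions.

    Parameters follow the standard STICS settings: ``sub`` x ``sub`` pixel
    subregions shifted by ``sub_shift``, TOI windows of ``toi`` frames
    shifted by ``toi_shift``. Vectors are marked invalid when the
    correlation maximum sits at the subregion half-size boundary, the
    Gaussian peak fit fails, or the peak amplitude is below
    ``amp_threshold_factor`` times the MAD of the correlation plane.

    Returns a VelocityField DataFrame with one row per (subregion, TOI):
    ``toi_index, t_start_s, x_um, y_um, vx_um_min, vy_um_min, speed_um_min,
    valid``.
    """
    data = np.asarray(stack.data, dtype=float)
    T, H, W = data.shape
    if max_lag is None:
        max_lag = max(1, toi - 1)
    max_lag = min(max_lag, toi - 1)
    max_shift = sub // 2
    px = stack.pixel_size
    dt = stack.frame_interval

    toi_starts = list(range(0, T - toi + 1, toi_shift))
    if not toi_starts:
        warnings.warn("stack shorter than one TOI window; no vectors", stacklevel=2)
        return pd.DataFrame(
            columns=["toi_index", "t_start_s", "x_um", "y_um",
                     "vx_um_min", "vy_um_min", "speed_um_min", "valid"]
        )
    margin = max_shift + 2  # room for a full 5x5 patch around |shift| = max_shift
    search = sub + 2 * margin
    nfft = int(2 ** np.ceil(np.log2(search + 1)))
    taus = np.arange(1, max_lag + 1)
    # subregion grid; a full search region must fit inside the image
    r_starts = np.arange(margin, H - sub - margin + 1, sub_shift)
    c_starts = np.arange(margin, W - sub - margin + 1, sub_shift)
    if r_starts.size == 0 or c_starts.size == 0:
        raise ValueError(f"image too small for {sub}px subregions with "
                         f"{margin}px search margin")

    frames = []
    for ti, t0 in enumerate(toi_starts):
        win = data[t0:t0 + toi]
        # templates: (toi, nr, nc, sub, sub); searches: larger windows around them
        tview = np.lib.stride_tricks.sliding_window_view(win, (sub, sub), axis=(1, 2))
        tem = tview[:, r_starts][:, :, c_starts].astype(float)
        sview = np.lib.stride_tricks.sliding_window_view(
            win, (search, search), axis=(1, 2)
        )
        sea = sview[:, r_starts - margin][:, :, c_starts - margin].astype(float)
        tem = tem - tem.mean(axis=(3, 4), keepdims=True)
        sea = sea - sea.mean(axis=(3, 4), keepdims=True)
        tem_f = np.fft.rfft2(tem, s=(nfft, nfft))
        sea_f = np.fft.rfft2(sea, s=(nfft, nfft))
        corr = _toi_correlations(tem_f, sea_f, toi, taus, margin, nfft)
        n_tau, nr, nc = corr.shape[:3]
        planes = corr.reshape(n_tau * nr * nc, 2 * margin + 1, 2 * margin + 1)

        # discrete maximum restricted to |shift| <= max_shift
        inner = planes[:, 2:-2, 2:-2]
        flat = inner.reshape(inner.shape[0], -1)
        amax = np.argmax(flat, axis=1)
        pr = amax // inner.shape[2] + 2
        pc = amax % inner.shape[2] + 2
        on_border = (
            (pr == 2) | (pr == planes.shape[1] - 3)
            | (pc == 2) | (pc == planes.shape[2] - 3)
        )
        idx = np.arange(planes.shape[0])
        d5 = np.arange(-2, 3)
        patches = planes[
            idx[:, None, None],
            pr[:, None, None] + d5[None, :, None],
            pc[:, None, None] + d5[None, None, :],
        ]
        x0, y0, amp, fit_ok = _fit_gauss_patches(patches)
        mad = np.median(
            np.abs(planes - np.median(planes, axis=(1, 2), keepdims=True)),
            axis=(1, 2),
        )
        ok = fit_ok & ~on_border & (amp >= amp_threshold_factor * mad)
        shift_x = (pc - margin) + x0
        shift_y = (pr - margin) + y0
        ok &= (np.abs(shift_x) <= max_shift) & (np.abs(shift_y) <= max_shift)

        ok = ok.reshape(n_tau, nr * nc)
        sx = np.where(ok, shift_x.reshape(n_tau, nr * nc), np.nan)
        sy = np.where(ok, shift_y.reshape(n_tau, nr * nc), np.nan)

        # weighted least-squares line displacement(tau) = v*tau + b per vector
        w = ok.astype(float)
        nok = w.sum(axis=0)
        tcol = taus[:, None].astype(float)
        tbar = (w * tcol).sum(axis=0) / np.maximum(nok, 1)
        var_t = (w * (tcol - tbar) ** 2).sum(axis=0)
        need_line = taus.size > 1
        min_ok = 2 if need_line else 1
        line_ok = (var_t > 0) if need_line else np.ones_like(var_t, dtype=bool)
        valid = (nok >= min_ok) & line_ok

        def slope(sv):
            sv0 = np.where(ok, sv, 0.0)
            sbar = sv0.sum(axis=0) / np.maximum(nok, 1)
            if need_line:
                cov = (w * (tcol - tbar) * (np.nan_to_num(sv) - sbar)).sum(axis=0)
                return np.where(var_t > 0, cov / np.maximum(var_t, 1e-300), np.nan)
            return sbar / tbar

        vx = slope(sx) * px / dt * 60.0  # um/min
        vy = slope(sy) * px / dt * 60.0
        speed = np.hypot(vx, vy)
        vx = np.where(valid, vx, np.nan)
        vy = np.where(valid, vy, np.nan)
        speed = np.where(valid, speed, np.nan)

        cc, rr = np.meshgrid(c_starts, r_starts)
        frames.append(pd.DataFrame(
            {
                "toi_index": ti,
                "t_start_s": t0 * dt,
                "x_um": stack.origin[0] + (cc.ravel() + sub / 2) * px,
                "y_um": stack.origin[1] + (rr.ravel() + sub / 2) * px,
                "vx_um_min": vx,
                "vy_um_min": vy,
                "speed_um_min": speed,
                "valid": valid,
            }
        ))
    return pd.concat(frames, ignore_index=True)


@dataclass
class CoherenceResult:
    """Directional-coherence summary of a velocity field."""

    coherence: np.ndarray  # per valid, nonzero vector, in [-1, 1]
    inward_fraction: float  # share with c > 0.9
    outward_fraction: float  # share with c < -0.9
    n: int

    def pdf(self, bins=40):
        """Probability-density histogram of coherence values over [-1, 1]."""
        hist, edges = np.histogram(self.coherence, bins=bins, range=(-1, 1),
                                   density=True)
        return 0.5 * (edges[:-1] + edges[1:]), hist


def directional_coherence(field: pd.DataFrame, centroid) -> CoherenceResult:
    """Cosine of the angle between each flow vector and the centroid direction.

    +1 = flow toward the cell centre, -1 = away. Invalid and zero-length
    vectors are excluded.
    """
    cx, cy = centroid
    f = field[field["valid"]]
    v = f[["vx_um_min", "vy_um_min"]].to_numpy()
    to_c = np.column_stack([cx - f["x_um"].to_numpy(), cy - f["y_um"].to_numpy()])
    nv = np.hypot(v[:, 0], v[:, 1])
    nc = np.hypot(to_c[:, 0], to_c[:, 1])
    keep = (nv > 0) & (nc > 0)
    c = np.sum(v[keep] * to_c[keep], axis=1) / (nv[keep] * nc[keep])
    c = np.clip(c, -1.0, 1.0)
    n = int(c.size)
    return CoherenceResult(
        coherence=c,
        inward_fraction=float(np.mean(c > 0.9)) if n else np.nan,
        outward_fraction=float(np.mean(c < -0.9)) if n else np.nan,
        n=n,
    )


def compare_flow_fractions(fraction_a: float, n_a: int, fraction_b: float, n_b: int):
    """Two-proportion pooled z-test (two-sided) for flow-direction fractions.

    Returns ``(z, p)``; when the pooled proportion is 0 or 1 the variance
    vanishes and ``(0, 1)`` is returned with a warning.
    """
    if n_a < 1 or n_b < 1:
        raise ValueError("counts must be >= 1")
    x_a = fraction_a * n_a
    x_b = fraction_b * n_b
    pooled = (x_a + x_b) / (n_a + n_b)
    var = pooled * (1 - pooled) * (1 / n_a + 1 / n_b)
    if var <= 0:
        logger.warning("degenerate proportions (pooled %.3f); p = 1", pooled)
        return 0.0, 1.0
    z = (fraction_a - fraction_b) / np.sqrt(var)
    p = 2 * stats.norm.sf(abs(z))
    return float(z), float(p)
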