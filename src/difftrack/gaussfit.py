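"""Batched least-squares 2-D Gaussian fitting on small image patches.

Shared by single-molecule localization and STICS correlation-peak
localization. Fits ``A exp(-((x-x0)^2 + (y-y0)^2) / (2 s^2)) + off`` to
every patch of a (M, h, w) array by damped Gauss-Newton with analytic
Jacobians; ~50 us per patch, against ~25 ms per `scipy.optimize`
call-based fit.
"""

from __future__ import annotations

import numpy as np

__all__ = ["fit_gaussian_patches"]


def fit_gaussian_patches(
    patches: np.ndarray,
    sigma0: float = 1.2,
    max_shift: float = 1.5,
    n_iter: int = 25,
):
    """Fit an isotropic 2-D Gaussian plus offset to each patch.

    Parameters
    ----------
    patches : (M, h, w) array
        Pixel values; the peak is assumed near the patch centre.
    sigma0 : float
        Initial width in pixels.
    max_shift : float
        Fits whose centre lands further than this (pixels) from the patch
        centre are flagged as failed.

    Returns
    -------
    x0, y0 : (M,) sub-pixel centre offsets from the patch centre (columns,
        rows); A, sigma, off : (M,) amplitude, width, baseline;
        ok : (M,) bool success flags (finite, positive amplitude, centre
        within ``max_shift``).
    """
    patches = np.asarray(patches, dtype=float)
    M, h, w = patches.shape
    z = patches.reshape(M, -1)
    gy, gx = np.mgrid[0:h, 0:w]
    cx = (w - 1) / 2.0
    cy = (h - 1) / 2.0
    gx = (gx.ravel()[None, :] - cx).astype(float)
    gy = (gy.ravel()[None, :] - cy).astype(float)

    off = z.min(axis=1)
    A = z[:, (h // 2) * w + w // 2] - off
    x0 = np.zeros(M)
    y0 = np.zeros(M)
    s = np.full(M, float(sigma0))
    lam = 1e-8
    smax = max(h, w)
    for _ in range(n_iter):
        ex = gx - x0[:, None]
        ey = gy - y0[:, None]
        E = np.exp(-(ex**2 + ey**2) / (2 * s**2)[:, None])
        r = z - (A[:, None] * E + off[:, None])
        J = np.stack(
            [
                E,
                A[:, None] * E * ex / (s**2)[:, None],
                A[:, None] * E * ey / (s**2)[:, None],
                A[:, None] * E * (ex**2 + ey**2) / (s**3)[:, None],
                np.ones_like(E),
            ],
            axis=2,
        )  # (M, h*w, 5)
        JtJ = np.einsum("mki,mkj->mij", J, J)
        diag_scale = np.einsum("mkk->mk", JtJ).mean(axis=1)
        JtJ[:, np.arange(5), np.arange(5)] += lam + 1e-12 * diag_scale[:, None]
        Jtr = np.einsum("mki,mk->mi", J, r)
        try:
            step = np.linalg.solve(JtJ, Jtr[:, :, None])[:, :, 0]
        except np.linalg.LinAlgError:  # pragma: no cover
            break
        A = A + step[:, 0]
        x0 = np.clip(x0 + step[:, 1], -(w / 2 + 1), w / 2 + 1)
        y0 = np.clip(y0 + step[:, 2], -(h / 2 + 1), h / 2 + 1)
        s = np.clip(s + step[:, 3], 0.3, smax)
        off = off + step[:, 4]
    ok = (
        np.isfinite(x0) & np.isfinite(y0) & np.isfinite(A) & np.isfinite(s)
        & (A > 0) & (np.abs(x0) <= max_shift) & (np.abs(y0) <= max_shift)
    )
    return x0, y0, A, s, off, ok
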