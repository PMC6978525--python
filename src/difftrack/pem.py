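"""Perturbation-expectation-maximization over diffusive states.

Fixed-length trajectory segments are modelled as draws from a mixture of K
"diffusive states", each a zero-mean Gaussian over the 14 per-axis
displacements with a symmetric tridiagonal Toeplitz covariance

    C_ii     = a = 2 D dt - 4 R D dt + 2 sigma^2
    C_i,i+1  = b = 2 R D dt - sigma^2

(D diffusion coefficient, sigma^2 static localization variance, R motion
blur). x and y are treated as independent, identically distributed axes.
EM alternates posterior responsibilities with per-state (D, sigma^2, pi)
updates; random reinitializations plus parameter perturbations followed by
EM polishing guard against local likelihood maxima, and the number of
states is selected by the Bayesian Information Criterion

    BIC(K) = -2 loglik + (3K - 1) ln N_segments.

States are reported sorted by D ascending (state 1 = slowest).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve, solve_triangular
from scipy.optimize import minimize
from scipy.special import logsumexp
from statsmodels.stats.proportion import proportion_confint

__all__ = [
    "StateModel",
    "TransitionMatrix",
    "displacement_covariance",
    "segment_loglik",
    "em_fit",
    "pem_search",
    "population_fractions",
    "transitions",
]

logger = logging.getLogger(__name__)

N_DISP = 14  # displacements per 15-frame segment
D_FLOOR = 1e-9  # um^2/s, keeps covariances positive-definite


@dataclass
class StateModel:
    """A K-state diffusive mixture with its fit diagnostics."""

    K: int
    D: np.ndarray  # um^2/s, ascending
    sigma2: np.ndarray  # um^2
    pi: np.ndarray
    loglik: float
    bic: float = np.nan
    converged: bool = False
    n_iter: int = 0
    loglik_history: np.ndarray = field(default_factory=lambda: np.array([]))
    dropped_states: int = 0

    def to_dict(self):
        return {
            "K": int(self.K),
            "D_um2_per_s": [float(v) for v in self.D],
            "sigma2_um2": [float(v) for v in self.sigma2],
            "pi": [float(v) for v in self.pi],
            "loglik": float(self.loglik),
            "bic": float(self.bic),
            "converged": bool(self.converged),
            "n_iter": int(self.n_iter),
        }


def displacement_covariance(
    D: float, sigma2: float, dt: float, R: float, n_disp: int = N_DISP
) -> np.ndarray:
    """Covariance of successive displacements of blurred, noisy Brownian motion.

    Symmetric tridiagonal Toeplitz: diagonal ``a = 2 D dt - 4 R D dt +
    2 sigma2``, first off-diagonal ``b = 2 R D dt - sigma2``.
    """
    a = 2 * D * dt - 4 * R * D * dt + 2 * sigma2
    b = 2 * R * D * dt - sigma2
    C = np.zeros((n_disp, n_disp))
    np.fill_diagonal(C, a)
    idx = np.arange(n_disp - 1)
    C[idx, idx + 1] = b
    C[idx + 1, idx] = b
    return C


def _chol(D, sigma2, dt, R, n_disp):
    C = displacement_covariance(D, sigma2, dt, R, n_disp)
    try:
        L = np.linalg.cholesky(C)
    except np.linalg.LinAlgError:
        return None, None
    return L, 2 * np.sum(np.log(np.diag(L)))


def segment_loglik(
    dx: np.ndarray, dy: np.ndarray, D: float, sigma2: float, dt: float, R: float
) -> np.ndarray:
    """Log-density of each segment under one state (x and y axes summed).

    ``dx``, ``dy``: (n_segments, n_disp) displacement arrays. Returns -inf
    for all segments when the implied covariance is not positive-definite.
    """
    dx = np.atleast_2d(dx)
    dy = np.atleast_2d(dy)
    n = dx.shape[1]
    L, logdet = _chol(D, sigma2, dt, R, n)
    if L is None:
        logger.debug("non-PD covariance at D=%g sigma2=%g", D, sigma2)
        return np.full(dx.shape[0], -np.inf)
    out = np.zeros(dx.shape[0])
    for d in (dx, dy):
        z = solve_triangular(L, d.T, lower=True)
        out += -0.5 * (n * np.log(2 * np.pi) + logdet + np.sum(z**2, axis=0))
    return out


def _weighted_scatter(dx, dy, gamma_k):
    """S = sum_i gamma_i (x_i x_i^T + y_i y_i^T) and diagonals needed for moments."""
    Sx = (dx * gamma_k[:, None]).T @ dx
    Sy = (dy * gamma_k[:, None]).T @ dy
    return Sx + Sy


def _q_value(D, sigma2, S, W, dt, R, n):
    """Expected complete-data log-likelihood term for one state (both axes)."""
    L, logdet = _chol(D, sigma2, dt, R, n)
    if L is None:
        return -np.inf
    tr = np.trace(cho_solve((L, True), S))
    return -0.5 * (2 * W * (n * np.log(2 * np.pi)) + 2 * W * logdet + tr)


def _moment_update(S, W, dt, R, n):
    """Closed-form (D, sigma2) from gamma-weighted displacement moments."""
    a_hat = np.trace(S) / (2 * W * n)
    b_hat = np.trace(S, offset=1) / (2 * W * (n - 1))
    D = (a_hat + 2 * b_hat) / (2 * dt)
    sigma2 = R * (a_hat + 2 * b_hat) - b_hat
    return max(D, D_FLOOR), max(sigma2, 0.0)


def _mstep_state(D_old, s2_old, S, W, dt, R, n):
    """Maximize Q over (D, sigma2); never returns a worse value than the
    current parameters (generalized EM step, guarantees monotonicity).

    The gamma-weighted moment inversion is used when it improves Q (it is
    the closed-form quasi-MLE and almost always does); otherwise a short
    Nelder-Mead refinement in log-parameters takes over.
    """
    q_old = _q_value(D_old, s2_old, S, W, dt, R, n)
    d_m, s_m = _moment_update(S, W, dt, R, n)
    q_m = _q_value(d_m, s_m, S, W, dt, R, n)
    if q_m > q_old:
        return float(d_m), float(s_m)
    if q_old - q_m < 1e-7 * abs(q_old) + 1e-12:
        return float(D_old), float(s2_old)  # stalled at the optimum

    def neg_q(u):
        return -_q_value(np.exp(u[0]), np.exp(u[1]), S, W, dt, R, n)

    u0 = np.log([max(D_old, D_FLOOR), max(s2_old, 1e-12)])
    res = minimize(neg_q, u0, method="Nelder-Mead",
                   options={"maxiter": 40, "xatol": 1e-4, "fatol": 1e-8})
    if np.isfinite(res.fun) and -res.fun > q_old:
        return float(np.exp(res.x[0])), float(np.exp(res.x[1]))
    return float(D_old), float(s2_old)


def _sort_states(D, sigma2, pi, gamma=None):
    order = np.argsort(D)
    if gamma is not None:
        gamma = gamma[:, order]
    return D[order], sigma2[order], pi[order], gamma


def em_fit(
    dx: np.ndarray,
    dy: np.ndarray,
    K: int,
    dt: float,
    R: float,
    D_init=None,
    sigma2_init=None,
    pi_init=None,
    max_iter: int = 150,
    tol: float = 1e-3,
    seed: int | None = None,
):
    """Fit a K-state mixture by EM on the displacement-covariance likelihood.

    Returns ``(StateModel, gamma)`` with gamma the (n_segments, K) posterior
    table, columns matching the (ascending-D) state order. States whose
    weight falls below 1/N are dropped. The total log-likelihood is
    non-decreasing across iterations by construction.
    """
    dx = np.atleast_2d(np.asarray(dx, dtype=float))
    dy = np.atleast_2d(np.asarray(dy, dtype=float))
    N, n = dx.shape
    if N < K:
        raise ValueError(f"need at least K={K} segments, got {N}")
    rng = np.random.default_rng(seed)

    m2 = np.mean(dx**2 + dy**2) / 2
    if D_init is None:
        D_init = np.sort(
            np.exp(rng.uniform(np.log(m2 / (20 * dt)), np.log(2 * m2 / dt), K))
        )
    if sigma2_init is None:
        sigma2_init = np.full(K, 0.1 * m2)
    if pi_init is None:
        pi_init = np.full(K, 1.0 / K)
    D = np.asarray(D_init, dtype=float).copy()
    s2 = np.asarray(sigma2_init, dtype=float).copy()
    pi = np.asarray(pi_init, dtype=float).copy()
    pi = pi / pi.sum()

    history = []
    loglik = -np.inf
    converged = False
    dropped = 0
    it = 0
    gamma = np.full((N, K), 1.0 / K)
    for it in range(1, max_iter + 1):
        # E-step
        ll_k = np.column_stack(
            [segment_loglik(dx, dy, D[k], s2[k], dt, R) for k in range(len(D))]
        )
        with np.errstate(divide="ignore"):
            logw = ll_k + np.log(pi)[None, :]
        norm = logsumexp(logw, axis=1)
        new_loglik = float(norm.sum())
        gamma = np.exp(logw - norm[:, None])
        history.append(new_loglik)
        if np.isfinite(loglik) and abs(new_loglik - loglik) < tol:
            loglik = new_loglik
            converged = True
            break
        loglik = new_loglik

        # M-step
        W = gamma.sum(axis=0)
        keep = W >= 1.0  # pi_k >= 1/N
        if not keep.all():
            dropped += int((~keep).sum())
            logger.debug("dropping %d empty state(s)", int((~keep).sum()))
            D, s2, pi, gamma = D[keep], s2[keep], pi[keep], gamma[:, keep]
            gamma = gamma / gamma.sum(axis=1, keepdims=True)
            W = gamma.sum(axis=0)
            # a drop changes the model dimension; restart the monotonic record
            history = []
            loglik = -np.inf
        pi = W / N
        for k in range(len(D)):
            S = _weighted_scatter(dx, dy, gamma[:, k])
            D[k], s2[k] = _mstep_state(D[k], s2[k], S, W[k], dt, R, n)

    D, s2, pi, gamma = _sort_states(D, s2, pi, gamma)
    model = StateModel(
        K=len(D), D=D, sigma2=s2, pi=pi, loglik=loglik,
        converged=converged, n_iter=it, loglik_history=np.asarray(history),
        dropped_states=dropped,
    )
    return model, gamma


def _bic(model: StateModel, N: int) -> float:
    p = 3 * model.K - 1
    return -2 * model.loglik + p * np.log(N)


def pem_search(
    dx: np.ndarray,
    dy: np.ndarray,
    dt: float,
    R: float,
    K_max: int = 15,
    n_reinit: int = 20,
    n_perturb: int = 150,
    seed: int = 0,
    max_iter: int = 150,
    polish_iter: int = 20,
    tol: float = 1e-3,
    stop_after: int | None = None,
):
    """Perturbation-EM model search over K = 1..K_max.

    For each K the EM is restarted from ``n_reinit`` random initializations;
    the best fit is then perturbed ``n_perturb`` times (log-normal jitter of
    scale 0.5 on D and sigma^2, Dirichlet jitter of pi) with short EM
    polishing, keeping the best likelihood, and finished with a full EM run.
    Returns ``(models, best_K)`` where ``models`` maps K -> StateModel and
    ``best_K`` minimizes BIC (ties to smaller K). If ``stop_after`` is set,
    the search over K stops early once BIC has risen for that many
    consecutive K values.
    """
    dx = np.atleast_2d(dx)
    dy = np.atleast_2d(dy)
    N, n = dx.shape
    rng = np.random.default_rng(seed)

    # data-driven initialization ranges from naive per-segment CVE
    m2 = np.mean(dx**2 + dy**2, axis=1) / 2
    m11 = np.mean(dx[:, :-1] * dx[:, 1:] + dy[:, :-1] * dy[:, 1:], axis=1) / 2
    d_cve = m2 / (2 * dt) + m11 / dt
    d_pos = np.maximum(d_cve, 1e-6)
    loD, hiD = np.quantile(d_pos, [0.05, 0.95])
    hiD = max(hiD, 2 * loD)
    s2_scale = max(np.median(np.abs(R * m2 + (2 * R - 1) * m11)), 1e-8)

    models: dict[int, StateModel] = {}
    prev_best: StateModel | None = None
    for K in range(1, K_max + 1):
        best: StateModel | None = None
        best_gamma = None
        inits = []
        for _ in range(n_reinit):
            inits.append(
                dict(
                    D_init=np.sort(np.exp(rng.uniform(np.log(loD), np.log(hiD), K))),
                    sigma2_init=np.exp(
                        rng.uniform(np.log(s2_scale / 10), np.log(s2_scale * 10), K)
                    ),
                    pi_init=rng.dirichlet(np.ones(K)),
                )
            )
        if prev_best is not None and prev_best.K == K - 1 and K > 1:
            # split the heaviest state of the best (K-1)-model as a warm start
            j = int(np.argmax(prev_best.pi))
            D0 = np.append(prev_best.D, prev_best.D[j] * 1.5)
            s0 = np.append(prev_best.sigma2, prev_best.sigma2[j])
            p0 = np.append(prev_best.pi, prev_best.pi[j] / 2)
            p0[j] /= 2
            inits.append(dict(D_init=D0, sigma2_init=s0, pi_init=p0 / p0.sum()))
        for ini in inits:
            m, g = em_fit(dx, dy, K, dt, R, max_iter=max_iter, tol=tol, **ini)
            if best is None or m.loglik > best.loglik:
                best, best_gamma = m, g
        for _ in range(n_perturb):
            Dp = best.D * np.exp(rng.normal(0, 0.5, best.K))
            s2p = best.sigma2 * np.exp(rng.normal(0, 0.5, best.K))
            pip = rng.dirichlet(10 * best.K * np.maximum(best.pi, 1e-3))
            m, g = em_fit(
                dx, dy, best.K, dt, R,
                D_init=Dp, sigma2_init=np.maximum(s2p, 1e-12), pi_init=pip,
                max_iter=polish_iter, tol=tol,
            )
            if m.loglik > best.loglik:
                best, best_gamma = m, g
        # polish the winner to convergence
        m, g = em_fit(
            dx, dy, best.K, dt, R,
            D_init=best.D, sigma2_init=best.sigma2, pi_init=best.pi,
            max_iter=max_iter, tol=tol,
        )
        if m.loglik >= best.loglik:
            best, best_gamma = m, g
        best.bic = _bic(best, N)
        models[K] = best
        prev_best = best
        logger.info("K=%d loglik=%.2f BIC=%.2f", K, best.loglik, best.bic)
        if stop_after is not None and K > stop_after:
            recent = [models[k].bic for k in range(K - stop_after, K + 1)]
            if all(np.diff(recent) > 0):
                logger.info("BIC rising for %d consecutive K; stopping at K=%d",
                            stop_after, K)
                break

    ks = sorted(models)
    bics = np.array([models[k].bic for k in ks])
    best_K = ks[int(np.argmin(bics))]  # argmin takes the first (smallest K) on ties
    return models, best_K


def posterior_table(dx, dy, model: StateModel, dt: float, R: float) -> np.ndarray:
    """Posterior responsibilities gamma under a fitted model (rows sum to 1)."""
    ll_k = np.column_stack(
        [segment_loglik(dx, dy, model.D[k], model.sigma2[k], dt, R)
         for k in range(model.K)]
    )
    with np.errstate(divide="ignore"):
        logw = ll_k + np.log(model.pi)[None, :]
    return np.exp(logw - logsumexp(logw, axis=1)[:, None])


def hard_labels(gamma: np.ndarray) -> np.ndarray:
    """Maximum-posterior state assignment, 1-based (state 1 = slowest)."""
    return np.argmax(gamma, axis=1) + 1


def population_fractions(labels: pd.DataFrame, K: int, alpha: float = 0.05) -> pd.DataFrame:
    """Per-burst population fraction of each state with Wilson 95% CI.

    ``labels`` needs columns ``burst`` and ``label`` (1-based states).
    """
    recs = []
    for burst, grp in labels.groupby("burst", sort=True):
        ntot = grp.shape[0]
        if ntot == 0:  # pragma: no cover
            logger.warning("empty burst %s omitted", burst)
            continue
        for k in range(1, K + 1):
            c = int((grp["label"] == k).sum())
            lo, hi = proportion_confint(c, ntot, alpha=alpha, method="wilson")
            recs.append((burst, k, c, ntot, c / ntot, lo, hi))
    return pd.DataFrame(
        recs, columns=["burst", "state", "count", "n", "fraction", "ci_low", "ci_high"]
    )


@dataclass
class TransitionMatrix:
    counts: np.ndarray  # K x K
    freq: np.ndarray  # row-normalized; rows with zero counts are NaN
    zero_rows: np.ndarray  # bool flags

    @property
    def n_pairs(self) -> int:
        return int(self.counts.sum())


def transitions(
    labels: pd.DataFrame, K: int, min_track_frames: int = 31
) -> TransitionMatrix:
    """State-transition statistics between consecutive segments of a track.

    Only parent tracks longer than 30 frames (``track_length >=
    min_track_frames``) are eligible; within each, consecutive segment pairs
    (seg_index i -> i+1) are tallied into a K x K count matrix which is then
    row-normalized. ``labels`` needs columns ``particle_id, burst,
    seg_index, label, track_length``.
    """
    counts = np.zeros((K, K), dtype=int)
    elig = labels[labels["track_length"] >= min_track_frames]
    for _, grp in elig.groupby(["particle_id", "burst"], sort=False):
        grp = grp.sort_values("seg_index")
        si = grp["seg_index"].to_numpy()
        lab = grp["label"].to_numpy()
        consec = np.diff(si) == 1
        for a, b in zip(lab[:-1][consec], lab[1:][consec]):
            counts[a - 1, b - 1] += 1
    if counts.sum() == 0:
        logger.warning("no eligible tracks for transition analysis")
    rowsum = counts.sum(axis=1)
    zero = rowsum == 0
    with np.errstate(invalid="ignore"):
        freq = counts / np.where(zero, 1, rowsum)[:, None]
    freq[zero] = np.nan
    return TransitionMatrix(counts=counts, freq=freq, zero_rows=zero)
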