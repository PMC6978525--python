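"""Synthetic single-molecule data with known ground truth.

Three generators mirror the acquisition this pipeline analyses:

* :func:`simulate_trackset` — multi-state Brownian trajectories with Markov
  switching between diffusive states, camera motion blur, per-state Gaussian
  localization noise, burst acquisition and an optional clustered spatial
  organisation of slow states inside a cell mask.
* :func:`render_spot_movie` — renders trajectories into a TIRF-like movie of
  diffraction-limited spots (integrated 2-D Gaussians) with optional shot and
  read noise, for testing detection and linking.
* :func:`simulate_flow_stack` — speckle movies advected by a prescribed
  velocity field, the ground truth for STICS velocimetry.

Every generator is fully reproducible from an integer seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.special import erf

from .geometry import DiskMask, Mask
from .stack import ImageStack

__all__ = [
    "SimConfig",
    "FlowTruth",
    "simulate_trackset",
    "render_spot_movie",
    "simulate_flow_stack",
    "write_trackset",
    "read_trackset",
]

TRACK_COLUMNS = ["particle_id", "burst", "frame", "x_um", "y_um", "true_state"]


@dataclass
class SimConfig:
    """Acquisition and motion model for the trajectory simulator.

    Defaults emulate 33 Hz burst imaging (1000 frames per one-minute time
    point), full-frame exposure (blur coefficient R = 1/6), a geometric
    track-length law with mean 40 frames and ~100 tracks per burst.

    Parameters
    ----------
    state_diffusivities : list of float
        Per-state diffusion coefficients D_k in um^2/s.
    state_loc_sigma : list of float
        Per-state localization noise std sigma_k in um (static error).
    per_frame_transition_matrix : (K, K) row-stochastic array
        Markov switching probabilities applied once per frame.
    exposure_fraction : float in [0, 1]
        Fraction of the frame interval the shutter is open. The motion-blur
        coefficient for uniform exposure is R = exposure_fraction / 6.
    cluster_spec : dict state -> (n_centers, radius_um)
        States whose particles are confined to small disks ("clusters")
        scattered in the mask; produces g(r) > 1 at short r for those states.
    switch_every : int or None
        If set, the Markov chain steps only every `switch_every` frames
        (block-wise switching); default None = per-frame switching.
    """

    state_diffusivities: list = dc_field(default_factory=lambda: [0.01])
    state_loc_sigma: list = dc_field(default_factory=lambda: [0.03])
    per_frame_transition_matrix: np.ndarray | None = None
    initial_fractions: np.ndarray | None = None
    frame_interval: float = 1.0 / 33.0
    frames_per_burst: int = 1000
    n_bursts: int = 1
    pixel_size: float = 0.1
    exposure_fraction: float = 1.0
    mask: Mask = dc_field(default_factory=lambda: DiskMask(5.0))
    cluster_spec: dict = dc_field(default_factory=dict)
    track_length_law: tuple = ("geometric", 40.0)
    n_tracks: int = 100
    n_blur_samples: int = 10
    switch_every: int | None = None
    seed: int = 0

    def __post_init__(self):
        D = np.asarray(self.state_diffusivities, dtype=float)
        S = np.asarray(self.state_loc_sigma, dtype=float)
        K = D.size
        if S.size != K:
            raise ValueError(
                f"configuration error: {K} diffusivities but {S.size} localization sigmas"
            )
        if self.per_frame_transition_matrix is None:
            self.per_frame_transition_matrix = np.eye(K)
        P = np.asarray(self.per_frame_transition_matrix, dtype=float)
        if P.shape != (K, K):
            raise ValueError(
                f"configuration error: transition matrix shape {P.shape} != ({K}, {K})"
            )
        if np.any(np.abs(P.sum(axis=1) - 1) > 1e-12) or np.any(P < 0):
            raise ValueError("transition matrix rows must be nonnegative and sum to 1")
        if self.initial_fractions is None:
            # stationary distribution of P (principal left eigenvector)
            w, v = np.linalg.eig(P.T)
            i = np.argmin(np.abs(w - 1))
            pi = np.real(v[:, i])
            self.initial_fractions = pi / pi.sum()
        pi = np.asarray(self.initial_fractions, dtype=float)
        if pi.size != K or abs(pi.sum() - 1) > 1e-9 or np.any(pi < 0):
            raise ValueError("initial_fractions must be a length-K simplex vector")
        if np.any(D < 0) or np.any(S < 0):
            raise ValueError("diffusivities and sigmas must be nonnegative")
        if not 0 <= self.exposure_fraction <= 1:
            raise ValueError("exposure_fraction must be in [0, 1]")
        self.state_diffusivities = D
        self.state_loc_sigma = S
        self.per_frame_transition_matrix = P
        self.initial_fractions = pi

    @property
    def n_states(self) -> int:
        return len(self.state_diffusivities)

    @property
    def blur_R(self) -> float:
        """Motion-blur coefficient for uniform exposure over the open fraction."""
        return self.exposure_fraction / 6.0


def _draw_lengths(law, n, rng, max_len):
    kind = law[0]
    if kind == "geometric":
        mean = float(law[1])
        lengths = rng.geometric(1.0 / mean, size=n)
    elif kind == "fixed":
        lengths = np.full(n, int(law[1]))
    else:
        raise ValueError(f"unknown track_length_law {law!r}")
    return np.minimum(lengths, max_len)


def _reflect_disks(xy, centers, radii):
    """Vectorized radial reflection of points into per-point disks."""
    d = xy - centers
    r = np.hypot(d[:, 0], d[:, 1])
    rr = r.copy()
    for _ in range(16):
        out = rr > radii
        if not out.any():
            break
        rr = np.abs(np.where(out, 2 * radii - rr, rr))
    rr = np.minimum(rr, radii * (1 - 1e-12))
    unit = np.where(r[:, None] > 0, d / np.maximum(r, 1e-300)[:, None], 0.0)
    return centers + unit * rr[:, None]


def _markov_step(states, P_cum, rng):
    u = rng.random(states.size)
    nxt = np.empty_like(states)
    for s in np.unique(states):
        sel = states == s
        nxt[sel] = np.searchsorted(P_cum[s], u[sel], side="right")
    return np.minimum(nxt, P_cum.shape[0] - 1)


def simulate_trackset(config: SimConfig) -> pd.DataFrame:
    """Simulate a TrackSet: per-particle time-ordered positions in um.

    Motion model per frame: the particle's true position performs Brownian
    motion with the current state's D; the reported position is the average
    of ``n_blur_samples`` equally spaced sub-frame positions over the exposure
    window (motion blur) plus isotropic Gaussian noise with the state's sigma.
    Trajectories reflect at the mask edge; particles whose initial state is a
    clustered state are confined to a randomly assigned cluster disk.

    Returns a DataFrame with columns
    ``particle_id, burst, frame, x_um, y_um, true_state``.
    """
    rng = np.random.default_rng(config.seed)
    K = config.n_states
    D = config.state_diffusivities
    sigma = config.state_loc_sigma
    P_cum = np.cumsum(config.per_frame_transition_matrix, axis=1)
    dt = config.frame_interval
    f_exp = config.exposure_fraction
    nsub = max(int(config.n_blur_samples), 1)

    n_total = config.n_tracks * config.n_bursts
    bursts = np.repeat(np.arange(config.n_bursts), config.n_tracks)
    lengths = _draw_lengths(config.track_length_law, n_total, rng, config.frames_per_burst)
    starts = rng.integers(0, config.frames_per_burst - lengths + 1)

    state0 = rng.choice(K, size=n_total, p=config.initial_fractions)

    # cluster geometry: sample centers per clustered state, assign particles
    centers = np.zeros((n_total, 2))
    radii = np.full(n_total, np.inf)  # inf = not confined
    cluster_centers = {}
    for s, (n_c, rad) in config.cluster_spec.items():
        pts = []
        for _ in range(int(n_c)):
            for _try in range(100):
                c = config.mask.sample(1, rng)[0]
                probe = c + rad * np.array(
                    [[1, 0], [-1, 0], [0, 1], [0, -1.0]]
                )
                if config.mask.contains(probe).all():
                    break
            pts.append(c)
        cluster_centers[s] = np.asarray(pts)
    for s, (n_c, rad) in config.cluster_spec.items():
        sel = np.flatnonzero(state0 == s)
        if sel.size:
            which = rng.integers(0, len(cluster_centers[s]), size=sel.size)
            centers[sel] = cluster_centers[s][which]
            radii[sel] = rad

    confined = np.isfinite(radii)
    pos = np.empty((n_total, 2))
    if confined.any():
        # uniform inside assigned disk
        n_c = int(confined.sum())
        u = rng.random(n_c)
        th = rng.uniform(0, 2 * np.pi, n_c)
        rr = radii[confined] * np.sqrt(u)
        pos[confined] = centers[confined] + np.column_stack(
            [rr * np.cos(th), rr * np.sin(th)]
        )
    if (~confined).any():
        pos[~confined] = config.mask.sample(int((~confined).sum()), rng)

    def reflect_all(xy, active_idx):
        conf = confined[active_idx]
        if conf.any():
            xy[conf] = _reflect_disks(xy[conf], centers[active_idx][conf], radii[active_idx][conf])
        if (~conf).any():
            xy[~conf] = config.mask.reflect(xy[~conf])
        return xy

    Lmax = int(lengths.max())
    states = state0.copy()
    obs = np.full((n_total, Lmax, 2), np.nan)
    state_rec = np.full((n_total, Lmax), -1, dtype=int)

    for t in range(Lmax):
        active = np.flatnonzero(lengths > t)
        st = states[active]
        state_rec[active, t] = st
        sd = np.sqrt(2 * D[st] * dt)  # per-axis full-frame step std

        if f_exp > 0:
            # substeps over the exposure window, left-endpoint samples
            dt_sub = f_exp * dt / nsub
            cur = pos[active].copy()
            acc = cur.copy()
            for _ in range(nsub - 1):
                cur = cur + rng.normal(0, 1, cur.shape) * np.sqrt(2 * D[st] * dt_sub)[:, None]
                cur = reflect_all(cur, active)
                acc += cur
            blurred = acc / nsub
            # advance to the end of the frame interval
            rem = dt - (nsub - 1) * dt_sub
            cur = cur + rng.normal(0, 1, cur.shape) * np.sqrt(2 * D[st] * rem)[:, None]
            cur = reflect_all(cur, active)
        else:
            blurred = pos[active].copy()
            cur = pos[active] + rng.normal(0, 1, (active.size, 2)) * sd[:, None]
            cur = reflect_all(cur, active)

        obs[active, t] = blurred + rng.normal(0, 1, blurred.shape) * sigma[st][:, None]
        pos[active] = cur

        if config.switch_every is None or (t + 1) % config.switch_every == 0:
            states[active] = _markov_step(states[active], P_cum, rng)

    total = int(lengths.sum())
    pid = np.repeat(np.arange(n_total), lengths)
    offsets = np.concatenate([[0], np.cumsum(lengths)[:-1]])
    within = np.arange(total) - np.repeat(offsets, lengths)
    return pd.DataFrame(
        {
            "particle_id": pid,
            "burst": bursts[pid],
            "frame": starts[pid] + within,
            "x_um": obs[pid, within, 0],
            "y_um": obs[pid, within, 1],
            "true_state": state_rec[pid, within],
        }
    )


def render_spot_movie(
    tracks: pd.DataFrame,
    psf_sigma: float,
    photon_scale: float,
    background: float,
    noise_model: str = "none",
    *,
    pixel_size: float = 0.1,
    frame_interval: float = 1.0 / 33.0,
    extent=None,
    pad: float = 1.0,
    read_noise: float = 2.0,
    burst: int | None = None,
    seed: int | None = None,
) -> ImageStack:
    """Render localizations as integrated 2-D Gaussian spots on a pixel grid.

    ``extent`` is (xmin, ymin, xmax, ymax) in um; by default it covers the
    tracks with ``pad`` um of margin. ``noise_model`` is ``"none"`` or
    ``"poisson+gaussian"`` (shot noise on signal+background plus read noise).
    """
    if psf_sigma <= 0:
        raise ValueError("psf_sigma must be positive")
    if noise_model not in ("none", "poisson+gaussian", "poisson"):
        raise ValueError(f"unknown noise_model {noise_model!r}")
    rng = np.random.default_rng(seed)

    if tracks.shape[0] and tracks["burst"].nunique() > 1:
        if burst is None:
            raise ValueError("tracks span multiple bursts; pass burst=")
        tracks = tracks[tracks["burst"] == burst]

    if extent is None:
        if tracks.shape[0] == 0:
            extent = (0.0, 0.0, 5.0, 5.0)
        else:
            extent = (
                tracks["x_um"].min() - pad,
                tracks["y_um"].min() - pad,
                tracks["x_um"].max() + pad,
                tracks["y_um"].max() + pad,
            )
    xmin, ymin, xmax, ymax = extent
    W = int(np.ceil((xmax - xmin) / pixel_size))
    H = int(np.ceil((ymax - ymin) / pixel_size))
    n_frames = int(tracks["frame"].max()) + 1 if tracks.shape[0] else 1

    bad = tracks[
        (tracks["x_um"] < xmin) | (tracks["x_um"] > xmax)
        | (tracks["y_um"] < ymin) | (tracks["y_um"] > ymax)
    ]
    if bad.shape[0]:
        pid = int(bad["particle_id"].iloc[0])
        raise ValueError(f"particle {pid} lies outside the image extent {extent}")

    stack = np.full((n_frames, H, W), float(background))
    s_px = psf_sigma / pixel_size
    win = max(4, int(np.ceil(6 * s_px)))  # wide support keeps centroids exact

    if photon_scale > 0:
        for frame, grp in tracks.groupby("frame"):
            img = stack[int(frame)]
            cx = (grp["x_um"].to_numpy() - xmin) / pixel_size  # pixel-edge coords
            cy = (grp["y_um"].to_numpy() - ymin) / pixel_size
            for x0, y0 in zip(cx, cy):
                c0 = int(np.floor(x0))
                r0 = int(np.floor(y0))
                cols = np.arange(max(0, c0 - win), min(W, c0 + win + 1))
                rows = np.arange(max(0, r0 - win), min(H, r0 + win + 1))
                if cols.size == 0 or rows.size == 0:
                    continue
                # integral of the Gaussian over each pixel via erf differences
                fx = 0.5 * (
                    erf((cols + 1 - x0) / (np.sqrt(2) * s_px))
                    - erf((cols - x0) / (np.sqrt(2) * s_px))
                )
                fy = 0.5 * (
                    erf((rows + 1 - y0) / (np.sqrt(2) * s_px))
                    - erf((rows - y0) / (np.sqrt(2) * s_px))
                )
                img[np.ix_(rows, cols)] += photon_scale * np.outer(fy, fx)

    if noise_model in ("poisson+gaussian", "poisson"):
        stack = rng.poisson(np.maximum(stack, 0)).astype(float)
        if noise_model == "poisson+gaussian" and read_noise > 0:
            stack = stack + rng.normal(0, read_noise, stack.shape)

    return ImageStack(stack, pixel_size, frame_interval, origin=(xmin, ymin))


@dataclass
class FlowTruth:
    """Prescribed velocity field of a synthetic flow movie (um/s)."""

    kind: str  # zero | uniform | radial_in | radial_out
    speed: float = 0.0
    vx: float = 0.0
    vy: float = 0.0
    center: tuple[float, float] = (0.0, 0.0)
    core_radius: float = 0.0

    def velocity(self, xy: np.ndarray) -> np.ndarray:
        xy = np.atleast_2d(xy)
        if self.kind == "zero":
            return np.zeros_like(xy)
        if self.kind == "uniform":
            return np.tile([self.vx, self.vy], (xy.shape[0], 1))
        d = np.asarray(self.center) - xy  # points toward center
        r = np.hypot(d[:, 0], d[:, 1])
        unit = np.where(r[:, None] > self.core_radius, d / np.maximum(r, 1e-300)[:, None], 0.0)
        sgn = 1.0 if self.kind == "radial_in" else -1.0
        return sgn * self.speed * unit


def simulate_flow_stack(
    field_spec,
    *,
    shape=(64, 64),
    n_frames: int = 25,
    pixel_size: float = 0.1,
    frame_interval: float = 2.0,
    texture_grain: float = 0.1,
    noise: float = 0.0,
    background: float = 100.0,
    contrast: float = 50.0,
    seed: int | None = None,
    subregion_px: int = 8,
) -> tuple[ImageStack, FlowTruth]:
    """Advect a static random speckle texture by a prescribed velocity field.

    ``field_spec`` is one of ``("zero",)``, ``("uniform", vx, vy)`` or
    ``("radial_in"|"radial_out", speed)`` with speeds in um/s. Uniform fields
    are sampled exactly from the base texture with periodic boundaries;
    radial fields use per-frame semi-Lagrangian warping. Returns the stack
    and the ground-truth field.
    """
    rng = np.random.default_rng(seed)
    H, W = shape
    kind = field_spec[0]
    cx = W * pixel_size / 2
    cy = H * pixel_size / 2
    if kind == "zero":
        truth = FlowTruth("zero")
    elif kind == "uniform":
        truth = FlowTruth("uniform", vx=float(field_spec[1]), vy=float(field_spec[2]))
    elif kind in ("radial_in", "radial_out"):
        truth = FlowTruth(kind, speed=float(field_spec[1]), center=(cx, cy),
                          core_radius=2 * pixel_size)
    else:
        raise ValueError(f"unknown field_spec {field_spec!r}")

    speeds = {
        "zero": 0.0,
        "uniform": float(np.hypot(truth.vx, truth.vy)),
        "radial_in": truth.speed,
        "radial_out": truth.speed,
    }[kind]
    if speeds * frame_interval / pixel_size > subregion_px / 2:
        warnings.warn(
            "flow exceeds half the STICS subregion per frame; expect aliasing",
            stacklevel=2,
        )

    base = rng.standard_normal((H, W))
    s_px = max(texture_grain / pixel_size, 1e-6)
    base = ndimage.gaussian_filter(base, s_px, mode="wrap")
    base = (base - base.mean()) / max(base.std(), 1e-12)

    frames = np.empty((n_frames, H, W))
    rows, cols = np.mgrid[0:H, 0:W].astype(float)
    if kind in ("zero", "uniform"):
        vx_px = truth.vx * frame_interval / pixel_size
        vy_px = truth.vy * frame_interval / pixel_size
        for t in range(n_frames):
            coords = np.array([rows - t * vy_px, cols - t * vx_px])
            frames[t] = ndimage.map_coordinates(base, coords, order=3, mode="grid-wrap")
    else:
        x_um = (cols + 0.5) * pixel_size
        y_um = (rows + 0.5) * pixel_size
        v = truth.velocity(np.column_stack([x_um.ravel(), y_um.ravel()]))
        vx_px = (v[:, 0] * frame_interval / pixel_size).reshape(H, W)
        vy_px = (v[:, 1] * frame_interval / pixel_size).reshape(H, W)
        cur = base
        frames[0] = cur
        back = np.array([rows - vy_px, cols - vx_px])
        for t in range(1, n_frames):
            cur = ndimage.map_coordinates(cur, back, order=3, mode="nearest")
            frames[t] = cur

    stack = background + contrast * frames
    if noise > 0:
        stack = stack + rng.normal(0, noise, stack.shape)
    return ImageStack(stack, pixel_size, frame_interval), truth


def write_trackset(tracks: pd.DataFrame, path, header_comment: str | None = None) -> None:
    """Write a TrackSet CSV (documented header; optional '#' comment line)."""
    cols = [c for c in TRACK_COLUMNS if c in tracks.columns]
    with open(path, "w") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        tracks[cols].to_csv(fh, index=False)


def read_trackset(path) -> pd.DataFrame:
    df = pd.read_csv(path, comment="#")
    missing = {"particle_id", "frame", "x_um", "y_um"} - set(df.columns)
    if missing:
        raise ValueError(f"track table missing columns {sorted(missing)}")
    if "burst" not in df.columns:
        df["burst"] = 0
    return df
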