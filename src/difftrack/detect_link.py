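"""Single-molecule detection, crossing-aware linking, and track segmentation.

Detection refines local intensity maxima with least-squares 2-D Gaussian
fits to reach sub-pixel (tens of nm) precision. Linking is greedy
nearest-neighbour with no gap closing; whenever an assignment is ambiguous
(two molecules within the search radius of the same track end, or vice
versa) all involved tracks are terminated and fresh tracks started — close
encounters therefore interrupt trajectories rather than risking identity
swaps. Surviving tracks of 15–105 frames are cut into consecutive
non-overlapping 15-frame segments, the unit of state classification; longer
tracks are discarded to avoid over-counting slow molecules, which seldom
cross paths.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from skimage.feature import peak_local_max

from .gaussfit import fit_gaussian_patches
from .stack import ImageStack

__all__ = [
    "detect_spots",
    "detect_stack",
    "link_tracks",
    "filter_and_segment",
    "SEGMENT_LENGTH",
    "MIN_TRACK_FRAMES",
    "MAX_TRACK_FRAMES",
]

logger = logging.getLogger(__name__)

SEGMENT_LENGTH = 15
MIN_TRACK_FRAMES = 15
MAX_TRACK_FRAMES = 105

LOC_COLUMNS = ["frame", "x_um", "y_um", "amplitude", "fit_sigma", "fit_ok"]


def detect_spots(
    frame_image: np.ndarray,
    intensity_threshold: float,
    psf_sigma_guess: float,
    *,
    pixel_size: float,
    origin=(0.0, 0.0),
    mask: np.ndarray | None = None,
    frame_index: int = 0,
) -> pd.DataFrame:
    """Localize diffraction-limited spots in one frame.

    Candidate maxima above ``intensity_threshold`` (absolute counts above the
    image median) are refined by least-squares 2-D Gaussian fits in a local
    window; positions are returned in um. Detections outside the (optional)
    binary cell ``mask`` are discarded.
    """
    img = np.asarray(frame_image, dtype=float)
    if img.ndim != 2:
        raise ValueError("detect_spots expects a single 2-D frame")
    if img.max() == img.min():
        logger.warning("frame %d is flat; no detections", frame_index)
        return pd.DataFrame(columns=LOC_COLUMNS)

    s_px = max(psf_sigma_guess / pixel_size, 0.8)
    med = np.median(img)
    peaks = peak_local_max(
        img,
        min_distance=max(2, int(round(2 * s_px))),
        threshold_abs=med + intensity_threshold,
        exclude_border=1,
    )
    if peaks.size == 0:
        return pd.DataFrame(columns=LOC_COLUMNS)

    H, W = img.shape
    win = max(3, int(np.ceil(3 * s_px)))
    # keep peaks whose fit window lies fully inside the frame
    inside = (
        (peaks[:, 0] >= win) & (peaks[:, 0] < H - win)
        & (peaks[:, 1] >= win) & (peaks[:, 1] < W - win)
    )
    peaks = peaks[inside]
    if peaks.shape[0] == 0:
        return pd.DataFrame(columns=LOC_COLUMNS)
    d = np.arange(-win, win + 1)
    patches = img[
        peaks[:, 0, None, None] + d[None, :, None],
        peaks[:, 1, None, None] + d[None, None, :],
    ]
    x0, y0, A, s_fit, _, ok = fit_gaussian_patches(
        patches, sigma0=s_px, max_shift=1.5
    )
    ok &= (A >= intensity_threshold) & (s_fit >= 0.3) & (s_fit <= 4 * s_px + 2)
    # sub-pixel position in pixel-centre coordinates -> physical um
    col = peaks[:, 1] + x0
    row = peaks[:, 0] + y0
    x_um = origin[0] + (col + 0.5) * pixel_size
    y_um = origin[1] + (row + 0.5) * pixel_size
    if mask is not None:
        rr = np.clip(np.round(row).astype(int), 0, H - 1)
        cc = np.clip(np.round(col).astype(int), 0, W - 1)
        ok &= mask[rr, cc]
    out = pd.DataFrame(
        {
            "frame": frame_index,
            "x_um": x_um[ok],
            "y_um": y_um[ok],
            "amplitude": A[ok],
            "fit_sigma": s_fit[ok] * pixel_size,
            "fit_ok": True,
        }
    )
    return out[LOC_COLUMNS]


def detect_stack(
    stack: ImageStack,
    intensity_threshold: float,
    psf_sigma_guess: float,
    mask: np.ndarray | None = None,
) -> pd.DataFrame:
    """Run :func:`detect_spots` on every frame of a stack."""
    frames = [
        detect_spots(
            stack.data[t],
            intensity_threshold,
            psf_sigma_guess,
            pixel_size=stack.pixel_size,
            origin=stack.origin,
            mask=mask,
            frame_index=t,
        )
        for t in range(stack.n_frames)
    ]
    frames = [f for f in frames if f.shape[0]]
    if not frames:
        return pd.DataFrame(columns=LOC_COLUMNS)
    return pd.concat(frames, ignore_index=True)


def link_tracks(
    localizations: pd.DataFrame,
    max_displacement: float,
    burst: int = 0,
) -> pd.DataFrame:
    """Link per-frame localizations into trajectories (no gap closing).

    Assignment is by mutual nearest neighbours within ``max_displacement``.
    Any ambiguity — more than one detection within range of a track end, or
    more than one track end within range of a detection — terminates all
    tracks involved and starts new ones (the crossing-interruption rule).
    """
    if localizations.shape[0] == 0:
        return pd.DataFrame(columns=["particle_id", "burst", "frame", "x_um", "y_um"])
    locs = localizations.sort_values("frame")
    next_id = 0
    active: dict[int, np.ndarray] = {}  # track id -> last position
    active_frame: dict[int, int] = {}
    out_pid, out_frame, out_xy = [], [], []

    def start_track(frame, xy):
        nonlocal next_id
        tid = next_id
        next_id += 1
        active[tid] = xy
        active_frame[tid] = frame
        out_pid.append(tid)
        out_frame.append(frame)
        out_xy.append(xy)
        return tid

    for frame, grp in locs.groupby("frame", sort=True):
        frame = int(frame)
        det = grp[["x_um", "y_um"]].to_numpy()
        # drop tracks that skipped a frame (no gap closing)
        stale = [tid for tid, f in active_frame.items() if f != frame - 1]
        for tid in stale:
            active.pop(tid)
            active_frame.pop(tid)
        if not active:
            for xy in det:
                start_track(frame, xy)
            continue
        tids = np.array(sorted(active))
        ends = np.array([active[t] for t in tids])
        tree_d = cKDTree(det)
        # candidate edges within the search radius
        pairs = cKDTree(ends).query_ball_tree(tree_d, r=max_displacement)
        deg_track = np.array([len(p) for p in pairs])
        deg_det = np.zeros(det.shape[0], dtype=int)
        for p in pairs:
            for j in p:
                deg_det[j] += 1
        linked_det = set()
        survivors = {}
        for i, p in enumerate(pairs):
            if deg_track[i] == 1 and deg_det[p[0]] == 1:
                j = p[0]
                survivors[tids[i]] = j
                linked_det.add(j)
            # deg 0 -> track ends; deg > 1 or contested detection -> terminate
        for tid in tids:
            if tid in survivors:
                j = survivors[tid]
                active[tid] = det[j]
                active_frame[tid] = frame
                out_pid.append(tid)
                out_frame.append(frame)
                out_xy.append(det[j])
            else:
                active.pop(tid)
                active_frame.pop(tid)
        for j in range(det.shape[0]):
            if j not in linked_det:
                start_track(frame, det[j])

    xy = np.asarray(out_xy)
    tracks = pd.DataFrame(
        {
            "particle_id": out_pid,
            "burst": burst,
            "frame": out_frame,
            "x_um": xy[:, 0],
            "y_um": xy[:, 1],
        }
    )
    return tracks.sort_values(["particle_id", "frame"]).reset_index(drop=True)


def filter_and_segment(tracks: pd.DataFrame) -> pd.DataFrame:
    """Apply track-length filters and cut tracks into 15-frame segments.

    Tracks shorter than 15 or longer than 105 frames are discarded; the rest
    are split into consecutive non-overlapping 15-frame segments, dropping
    any trailing remainder. Returns one row per retained point with columns
    ``segment_id, particle_id, burst, seg_index, frame, x_um, y_um,
    track_length`` (+ ``true_state`` if present).
    """
    keep_state = "true_state" in tracks.columns
    cols = [
        "segment_id", "particle_id", "burst", "seg_index",
        "frame", "x_um", "y_um", "track_length",
    ] + (["true_state"] if keep_state else [])
    if tracks.shape[0] == 0:
        return pd.DataFrame(columns=cols)
    df = tracks.sort_values(["particle_id", "burst", "frame"], kind="stable").reset_index(drop=True)
    grp = df.groupby(["particle_id", "burst"], sort=True)
    new_group = grp.cumcount().to_numpy() == 0
    dframe = np.diff(df["frame"].to_numpy(), prepend=df["frame"].iloc[0] - 1)
    if np.any((dframe != 1) & ~new_group):
        pid = df.loc[(dframe != 1) & ~new_group, "particle_id"].iloc[0]
        raise ValueError(f"particle {pid} has non-contiguous frames")
    L = grp["frame"].transform("size").to_numpy()
    pos = grp.cumcount().to_numpy()
    keep = (L >= MIN_TRACK_FRAMES) & (L <= MAX_TRACK_FRAMES) & (
        pos < (L // SEGMENT_LENGTH) * SEGMENT_LENGTH
    )
    out = df[keep].copy()
    out["seg_index"] = pos[keep] // SEGMENT_LENGTH
    out["track_length"] = L[keep]
    # consecutive global segment ids, ordered by (particle, burst, seg_index)
    first_row = np.arange(out.shape[0]) % SEGMENT_LENGTH == 0
    out["segment_id"] = np.cumsum(first_row) - 1
    return out[cols].reset_index(drop=True)


def segment_displacements(segments: pd.DataFrame):
    """Per-segment displacement arrays.

    Returns ``(segment_ids, dx, dy)`` with dx, dy of shape
    (n_segments, SEGMENT_LENGTH - 1) in um.
    """
    seg = segments.sort_values(["segment_id", "frame"])
    n = seg["segment_id"].nunique()
    x = seg["x_um"].to_numpy().reshape(n, SEGMENT_LENGTH)
    y = seg["y_um"].to_numpy().reshape(n, SEGMENT_LENGTH)
    ids = seg["segment_id"].to_numpy().reshape(n, SEGMENT_LENGTH)[:, 0]
    return ids, np.diff(x, axis=1), np.diff(y, axis=1)
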