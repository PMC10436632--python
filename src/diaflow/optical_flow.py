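"""Lucas-Kanade point tracking through an ultrasound cine loop.

For each retained seed point the inter-frame motion is estimated by solving
the local brightness-constancy normal equations over an m x m window

    [ sum Ix^2   sum IxIy ] [u]   [ -sum IxIt ]
    [ sum IxIy   sum Iy^2 ] [v] = [ -sum IyIt ]

where Ix, Iy are spatial intensity gradients, It the temporal difference,
u the horizontal (column) and v the vertical (row) velocity in
pixels/frame.  The plain solve assumes small motion; an optional
coarse-to-fine image pyramid with per-level Gauss-Newton refinement relaxes
that assumption so motions of several pixels per frame remain trackable
(with ``pyramid_levels=1`` and ``iterations=1`` the update is the single
plain solve).  Point positions are maintained with sub-pixel precision via
bilinear intensity sampling; a point whose local structure matrix is
degenerate (textureless window) or whose position leaves the frame is
invalidated and excluded from all subsequent statistics.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .errors import InputError, TrackingError
from .segmentation import SeedPoints, mean_filter_3x3
from .video_io import FrameSequence

#: Default relative floor for the smaller structure-matrix eigenvalue,
#: multiplied by the window area (n = m^2).
MIN_EIG_FLOOR_PER_PIXEL = 1e-4
#: Default cap on the structure-matrix condition number.
MAX_CONDITION = 1e6


@dataclass
class FlowVector:
    """One Lucas-Kanade flow estimate.

    u is the horizontal (column) velocity, v the vertical (row) velocity,
    both in pixels/frame.  ``valid`` is False when the 2x2 structure matrix
    is numerically singular or the point left the frame.
    """

    u: float
    v: float
    valid: bool


@dataclass
class TrackedPoints:
    """Sub-pixel trajectories of the kept seed points.

    ``trajectories`` has shape ``(n_frames, n_points, 2)`` in (row, col);
    ``valid_mask`` has shape ``(n_frames, n_points)`` and is monotonically
    non-increasing along time: once lost, a point is never re-acquired.
    ``group_id`` (1..k, or None before grouping) partitions points into the
    contiguous along-band groups used for strain estimation.
    """

    trajectories: np.ndarray
    valid_mask: np.ndarray
    window_m: int
    group_id: np.ndarray | None = None

    @property
    def n_frames(self) -> int:
        return self.trajectories.shape[0]

    @property
    def n_points(self) -> int:
        return self.trajectories.shape[1]


def image_gradients(
    frame_t: np.ndarray, frame_t1: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Spatial and temporal intensity derivatives of a frame pair.

    Ix, Iy are central differences on ``frame_t`` (one-sided at borders);
    It is the pixelwise difference ``frame_t1 - frame_t``.
    """
    frame_t = np.asarray(frame_t, dtype=np.float64)
    frame_t1 = np.asarray(frame_t1, dtype=np.float64)
    if frame_t.shape != frame_t1.shape:
        raise InputError(
            f"frame dimensions differ: {frame_t.shape} vs {frame_t1.shape}"
        )
    Iy, Ix = np.gradient(frame_t)
    It = frame_t1 - frame_t
    return Ix, Iy, It


def _solve_2x2(
    sxx: np.ndarray,
    sxy: np.ndarray,
    syy: np.ndarray,
    bx: np.ndarray,
    by: np.ndarray,
    min_eig_floor: float,
    max_condition: float,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Solve symmetric 2x2 normal equations elementwise; flag degeneracy.

    Returns (u, v, ok) arrays; u = v = 0 where not ok.
    """
    tr = sxx + syy
    disc = np.sqrt(np.maximum((sxx - syy) ** 2 + 4.0 * sxy**2, 0.0))
    eig_min = 0.5 * (tr - disc)
    eig_max = 0.5 * (tr + disc)
    with np.errstate(divide="ignore", invalid="ignore"):
        cond = np.where(eig_min > 0, eig_max / eig_min, np.inf)
    ok = (eig_min > min_eig_floor) & (cond < max_condition)

    det = sxx * syy - sxy**2
    safe_det = np.where(ok, det, 1.0)
    u = np.where(ok, (syy * bx - sxy * by) / safe_det, 0.0)
    v = np.where(ok, (sxx * by - sxy * bx) / safe_det, 0.0)
    return u, v, ok


def lk_point_flow(
    Ix: np.ndarray,
    Iy: np.ndarray,
    It: np.ndarray,
    point: tuple[float, float],
    m: int = 15,
    min_eig_floor: float | None = None,
    max_condition: float = MAX_CONDITION,
) -> FlowVector:
    """Single-point Lucas-Kanade solve over an m x m window.

    The window is centred at ``point`` (row, col), rounded to the nearest
    pixel and clipped to the frame bounds.  Degeneracy (textureless or
    anisotropic-only structure) is signalled through ``valid=False`` rather
    than an exception.
    """
    if m < 3 or m % 2 == 0:
        raise InputError(f"window side m must be odd and >= 3, got {m}")
    H, W = Ix.shape
    r = m // 2
    row = int(round(point[0]))
    col = int(round(point[1]))
    if not (0 <= row < H and 0 <= col < W):
        return FlowVector(0.0, 0.0, False)
    r0, r1 = max(0, row - r), min(H, row + r + 1)
    c0, c1 = max(0, col - r), min(W, col + r + 1)
    wx = Ix[r0:r1, c0:c1].ravel()
    wy = Iy[r0:r1, c0:c1].ravel()
    wt = It[r0:r1, c0:c1].ravel()

    floor = MIN_EIG_FLOOR_PER_PIXEL * m * m if min_eig_floor is None else min_eig_floor
    u, v, ok = _solve_2x2(
        np.dot(wx, wx),
        np.dot(wx, wy),
        np.dot(wy, wy),
        -np.dot(wx, wt),
        -np.dot(wy, wt),
        floor,
        max_condition,
    )
    return FlowVector(float(u), float(v), bool(ok))


def _pyramid(frame: np.ndarray, levels: int) -> list[np.ndarray]:
    """Gaussian image pyramid, level 0 = full resolution."""
    pyr = [np.asarray(frame, dtype=np.float64)]
    for _ in range(1, levels):
        smoothed = ndimage.gaussian_filter(pyr[-1], sigma=1.0, mode="nearest")
        pyr.append(smoothed[::2, ::2])
    return pyr


def _sample(img: np.ndarray, coords: np.ndarray) -> np.ndarray:
    """Bilinear sampling at (N, ..., 2) float (row, col) coordinates.

    Out-of-frame coordinates replicate the nearest edge pixel, the sampling
    analogue of clipping the window to the frame bounds.
    """
    flat = coords.reshape(-1, 2)
    vals = ndimage.map_coordinates(
        img, [flat[:, 0], flat[:, 1]], order=1, mode="nearest"
    )
    return vals.reshape(coords.shape[:-1])


def _effective_levels(shape: tuple[int, int], m: int, requested: int) -> int:
    """Limit pyramid depth so the coarsest level still contains a window."""
    levels = 1
    h, w = shape
    while levels < requested and min(h, w) // 2 >= 2 * m:
        h, w = h // 2, w // 2
        levels += 1
    return levels


def _flow_step(
    I0_pyr: list[np.ndarray],
    grad_pyr: list[tuple[np.ndarray, np.ndarray]],
    I1_pyr: list[np.ndarray],
    pts: np.ndarray,
    offsets: np.ndarray,
    min_eig_floor: float,
    max_condition: float,
    iterations: int,
    tol: float = 1e-2,
) -> tuple[np.ndarray, np.ndarray]:
    """Pyramidal LK flow for all points between one frame pair.

    Returns (flow, ok): flow has shape (N, 2) in (drow, dcol); ok flags
    points with a well-conditioned structure matrix at the finest level.
    """
    n_levels = len(I0_pyr)
    N = len(pts)
    g = np.zeros((N, 2))  # accumulated guess at the current level's scale
    ok = np.ones(N, dtype=bool)

    for L in range(n_levels - 1, -1, -1):
        scale = 2.0**L
        pL = pts / scale
        Ix, Iy = grad_pyr[L]
        win = pL[:, None, :] + offsets[None, :, :]  # (N, m^2, 2)

        w0 = _sample(I0_pyr[L], win)
        wx = _sample(Ix, win)
        wy = _sample(Iy, win)
        sxx = np.einsum("nk,nk->n", wx, wx)
        sxy = np.einsum("nk,nk->n", wx, wy)
        syy = np.einsum("nk,nk->n", wy, wy)

        d = np.zeros((N, 2))
        for _ in range(iterations):
            shifted = win + (g + d)[:, None, :]
            wt = _sample(I1_pyr[L], shifted) - w0
            bx = -np.einsum("nk,nk->n", wx, wt)
            by = -np.einsum("nk,nk->n", wy, wt)
            du, dv, step_ok = _solve_2x2(
                sxx, sxy, syy, bx, by, min_eig_floor, max_condition
            )
            d[:, 0] += dv  # row
            d[:, 1] += du  # col
            if L == 0:
                ok &= step_ok
            if max(np.abs(du).max(initial=0.0), np.abs(dv).max(initial=0.0)) < tol:
                break
        g = (g + d) * (2.0 if L > 0 else 1.0)

    return g, ok


def track_sequence(
    seq: FrameSequence,
    seeds: SeedPoints,
    m: int = 15,
    pyramid_levels: int = 3,
    iterations: int = 5,
    min_eig_floor: float | None = None,
    max_condition: float = MAX_CONDITION,
) -> TrackedPoints:
    """Track the kept seed points through every frame of the sequence.

    Each frame is mean-filtered (3x3) before gradients are computed, then
    each consecutive pair is processed with pyramidal LK and point positions
    advanced by the estimated flow.  Points are invalidated when they leave
    the frame or when the structure matrix degenerates; invalidation is
    permanent.

    Raises
    ------
    TrackingError
        If every point has been invalidated before the final frame; the
        message names the frame index where tracking collapsed.
    """
    start = seeds.kept_coords.astype(np.float64)
    if len(start) == 0:
        raise InputError("no kept seed points to track")
    if m < 3 or m % 2 == 0:
        raise InputError(f"window side m must be odd and >= 3, got {m}")

    H, W = seq.shape
    n_frames = seq.n_frames
    N = len(start)
    levels = _effective_levels((H, W), m, pyramid_levels)
    floor = MIN_EIG_FLOOR_PER_PIXEL * m * m if min_eig_floor is None else min_eig_floor

    r = m // 2
    rng = np.arange(-r, r + 1, dtype=np.float64)
    offsets = np.stack(np.meshgrid(rng, rng, indexing="ij"), axis=-1).reshape(-1, 2)

    trajectories = np.zeros((n_frames, N, 2))
    valid = np.zeros((n_frames, N), dtype=bool)
    trajectories[0] = start
    valid[0] = True

    def prepare(frame: np.ndarray):
        pyr = _pyramid(mean_filter_3x3(frame), levels)
        grads = []
        for img in pyr:
            gy, gx = np.gradient(img)
            grads.append((gx, gy))
        return pyr, grads

    cur_pyr, cur_grads = prepare(seq.frames[0])
    for t in range(1, n_frames):
        nxt_pyr, nxt_grads = prepare(seq.frames[t])

        alive = valid[t - 1]
        if not alive.any():
            raise TrackingError(
                f"all points lost before frame {t - 1}; tracking cannot continue"
            )
        pts = trajectories[t - 1, alive]
        flow, ok = _flow_step(
            cur_pyr, cur_grads, nxt_pyr, pts, offsets,
            floor, max_condition, iterations,
        )
        new_pts = pts + flow
        in_bounds = (
            (new_pts[:, 0] >= 0)
            & (new_pts[:, 0] <= H - 1)
            & (new_pts[:, 1] >= 0)
            & (new_pts[:, 1] <= W - 1)
        )
        still = ok & in_bounds

        idx = np.flatnonzero(alive)
        trajectories[t, idx] = new_pts
        valid[t, idx[still]] = True
        # dead points keep their last position for inspection
        trajectories[t, idx[~still]] = pts[~still]
        dead = ~valid[t - 1]
        trajectories[t, dead] = trajectories[t - 1, dead]

        cur_pyr, cur_grads = nxt_pyr, nxt_grads

    if not valid[-1].any():
        raise TrackingError(f"all points lost at final frame {n_frames - 1}")
    return TrackedPoints(trajectories=trajectories, valid_mask=valid, window_m=m)


def assign_groups(tracked: TrackedPoints, k: int = 15) -> TrackedPoints:
    """Partition points into k contiguous along-band groups.

    Points are sorted by their frame-0 column (ties by row) and split into k
    contiguous groups of size ``floor(N/k)`` or ``ceil(N/k)``, so summed
    centroid-to-centroid distances approximate the band length.  Group ids
    run 1..k from left to right.
    """
    alive0 = tracked.valid_mask[0]
    if int(alive0.sum()) < k:
        raise InputError(
            f"need at least {k} valid points at frame 0, have {int(alive0.sum())}"
        )
    pts0 = tracked.trajectories[0]
    order = np.lexsort((pts0[:, 0], pts0[:, 1]))  # by col, tie row
    group_id = np.zeros(tracked.n_points, dtype=np.int64)
    for gid, chunk in enumerate(np.array_split(order, k), start=1):
        group_id[chunk] = gid
    return TrackedPoints(
        trajectories=tracked.trajectories,
        valid_mask=tracked.valid_mask,
        window_m=tracked.window_m,
        group_id=group_id,
    )


def group_centroids(tracked: TrackedPoints) -> np.ndarray:
    """Per-frame centroid of each group's valid points.

    Returns an array of shape ``(n_frames, k, 2)`` in (row, col); a group
    with no valid point at a frame yields NaN there.
    """
    if tracked.group_id is None:
        raise InputError("assign_groups must be called before group_centroids")
    k = int(tracked.group_id.max())
    out = np.full((tracked.n_frames, k, 2), np.nan)
    for gid in range(1, k + 1):
        members = tracked.group_id == gid
        for t in range(tracked.n_frames):
            sel = members & tracked.valid_mask[t]
            if sel.any():
                out[t, gid - 1] = tracked.trajectories[t, sel].mean(axis=0)
    return out
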