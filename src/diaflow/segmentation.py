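"""Locating the diaphragm band and selecting the points to track.

In B-mode ultrasound the diaphragm appears as a band markedly brighter than
the surrounding tissue, so the first frame is mean-filtered, thresholded
(automatic Otsu threshold by default, manually overridable), and the largest
connected white region is taken as the diaphragm.  Tracking seeds are drawn
uniformly at random from the white pixels of that region and then cleaned
with DBSCAN density clustering: stray seeds falling on bright clutter away
from the band form small clusters or noise and are discarded, keeping the
largest (densest) cluster as the diaphragm point set.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree
from skimage import measure
from skimage.filters import threshold_otsu

from .errors import ClusteringError, InputError, SegmentationError

logger = logging.getLogger(__name__)

_NOISE = -1
_UNCLASSIFIED = -2


@dataclass
class DiaphragmMask:
    """Binary segmentation of frame 0, reduced to its largest component.

    ``binary`` holds exactly {0, 255}; ``bbox`` is the tight inclusive
    bounding rectangle ``(row_min, col_min, row_max, col_max)`` of the white
    region.
    """

    binary: np.ndarray
    threshold_used: float
    component_label: int
    bbox: tuple[int, int, int, int]

    @property
    def n_white(self) -> int:
        return int(np.count_nonzero(self.binary))


@dataclass
class SeedPoints:
    """Integer-seeded tracking points with their post-filter keep mask.

    ``coords`` is an ``(n, 2)`` array of (row, col) positions.  After
    :func:`dbscan_filter`, ``kept_mask`` marks the points retained for
    tracking; the coordinates themselves are never modified.
    """

    coords: np.ndarray
    n_requested: int
    seed: int
    kept_mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords)
        if self.kept_mask is None:
            self.kept_mask = np.ones(len(self.coords), dtype=bool)

    @property
    def kept_coords(self) -> np.ndarray:
        return self.coords[self.kept_mask]

    @property
    def n_kept(self) -> int:
        return int(self.kept_mask.sum())


def mean_filter_3x3(frame: np.ndarray) -> np.ndarray:
    """3x3 moving-average filter with edge replication.

    Each interior pixel becomes the arithmetic mean of its 3x3
    neighbourhood; borders replicate the edge rows/columns.  The result is
    kept as floating point (not re-quantized) because it feeds the gradient
    computation of the tracker.
    """
    frame = np.asarray(frame, dtype=np.float64)
    if frame.ndim != 2 or min(frame.shape) < 3:
        raise InputError(f"mean filter needs a 2-D frame of at least 3x3, got {frame.shape}")
    return ndimage.uniform_filter(frame, size=3, mode="nearest")


def select_threshold(frame: np.ndarray, manual: float | None = None) -> float:
    """Choose the segmentation threshold T for the first frame.

    By default T maximizes the between-class intensity variance (Otsu); a
    manual value overrides the automatic choice.
    """
    if manual is not None:
        return float(manual)
    frame = np.asarray(frame)
    if frame.min() == frame.max():
        raise SegmentationError(
            "constant frame: no intensity classes to separate; supply a manual threshold"
        )
    return float(threshold_otsu(frame))


def threshold_segment(frame: np.ndarray, T: float) -> np.ndarray:
    """Binarize a frame: intensity >= T maps to 255 (white), else 0."""
    frame = np.asarray(frame)
    return np.where(frame >= T, 255, 0).astype(np.uint8)


def largest_component(binary: np.ndarray, threshold_used: float = float("nan")) -> DiaphragmMask:
    """Keep only the largest 8-connected white region of a binary image.

    Ties on pixel count are broken by the smallest ``(row_min, col_min)``
    bounding-box corner.
    """
    binary = np.asarray(binary)
    fg = binary > 0
    if not fg.any():
        raise SegmentationError("no diaphragm found: thresholded image is all black")

    labels = measure.label(fg, connectivity=2)
    counts = np.bincount(labels.ravel())
    counts[0] = 0
    best = int(np.argmax(counts))
    tied = np.flatnonzero(counts == counts[best])
    if len(tied) > 1:
        corners = []
        for lab in tied:
            rows, cols = np.nonzero(labels == lab)
            corners.append((rows.min(), cols.min(), lab))
        best = int(min(corners)[2])

    keep = labels == best
    rows, cols = np.nonzero(keep)
    bbox = (int(rows.min()), int(cols.min()), int(rows.max()), int(cols.max()))
    out = np.where(keep, 255, 0).astype(np.uint8)
    return DiaphragmMask(
        binary=out, threshold_used=float(threshold_used), component_label=best, bbox=bbox
    )


def seed_random_points(mask: DiaphragmMask, n: int = 300, seed: int = 0) -> SeedPoints:
    """Sample n distinct pixel positions uniformly from the white region.

    Points are drawn without replacement at integer pixel centres.  If the
    region holds fewer than n white pixels, all of them are used and a
    warning is logged.
    """
    rows, cols = np.nonzero(mask.binary)
    if len(rows) == 0:
        raise SegmentationError("cannot seed points: mask is empty")
    candidates = np.column_stack([rows, cols])
    if len(candidates) < n:
        logger.warning(
            "mask has %d white pixels, fewer than the %d requested; using all",
            len(candidates),
            n,
        )
        chosen = candidates
    else:
        rng = np.random.default_rng(seed)
        idx = rng.choice(len(candidates), size=n, replace=False)
        chosen = candidates[np.sort(idx)]
    return SeedPoints(coords=chosen.astype(np.float64), n_requested=n, seed=seed)


def dbscan_labels(points: np.ndarray, eps: float, min_pts: int) -> np.ndarray:
    """Label 2-D points with DBSCAN (Euclidean metric).

    Classic density-based clustering: a point with at least ``min_pts``
    neighbours within ``eps`` (itself included) is a core point; clusters
    grow by expanding density-reachable core points; points reachable from
    no core point are labelled noise (-1).  Cluster labels start at 0.
    """
    points = np.asarray(points, dtype=np.float64)
    n = len(points)
    tree = cKDTree(points)
    neighbors = tree.query_ball_point(points, r=eps)
    labels = np.full(n, _UNCLASSIFIED, dtype=np.int64)
    cluster = 0
    for i in range(n):
        if labels[i] != _UNCLASSIFIED:
            continue
        if len(neighbors[i]) < min_pts:
            labels[i] = _NOISE
            continue
        # i is a core point: grow a new cluster from its neighbourhood
        labels[i] = cluster
        frontier = [j for j in neighbors[i] if j != i]
        while frontier:
            j = frontier.pop()
            if labels[j] == _NOISE:
                labels[j] = cluster  # border point, previously mislabelled noise
            if labels[j] != _UNCLASSIFIED:
                continue
            labels[j] = cluster
            if len(neighbors[j]) >= min_pts:
                frontier.extend(k for k in neighbors[j] if labels[k] in (_UNCLASSIFIED, _NOISE))
        cluster += 1
    return labels


def dbscan_filter(
    points: SeedPoints,
    eps: float = 15.0,
    min_pts: int = 10,
    keep_all_clusters: bool = False,
) -> SeedPoints:
    """Discard seed points outside the dominant density cluster.

    Noise points and all clusters except the largest are marked not-kept
    (``keep_all_clusters=True`` retains every non-noise cluster instead).
    Ties on cluster size are broken by the cluster containing the
    smallest-index point.  The coordinates are untouched; only
    ``kept_mask`` changes.
    """
    if len(points.coords) == 0:
        raise InputError("dbscan_filter needs at least one point")
    labels = dbscan_labels(points.coords, eps=eps, min_pts=min_pts)
    if (labels == _NOISE).all():
        raise ClusteringError(
            "DBSCAN classified every seed point as noise; "
            "increase dbscan.eps or decrease dbscan.min_pts"
        )
    if keep_all_clusters:
        kept = labels != _NOISE
    else:
        sizes = np.bincount(labels[labels >= 0])
        best_size = sizes.max()
        # tie-break: cluster of the smallest-index member point
        best = next(int(lab) for lab in labels if lab >= 0 and sizes[lab] == best_size)
        kept = labels == best
    logger.info("DBSCAN kept %d of %d seed points", int(kept.sum()), len(kept))
    return SeedPoints(
        coords=points.coords,
        n_requested=points.n_requested,
        seed=points.seed,
        kept_mask=kept,
    )


def segment_first_frame(
    frame: np.ndarray, manual_threshold: float | None = None
) -> DiaphragmMask:
    """Convenience: mean-filter, threshold and reduce frame 0 to the band."""
    filtered = mean_filter_3x3(frame)
    T = select_threshold(filtered, manual=manual_threshold)
    binary = threshold_segment(filtered, T)
    return largest_component(binary, threshold_used=T)
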