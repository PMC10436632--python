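"""From trajectories to displacement, strain, cycles and drift correction.

The tracked point cloud is reduced to the study's output quantities:

* inter-frame displacement — mean per-point motion between adjacent frames,
  split into horizontal (column) and vertical (row) components, in pixels;
* cumulative displacement — running sum of the inter-frame values, i.e. the
  position of the current frame relative to frame 0;
* global strain GS(t) = (L(t) - L(0)) / L(0) * 100 %, where L(t) is the
  band length approximated by chaining the Euclidean distances between the
  k (default 15) group centroids — a shortening (contracting) band yields
  negative GS;
* the respiratory period T = 2 * |adjacent peak - trough spacing|, taken as
  twice the median half-period over all adjacent extremum pairs;
* drift correction S_corr(t) = S(t) - (S(T)/T) * t, anchored on the first
  respiratory cycle, which removes the linear error accumulation of
  sequential tracking so cumulative curves return to zero at every cycle
  boundary;
* per-cycle peak-to-peak values (max - min within each cycle window).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.signal import find_peaks

from .errors import CycleError, InputError
from .optical_flow import TrackedPoints

logger = logging.getLogger(__name__)


@dataclass
class KinematicCurves:
    """Frame-aligned displacement / length / strain series.

    All series share the frame count; ``cumulative_*`` is by construction
    the running sum of ``interframe_*``, and ``gs[0] == 0``.
    """

    time: np.ndarray
    interframe_h: np.ndarray
    interframe_v: np.ndarray
    cumulative_h: np.ndarray
    cumulative_v: np.ndarray
    length: np.ndarray | None = None
    gs: np.ndarray | None = None

    @property
    def n_samples(self) -> int:
        return len(self.time)


@dataclass
class CycleAnnotation:
    """Detected respiratory extrema and the derived period."""

    peaks: np.ndarray
    troughs: np.ndarray
    period_T: float
    source_curve: str = ""


@dataclass
class PeakToPeak:
    """Per-cycle max - min values with their mean +/- SD summary."""

    values: np.ndarray
    mean: float
    sd: float


def displacement_curves(
    tracked: TrackedPoints, frame_interval: float
) -> KinematicCurves:
    """Mean per-frame displacement of the valid tracked points.

    At frame j the inter-frame displacement is the mean over points valid
    at frame j of ``position_j - position_{j-1}`` (validity is monotone, so
    such points were also valid at j-1).  Index 0 is zero by definition.
    """
    n_frames, _, _ = tracked.trajectories.shape
    interframe_h = np.zeros(n_frames)
    interframe_v = np.zeros(n_frames)
    for j in range(1, n_frames):
        sel = tracked.valid_mask[j]
        if not sel.any():
            raise InputError(f"no valid points at frame {j}; cannot form displacement")
        delta = tracked.trajectories[j, sel] - tracked.trajectories[j - 1, sel]
        interframe_v[j] = delta[:, 0].mean()
        interframe_h[j] = delta[:, 1].mean()
    return KinematicCurves(
        time=np.arange(n_frames) * float(frame_interval),
        interframe_h=interframe_h,
        interframe_v=interframe_v,
        cumulative_h=np.cumsum(interframe_h),
        cumulative_v=np.cumsum(interframe_v),
    )


def band_length(group_centroids: np.ndarray) -> float:
    """Chained Euclidean distance through the ordered group centroids.

    L = sum_i ||c_{i+1} - c_i||; an approximation of the band length by its
    inscribed polyline.
    """
    pts = np.asarray(group_centroids, dtype=np.float64)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise InputError(f"expected (k, 2) centroids, got shape {pts.shape}")
    if np.isnan(pts).any():
        raise InputError("invalid (NaN) centroid: a group lost all its points")
    return float(np.linalg.norm(np.diff(pts, axis=0), axis=1).sum())


def global_strain(L_t: float | np.ndarray, L_0: float) -> float | np.ndarray:
    """Global strain in percent: (L(t) - L(0)) / L(0) * 100."""
    if not L_0 > 0:
        raise InputError(f"reference length L(0) must be positive, got {L_0}")
    return (np.asarray(L_t, dtype=np.float64) - L_0) / L_0 * 100.0


def strain_curve(centroids_per_frame: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Band length and GS series from per-frame group centroids.

    ``centroids_per_frame`` has shape (n_frames, k, 2).  Returns
    ``(length, gs)`` arrays of length n_frames with ``gs[0] == 0``.
    """
    lengths = np.array([band_length(c) for c in centroids_per_frame])
    return lengths, np.asarray(global_strain(lengths, lengths[0]))


def smooth_curve(
    series: np.ndarray, kernel_size: int = 5, boundary: str = "replicate"
) -> np.ndarray:
    """Moving-average smoothing with a uniform kernel of odd size.

    Output length equals input length.  Ends are handled by edge
    replication by default; ``boundary="reflect_odd"`` extends the series
    anti-symmetrically about its end values instead, which preserves the
    end samples of locally linear curves exactly — used for cumulative-type
    curves whose value at t = 0 is zero by definition (edge replication
    would drag it toward the early samples).  A series shorter than the
    kernel is returned unchanged with a warning.
    """
    series = np.asarray(series, dtype=np.float64)
    if kernel_size < 1 or kernel_size % 2 == 0:
        raise InputError(f"kernel_size must be odd and >= 1, got {kernel_size}")
    if len(series) < kernel_size:
        logger.warning(
            "series of length %d shorter than kernel %d; returned unsmoothed",
            len(series),
            kernel_size,
        )
        return series.copy()
    r = kernel_size // 2
    if boundary == "replicate":
        left = np.full(r, series[0])
        right = np.full(r, series[-1])
    elif boundary == "reflect_odd":
        left = 2.0 * series[0] - series[r:0:-1]
        right = 2.0 * series[-1] - series[-2 : -r - 2 : -1]
    else:
        raise InputError(f"unknown boundary mode {boundary!r}")
    padded = np.concatenate([left, series, right])
    kernel = np.full(kernel_size, 1.0 / kernel_size)
    return np.convolve(padded, kernel, mode="valid")


def detect_cycles(
    series: np.ndarray,
    frame_interval: float,
    min_prominence: float | None = None,
    source_curve: str = "",
) -> CycleAnnotation:
    """Locate respiratory peaks/troughs and derive the period T.

    Extrema are found with a minimum-prominence criterion (default 10 % of
    the series range).  Each adjacent peak-trough pair spans half a period;
    T is twice the median half-period, which is robust when the record
    holds several (typically 3-5) breathing cycles.

    A least-squares linear trend is removed before locating extrema: on a
    drifting curve the slope shifts peaks and troughs in opposite
    directions, which would bias every adjacent half-period.  Detrending is
    internal to the detection; the reported indices refer to the input
    samples.
    """
    series = np.asarray(series, dtype=np.float64)
    x = np.arange(len(series), dtype=np.float64)
    slope, intercept = np.polyfit(x, series, 1)
    detrended = series - (slope * x + intercept)
    if min_prominence is None:
        rng = float(detrended.max() - detrended.min())
        min_prominence = 0.1 * rng if rng > 0 else 0.0
    peaks, _ = find_peaks(detrended, prominence=min_prominence)
    troughs, _ = find_peaks(-detrended, prominence=min_prominence)
    if len(peaks) == 0 or len(troughs) == 0:
        raise CycleError(
            "no peak/trough pair found; the record may be too short "
            "(3-5 breathing cycles are expected) or too noisy"
        )

    # merge into one alternating extremum sequence
    merged = sorted(
        [(int(i), "pk") for i in peaks] + [(int(i), "th") for i in troughs]
    )
    half_periods = [
        abs(b[0] - a[0]) * frame_interval
        for a, b in zip(merged[:-1], merged[1:])
        if a[1] != b[1]
    ]
    if not half_periods:
        raise CycleError("peaks and troughs do not alternate; cannot derive a period")
    if len(half_periods) == 1:
        period_T = 2.0 * half_periods[0]
    else:
        # sum consecutive half-periods (trough -> peak -> trough spans one
        # full cycle): any residual baseline tilt shifts peaks and troughs
        # in opposite directions, so single spacings are biased but their
        # pairwise sums are not
        full_periods = [a + b for a, b in zip(half_periods[:-1], half_periods[1:])]
        period_T = float(np.median(full_periods))
    return CycleAnnotation(
        peaks=np.asarray(peaks),
        troughs=np.asarray(troughs),
        period_T=period_T,
        source_curve=source_curve,
    )


def drift_correct(
    series: np.ndarray, period_T: float, frame_interval: float
) -> np.ndarray:
    """Remove linear tracking drift, anchored on the first cycle.

    Subtracts the ramp (S(T)/T) * t, with S(T) read at the sample nearest
    t = T, so the corrected series is exactly zero there.  Applying the
    correction twice equals applying it once (the anchor residual is zero
    after the first pass).
    """
    series = np.asarray(series, dtype=np.float64)
    idx_T = int(round(period_T / frame_interval))
    if idx_T < 1 or idx_T >= len(series):
        raise CycleError(
            f"period {period_T:.3f}s (sample {idx_T}) not covered by the "
            f"{len(series)}-sample record"
        )
    ramp = series[idx_T] * (np.arange(len(series)) / idx_T)
    return series - ramp


def _cycle_windows(series_len: int, cycles: CycleAnnotation) -> list[tuple[int, int]]:
    """Complete-cycle index windows from consecutive same-type extrema."""
    anchors = cycles.peaks if len(cycles.peaks) >= 2 else cycles.troughs
    if len(anchors) < 2:
        return []
    return [(int(a), int(b)) for a, b in zip(anchors[:-1], anchors[1:])]


def peak_to_peak(series: np.ndarray, cycles: CycleAnnotation) -> PeakToPeak:
    """Per-cycle peak-to-peak (max - min) values of a curve.

    Cycle windows run between consecutive same-type extrema (peaks when at
    least two were detected, else troughs), so each window spans one full
    respiratory cycle.  The summary reports mean +/- SD over cycles.
    """
    series = np.asarray(series, dtype=np.float64)
    windows = _cycle_windows(len(series), cycles)
    if not windows:
        raise CycleError("no complete respiratory cycle in the record")
    values = np.array([series[a : b + 1].max() - series[a : b + 1].min() for a, b in windows])
    sd = float(values.std(ddof=1)) if len(values) > 1 else 0.0
    return PeakToPeak(values=values, mean=float(values.mean()), sd=sd)
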