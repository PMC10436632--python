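"""Reading ultrasound cine loops and writing curve outputs.

A cine loop is represented as a :class:`FrameSequence`: an ordered stack of
2-D grayscale frames with a fixed frame interval.  Sources are multi-frame
DICOM files (the native export format of clinical ultrasound systems) or a
directory of sequentially numbered grayscale images.

Coordinate convention, used throughout the package: frames are indexed
``(row, col)`` with row 0 at the top.  "Horizontal" motion is along the
column axis, "vertical" motion along the row axis, matching the on-screen
orientation of a B-mode image.  Displacements are reported in pixels;
millimetre columns are added on output only when a pixel spacing is known.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass
from pathlib import Path
from typing import TYPE_CHECKING

import imageio.v3 as iio
import numpy as np
import pandas as pd
import pydicom

from .errors import ConfigError, InputError

if TYPE_CHECKING:  # pragma: no cover
    from .kinematics import CycleAnnotation, KinematicCurves

#: ITU-R BT.601 luma weights used for colour-to-grayscale conversion.
LUMA_WEIGHTS = (0.299, 0.587, 0.114)

# Image file types accepted by read_image_directory.
_IMAGE_SUFFIXES = {".png", ".tif", ".tiff", ".bmp", ".jpg", ".jpeg"}


@dataclass
class FrameSequence:
    """An ordered grayscale image sequence with uniform timing.

    Parameters
    ----------
    frames
        Array of shape ``(n_frames, height, width)`` with intensities in
        ``[0, 255]``.
    frame_interval
        Seconds between consecutive frames (> 0).
    pixel_spacing
        Physical size of one pixel in millimetres, if known.
    source_id
        Free-text provenance (file path, phantom spec, ...).
    """

    frames: np.ndarray
    frame_interval: float
    pixel_spacing: float | None = None
    source_id: str = ""

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3:
            raise InputError(
                f"frames must be a (n_frames, height, width) stack, got shape {self.frames.shape}"
            )
        if self.frames.shape[0] < 2:
            raise InputError("a frame sequence needs at least 2 frames")
        if self.frames.min() < 0 or self.frames.max() > 255:
            raise InputError("frame intensities must lie in [0, 255]")
        if not self.frame_interval > 0:
            raise InputError(f"frame_interval must be > 0, got {self.frame_interval}")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        """(height, width) of a single frame."""
        return self.frames.shape[1:]

    @property
    def duration(self) -> float:
        """Total record duration in seconds (n_frames * frame_interval)."""
        return self.n_frames * self.frame_interval

    @property
    def times(self) -> np.ndarray:
        """Acquisition time of each frame in seconds, starting at 0."""
        return np.arange(self.n_frames) * self.frame_interval


def to_grayscale(frames: np.ndarray) -> np.ndarray:
    """Collapse an RGB frame stack to grayscale with standard luma weights."""
    if frames.ndim == 3:
        return frames
    if frames.ndim == 4 and frames.shape[-1] in (3, 4):
        rgb = frames[..., :3].astype(np.float64)
        gray = rgb @ np.asarray(LUMA_WEIGHTS)
        return np.clip(np.rint(gray), 0, 255).astype(np.uint8)
    raise InputError(f"cannot interpret pixel array of shape {frames.shape} as a cine loop")


def _single_to_grayscale(img: np.ndarray) -> np.ndarray:
    """Grayscale conversion for one image (2-D gray or H x W x 3/4 colour)."""
    if img.ndim == 2:
        return img
    if img.ndim == 3 and img.shape[-1] in (3, 4):
        rgb = img[..., :3].astype(np.float64)
        gray = rgb @ np.asarray(LUMA_WEIGHTS)
        return np.clip(np.rint(gray), 0, 255).astype(np.uint8)
    raise InputError(f"cannot interpret image of shape {img.shape} as a grayscale frame")


def read_dicom_sequence(
    path: str | Path, default_interval: float | None = None
) -> FrameSequence:
    """Read a multi-frame DICOM cine loop.

    The frame interval is taken from the Frame Time attribute (0018,1063,
    milliseconds) when present, falling back to ``default_interval``
    (seconds).  Pixel spacing is taken from Pixel Spacing (0028,0030) when
    present.  Colour loops are converted to grayscale by the luma
    combination.

    Raises
    ------
    InputError
        If the file is unreadable or holds a single frame only.
    ConfigError
        If the file has no frame-time metadata and no default was supplied.
    """
    path = Path(path)
    try:
        ds = pydicom.dcmread(path)
        frames = np.asarray(ds.pixel_array)
    except Exception as exc:  # pydicom raises a zoo of exception types
        raise InputError(f"cannot read DICOM file {path}: {exc}") from exc

    n_frames = int(getattr(ds, "NumberOfFrames", 1))
    if n_frames < 2 or (frames.ndim == 2):
        raise InputError(f"{path} is not a cine loop (single frame)")

    gray = to_grayscale(frames)

    frame_time_ms = getattr(ds, "FrameTime", None)
    if frame_time_ms is not None and float(frame_time_ms) > 0:
        interval = float(frame_time_ms) / 1000.0
    elif default_interval is not None:
        interval = float(default_interval)
    else:
        raise ConfigError(
            f"{path} has no FrameTime metadata; supply a default frame interval"
        )

    spacing = None
    ps = getattr(ds, "PixelSpacing", None)
    if ps is not None:
        spacing = float(ps[0])

    return FrameSequence(
        frames=gray,
        frame_interval=interval,
        pixel_spacing=spacing,
        source_id=str(path),
    )


def _numeric_sort_key(name: str) -> tuple:
    """Sort key placing embedded integers in numeric order (f2 < f10)."""
    parts = re.split(r"(\d+)", name)
    return tuple(int(p) if p.isdigit() else p for p in parts)


def read_image_directory(path: str | Path, frame_interval: float) -> FrameSequence:
    """Read a directory of sequentially numbered grayscale images.

    Files are loaded in lexicographic-numeric order of their names, so
    ``f1, f2, f10`` order correctly without zero padding.
    """
    path = Path(path)
    if not path.is_dir():
        raise InputError(f"{path} is not a directory")
    files = sorted(
        (p for p in path.iterdir() if p.suffix.lower() in _IMAGE_SUFFIXES),
        key=lambda p: _numeric_sort_key(p.name),
    )
    if len(files) < 2:
        raise InputError(f"{path} holds {len(files)} image(s); at least 2 are required")

    frames = []
    shape = None
    for f in files:
        img = _single_to_grayscale(np.asarray(iio.imread(f)))
        if shape is None:
            shape = img.shape
        elif img.shape != shape:
            raise InputError(
                f"mixed image dimensions in {path}: {f.name} is {img.shape}, expected {shape}"
            )
        frames.append(img)

    return FrameSequence(
        frames=np.stack(frames),
        frame_interval=float(frame_interval),
        pixel_spacing=None,
        source_id=str(path),
    )


def write_curves(
    curves: "KinematicCurves",
    cycles: "CycleAnnotation | None",
    path: str | Path,
    pixel_spacing: float | None = None,
    config: dict | None = None,
) -> Path:
    """Write kinematic curves as CSV plus a JSON metadata sidecar.

    The CSV has columns ``time_s, interframe_h_px, interframe_v_px,
    cumulative_h_px, cumulative_v_px, gs_percent`` (plus ``*_mm`` columns
    when ``pixel_spacing`` is given and ``length_px`` when band length is
    available).  The sidecar ``<path>.meta.json`` records the detected
    period, peaks, troughs and the configuration used.

    Returns the path of the written CSV.
    """
    if curves.time is None or len(curves.time) == 0:
        raise InputError("cannot write empty curves")
    path = Path(path)

    cols: dict[str, np.ndarray] = {
        "time_s": np.asarray(curves.time, dtype=float),
        "interframe_h_px": np.asarray(curves.interframe_h, dtype=float),
        "interframe_v_px": np.asarray(curves.interframe_v, dtype=float),
        "cumulative_h_px": np.asarray(curves.cumulative_h, dtype=float),
        "cumulative_v_px": np.asarray(curves.cumulative_v, dtype=float),
    }
    if curves.gs is not None:
        cols["gs_percent"] = np.asarray(curves.gs, dtype=float)
    if curves.length is not None:
        cols["length_px"] = np.asarray(curves.length, dtype=float)
    if pixel_spacing is not None:
        cols["cumulative_h_mm"] = cols["cumulative_h_px"] * pixel_spacing
        cols["cumulative_v_mm"] = cols["cumulative_v_px"] * pixel_spacing

    try:
        pd.DataFrame(cols).to_csv(path, index=False, float_format="%.6f")
    except OSError as exc:
        raise InputError(f"cannot write curves to {path}: {exc}") from exc

    meta: dict = {"config": config or {}}
    if cycles is not None:
        meta["period_T_s"] = float(cycles.period_T)
        meta["peaks"] = [int(i) for i in cycles.peaks]
        meta["troughs"] = [int(i) for i in cycles.troughs]
        meta["source_curve"] = cycles.source_curve
    sidecar = path.with_suffix(path.suffix + ".meta.json")
    sidecar.write_text(json.dumps(meta, indent=2, sort_keys=True))
    return path
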