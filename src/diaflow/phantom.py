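"""Synthetic speckle phantoms of a breathing diaphragm band.

No clinical recordings ship with this package, so every stage is exercised
on synthetic cine loops with exact ground truth: a bright, gently curved
band (the diaphragm) over a darker background, both textured with
multiplicative speckle-like noise that is frozen in the band's material
frame and advected with the motion — the temporal coherence real speckle
exhibits under small tissue motion, which is what makes optical-flow
tracking possible in the first place.

Motion model, per frame time t:

* rigid sinusoidal translation with configurable horizontal/vertical
  amplitudes and period (one breathing cycle per period);
* an optional linear drift (pixels/frame) added to the vertical
  translation, emulating the slow baseline wander the drift-correction
  stage must remove;
* an along-band stretch realized as an isotropic similarity scaling s(t)
  about the band centre, so every length scales exactly by s(t) and the
  true global strain is GS(t) = (s(t) - 1) * 100.  The strain profile is
  -(A/2) * (1 - cos(2*pi*t/T)): GS starts at 0, dips to -A at mid-cycle
  (inspiratory contraction, negative strain) and returns to 0, so the
  programmed GS peak-to-peak equals the strain amplitude A.

Frames are rendered by backward-mapping pixel coordinates into the static
material image with cubic spline interpolation and quantizing to 8 bit.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np
from scipy import ndimage

from .errors import InputError
from .video_io import FrameSequence

#: Margin (pixels) around the image when building the material texture, so
#: backward-mapped coordinates never leave it at realistic amplitudes.
_PAD = 32


@dataclass
class PhantomSpec:
    """Geometry, motion and noise parameters of a synthetic cine loop.

    Defaults describe a desk-scale recording: a 2 s breathing period
    sampled at 25 fps over 4 cycles, 3 px vertical and 5 px horizontal
    translation amplitude, 10 % strain amplitude and a 0.05 px/frame
    vertical drift.
    """

    image_size: tuple[int, int] = (160, 224)
    band_center_row: int = 70
    band_thickness: float = 12.0
    band_curvature: float = 10.0  # dome sagitta in pixels
    band_col_margin: float = 24.0  # gap between band ends and the lateral image edges
    band_mean_intensity: float = 200.0
    background_mean_intensity: float = 60.0
    speckle_sigma: float = 10.0  # gray levels (band-referred)
    n_frames: int = 200
    frame_interval: float = 0.04
    breath_period: float = 2.0
    translation_amplitude_h: float = 5.0
    translation_amplitude_v: float = 3.0
    strain_amplitude: float = 10.0  # percent, peak along-band shortening
    drift_rate: float = 0.05  # pixels/frame, added to vertical translation
    breath_profile: str = "sinusoid"  # or "asymmetric"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_frames < 2:
            raise InputError("phantom needs at least 2 frames")
        if self.breath_period < 4 * self.frame_interval:
            raise InputError(
                "breath_period must be at least 4 frame intervals to be resolvable"
            )


@dataclass
class PhantomTruth:
    """Exact per-frame ground truth of a rendered phantom.

    ``translation_h/v`` are the actual applied translations (the vertical
    one includes the linear drift); ``length`` and ``gs`` describe the true
    band geometry; ``mask0`` is the true binary band mask of frame 0.
    """

    translation_h: np.ndarray
    translation_v: np.ndarray
    length: np.ndarray
    gs: np.ndarray
    period: float
    mask0: np.ndarray
    drift_rate: float = 0.0

    @property
    def cyclic_translation_v(self) -> np.ndarray:
        """Vertical translation with the linear drift component removed."""
        return self.translation_v - self.drift_rate * np.arange(len(self.translation_v))


def _profile(phase: np.ndarray, kind: str) -> tuple[np.ndarray, np.ndarray]:
    """Translation profile p(phase) and unit strain profile q(phase).

    p is a zero-start unit-amplitude oscillation; q runs 0 -> 1 -> 0 over a
    cycle (fraction of peak contraction).
    """
    if kind == "sinusoid":
        warped = phase
    elif kind == "asymmetric":
        # faster inhale / slower exhale via phase warping
        warped = phase - 0.35 * np.sin(phase)
    else:
        raise InputError(f"unknown breath_profile {kind!r}")
    return np.sin(warped), 0.5 * (1.0 - np.cos(warped))


def _motion(spec: PhantomSpec) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-frame translation (h, v) and scale factor s(t)."""
    t = np.arange(spec.n_frames) * spec.frame_interval
    phase = 2.0 * np.pi * t / spec.breath_period
    p, q = _profile(phase, spec.breath_profile)
    trans_h = spec.translation_amplitude_h * p
    trans_v = spec.translation_amplitude_v * p + spec.drift_rate * np.arange(spec.n_frames)
    s = 1.0 - (spec.strain_amplitude / 100.0) * q
    return trans_h, trans_v, s


def _material_image(spec: PhantomSpec) -> tuple[np.ndarray, np.ndarray, float]:
    """Static material-frame texture, band indicator and centreline length.

    Returns ``(intensity, band_weight, centerline_length)`` on the padded
    material grid.  ``band_weight`` is the soft band indicator in [0, 1].
    """
    H, W = spec.image_size
    rows = np.arange(-_PAD, H + _PAD, dtype=np.float64)[:, None]
    cols = np.arange(-_PAD, W + _PAD, dtype=np.float64)[None, :]

    cc = (W - 1) / 2.0
    half_span = cc
    xi = (cols - cc) / half_span  # -1..1 across the frame
    centerline = spec.band_center_row - spec.band_curvature * (1.0 - xi**2)
    dist = np.abs(rows - centerline)
    band_w = np.clip(spec.band_thickness / 2.0 + 0.5 - dist, 0.0, 1.0)
    # taper the band ends so the band sits clear of the lateral image edges
    # (tracked points must not exit the frame at realistic stretch/translation)
    margin = spec.band_col_margin
    lateral = np.clip(np.minimum(cols - margin, (W - 1 - margin) - cols) + 0.5, 0.0, 1.0)
    band_w = band_w * lateral

    rng = np.random.default_rng(spec.seed)
    speckle = ndimage.gaussian_filter(
        rng.standard_normal(band_w.shape), sigma=1.2, mode="wrap"
    )
    speckle /= speckle.std()

    mean_img = spec.background_mean_intensity + (
        spec.band_mean_intensity - spec.background_mean_intensity
    ) * band_w
    intensity = mean_img * (1.0 + (spec.speckle_sigma / spec.band_mean_intensity) * speckle)
    intensity = ndimage.gaussian_filter(intensity, sigma=0.8, mode="nearest")
    intensity = np.clip(intensity, 0.0, 255.0)

    # true centreline arc length over the band's lateral extent
    c = np.arange(int(np.ceil(margin)), int(W - margin), dtype=np.float64)
    xi_c = (c - cc) / half_span
    r_c = spec.band_center_row - spec.band_curvature * (1.0 - xi_c**2)
    centerline_length = float(
        np.sqrt(np.diff(c) ** 2 + np.diff(r_c) ** 2).sum()
    )
    return intensity, band_w, centerline_length


def render_sequence(spec: PhantomSpec) -> tuple[FrameSequence, PhantomTruth]:
    """Render a phantom cine loop with its exact ground truth.

    Fully reproducible from ``spec.seed``.  Raises :class:`InputError`
    naming the first frame at which the band would leave the image.
    """
    H, W = spec.image_size
    trans_h, trans_v, scale = _motion(spec)
    intensity, band_w, centerline_length = _material_image(spec)

    cc = (W - 1) / 2.0
    center = np.array([spec.band_center_row, cc])

    # band-fit check: vertical extent of the band under each frame's transform
    band_top = spec.band_center_row - spec.band_curvature - spec.band_thickness / 2.0
    band_bot = spec.band_center_row + spec.band_thickness / 2.0
    for t in range(spec.n_frames):
        top = center[0] + scale[t] * (band_top - center[0]) + trans_v[t]
        bot = center[0] + scale[t] * (band_bot - center[0]) + trans_v[t]
        if top < 0 or bot > H - 1:
            raise InputError(
                f"band exits the frame vertically at frame {t} "
                f"(extent [{top:.1f}, {bot:.1f}] vs image height {H})"
            )
        left = center[1] + scale[t] * (spec.band_col_margin - center[1]) + trans_h[t]
        right = center[1] + scale[t] * (W - 1 - spec.band_col_margin - center[1]) + trans_h[t]
        if left < 0 or right > W - 1:
            raise InputError(
                f"band exits the frame laterally at frame {t} "
                f"(extent [{left:.1f}, {right:.1f}] vs image width {W})"
            )

    grid_r, grid_c = np.meshgrid(
        np.arange(H, dtype=np.float64), np.arange(W, dtype=np.float64), indexing="ij"
    )
    frames = np.empty((spec.n_frames, H, W), dtype=np.uint8)
    for t in range(spec.n_frames):
        # backward map: image -> material coordinates
        mr = center[0] + (grid_r - trans_v[t] - center[0]) / scale[t] + _PAD
        mc = center[1] + (grid_c - trans_h[t] - center[1]) / scale[t] + _PAD
        vals = ndimage.map_coordinates(intensity, [mr, mc], order=3, mode="nearest")
        frames[t] = np.clip(np.rint(vals), 0, 255).astype(np.uint8)

    # frame-0 transform is identity (profiles start at zero), so the true
    # mask is the unpadded band indicator
    mask0 = band_w[_PAD : _PAD + H, _PAD : _PAD + W] > 0.5

    truth = PhantomTruth(
        translation_h=trans_h,
        translation_v=trans_v,
        length=centerline_length * scale,
        gs=(scale - 1.0) * 100.0,
        period=spec.breath_period,
        mask0=mask0,
        drift_rate=spec.drift_rate,
    )
    seq = FrameSequence(
        frames=frames,
        frame_interval=spec.frame_interval,
        pixel_spacing=None,
        source_id=f"phantom(seed={spec.seed})",
    )
    return seq, truth


def write_fixture(
    seq: FrameSequence, truth: PhantomTruth, path: str | Path, spec: PhantomSpec | None = None
) -> Path:
    """Save a rendered phantom as a PNG directory plus truth.json.

    The directory can be read back with
    :func:`diaflow.video_io.read_image_directory`, so the full pipeline can
    be exercised from disk exactly as with clinical data.
    """
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    for t in range(seq.n_frames):
        iio.imwrite(path / f"frame_{t:04d}.png", seq.frames[t])
    payload = {
        "frame_interval": seq.frame_interval,
        "translation_h": truth.translation_h.tolist(),
        "translation_v": truth.translation_v.tolist(),
        "length": truth.length.tolist(),
        "gs": truth.gs.tolist(),
        "period": truth.period,
        "drift_rate": truth.drift_rate,
        "mask0": truth.mask0.astype(int).tolist(),
    }
    if spec is not None:
        payload["spec"] = asdict(spec)
    (path / "truth.json").write_text(json.dumps(payload))
    return path


def read_truth(path: str | Path) -> PhantomTruth:
    """Load a truth.json written by :func:`write_fixture`."""
    data = json.loads((Path(path) / "truth.json").read_text())
    return PhantomTruth(
        translation_h=np.asarray(data["translation_h"]),
        translation_v=np.asarray(data["translation_v"]),
        length=np.asarray(data["length"]),
        gs=np.asarray(data["gs"]),
        period=float(data["period"]),
        mask0=np.asarray(data["mask0"], dtype=bool),
        drift_rate=float(data.get("drift_rate", 0.0)),
    )
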