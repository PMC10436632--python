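"""Shared fixtures: small phantoms and synthetic DICOM loops.

All fixtures are generated programmatically; nothing is read from disk
except files the tests themselves write to tmp_path.
"""

from __future__ import annotations

import numpy as np
import pytest

from diaflow import PhantomSpec, render_sequence


def small_phantom_spec(**overrides) -> PhantomSpec:
    """A fast desk-scale phantom: ~2.5 cycles, 100 frames, 96x144 px."""
    defaults = dict(
        image_size=(96, 144),
        band_center_row=44,
        band_thickness=10.0,
        band_curvature=6.0,
        band_col_margin=20.0,
        n_frames=100,
        frame_interval=0.04,
        breath_period=1.6,
        translation_amplitude_h=3.0,
        translation_amplitude_v=2.0,
        strain_amplitude=8.0,
        drift_rate=0.03,
        seed=11,
    )
    defaults.update(overrides)
    return PhantomSpec(**defaults)


@pytest.fixture(scope="session")
def small_phantom():
    """Rendered small phantom (sequence, truth) shared across tests."""
    spec = small_phantom_spec()
    seq, truth = render_sequence(spec)
    return spec, seq, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def make_speckle_frame(rng, shape=(64, 96), sigma=1.5, lo=40.0, hi=200.0):
    """A smooth random texture frame with strong gradients everywhere."""
    from scipy import ndimage

    field = ndimage.gaussian_filter(rng.standard_normal(shape), sigma=sigma)
    field = (field - field.min()) / (field.max() - field.min())
    return lo + (hi - lo) * field


def translate_frame(frame, drow, dcol):
    """Shift a frame by (drow, dcol) with cubic interpolation."""
    from scipy import ndimage

    H, W = frame.shape
    rr, cc = np.meshgrid(np.arange(H, dtype=float), np.arange(W, dtype=float), indexing="ij")
    return ndimage.map_coordinates(frame, [rr - drow, cc - dcol], order=3, mode="nearest")
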