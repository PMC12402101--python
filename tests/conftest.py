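"""Shared fixtures and synthetic-data helpers."""

from __future__ import annotations

import numpy as np
import pytest

from spottrack import CameraModel, Focus, Track


@pytest.fixture
def camera() -> CameraModel:
    return CameraModel(gain=0.6, offset=100.0, read_noise=1.6, bit_depth=16)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(42)


def gaussian_spot_frame(shape=(64, 64), x=30.0, y=30.0, total_photons=1000.0,
                        sigma=1.4, background=0.0):
    """Noiseless frame with one integrated-amplitude Gaussian spot."""
    yy, xx = np.mgrid[0:shape[0], 0:shape[1]]
    g = np.exp(-((xx - x) ** 2 + (yy - y) ** 2) / (2 * sigma ** 2))
    return background + total_photons * g / (2 * np.pi * sigma ** 2)


def make_focus(frame=0, x=10.0, y=10.0, intensity=100.0, snr=1.0,
               sigma=1.4) -> Focus:
    return Focus(frame=frame, x=x, y=y, intensity=intensity,
                 background_mean=0.0, background_sd=1.0, snr=snr,
                 sigma_x=sigma, sigma_y=sigma, n_mask_pixels=81)


def make_track(track_id=0, positions=None, intensities=None, frames=None,
               snr=1.0, sigma=1.4) -> Track:
    """Track from raw position / intensity arrays (frames default 0..n-1)."""
    positions = np.atleast_2d(positions)
    n = len(positions)
    if intensities is None:
        intensities = np.full(n, 100.0)
    if frames is None:
        frames = np.arange(n)
    foci = [make_focus(int(f), float(p[0]), float(p[1]), float(i), snr, sigma)
            for f, p, i in zip(frames, positions, intensities)]
    return Track(id=track_id, foci=foci)
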