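"""Image-stack and mask I/O, camera count/photon conversion, track tables.

The camera model is a simple affine one: ``photons = (counts - offset) * gain``
with gain in photoelectrons per count (photoelectrons are reported as photons
throughout — the convention used when brightness values are printed as
"photons (counts)"; quantum efficiency is not re-applied).  Intensities that
are already background-subtracted convert with the gain alone, since the
offset cancels in the subtraction.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import tifffile
from skimage.measure import regionprops

logger = logging.getLogger("spottrack")

#: Default camera: sCMOS in 16-bit mode, 0.6 photoelectrons/count, 100-count offset.
DEFAULT_GAIN = 0.6
DEFAULT_OFFSET = 100.0


class UnitsError(ValueError):
    """Raised when an operation receives data in the wrong units."""


@dataclass(frozen=True)
class CameraModel:
    """Affine camera response: counts -> photoelectrons (reported as photons).

    Parameters
    ----------
    gain : float
        Photoelectrons per camera count (dimensionless conversion factor).
    offset : float
        Dark offset in counts added by the camera electronics.
    read_noise : float
        RMS read noise in photoelectrons.
    bit_depth : int
        ADC bit depth; the saturation level is ``2**bit_depth - 1`` counts.
    """

    gain: float = DEFAULT_GAIN
    offset: float = DEFAULT_OFFSET
    read_noise: float = 1.6
    bit_depth: int = 16

    def __post_init__(self) -> None:
        if self.gain <= 0:
            raise ValueError("gain must be positive")
        if self.offset < 0:
            raise ValueError("offset must be non-negative")
        if self.read_noise < 0:
            raise ValueError("read_noise must be non-negative")


@dataclass
class ImageStack:
    """A time-ordered stack of 2D frames plus acquisition metadata.

    ``frames`` has axis order (frame, row, column).  ``channel_pattern`` labels
    each frame position within one repeating excitation cycle, e.g.
    ``("yellow", "red")`` for alternating two-colour excitation.  ``units``
    flags whether pixel values are raw camera counts or photons.
    """

    frames: np.ndarray
    pixel_size: float  # nm
    frame_interval: float  # ms
    exposure_time: float  # ms
    channel_pattern: tuple[str, ...] = ("0",)
    units: str = "counts"

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3:
            raise ValueError("frames must be a 3D (frame, row, col) array")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")
        if self.frame_interval < self.exposure_time:
            raise ValueError("frame_interval must be >= exposure_time")
        self.channel_pattern = tuple(self.channel_pattern)
        if len(self.frames) % len(self.channel_pattern) != 0:
            raise ValueError(
                "channel_pattern length must divide evenly into frame count"
            )
        if self.units not in ("counts", "photons"):
            raise ValueError("units must be 'counts' or 'photons'")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        return self.frames.shape[1:]

    def channels(self) -> dict[str, "ImageStack"]:
        """De-interleave into one single-channel stack per pattern label."""
        period = len(self.channel_pattern)
        out = {}
        for i, name in enumerate(self.channel_pattern):
            out[name] = ImageStack(
                frames=self.frames[i::period],
                pixel_size=self.pixel_size,
                frame_interval=self.frame_interval * period,
                exposure_time=self.exposure_time,
                channel_pattern=(name,),
                units=self.units,
            )
        return out


@dataclass
class NuclearSegment:
    """Binary nuclear mask with a moment-fitted in-plane ellipse.

    ``a`` and ``b`` are the semi-major and semi-minor axes in micrometres,
    obtained from the second central moments of the mask.
    """

    mask: np.ndarray
    area: int  # pixels
    a: float  # semi-major axis, µm
    b: float  # semi-minor axis, µm
    pixel_size: float  # nm
    label: str = ""

    @property
    def area_um2(self) -> float:
        return self.area * (self.pixel_size / 1000.0) ** 2


# ---------------------------------------------------------------------------
# Count <-> photon conversion
# ---------------------------------------------------------------------------

def counts_to_photons(values, camera: CameraModel, *, background_subtracted: bool = False):
    """Convert camera counts to photons via ``(counts - offset) * gain``.

    Background-subtracted intensities (differences of counts) use the gain
    only, since the offset has already cancelled.  Negative results are kept:
    noise fluctuations below the offset carry information about the
    background statistics and must not be clipped.

    Accepts a scalar, an array, or an :class:`ImageStack` (whose ``units``
    flag must be ``counts``; the returned stack is flagged ``photons``).
    """
    if isinstance(values, ImageStack):
        if values.units != "counts":
            raise UnitsError("stack is not in counts")
        frames = counts_to_photons(
            values.frames.astype(float), camera,
            background_subtracted=background_subtracted,
        )
        out = dataclasses.replace(values, frames=frames)
        out.units = "photons"
        return out
    offset = 0.0 if background_subtracted else camera.offset
    return (np.asarray(values, dtype=float) - offset) * camera.gain


def photons_to_counts(values, camera: CameraModel, *, background_subtracted: bool = False):
    """Exact inverse of :func:`counts_to_photons` (affine bijection)."""
    if isinstance(values, ImageStack):
        if values.units != "photons":
            raise UnitsError("stack is not in photons")
        frames = photons_to_counts(
            values.frames, camera, background_subtracted=background_subtracted
        )
        out = dataclasses.replace(values, frames=frames)
        out.units = "counts"
        return out
    offset = 0.0 if background_subtracted else camera.offset
    return np.asarray(values, dtype=float) / camera.gain + offset


# ---------------------------------------------------------------------------
# Stack I/O
# ---------------------------------------------------------------------------

_META_KEYS = ("pixel_size", "frame_interval", "exposure_time", "channel_pattern", "units")


def write_stack(stack: ImageStack, path) -> None:
    """Write a stack as multi-page TIFF with metadata in the image description."""
    meta = {
        "pixel_size": stack.pixel_size,
        "frame_interval": stack.frame_interval,
        "exposure_time": stack.exposure_time,
        "channel_pattern": list(stack.channel_pattern),
        "units": stack.units,
    }
    tifffile.imwrite(path, stack.frames, description=json.dumps(meta),
                     photometric="minisblack")


def read_stack(path, **overrides) -> ImageStack:
    """Read a TIFF/OME-TIFF stack.

    Metadata come from the file's JSON image description where present;
    explicit keyword overrides (``pixel_size``, ``frame_interval``,
    ``exposure_time``, ``channel_pattern``, ``units``) win.  Missing required
    metadata with no override is an error.
    """
    with tifffile.TiffFile(path) as tif:
        frames = tif.asarray()
        meta: dict = {}
        desc = tif.pages[0].description
        if desc:
            try:
                parsed = json.loads(desc)
                if isinstance(parsed, dict):
                    meta = {k: parsed[k] for k in _META_KEYS if k in parsed}
            except (json.JSONDecodeError, TypeError):
                pass
    if frames.ndim == 2:
        frames = frames[None]
    meta.update({k: v for k, v in overrides.items() if v is not None})
    for req in ("pixel_size", "frame_interval"):
        if req not in meta:
            raise ValueError(f"stack metadata missing {req!r}; pass it explicitly")
    meta.setdefault("exposure_time", meta["frame_interval"])
    meta.setdefault("channel_pattern", ("0",))
    meta.setdefault("units", "counts")
    stack = ImageStack(frames=frames, **meta)
    logger.info("read %d frames of %s from %s", stack.n_frames, stack.shape, path)
    return stack


def read_mask(path) -> np.ndarray:
    """Read an 8-bit binary mask image; any non-zero pixel is foreground."""
    arr = tifffile.imread(path)
    if arr.ndim != 2:
        raise ValueError("mask must be a single 2D image")
    return arr > 0


# ---------------------------------------------------------------------------
# Track tables
# ---------------------------------------------------------------------------

FOCUS_COLUMNS = ["track_id", "frame", "x_px", "y_px", "intensity_photons",
                 "snr", "sigma_x_px", "sigma_y_px"]
SUMMARY_COLUMNS = ["track_id", "n_foci", "initial_intensity", "stoichiometry",
                   "diffusivity", "mean_snr"]


def write_track_table(tracks: Sequence, path) -> None:
    """Write per-focus detail CSV plus a per-track summary CSV.

    ``path`` is the detail file; the summary is written alongside with a
    ``_summary`` suffix.  Coordinates are 0-based with pixel centres at
    integers.
    """
    path = Path(path)
    detail_rows = []
    summary_rows = []
    for tr in tracks:
        for f in tr.foci:
            detail_rows.append({
                "track_id": tr.id, "frame": f.frame, "x_px": f.x, "y_px": f.y,
                "intensity_photons": f.intensity, "snr": f.snr,
                "sigma_x_px": f.sigma_x, "sigma_y_px": f.sigma_y,
            })
        summary_rows.append({
            "track_id": tr.id, "n_foci": tr.n_foci,
            "initial_intensity": tr.initial_intensity,
            "stoichiometry": tr.stoichiometry,
            "diffusivity": tr.diffusivity,
            "mean_snr": tr.mean_snr,
        })
    pd.DataFrame(detail_rows, columns=FOCUS_COLUMNS).to_csv(path, index=False)
    summary_path = path.with_name(path.stem + "_summary" + path.suffix)
    pd.DataFrame(summary_rows, columns=SUMMARY_COLUMNS).to_csv(summary_path, index=False)


def read_track_table(path) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Read the (detail, summary) pair written by :func:`write_track_table`."""
    path = Path(path)
    detail = pd.read_csv(path)
    summary_path = path.with_name(path.stem + "_summary" + path.suffix)
    summary = pd.read_csv(summary_path)
    return detail, summary


# ---------------------------------------------------------------------------
# Nuclear segment ellipse fit
# ---------------------------------------------------------------------------

def segment_ellipse(mask: np.ndarray, pixel_size: float, label: str = "") -> NuclearSegment:
    """Fit an ellipse to a binary mask by image moments.

    Semi-axes are half the regionprops major/minor axis lengths (the ellipse
    with the same normalised second central moments as the mask), converted
    to micrometres.  Degenerate masks (single pixel, or a line with zero
    minor axis) raise rather than returning a zero axis.
    """
    mask = np.asarray(mask).astype(bool)
    if not mask.any():
        raise ValueError("mask is empty")
    # treat all foreground as one region: label image is the mask itself
    props = regionprops(mask.astype(np.uint8))
    p = props[0]
    a_px = p.axis_major_length / 2.0
    b_px = p.axis_minor_length / 2.0
    if b_px <= 0:
        raise ValueError("degenerate mask: minor axis is zero")
    scale = pixel_size / 1000.0  # nm -> µm
    return NuclearSegment(
        mask=mask, area=int(mask.sum()), a=a_px * scale, b=b_px * scale,
        pixel_size=pixel_size, label=label,
    )
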