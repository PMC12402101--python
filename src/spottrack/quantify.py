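"""Nucleus-level quantification in molecular equivalents.

The integrated nuclear intensity is the sum of pixel photons over a nuclear
segment in the first fluorescence frame, normalised by the characteristic
molecular brightness.  Subtracting the (area-adjusted) mean of an unlabelled
autofluorescence control yields the total protein number; dividing by the
prolate-spheroid nuclear volume and Avogadro's number gives the
nucleoplasmic concentration.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.constants import Avogadro

from .camera_io import CameraModel, ImageStack, NuclearSegment, counts_to_photons
from .track import Track


@dataclass
class NuclearQuant:
    """Per-nucleus quantities in molecular equivalents."""

    equivalents: float  # integrated nuclear intensity / B
    area_px: int
    area_um2: float
    n_tracks: int = 0
    track_density: float = np.nan  # per µm²


def integrated_nuclear_intensity(stack: ImageStack, segment: NuclearSegment,
                                 brightness: float,
                                 camera: CameraModel | None = None,
                                 n_initial_frames: int = 1,
                                 bleach_tau_frames: float | None = None) -> float:
    """Integrated nuclear intensity in molecular equivalents.

    Pixel values in the first fluorescence frame are offset-corrected,
    converted to photons, summed within the mask and divided by the
    characteristic molecular brightness.  Optionally the first
    ``n_initial_frames`` are averaged with exponential photobleach
    back-correction (requires ``bleach_tau_frames``).
    """
    if brightness <= 0:
        raise ValueError("brightness must be positive")
    mask = segment.mask
    if mask.shape != stack.shape:
        raise ValueError("mask shape does not match the stack frames")
    if stack.units == "counts":
        camera = camera or CameraModel()
        frames = counts_to_photons(stack.frames[:n_initial_frames].astype(float), camera)
    else:
        frames = stack.frames[:n_initial_frames].astype(float)
    if n_initial_frames == 1:
        total = float(frames[0][mask].sum())
    else:
        if bleach_tau_frames is None:
            raise ValueError("averaging initial frames requires bleach_tau_frames")
        sums = np.array([f[mask].sum() for f in frames])
        corr = np.exp(np.arange(n_initial_frames) / bleach_tau_frames)
        total = float((sums * corr).mean())
    return total / brightness


def total_protein_number(labelled: list[NuclearQuant],
                         control: list[NuclearQuant]) -> tuple[float, float]:
    """Autofluorescence-corrected mean protein number per nucleus.

    ``N = mean(labelled) - mean(control) * (mean area labelled / mean area
    control)``; the s.e. propagates the two s.e.m.s (the control term scaled
    by the same area ratio).
    """
    if not labelled or not control:
        raise ValueError("both datasets must be non-empty")
    lab = np.array([q.equivalents for q in labelled], dtype=float)
    ctl = np.array([q.equivalents for q in control], dtype=float)
    area_ratio = (np.mean([q.area_um2 for q in labelled])
                  / np.mean([q.area_um2 for q in control]))
    n = lab.mean() - ctl.mean() * area_ratio
    sem_lab = lab.std(ddof=1) / np.sqrt(len(lab)) if len(lab) > 1 else 0.0
    sem_ctl = ctl.std(ddof=1) / np.sqrt(len(ctl)) if len(ctl) > 1 else 0.0
    se = float(np.hypot(sem_lab, sem_ctl * area_ratio))
    return float(n), se


def copy_number_correction(n_labelled: float, labelled_fraction: float) -> float:
    """Scale a labelled-only copy number to the total over all gene copies.

    With a labelled fraction f (e.g. 0.5 for one labelled and one
    equal-expressing unlabelled copy), ``N_total = N_labelled / f``.
    """
    if not 0 < labelled_fraction <= 1:
        raise ValueError("labelled_fraction must lie in (0, 1]")
    return n_labelled / labelled_fraction


def nuclear_volume_um3(segment: NuclearSegment) -> float:
    """Prolate-spheroid volume: in-plane major axis unique, (4/3) pi a b^2."""
    if segment.a <= 0 or segment.b <= 0:
        raise ValueError("degenerate segment axes")
    return (4.0 / 3.0) * np.pi * segment.a * segment.b ** 2


def nuclear_concentration(n_molecules: float, segment: NuclearSegment) -> float:
    """Nucleoplasmic concentration in molar: N / (V * N_A), V in litres."""
    if n_molecules < 0:
        raise ValueError("molecule number must be non-negative")
    v_litres = nuclear_volume_um3(segment) * 1e-15  # 1 µm³ = 1e-15 L
    return n_molecules / (v_litres * Avogadro)


def track_density(tracks: list[Track], segment: NuclearSegment) -> tuple[int, float]:
    """Count of tracks starting inside the mask, and per-µm² density."""
    if segment.area <= 0:
        raise ValueError("segment area must be positive")
    mask = segment.mask
    h, w = mask.shape
    count = 0
    for t in tracks:
        f = t.foci[0]
        r, c = int(round(f.y)), int(round(f.x))
        if 0 <= r < h and 0 <= c < w and mask[r, c]:
            count += 1
    return count, count / segment.area_um2
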