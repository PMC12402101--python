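"""Photobleaching analysis: Chung-Kennedy filtering, characteristic
molecular brightness, initial track intensity and stoichiometry.

The characteristic molecular brightness B is the most common intensity step
observed for tracks in the final stage of photobleaching — estimated as the
mode of a kernel density over the Chung-Kennedy-filtered terminal intensity
of qualifying tracks.  Stoichiometry is the ratiometric count
``S = I0 / B``, with the initial intensity I0 obtained by backward
extrapolation of the first few focus intensities to the pre-bleach frame.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter1d
from scipy.optimize import curve_fit

from .track import Track

CK_WINDOW = 10
CK_EXPONENT = 2
KDE_WIDTH_FRACTION = 0.3  # kernel width = 0.3 x running median terminal level
TERMINAL_QUALIFY_FACTOR = 2.5  # last CK level must be < 2.5 x running B


@dataclass
class BrightnessEstimate:
    """Characteristic molecular brightness with bootstrap uncertainty."""

    brightness: float  # B, photons/frame
    se: float
    n_tracks: int
    kde_grid: np.ndarray
    kde_density: np.ndarray


def chung_kennedy(series, window: int = CK_WINDOW, p: float = CK_EXPONENT) -> np.ndarray:
    """Edge-preserving Chung-Kennedy filter.

    Each point is a weighted combination of the mean over a backward-looking
    and a forward-looking window (both including the point), with weights
    proportional to the inverse p-th power of the corresponding window
    variance, so the smoother window on the point's own side of a step
    dominates and step edges survive.  Edges of the series use truncated
    windows.
    """
    x = np.asarray(series, dtype=float)
    n = len(x)
    if n < 2:
        raise ValueError("series must have length >= 2")
    out = np.empty(n)
    eps = 1e-12
    for i in range(n):
        back = x[max(0, i - window + 1): i + 1]
        fwd = x[i: min(n, i + window)]
        mb, mf = back.mean(), fwd.mean()
        vb = back.var() if len(back) > 1 else 0.0
        vf = fwd.var() if len(fwd) > 1 else 0.0
        wb = 1.0 / (vb + eps) ** p
        wf = 1.0 / (vf + eps) ** p
        out[i] = (wb * mb + wf * mf) / (wb + wf)
    return out


def _fixed_width_kde(values: np.ndarray, width: float,
                     grid: np.ndarray | None = None,
                     grid_step: float | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Gaussian KDE with a fixed kernel width, via fine histogram + smoothing."""
    values = np.asarray(values, dtype=float)
    if grid is None:
        step = grid_step if grid_step is not None else max(width / 6.0, 1e-6)
        lo = values.min() - 4 * width
        hi = values.max() + 4 * width
        grid = np.arange(lo, hi + step, step)
    step = grid[1] - grid[0]
    hist, _ = np.histogram(values, bins=np.concatenate([grid - step / 2, [grid[-1] + step / 2]]))
    density = gaussian_filter1d(hist.astype(float), sigma=width / step, mode="constant")
    density /= (len(values) * step)
    return grid, density


def terminal_intensity(track: Track, window: int = CK_WINDOW) -> float:
    """Last Chung-Kennedy-filtered intensity level of a track."""
    return float(chung_kennedy(track.intensities, window)[-1])


def estimate_characteristic_brightness(
    tracks: list[Track], window: int = CK_WINDOW,
    qualify_factor: float = TERMINAL_QUALIFY_FACTOR,
    kde_width_fraction: float = KDE_WIDTH_FRACTION,
    n_bootstrap: int = 200, min_tracks: int = 10,
    rng: np.random.Generator | None = None,
) -> BrightnessEstimate:
    """Estimate B from the CK-filtered terminal intensities of tracks.

    Terminal levels are pooled over tracks with at least 2 foci; a first-pass
    KDE mode gives a running estimate used to exclude tracks whose terminal
    level exceeds ``qualify_factor`` times it (tracks lost by diffusion
    mid-bleach rather than bleaching to the final step).  B is the KDE mode
    of the qualifying terminal levels, kernel width
    ``kde_width_fraction x median``; the s.e. is a bootstrap over tracks.
    """
    candidates = [t for t in tracks if t.n_foci >= 2]
    terms = np.array([terminal_intensity(t, window) for t in candidates])
    terms = terms[terms > 0]
    if len(terms) < min_tracks:
        raise ValueError(
            f"only {len(terms)} qualifying tracks (<{min_tracks}); pool "
            "acquisitions of the same sample to calibrate brightness"
        )

    def _mode(vals: np.ndarray) -> float:
        width = kde_width_fraction * np.median(vals)
        grid, dens = _fixed_width_kde(vals, width)
        return float(grid[np.argmax(dens)])

    running = _mode(terms)
    kept = terms[terms < qualify_factor * running]
    if len(kept) < min_tracks:
        kept = terms
    width = kde_width_fraction * np.median(kept)
    grid, dens = _fixed_width_kde(kept, width)
    b = float(grid[np.argmax(dens)])
    rng = rng or np.random.default_rng(0)
    boots = np.empty(n_bootstrap)
    for i in range(n_bootstrap):
        sample = rng.choice(kept, size=len(kept), replace=True)
        boots[i] = _mode(sample)
    return BrightnessEstimate(
        brightness=b, se=float(boots.std(ddof=1)), n_tracks=len(kept),
        kde_grid=grid, kde_density=dens,
    )


def initial_track_intensity(track: Track, n_points: int = 5,
                            method: str = "linear",
                            decay_tau_frames: float | None = None) -> float:
    """Backward-extrapolated intensity at the first exposure frame.

    By default a straight line is fitted to intensity versus frame over the
    first ``min(n_points, n_foci)`` foci and evaluated at frame 0 (the
    acquisition's first exposure) — the minimal model over so short an early
    window.  If the fitted slope is positive — photobleaching cannot
    brighten a track — the mean of those foci is used instead.
    ``method='exponential'`` back-projects with a known photobleach decay
    constant instead: I0 = mean(I_i * exp(frame_i / tau)).
    """
    if track.n_foci < 3:
        raise ValueError("need at least 3 foci to extrapolate initial intensity")
    k = min(n_points, track.n_foci)
    frames = track.frames[:k].astype(float)
    vals = track.intensities[:k]
    if method == "exponential":
        if decay_tau_frames is None or decay_tau_frames <= 0:
            raise ValueError("exponential back-projection needs decay_tau_frames")
        return float(np.mean(vals * np.exp(frames / decay_tau_frames)))
    if method != "linear":
        raise ValueError("method must be 'linear' or 'exponential'")
    slope, intercept = np.polyfit(frames, vals, 1)
    if slope > 0:
        return float(vals.mean())
    return float(intercept)


def stoichiometry(track: Track, brightness: float,
                  decay_time_frames: float | None = None) -> float:
    """Molecules per assembly: initial intensity over molecular brightness.

    The value is continuous (not rounded).  If the photobleach decay time is
    supplied, tracks that begin later than a quarter of it are flagged
    ``late_start`` — their stoichiometry is biased low because part of the
    assembly has already bleached.
    """
    if brightness <= 0:
        raise ValueError("brightness must be positive")
    i0 = initial_track_intensity(track)
    s = i0 / brightness
    track.initial_intensity = i0
    track.stoichiometry = s
    if decay_time_frames is not None and track.start_frame > decay_time_frames / 4:
        track.flags.add("late_start")
    return s


def photobleach_decay_time(intensity_series, frame_interval_ms: float | None = None):
    """Exponential decay constant of an integrated-intensity series.

    Fits ``A * exp(-t / tau) + C`` to intensity versus frame index and
    returns tau in frames (and in ms when the frame interval is given).
    Non-decaying series raise.
    """
    y = np.asarray(intensity_series, dtype=float)
    t = np.arange(len(y), dtype=float)
    if len(y) < 4:
        raise ValueError("series too short for an exponential fit")
    # initial guesses from the sample
    c0 = y.min()
    a0 = max(y[0] - c0, 1e-9)
    if y[0] <= y[-1] or a0 <= 0 or np.allclose(y, y[0]):
        raise ValueError("series does not decay")
    # crude tau guess: frame where the excess halves
    excess = y - c0
    below = np.nonzero(excess <= a0 / 2)[0]
    tau0 = below[0] / np.log(2) if len(below) and below[0] > 0 else len(y) / 4

    def model(t, a, tau, c):
        return a * np.exp(-t / tau) + c

    popt, _ = curve_fit(model, t, y, p0=(a0, tau0, c0),
                        bounds=([0, 1e-6, -np.inf], [np.inf, np.inf, np.inf]),
                        maxfev=10000)
    tau = float(popt[1])
    if frame_interval_ms is not None:
        return tau, tau * frame_interval_ms
    return tau
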