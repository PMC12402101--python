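"""Mean-square-displacement analysis and diffusivity matching.

The 2D diffusivity of a track is a quarter of the initial slope of its
time-averaged mean-squared displacement versus lag time.  A free intercept
absorbs the static localisation-error offset (~4 sigma_loc^2).  Diffusivity
matching selects tracks whose D lies within per-track measurement error of a
reference mobility (e.g. a chromosomal locus at 0.20 um^2/s with +/-0.07
per-track error, giving the closed window [0.13, 0.27]).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .track import Track

DEFAULT_N_FIT_LAGS = 4


@dataclass(frozen=True)
class MobilityParams:
    """Fit depth and the reference-mobility matching window."""

    n_fit_lags: int = DEFAULT_N_FIT_LAGS
    d_ref: float = 0.20  # µm²/s
    d_err: float = 0.07  # µm²/s, per-track measurement error

    def __post_init__(self) -> None:
        if self.n_fit_lags < 2:
            raise ValueError("n_fit_lags must be >= 2")
        if self.d_ref <= 0 or self.d_err < 0:
            raise ValueError("invalid reference mobility window")


def msd(positions_um: np.ndarray, frame_interval_ms: float):
    """Time-averaged MSD of one trajectory over all overlapping pairs.

    Returns ``(lag_times_s, msd_um2, counts)`` for lags 1..n-1.
    """
    pos = np.asarray(positions_um, dtype=float)
    n = len(pos)
    if n < 3:
        raise ValueError("track too short for MSD analysis")
    lags = np.arange(1, n)
    out = np.empty(len(lags))
    counts = np.empty(len(lags), dtype=int)
    for i, lag in enumerate(lags):
        d = pos[lag:] - pos[:-lag]
        out[i] = (d ** 2).sum(axis=1).mean()
        counts[i] = len(d)
    return lags * frame_interval_ms / 1000.0, out, counts


def track_msd(track: Track, pixel_size_nm: float, frame_interval_ms: float):
    return msd(track.positions_um(pixel_size_nm), frame_interval_ms)


def diffusivity(positions_um: np.ndarray, frame_interval_ms: float,
                params: MobilityParams = MobilityParams()) -> tuple[float, bool]:
    """Per-track D from the initial MSD slope.

    An unweighted straight line (free intercept) is fitted over the first
    ``n_fit_lags`` lags; D = slope / 4.  Negative fitted slopes are clamped
    to D = 0 and flagged so they can be excluded from ensemble means.
    Returns ``(D_um2_per_s, clamped_flag)``.
    """
    pos = np.asarray(positions_um, dtype=float)
    if len(pos) < params.n_fit_lags + 1:
        raise ValueError("track too short for the requested number of fit lags")
    taus, m, _ = msd(pos, frame_interval_ms)
    k = params.n_fit_lags
    slope, _ = np.polyfit(taus[:k], m[:k], 1)
    if slope < 0:
        return 0.0, True
    return float(slope / 4.0), False


def track_diffusivity(track: Track, pixel_size_nm: float, frame_interval_ms: float,
                      params: MobilityParams = MobilityParams()) -> float:
    d, clamped = diffusivity(track.positions_um(pixel_size_nm),
                             frame_interval_ms, params)
    track.diffusivity = d
    if clamped:
        track.flags.add("negative_msd_slope")
    return d


def matches_reference(d: float, params: MobilityParams = MobilityParams()) -> bool:
    """True iff D lies in the closed window [d_ref - d_err, d_ref + d_err]."""
    return params.d_ref - params.d_err <= d <= params.d_ref + params.d_err
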