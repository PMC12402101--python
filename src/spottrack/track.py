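"""Frame-to-frame linking of foci into tracks, sifting, and SNR thresholds.

Foci in consecutive frames are linked when their centroids lie within 8
pixels and their width and intensity ratios fall in [0.5, 2] and [0.5, 3]
respectively; among suitable candidates the spatially nearest is chosen, and
each focus joins at most one track.  There is no gap closing: "consecutive"
is literal.  Sifting keeps tracks whose mean focus SNR clears a strict
threshold and which contain at least 3 consecutive foci; the threshold itself
is calibrated as the SNR at which retained positives (single-molecule
control) and retained negatives (noise-only control) occur at equal
per-acquisition frequency.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .detect import Focus

LINK_RADIUS_PX = 8.0
WIDTH_RATIO_RANGE = (0.5, 2.0)
INTENSITY_RATIO_RANGE = (0.5, 3.0)
MIN_CONSECUTIVE = 3


@dataclass
class Track:
    """A chain of foci in strictly consecutive frames for one assembly."""

    id: int
    foci: list[Focus] = field(default_factory=list)
    initial_intensity: float = np.nan  # I0, photons
    stoichiometry: float = np.nan  # molecules
    diffusivity: float = np.nan  # µm²/s
    flags: set = field(default_factory=set)

    @property
    def n_foci(self) -> int:
        return len(self.foci)

    @property
    def frames(self) -> np.ndarray:
        return np.array([f.frame for f in self.foci])

    @property
    def positions(self) -> np.ndarray:
        """(n, 2) array of (x, y) centroids in pixels."""
        return np.array([[f.x, f.y] for f in self.foci])

    @property
    def intensities(self) -> np.ndarray:
        return np.array([f.intensity for f in self.foci])

    @property
    def mean_snr(self) -> float:
        return float(np.mean([f.snr for f in self.foci]))

    @property
    def start_frame(self) -> int:
        return self.foci[0].frame

    def positions_um(self, pixel_size_nm: float) -> np.ndarray:
        return self.positions * (pixel_size_nm / 1000.0)


def _mean_sigma(f: Focus) -> float:
    s = np.nanmean([f.sigma_x, f.sigma_y])
    return float(s) if np.isfinite(s) else 1.0


def _link_ok(prev: Focus, new: Focus,
             max_distance: float = LINK_RADIUS_PX,
             width_ratio: tuple[float, float] = WIDTH_RATIO_RANGE,
             intensity_ratio: tuple[float, float] = INTENSITY_RATIO_RANGE,
             symmetric: bool = False) -> bool:
    d = np.hypot(new.x - prev.x, new.y - prev.y)
    if d > max_distance:
        return False
    def _ratio_in(r, band):
        if symmetric:
            lo = min(band[0], 1 / band[1])
            hi = max(band[1], 1 / band[0])
            return lo <= r <= hi
        return band[0] <= r <= band[1]
    sw, pw = _mean_sigma(new), _mean_sigma(prev)
    if pw > 0 and not _ratio_in(sw / pw, width_ratio):
        return False
    if prev.intensity > 0:
        if not _ratio_in(new.intensity / prev.intensity, intensity_ratio):
            return False
    return True


def link_foci(foci_per_frame: list[list[Focus]],
              max_distance: float = LINK_RADIUS_PX,
              symmetric_bands: bool = False) -> list[Track]:
    """Greedy nearest-neighbour linking of per-frame foci into tracks.

    Candidate (track-end, new-focus) pairs within each frame transition are
    processed in ascending centroid distance, so the result is deterministic
    and each focus joins at most one track.  Unlinked foci start new tracks.
    """
    tracks: list[Track] = []
    open_tracks: dict[int, Track] = {}  # keyed by id, ends at previous frame
    next_id = 0
    for t, frame_foci in enumerate(foci_per_frame):
        candidates = []
        for tid, tr in open_tracks.items():
            prev = tr.foci[-1]
            for j, f in enumerate(frame_foci):
                if _link_ok(prev, f, max_distance, symmetric=symmetric_bands):
                    d = np.hypot(f.x - prev.x, f.y - prev.y)
                    candidates.append((d, tid, j))
        candidates.sort(key=lambda c: (c[0], c[1], c[2]))
        used_tracks: set[int] = set()
        used_foci: set[int] = set()
        for d, tid, j in candidates:
            if tid in used_tracks or j in used_foci:
                continue
            open_tracks[tid].foci.append(frame_foci[j])
            used_tracks.add(tid)
            used_foci.add(j)
        # tracks not extended are closed
        next_open: dict[int, Track] = {tid: open_tracks[tid] for tid in used_tracks}
        for j, f in enumerate(frame_foci):
            if j not in used_foci:
                tr = Track(id=next_id, foci=[f])
                next_id += 1
                tracks.append(tr)
                next_open[tr.id] = tr
        open_tracks = next_open
    return tracks


def sift_tracks(tracks: list[Track], snr_threshold: float,
                min_consecutive: int = MIN_CONSECUTIVE) -> list[Track]:
    """Keep tracks with mean focus SNR >= threshold and enough consecutive foci."""
    return [t for t in tracks
            if t.n_foci >= min_consecutive and t.mean_snr >= snr_threshold]


def determine_snr_threshold(positive_tracks: list[Track],
                            negative_tracks: list[Track],
                            n_positive_acq: int = 1,
                            n_negative_acq: int = 1,
                            min_consecutive: int = MIN_CONSECUTIVE) -> tuple[float, bool]:
    """Calibrate the sifting SNR threshold from positive and negative controls.

    Scans thresholds over the observed per-track mean-SNR range and returns
    the value where the per-acquisition frequency of retained positive-control
    tracks equals that of retained negative-control tracks, linearly
    interpolated at the crossing (ties broken toward the higher threshold).
    Fully separated controls return the flagged midpoint between the largest
    negative and smallest positive SNR.

    Returns ``(threshold, separated_flag)``.
    """
    if not positive_tracks or not negative_tracks:
        raise ValueError("both control sets must be non-empty")
    pos = np.sort([t.mean_snr for t in positive_tracks if t.n_foci >= min_consecutive])
    neg = np.sort([t.mean_snr for t in negative_tracks if t.n_foci >= min_consecutive])
    if len(neg) == 0 or (len(pos) and neg.max() < pos.min()):
        lo = neg.max() if len(neg) else 0.0
        hi = pos.min() if len(pos) else lo
        return float((lo + hi) / 2), True
    if len(pos) == 0:
        return float(neg.max()), True
    grid = np.unique(np.concatenate([pos, neg]))
    # frequency of retained tracks per acquisition at each threshold
    f_pos = np.array([(pos >= g).sum() for g in grid]) / n_positive_acq
    f_neg = np.array([(neg >= g).sum() for g in grid]) / n_negative_acq
    diff = f_pos - f_neg
    # find the last sign change scanning upward (ties toward higher threshold)
    crossing = None
    for i in range(len(grid) - 1):
        if diff[i] == 0:
            crossing = float(grid[i])
        elif diff[i] * diff[i + 1] < 0:
            # linear interpolation between grid[i] and grid[i+1]
            x0, x1 = grid[i], grid[i + 1]
            y0, y1 = diff[i], diff[i + 1]
            crossing = float(x0 - y0 * (x1 - x0) / (y1 - y0))
    if diff[-1] == 0:
        crossing = float(grid[-1])
    if crossing is None:
        # no crossing inside the observed range: controls effectively separated
        return float((neg.max() + pos.min()) / 2), True
    return crossing, False


def match_tracks_to_truth(tracks: list[Track], truth_positions: np.ndarray,
                          tol_px: float = 2.0) -> np.ndarray:
    """Score tracks against simulator ground truth.

    A track is a true positive when the median distance between its foci and
    the nearest true assembly position in the matching frames is within
    ``tol_px``.  Returns a boolean array over tracks.
    """
    n_frames = truth_positions.shape[0]
    out = np.zeros(len(tracks), dtype=bool)
    for i, tr in enumerate(tracks):
        dists = []
        for f in tr.foci:
            if f.frame >= n_frames or truth_positions.shape[1] == 0:
                continue
            d = np.hypot(truth_positions[f.frame, :, 0] - f.x,
                         truth_positions[f.frame, :, 1] - f.y)
            dists.append(d.min())
        if dists and np.median(dists) <= tol_px:
            out[i] = True
    return out


def positive_predictive_value(tracks: list[Track], truth_positions: np.ndarray,
                              tol_px: float = 2.0) -> float:
    """Fraction of tracks that match a true emitter within tolerance."""
    if not tracks:
        return np.nan
    return float(match_tracks_to_truth(tracks, truth_positions, tol_px).mean())
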