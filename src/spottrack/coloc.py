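"""Two-colour colocalisation: channel registration, candidate selection,
track-pair overlap events, residence times, and the random-coincidence null.

Two tracks are deemed colocalised over a run of shared frames when their
fitted Gaussian profiles overlap by at least 50% (equivalently a lateral
separation of ~3 pixels at typical widths) while their centroids remain
within 7 pixels, for at least 3 consecutive shared frames.  The overlap
fraction is the normalised cross-correlation of the two elliptical Gaussians
at their measured separation, which for circular spots reduces to
``exp(-d^2 / (2 (sigma_1^2 + sigma_2^2)))``.  The chance-coincidence
expectation follows continuum nearest-neighbour statistics of a random
Poisson point process: ``P = 1 - exp(-lambda pi r^2)``.
"""

from __future__ import annotations


import numpy as np

from dataclasses import dataclass

from .detect import Focus
from .track import Track


@dataclass(frozen=True)
class ColocParams:
    overlap_threshold: float = 0.5
    max_distance: float = 7.0  # pixels
    min_frames: int = 3
    frame_interval: float = 10.0  # ms, per-channel (2x camera frame time
    # when excitation alternates between the channels)

    def __post_init__(self) -> None:
        if not 0 < self.overlap_threshold <= 1:
            raise ValueError("overlap_threshold must lie in (0, 1]")
        if self.max_distance <= 0 or self.min_frames < 1:
            raise ValueError("invalid colocalisation parameters")


@dataclass
class ColocEvent:
    track_a: int
    track_b: int
    start_frame: int
    end_frame: int  # inclusive
    mean_overlap: float
    residence_time_ms: float
    stoichiometry_a: float = np.nan
    stoichiometry_b: float = np.nan

    @property
    def n_frames(self) -> int:
        return self.end_frame - self.start_frame + 1


# ---------------------------------------------------------------------------
# Channel registration
# ---------------------------------------------------------------------------

@dataclass
class AffineTransform:
    """2D affine map ``x' = A x + t`` taking channel-B onto channel-A coordinates."""

    matrix: np.ndarray  # (2, 2)
    offset: np.ndarray  # (2,)
    residual: float  # rms residual, pixels

    def apply(self, points: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(points)
        return pts @ self.matrix.T + self.offset


def register_channels(points_b: np.ndarray, points_a: np.ndarray) -> AffineTransform:
    """Least-squares affine transform from matched bead positions.

    ``points_b`` map onto ``points_a`` (both (n, 2), n >= 3, non-collinear).
    """
    b = np.asarray(points_b, dtype=float)
    a = np.asarray(points_a, dtype=float)
    if b.shape != a.shape or b.shape[0] < 3:
        raise ValueError("need at least 3 matched bead pairs")
    design = np.column_stack([b, np.ones(len(b))])
    if np.linalg.matrix_rank(design) < 3:
        raise ValueError("bead positions are collinear; affine fit is degenerate")
    coef, *_ = np.linalg.lstsq(design, a, rcond=None)
    matrix = coef[:2].T
    offset = coef[2]
    pred = design @ coef
    residual = float(np.sqrt(((pred - a) ** 2).sum(axis=1).mean()))
    return AffineTransform(matrix=matrix, offset=offset, residual=residual)


# ---------------------------------------------------------------------------
# Candidate selection and overlap
# ---------------------------------------------------------------------------

def select_locus_candidates(tracks: list[Track], d_max: float, s_min: float,
                            k_brightest: int = 8) -> list[Track]:
    """Slow, bright reference-locus candidates.

    Keeps tracks with diffusivity <= ``d_max`` and stoichiometry > ``s_min``,
    then the ``k_brightest`` by initial intensity (all if fewer).
    """
    ok = [t for t in tracks
          if np.isfinite(t.diffusivity) and t.diffusivity <= d_max
          and np.isfinite(t.stoichiometry) and t.stoichiometry > s_min]
    ok.sort(key=lambda t: t.initial_intensity, reverse=True)
    return ok[:k_brightest]


def overlap_fraction(fa: Focus, fb: Focus) -> float:
    """Normalised cross-correlation of two axis-aligned elliptical Gaussians.

    ``exp(-dx^2/(2(sx_a^2+sx_b^2)) - dy^2/(2(sy_a^2+sy_b^2)))``; equals 1 for
    coincident spots and reduces to ``exp(-d^2/(2(s_a^2+s_b^2)))`` for
    circular ones.
    """
    sxa = fa.sigma_x if np.isfinite(fa.sigma_x) else 1.6
    sxb = fb.sigma_x if np.isfinite(fb.sigma_x) else 1.6
    sya = fa.sigma_y if np.isfinite(fa.sigma_y) else 1.6
    syb = fb.sigma_y if np.isfinite(fb.sigma_y) else 1.6
    dx = fa.x - fb.x
    dy = fa.y - fb.y
    return float(np.exp(-dx ** 2 / (2 * (sxa ** 2 + sxb ** 2))
                        - dy ** 2 / (2 * (sya ** 2 + syb ** 2))))


def colocalise(tracks_a: list[Track], tracks_b: list[Track],
               params: ColocParams = ColocParams(),
               transform: AffineTransform | None = None) -> list[ColocEvent]:
    """Find sustained overlap events between two registered track sets.

    Channel-B foci are mapped through ``transform`` when given (channels from
    alternating excitation should already share a common frame index, each
    channel's foci indexed by its own de-interleaved frame number).  For each
    track pair, maximal runs of consecutive shared frames where the overlap
    fraction meets the threshold and the centroid distance stays within
    ``max_distance`` become events when at least ``min_frames`` long.
    """
    events: list[ColocEvent] = []
    for ta in tracks_a:
        fa_by_frame = {f.frame: f for f in ta.foci}
        for tb in tracks_b:
            run: list[tuple[int, float]] = []

            def _flush():
                if len(run) >= params.min_frames:
                    overlaps = [o for _, o in run]
                    events.append(ColocEvent(
                        track_a=ta.id, track_b=tb.id,
                        start_frame=run[0][0], end_frame=run[-1][0],
                        mean_overlap=float(np.mean(overlaps)),
                        residence_time_ms=len(run) * params.frame_interval,
                        stoichiometry_a=ta.stoichiometry,
                        stoichiometry_b=tb.stoichiometry,
                    ))
                run.clear()

            for fb in tb.foci:
                fa = fa_by_frame.get(fb.frame)
                if fa is None:
                    _flush()
                    continue
                if transform is not None:
                    x, y = transform.apply([fb.x, fb.y])[0]
                    fb = Focus(**{**fb.__dict__, "x": float(x), "y": float(y)})
                d = np.hypot(fa.x - fb.x, fa.y - fb.y)
                ov = overlap_fraction(fa, fb)
                if d <= params.max_distance and ov >= params.overlap_threshold:
                    if run and fb.frame != run[-1][0] + 1:
                        _flush()
                    run.append((fb.frame, ov))
                else:
                    _flush()
            _flush()
    return events


def random_coincidence_probability(density_per_um2: float, radius_um: float) -> float:
    """Chance of a nearest neighbour within ``radius`` under Poisson statistics."""
    if density_per_um2 < 0 or radius_um <= 0:
        raise ValueError("invalid density or radius")
    return float(1.0 - np.exp(-density_per_um2 * np.pi * radius_um ** 2))


def augment_with_prescan(tracks_live: list[Track], prescan_tracks: list[Track],
                         dedupe_radius_px: float = 1.0) -> list[Track]:
    """Append static tracks from a prescan-replicated sequence.

    The prescan best frame I* is replicated in place of every channel-A frame
    and tracked normally elsewhere; here the resulting static tracks are
    appended to the live channel-A list, discarding any whose median centroid
    falls within ``dedupe_radius_px`` of a live track's median centroid.
    """
    out = list(tracks_live)
    next_id = max((t.id for t in out), default=-1) + 1
    live_centroids = [np.median(t.positions, axis=0) for t in out]
    for t in prescan_tracks:
        c = np.median(t.positions, axis=0)
        if any(np.hypot(*(c - lc)) < dedupe_radius_px for lc in live_centroids):
            continue
        t.id = next_id
        next_id += 1
        t.flags.add("prescan")
        out.append(t)
        live_centroids.append(c)
    return out


def make_prescan_stack(n_frames: int, best_frame: np.ndarray) -> np.ndarray:
    """Build the replicated sequence in which every frame is the prescan I*."""
    best_frame = np.asarray(best_frame)
    if best_frame.ndim != 2:
        raise ValueError("I* must be a single 2D frame")
    return np.repeat(best_frame[None], n_frames, axis=0)


def partition_by_stoichiometry(locus_tracks: list[Track], events: list[ColocEvent],
                               s_threshold: float) -> np.ndarray:
    """2x2 contingency of locus candidates: colocalised x partner-above-threshold.

    Rows: locus colocalised with any partner / not colocalised.  Columns:
    partner stoichiometry (max over the locus's events) above / at-or-below
    ``s_threshold``.  Non-colocalised loci count in the second column.
    """
    by_locus: dict[int, list[ColocEvent]] = {}
    for e in events:
        by_locus.setdefault(e.track_a, []).append(e)
    table = np.zeros((2, 2), dtype=int)
    for t in locus_tracks:
        evs = by_locus.get(t.id, [])
        if evs:
            partner_s = np.nanmax([e.stoichiometry_b for e in evs])
            col = 0 if partner_s > s_threshold else 1
            table[0, col] += 1
        else:
            table[1, 1] += 1
    return table
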