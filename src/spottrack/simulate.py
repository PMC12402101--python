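"""Synthetic image sequences and stoichiometry samples with ground truth.

The image simulator renders diffusing molecular assemblies, each carrying a
set of fluorophores at a common (sub-diffraction) position.  Per frame, each
unbleached fluorophore contributes an expected ``B_true`` photons through a
symmetric 2D Gaussian PSF; assemblies take isotropic Brownian steps with
reflecting boundaries; fluorophores bleach irreversibly with probability
``p_b`` per frame; a uniform autofluorescent background is added; Poisson
shot noise, Gaussian read noise and the affine camera response produce the
recorded counts.  The noiseless photon truth and every per-fluorophore bleach
frame are recorded for positive-predictive-value and recovery scoring.

Stoichiometry samples for periodicity testing are drawn either as noisy
Poisson-distributed multiples of an oligomeric subunit (periodic positive
control) or uniformly at random on [1, 30] (aperiodic null).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .camera_io import CameraModel, ImageStack


@dataclass
class SimParams:
    """Conditions for one simulated acquisition.

    Defaults emulate the in-planta single-channel imaging regime: 53 nm
    pixels, 10 ms frames, ~170 nm FWHM PSF (sigma ~72 nm), characteristic
    molecular brightness 76 photons/frame, autofluorescent background 26
    photons/pixel, and a per-frame bleach probability giving a decay constant
    of a few frames.
    """

    field_size: int = 128  # pixels (square)
    pixel_size: float = 53.0  # nm
    frame_interval: float = 10.0  # ms
    exposure_time: float = 10.0  # ms
    psf_sigma: float = 72.0  # nm (~170 nm FWHM)
    n_assemblies: int = 20
    stoichiometry: int | None = 1  # fixed copies per assembly, or None
    subunit: int = 2  # used when stoichiometry is None: Poisson multiples
    mean_multiple: float = 8.0
    brightness: float = 76.0  # B_true, photons/frame/fluorophore
    bleach_prob: float = 0.1  # p_b per frame
    diffusivity: float = 0.2  # µm²/s
    background: float = 26.0  # photons/pixel
    blinking: bool = False  # two-state photoblinking, off by default
    blink_off_prob: float = 0.0  # on -> dark per frame, when blinking
    blink_on_prob: float = 0.5  # dark -> on per frame, when blinking
    read_noise: float = 1.6  # photoelectrons rms (overrides camera's)
    camera: CameraModel = field(default_factory=CameraModel)
    n_frames: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.bleach_prob <= 1:
            raise ValueError("bleach_prob must lie in [0, 1]")
        for name in ("field_size", "pixel_size", "frame_interval",
                     "exposure_time", "psf_sigma", "brightness", "n_frames"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.psf_sigma >= self.field_size * self.pixel_size:
            raise ValueError("psf_sigma exceeds the field extent")
        if self.diffusivity < 0 or self.background < 0:
            raise ValueError("rates must be non-negative")


@dataclass
class GroundTruth:
    """Simulator truth: trajectories, stoichiometries and bleach frames.

    ``positions`` is (n_frames, n_assemblies, 2) in pixels, (x, y) order;
    ``stoichiometries`` the initial fluorophore count per assembly;
    ``bleach_frames`` a list per assembly of the frame index at which each
    fluorophore went dark (``n_frames`` if it survived the acquisition);
    ``clean_frames`` the expected photon image per frame before any noise.
    """

    positions: np.ndarray
    stoichiometries: np.ndarray
    bleach_frames: list[np.ndarray]
    clean_frames: np.ndarray
    pixel_size: float

    def n_unbleached(self, frame: int) -> np.ndarray:
        """Fluorophores still emitting in a given frame, per assembly."""
        return np.array([(bf > frame).sum() for bf in self.bleach_frames])


def simulate_stack(params: SimParams) -> tuple[ImageStack, GroundTruth]:
    """Simulate one acquisition; returns the counts stack and its truth."""
    rng = np.random.default_rng(params.seed)
    n, T = params.n_assemblies, params.n_frames
    size = params.field_size
    sigma_px = params.psf_sigma / params.pixel_size
    px_um = params.pixel_size / 1000.0
    dt = params.frame_interval / 1000.0  # s

    # initial stoichiometries
    if params.stoichiometry is not None:
        stoich = np.full(n, int(params.stoichiometry))
    else:
        mult = rng.poisson(params.mean_multiple, size=n)
        mult = np.maximum(mult, 1)
        stoich = params.subunit * mult

    # Brownian trajectories with reflecting boundaries, in pixels
    step_sd_px = np.sqrt(2 * params.diffusivity * dt) / px_um
    pos = np.empty((T, n, 2))
    if n:
        pos[0] = rng.uniform(0, size - 1, size=(n, 2))
        for t in range(1, T):
            nxt = pos[t - 1] + rng.normal(0, step_sd_px, size=(n, 2))
            # reflect into [0, size-1]
            span = size - 1
            nxt = np.abs(nxt)
            nxt = span - np.abs(span - nxt % (2 * span))
            pos[t] = nxt
    # Per-fluorophore bleach frames: every fluorophore emits in frame 0 and
    # goes dark after a Geometric(p_b) number of frames, so the expected
    # number still emitting in frame t is k * (1 - p_b)^t.
    bleach_frames = []
    for k in stoich:
        if params.bleach_prob > 0:
            bf = rng.geometric(params.bleach_prob, size=int(k))
            bf = np.minimum(bf, T)
        else:
            bf = np.full(int(k), T)
        bleach_frames.append(bf)

    clean = np.empty((T, size, size))
    frames = np.empty((T, size, size))
    read_noise = params.read_noise
    on_state = [np.ones(int(k), dtype=bool) for k in stoich]
    for t in range(T):
        if n:
            if params.blinking:
                for i in range(n):
                    s = on_state[i]
                    flip_off = rng.random(s.size) < params.blink_off_prob
                    flip_on = rng.random(s.size) < params.blink_on_prob
                    on_state[i] = np.where(s, ~flip_off, flip_on)
                active = np.array([((bf > t) & s).sum()
                                   for bf, s in zip(bleach_frames, on_state)])
            else:
                active = np.array([(bf > t).sum() for bf in bleach_frames])
        else:
            active = np.zeros(0)
        amps = active * params.brightness
        img = np.zeros((size, size))
        if n:
            r = int(np.ceil(4 * sigma_px))
            for (x, y), a in zip(pos[t], amps):
                if a <= 0:
                    continue
                c0, c1 = max(0, int(x) - r), min(size, int(x) + r + 1)
                r0, r1 = max(0, int(y) - r), min(size, int(y) + r + 1)
                if c0 >= c1 or r0 >= r1:
                    continue
                gx = np.exp(-((np.arange(c0, c1) - x) ** 2) / (2 * sigma_px ** 2))
                gy = np.exp(-((np.arange(r0, r1) - y) ** 2) / (2 * sigma_px ** 2))
                img[r0:r1, c0:c1] += a * np.outer(gy, gx) / (2 * np.pi * sigma_px ** 2)
        img += params.background
        clean[t] = img
        noisy = rng.poisson(img).astype(float)
        if read_noise > 0:
            noisy += rng.normal(0, read_noise, size=noisy.shape)
        frames[t] = noisy / params.camera.gain + params.camera.offset

    stack = ImageStack(
        frames=frames, pixel_size=params.pixel_size,
        frame_interval=params.frame_interval, exposure_time=params.exposure_time,
        units="counts",
    )
    truth = GroundTruth(
        positions=pos, stoichiometries=stoich, bleach_frames=bleach_frames,
        clean_frames=clean, pixel_size=params.pixel_size,
    )
    return stack, truth


def simulate_single_molecule_control(params: SimParams | None = None, **kw) -> tuple[ImageStack, GroundTruth]:
    """Sparse single-fluorophore positive control for threshold calibration.

    Fixes stoichiometry at 1 and, by default, slow diffusion and low in-vitro
    style background.  A zero-brightness variant reproduces the noise-only
    negative control, in which every detected track is a false positive.
    """
    if params is None:
        params = SimParams(
            stoichiometry=1, n_assemblies=20, diffusivity=0.05,
            background=2.0, bleach_prob=0.02, **kw,
        )
    else:
        params = replace(params, stoichiometry=1)
    return simulate_stack(params)


def simulate_stoichiometries(kind: str, n: int, subunit: int = 2,
                             mean_multiple: float = 8.0, noise_sd: float = 0.6,
                             lo: float = 1.0, hi: float = 30.0,
                             seed: int | np.random.Generator = 0) -> np.ndarray:
    """Draw a synthetic stoichiometry sample.

    ``periodic``: ``s_i = m * k_i + eps_i`` with ``k_i ~ Poisson(mean_multiple)``
    conditioned to be >= 1 and ``eps_i ~ Normal(0, noise_sd)``.
    ``aperiodic``: continuous uniform on [lo, hi].
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if n < 1:
        raise ValueError("n must be >= 1")
    if kind == "aperiodic":
        return rng.uniform(lo, hi, size=n)
    if kind == "periodic":
        if subunit < 1 or mean_multiple <= 0 or noise_sd < 0:
            raise ValueError("invalid periodic parameters")
        k = rng.poisson(mean_multiple, size=n)
        while (k < 1).any():
            redraw = k < 1
            k[redraw] = rng.poisson(mean_multiple, size=int(redraw.sum()))
        return subunit * k + rng.normal(0, noise_sd, size=n)
    raise ValueError(f"unknown kind {kind!r}")


def simulate_brownian_tracks(n_tracks: int, n_frames: int, diffusivity: float,
                             frame_interval_ms: float = 10.0,
                             loc_noise_um: float = 0.0,
                             seed: int | np.random.Generator = 0) -> list[np.ndarray]:
    """Pure Brownian (x, y) trajectories in µm, optionally with localisation noise.

    A lightweight generator for mobility tests that bypasses image rendering.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    dt = frame_interval_ms / 1000.0
    sd = np.sqrt(2 * diffusivity * dt)
    tracks = []
    for _ in range(n_tracks):
        steps = rng.normal(0, sd, size=(n_frames - 1, 2))
        path = np.vstack([np.zeros(2), np.cumsum(steps, axis=0)])
        if loc_noise_um > 0:
            path = path + rng.normal(0, loc_noise_um, size=path.shape)
        tracks.append(path)
    return tracks
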