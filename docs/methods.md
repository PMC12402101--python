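# Methods

This note documents the models implemented in `spottrack`, the defaults and
their rationale, what the simulator does and does not emulate, and the
numerical choices made where the design was genuinely open. It states no
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## Camera model and units

The camera response is affine: `photons = (counts − offset) × gain`, with
gain in photoelectrons per count (default 0.6) and offset in counts
(default 100), matching a back-illuminated sCMOS in 16-bit mode.
Photoelectrons are reported as photons throughout; quantum efficiency is
not re-applied. Two conversion paths exist deliberately:

- raw pixel values subtract the offset first;
- background-subtracted intensities (spot photometry, brightness values)
  use the gain alone, because the offset has already cancelled in the
  subtraction.

Negative photon values are preserved, never clipped, so background
statistics remain unbiased. Coordinates are 0-based, (x, y) = (column,
row), with pixel centres at integers.

## Spot detection and photometry

Local maxima are found on a 1-px Gaussian-smoothed copy of each frame
(8-connected neighbourhood) to suppress single-pixel noise; all photometry
uses the raw frame. A focus is measured with a circular mask of radius
5 px (81 pixels) inside a 17×17-px window; the background region is the
window minus the mask. The SNR uses the per-pixel form,

    SNR = (I / n_mask) / σ_background ,

which is the form consistent with the worked expectation
(B/area)/√b for a single molecule of brightness B over a Poisson
background b — e.g. (76/30)/√26 ≈ 0.50. The total-intensity form
(I/σ_background) is available behind the same function but is not the
default. The "effective focus area" of ~30 px used in that expectation is
the signal footprint of a ~1.4-px-sigma PSF, not the photometric mask.

Candidates above a permissive SNR of 0.2 are refined by iterative
Gaussian-masked centroiding: the centroid is recomputed under a circular
Gaussian weight (initialised at the nominal PSF sigma, 1.4 px for a
~170 nm FWHM PSF at 53 nm pixels) until the shift falls below 0.01 px or
20 iterations. Elliptical widths come from mask-weighted second moments
with the mask taper inverted analytically: a Gaussian spot of width s
weighted by a mask of width m has measured variance s²m²/(s²+m²). On
simulated spots this agrees with a full nonlinear least-squares Gaussian
fit within 5% (tested). Candidates whose window exits the frame are
discarded; maxima closer than the 5-px integration radius merge to the
brighter one.

## Linking and sifting

Greedy frame-to-frame linking: candidate (track-end, focus) pairs are
processed in ascending centroid distance; a link requires distance ≤ 8 px,
width ratio (new/old, mean sigma) in [0.5, 2] and intensity ratio in
[0.5, 3]. The bands are applied directionally as new/old, as written; a
symmetric-band option exists. There is no gap closing — "consecutive" is
literal. Sifting keeps tracks with at least 3 consecutive foci whose
*mean* focus SNR clears the strict threshold; the mean was chosen over
minimum or median because per-track SNR is reported as a mean elsewhere in
the pipeline. The strict threshold is calibrated as the SNR at which
retained positives (single-molecule control) and retained negatives
(noise-only control) occur at equal per-acquisition frequency, linearly
interpolated at the crossing with ties broken toward the higher threshold;
fully separated controls return a flagged midpoint.

## Brightness, stoichiometry, photobleaching

The Chung–Kennedy filter replaces each point with a variance-weighted
combination of backward- and forward-window means (window 10 samples,
weight exponent p = 2, both config-exposed; the values follow common
step-detection practice). Zero-variance windows dominate via an epsilon
floor, so noiseless steps are preserved exactly.

The characteristic molecular brightness B is the mode of a fixed-width
Gaussian KDE over the Chung–Kennedy terminal intensities of tracks
(kernel width 0.3 × the running median, mirroring the ±14% standard error
used for stoichiometry kernels). Tracks whose terminal level exceeds
2.5 × a first-pass estimate are excluded as having vanished mid-bleach by
diffusion rather than bleaching to the final step. Fewer than 10
qualifying tracks raises an error advising pooling acquisitions of the
same sample. Uncertainty is a bootstrap over tracks.

Initial intensity I₀ is a straight-line fit over a track's first
min(5, n) foci evaluated at frame 0; linear is the minimal model over so
short a window, and an exponential back-projection with a fitted decay
constant is available as an option. Positive fitted slopes (which
photobleaching cannot produce) fall back to the mean. Stoichiometry is the
continuous ratio S = I₀/B; tracks starting later than a quarter of the
photobleach decay time are flagged biased-low. The decay time itself comes
from a single-exponential fit with free offset.

All KDEs with fixed bandwidth are computed as a fine histogram convolved
with a Gaussian (`scipy.ndimage.gaussian_filter1d`); `scipy.stats.
gaussian_kde` is not used because its bandwidth is data-driven, and the
method requires stated kernel widths.

## Stoichiometry periodicity

Pipeline: KDE of the stoichiometry sample (Gaussian kernel width 0.3
molecules for analysis — the single-molecule standard error; 0.6 is for
display only) on a grid of step 0.05 molecules; strict local maxima with
no prominence filter (the kernel provides the smoothing), refined by
parabolic interpolation; nearest-neighbour intervals of the sorted peaks;
interval uncertainty u = 0.6·√(mean S)/√(n intervals), with n counted
before discarding; intervals < u discarded; a second KDE over the
survivors with kernel width u, normalised to unit area so curves are
comparable across samples.

The null curve is the pointwise 95th percentile of these interval
distributions over 100 samples of 10⁴ values uniform on [1, 30]. A sample
is called periodic when a local maximum of its interval distribution
exceeds the null at its own position; the tallest such peak is the
reported periodicity, and the s.e. is the s.e.m. of retained intervals in
the above-null region. For genuinely periodic data this coincides with
restricting the modal search to the above-null region, since the global
mode clears the null.

**Known limitation — attained type-I rate.** The 95th-percentile envelope
controls the false-periodicity rate at any *fixed* interval size. The
decision, however, is taken at the sample's own modal interval — a
selection-biased point — and with 100 null sets the envelope near the mode
region is effectively estimated from the few dozen sets peaking there. The
attained family-wise rate measured by the test suite is ~8–12% rather
than 5%, i.e. uniform aperiodic samples are rejected in roughly 90% of
seeds, not ≥95%. This is a property of the construction itself, not of
sample size; dimer positive controls are still recovered at 2.0 ± 0.3 in
every tested seed. Users needing strict 5% control should raise the
percentile or the number of null sets.

The minimum sample size for reliable peak sampling is 14 × the mean
stoichiometry; smaller samples are flagged underpowered. Replicate spread
is estimated by analysing all C(k, 2) pooled replicate pairs that meet the
rule.

## Mobility

Per-track diffusivity is slope/4 of an unweighted straight-line fit (free
intercept, absorbing the static localisation-error offset ≈ 4σ_loc²) to
the time-averaged MSD over its first 4 lags (the "initial portion" is not
further specified; 4 is config-exposed). Negative slopes clamp to D = 0
with a flag so they can be excluded from means. Diffusivity matching is a
closed interval [D_ref − D_err, D_ref + D_err]; defaults 0.20 and
0.07 µm²/s give [0.13, 0.27].

## Nuclear quantification

Integrated nuclear intensity uses the first fluorescence frame only
(pre-bleach intent); an option averages the first k frames with
exponential bleach back-correction. Total protein number subtracts the
control mean scaled by the labelled/control mean-area ratio (the
adjustment multiplies the control, as defined), with errors propagated
from the two s.e.m.s, applied at dataset level. Nuclear volume is a
prolate spheroid V = (4/3)πab² with the in-plane major axis unique;
concentration is N/(V·N_A). Track density counts sifted tracks whose
first focus lies inside the mask, per µm² of cross-section.

## Two-colour colocalisation

Channels are registered by a least-squares affine transform from matched
bead foci (≥3, non-collinear). The overlap fraction of two foci is the
normalised cross-correlation of their fitted axis-aligned elliptical
Gaussians at the measured separation,

    exp(−dx²/(2(σx₁²+σx₂²)) − dy²/(2(σy₁²+σy₂²))) ,

chosen because at typical widths (σ ≈ 1.6 px) a 50% overlap corresponds to
~2.7–3 px separation, anchoring the stated 50% ⇔ ~3 px equivalence. An
event is a maximal run of ≥3 consecutive shared frames with overlap ≥50%
and centroid distance ≤7 px; residence time is run length × the
per-channel frame interval (twice the camera frame time under alternating
excitation, with channel frames compared at nearest timestamps). Chance
coincidence follows continuum nearest-neighbour statistics,
P = 1 − exp(−λπr²). Locus candidates are the ≤8 brightest tracks with
D ≤ D_ref and S above a stoichiometry floor. Prescan augmentation
replicates the best z-frame I* through the sequence, tracks it, and
appends the resulting static tracks after deduplication within 1 px of a
live track's median centroid.

## Statistics

The Brunner–Munzel test uses mid-rank relative effects with a studentised
statistic and Satterthwaite degrees of freedom (t-approximation by
default, appropriate at the pipeline's sample sizes; a permutation mode is
recommended below ~10 per group). All-tied inputs return the degenerate
p̂ = 0.5, p = 1. Fisher's exact test is two-tailed by the
sum-of-smaller-probability-tables convention — stated explicitly because
two-sided Fisher conventions differ — with a conditional-MLE odds ratio
and exact conditional CI. Bonferroni adjustment is α/m.

## Simulator: what it emulates, and what it does not

Each assembly carries k fluorophores at a coincident position (assemblies
are far below the diffraction limit); positions follow isotropic Brownian
steps of per-axis variance 2DΔt with reflecting boundaries (keeping
density constant for coincidence nulls). Every fluorophore emits an
expected B photons/frame through a symmetric 2D Gaussian PSF while alive
and dies irreversibly with probability p_b per frame (geometric lifetime;
all fluorophores emit in frame 0). A uniform background, per-pixel Poisson
shot noise, Gaussian read noise and the affine camera response complete
the frame; the noiseless photon image and all bleach frames are recorded
as ground truth.

Defaults mirror the in-planta single-channel regime: 53 nm pixels, 10 ms
frames, PSF sigma 72 nm (~170 nm FWHM), B = 76 photons/frame, background
26 photons/pixel, p_b = 0.1/frame, D = 0.2 µm²/s. The periodic
stoichiometry generator draws m·k + ε with k ~ Poisson(λ) conditioned
≥1 and ε ~ N(0, σ_s); σ_s defaults to 0.6 molecules, the single-molecule
spread at the sifting threshold. Aperiodic samples are continuous uniform
on [1, 30].

Not emulated: optical aberrations and defocus (the analysis is 2D+time),
pixel-dependent sCMOS noise maps, photoblinking (a two-state option exists
but is off by default), nuclear texture in the background, and motion blur
within an exposure. Passing tests therefore demonstrate correctness of the
analysis chain under an idealised but statistically faithful imaging
model; they do not certify performance on aberrated or vignetted real
data.

## Problem sizes used in the shipped checks

The end-to-end sifting check uses 10 simulated fields of 100 frames with
20 single fluorophores each at B = 76 over a low background; periodicity
checks use 10⁴-value samples against a 100-set null; mobility ensembles
use 500–1000 tracks of 15–21 frames. These sizes give stable statistics
while keeping the whole suite fast on a single CPU.
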