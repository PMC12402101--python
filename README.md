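# spottrack

Single-particle tracking and molecular counting for rapid-photobleaching
fluorescence microscopy.

## The problem

Oblique-illumination (HILO-style) microscopy of living tissue can
resolve individual fluorescent-protein–tagged molecules and their
assemblies as sub-diffraction foci, but turning raw image sequences into
biology requires a chain of quantitative steps: detect spots against
autofluorescent background, link them through time, reject noise, convert
intensity into *numbers of molecules* via the unit step of photobleaching,
and test whether those numbers carry structure (oligomeric periodicity,
locus-like mobility, two-colour co-occupancy). `spottrack` implements that
chain as a tested Python library with a bundled simulator, so every stage
can be validated against ground truth without any experimental data.

It is aimed at microscopists and image-analysis developers working on
single-molecule counting in noisy, living samples (plant roots, nuclei,
tissue) where per-spot signal-to-noise is of order 0.5, not 5.

## The method

- **Detection.** In each frame, local maxima are measured by integrating
  pixel photons within a 5-px-radius mask and subtracting the mean of the
  surrounding 17×17-px window; the signal-to-noise ratio is
  SNR = (I/n_mask)/σ_bg. Candidates above a permissive SNR of 0.2 are
  refined to sub-pixel precision by iterative elliptical Gaussian masking.
- **Tracking and sifting.** Foci in consecutive frames are linked if within
  8 px with width and intensity ratios in [0.5, 2] and [0.5, 3]; tracks are
  kept only if their mean SNR clears a strict threshold (calibrated so true
  and false positives occur at equal frequency in single-molecule vs
  noise-only controls, typically 0.35–0.50) and contain ≥3 consecutive
  foci.
- **Molecular counting.** The characteristic molecular brightness *B* is
  the modal Chung–Kennedy-filtered terminal intensity of tracks — the last
  photobleaching step. A track's stoichiometry is S = I₀/B, with I₀
  back-extrapolated from its first five foci. Camera counts convert to
  photons as (counts − offset) × gain.
- **Periodicity.** The repeat unit of a stoichiometry distribution is the
  most common nearest-neighbour spacing of its kernel-density peaks
  (kernel width 0.3 molecules), with intervals below the uncertainty
  u = 0.6·√(mean S)/√(n intervals) discarded, compared against a null
  curve: the pointwise 95th percentile of interval distributions from 100
  aperiodic uniform samples.
- **Mobility.** D = slope/4 of the time-averaged MSD over its first lags;
  diffusivity matching selects tracks with D within per-track error of a
  reference locus (e.g. 0.20 ± 0.07 µm²/s → [0.13, 0.27]).
- **Quantification and colocalisation.** Integrated nuclear intensity in
  molecular equivalents with autofluorescence-control subtraction; prolate
  spheroid concentrations; two-colour events require ≥50% Gaussian overlap
  within 7 px for ≥3 frames, with chance coincidence 1 − exp(−λπr²).
- **Statistics.** Two-sided Brunner–Munzel rank test and two-tailed
  Fisher's exact test with conditional-MLE odds ratio.

## Worked example

Everything below is synthetic — the simulator renders diffusing assemblies
of photobleaching fluorophores with Poisson shot noise, read noise and the
affine camera response, and keeps the ground truth.

```python
import spottrack as sp

params = sp.SimParams(n_assemblies=10, stoichiometry=8, brightness=76.0,
                      background=26.0, diffusivity=0.2, bleach_prob=0.1,
                      n_frames=40, seed=3)
stack, truth = sp.simulate_stack(params)

photons = sp.counts_to_photons(stack, params.camera)
foci = sp.detect_stack(photons.frames)
tracks = sp.sift_tracks(sp.link_foci(foci), snr_threshold=0.4)

for t in tracks[:3]:
    s = sp.stoichiometry(t, 76.0)
    d = sp.track_diffusivity(t, params.pixel_size, params.frame_interval)
    print(f"track {t.id}: S = {s:.1f} molecules, D = {d:.2f} um2/s")

sample = sp.simulate_stoichiometries("periodic", 10_000, subunit=2,
                                     mean_multiple=8, noise_sd=0.6, seed=7)
null = sp.null_threshold(n_sets=100, n=10_000, seed=5)
res = sp.periodicity_analysis(sample, kernel_width=0.3, null_curve=null)
print(f"periodicity = {res.periodicity:.1f} +/- {res.periodicity_se:.2f}")
```

prints

```
track 0: S = 8.6 molecules, D = 0.27 um2/s
track 1: S = 8.3 molecules, D = 0.05 um2/s
track 2: S = 7.4 molecules, D = 0.09 um2/s
periodicity = 2.0 +/- 0.03
```

The octameric ground truth is recovered as S ≈ 7–9 molecules per track (the
small deficit is fluorophores lost to bleaching before the first detected
frame), and the dimer-built stoichiometry sample yields a periodicity of
2.0 molecules against the aperiodic null.

A command-line interface mirrors the library
(`spottrack simulate|detect|track|brightness|stoich|periodicity|mobility|stats`),
reading and writing TIFF stacks and CSV tables.

## Layout

- `src/spottrack/` — `camera_io`, `simulate`, `detect`, `track`,
  `photometry`, `periodicity`, `mobility`, `quantify`, `coloc`, `stats`,
  plus `config` and the `cli`.
- `tests/` — unit, property and end-to-end acceptance tests (all synthetic).
- `docs/methods.md` — the models, defaults and their rationale.
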