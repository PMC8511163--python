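# fabtirf

Single-molecule and cell-level image analysis for membrane-tethered
synthetic T cell receptor (TCR) ligands — antibody Fab′ fragments coupled
to DNA tethers on supported lipid bilayers (SLBs) — together with a
forward simulator that generates every input with known ground truth.

The package is aimed at quantitative microscopists studying
ligand–receptor engagement at cell–bilayer junctions.  It covers the full
measurement chain:

- **Spot detection and tracking** — difference-of-Gaussians detection with
  sub-pixel centroid refinement, and linear-assignment-problem (LAP)
  frame-to-frame linking.
- **Diffusion** — step-size distributions at multiple delays τ fitted
  simultaneously with the 2-D Brownian model
  ρ(r, τ; D) = (r / 2Dτ) · exp(−r² / 4Dτ); the joint maximum-likelihood
  estimate is D̂ = Σ r²/(4τ) / N.
- **Valency** — photobleaching step counting by penalized change-point
  segmentation, compared with the diffraction-limit coincidence
  probability 1 − exp(−ρπr²).
- **Binding kinetics** — bound-ligand classification from long-exposure
  mobility, censoring-aware exponential dwell-time fitting with the
  photobleach correction 1/τ_off = 1/τ_obs − duty/τ_bleach, and the
  long/short-exposure fraction-bound estimator.
- **Cell activation** — NFAT nucleus/cytosol translocation scoring and
  Hill dose-response fits, f(ρ) = max_resp · ρʰ/(ρʰ + EC50ʰ), by binomial
  maximum likelihood with profile-likelihood EC50 intervals.
- **TCR-proximal signaling** — LAT condensate detection and tracking with
  a ≥4-frame persistence filter, per-cell condensate/binding-event
  ratios, and Mann-Whitney group comparison.
- **Geometry** — maximum intermembrane spacing of DNA-tether designs
  (0.34 nm/bp duplex + 0.6 nm/nt single-stranded poly(dT), calibrated to
  the 14 nm native pMHC:TCR anchor) and evanescent-field intensity versus
  fluorophore height.

## Worked example

Simulate a TIRF movie of ligands diffusing at 2.49 μm²/s, track them, and
fit the diffusion coefficient:

```sh
$ fabtirf simulate --density 0.06 --d-free 2.49 --box-um 25 --n-frames 80 \
    --exposure-s 0.01 --frame-interval-s 0.04 --seed 42 --out movie.tif
wrote movie.tif (80 frames, 43 molecules)

$ fabtirf track movie.tif tracks.csv
2794 localizations -> 492 tracks

$ fabtirf diffusion tracks.csv --delays 0.04,0.08,0.12 --out fit.json
D = 2.357 μm²/s (95% CI 2.261-2.453)
```

The fitted D sits ~5% below the simulated truth: with a 10 ms exposure in
a 40 ms frame interval, each localization is the centroid of a slightly
motion-blurred image, which attenuates apparent displacements by the
well-known blur factor 1 − t_exp/(3Δt) at the shortest delay.  Fitting
ground-truth-sampled tracks (no imaging step) recovers 2.49 within the
CI.  The tether-geometry model, calibrated to the 14 nm anchor:

```sh
$ fabtirf geometry --duplex-nt 16 --polyt-nt 59
{"duplex_nt": 16, "polyT_nt": 59, "max_spacing_nm": 49.39999999999999}
```

i.e. a 76-nucleotide tether permits up to ~50 nm of intermembrane space.
All analysis stages are equally usable as library functions
(`fabtirf.fit_brownian`, `fabtirf.fit_dwell_distribution`,
`fabtirf.fit_dose_response`, …); see the module docstrings.

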