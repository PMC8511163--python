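# Methods

This note documents the models implemented in `fabtirf`, the simulator
that exercises them, the defaults that matter, and the numerical choices
made where the design was genuinely open.  It states no empirical result
that the test suite or `scripts/acceptance.py` does not itself compute.

## The measurement problem

A T cell rests on a supported lipid bilayer (SLB) presenting mobile,
fluorescently labelled ligands (Fab′–DNA constructs or pMHC) at surface
densities of 0.01–1 μm⁻².  Under TIRF illumination only the ~100 nm
nearest the glass is excited, so individual membrane-bound ligands are
visible as diffraction-limited spots.  Five quantities characterize a
ligand: its diffusion coefficient and valency on the bilayer (is it a
freely diffusing monomer?), its receptor dwell time and the fraction of
ligands bound under a cell, the ligand density at which half the cell
population activates (EC50), and the per-binding-event probability of
triggering a proximal LAT condensate.  No reference image data ships with
the package; instead a forward simulator generates every input with known
ground truth, and correctness is established by parameter recovery.

## Simulator

**Trajectories.** Molecules perform 2-D Brownian motion in a square box
with reflecting walls; per-axis substep displacements are N(0, 2D·dt).
Each molecule is `free` (D_free, default 2.5 μm²/s) or `bound` (D_bound,
default 0.01 μm²/s), switching free→bound at rate `k_on_app` and
bound→free at rate 1/τ_off.  Photobleaching is single-step and absorbing;
its exponential clock (τ_bleach) advances only while the molecule is
illuminated (the exposure fraction of each frame).  Trajectories are
advanced at ≥10 substeps per camera exposure so that the motion-blur
integral in rendering is converged.  Reflecting walls preserve density
without bookkeeping molecule exchange; the cost is that positions fold at
the walls, so analyses sensitive to small biases (diffusion recovery)
are run in a box much larger than a trajectory's excursion.

**Rendering.** Each unbleached molecule contributes a pixel-integrated
Gaussian PSF (σ = 0.15 μm) at every substep of the exposure window,
scaled by exp(−h/d) for fluorophore height h and evanescent depth
d = 100 nm.  Expected photon images receive Poisson shot noise (including
a uniform background), camera gain, a constant offset, and Gaussian read
noise.  A 500 ms exposure renders bound molecules as sharp spots and free
molecules as streaks with ≥5× lower peak intensity — the contrast the
"bound-only" imaging mode exploits; a 20 ms exposure resolves all
molecules.

**Photon and camera defaults.** The source experiments do not state
photon budgets or camera noise, so the following were chosen once as
typical for a single-fluorophore TIRF setup and are configurable in
`OpticsModel`: detected photon rate 2×10⁴ s⁻¹ per fluorophore at height
zero, background 100 photons μm⁻² s⁻¹, gain 1, read noise 2 counts,
offset 100 counts, pixel 0.1 μm.

**Fluorophore heights.** The poly(dT) tether holds the fluorophore at a
height drawn from a truncated normal on [0, contour length] with mean at
half the contour length and SD a quarter of it — a deliberately simple
stand-in for the worm-like-chain height distribution (persistence length
1.5–3 nm) that preserves the only property the analysis uses: longer
tethers give larger mean heights and therefore lower mean intensity.

**Intensity traces.** Step-photobleaching traces are sums of
`n_fluorophores` unit levels with independent exponential bleach times
plus Gaussian noise of SD level/SNR.  Populations are conditioned on
observability: every emitter survives at least 5 frames (a particle must
be detected and tracked before its trace can be analyzed, so real trace
populations carry the same selection) and all emitters bleach before the
trace ends.  For multi-emitter populations an optional minimum separation
between bleach events excludes drops closer than a change-point
detector's temporal resolution (two drops within one or two frames merge
into a single taller step for any detector).

**Activation populations and event streams.** Cell activation is
Bernoulli with p(ρ) = max_resp·ρʰ/(ρʰ+EC50ʰ).  Binding-event streams are
Poisson per cell (events uniform in the 120 s observation window); each
event spawns a condensate with probability `p_condensate` after an
exponential lag (mean 4 s, capped at 10 s, within 0.1 μm), persisting
4 + Poisson(3) frames; background condensates arise at a per-cell Poisson
rate.  These defaults mirror the observation conditions of the
experiments the pipeline reproduces (2 s frame lapse, first-2-minute
counting window, condensates forming "a handful of seconds" after
binding).

## Analysis models and numerical choices

**Detection.** Difference-of-Gaussians band-pass (σ₁ = diameter/4,
σ₂ = 1.6σ₁), local maxima above threshold, intensity-weighted centroid in
a window of the expected diameter (default 0.4 μm).  Centroid refinement
was chosen over Gaussian fitting: it is exact for a symmetric PSF, an
order of magnitude faster, and sufficient for step-size statistics at the
working SNR; the function boundary allows a Gaussian fitter to be swapped
in.  The default threshold is 6 robust (MAD-based) SDs of the band-pass
response — the programmatic analogue of a threshold set by eye — giving a
false-positive rate below 0.1 per blank frame.  For long-exposure
bound-only counting the threshold is instead calibrated to 0.3× the
response of an in-focus stationary spot of the full photon budget, which
rejects the motion-blur streaks of free ligands.

**Linking.** Frame-to-frame linear assignment with squared-displacement
costs and birth/death at cost `max_link_dist²`, solved exactly
(`scipy.optimize.linear_sum_assignment`); optional gap closing re-offers
track ends for up to `max_gap` missed frames.  Ties are broken by
smallest displacement, then lowest index, so linking is deterministic.  A
greedy nearest-neighbour fallback exists for testing.  The default link
radius is 3·√(4DΔt) for the expected mobility.

**Diffusion.** All (overlapping) displacements k frames apart enter the
delay-kΔt step-size distribution; the single-component Brownian density
is fitted jointly across delays by maximum likelihood, which has the
closed form D̂ = Σ r²/(4τ)/N.  Overlapping windows and longer delays
reuse the same one-frame increments, so the 95% CI uses the number of
independent increments as its effective sample size (relative SE
1/√n_indep) — the Fisher bound for the underlying data — rather than the
raw step count.  A binned weighted-least-squares fit is provided as a
cross-check.  An optional localization-error term is off by default
because the fitted model as stated has none.  Known limitation: positions
measured from finite-exposure images are blur-averaged centroids, which
attenuate the apparent MSD by ≈(1 − t_exp/3Δt) at the shortest delay; the
package does not correct for this, so diffusion fits on rendered movies
should use exposures short relative to the frame interval.

**Bleach steps.** Binary segmentation of the trace into
piecewise-constant segments, keeping a split when its SSE reduction
exceeds a BIC-style penalty of 10σ²·log n, with σ the MAD of first
differences divided by √2 (robust to the steps themselves).  Only
downward mean shifts of ≥3σ count as bleach steps, which suppresses false
steps at the working SNR; both the penalty scale and the minimum step
height are exposed.  Counts are invariant under multiplicative intensity
rescaling because both the penalty and the step floor scale with σ².

**Dwell times.** On a frame lapse Δ an exponential dwell is geometric
with survival q = e^(−Δ/τ); the censored maximum-likelihood estimate is
closed-form (q̂ = A/(A+n_u) with A the total extra-frame count).  Events
shorter than one lapse are unobservable and excluded, which the
conditional geometric likelihood handles without bias.  Bleaching is
indistinguishable from unbinding in the data, so the observed rate is
corrected by subtracting the bleach hazard: 1/τ_off = 1/τ_obs −
duty/τ_bleach, with τ_bleach measured per illuminated second under the
same duty cycle (a per-wall-clock-second convention is also supported).
First-order rates compose additively, which is the standard form when the
correction itself is not specified.  If the observed rate does not exceed
the bleach rate, or more than half the events are right-censored
(tracking loss near the cell center), τ_off is reported as a lower bound.

**Fraction bound.** Spots are counted inside the cell footprint in paired
long-exposure (bound only) and short-exposure (all ligands) frames and
the fraction is the pooled ratio, clipped to [0, 1].  At realistic
densities a 100 μm² footprint carries only ~5 ligands, so a single frame
pair quantizes the per-cell ratio to multiples of ~1/5 and the median
over cells of such coarse ratios is itself biased; the estimator
therefore pools counts over several (default 6) frame pairs per cell,
which leaves the expectation unchanged and makes the per-cell median
meaningful.

**Bound classification.** A long-exposure track segment is bound while
the 3-frame rolling mean of its frame-to-frame speed stays below
0.5 μm/s.  At 500 ms frames a bound ligand (D ≤ 0.05 μm²/s) has rms
centroid speed ≤0.3 μm/s while a free ligand moves at ~4 μm/s; 0.3 μm/s
itself sits at the bound rms and fragments genuinely bound tracks, so the
threshold is placed several noise SDs above it while remaining ~8× below
free speeds.

**NFAT scoring and segmentation.** Activation is a background-subtracted
nucleus/cytosol mean-intensity ratio strictly greater than one.  The
nucleus is segmented classically (the learned pixel classification used
on real data is replaced for synthetic images, behind the same module
boundary): Otsu split of the smoothed in-footprint intensities, candidate
components must be interior (not touching the footprint boundary — the
"clear nucleus" rule) and, when both intensity polarities yield a
candidate (bright nucleus in activated cells, dark in resting cells), the
more compact one wins.  Cells with no intensity structure, no interior
candidate, or cytosol at background are excluded with QC flags.

**Dose-response.** Binomial maximum likelihood on per-density activation
counts with the Hill coefficient bounded in [0.5, 4] (no functional form
is prescribed by the data; the bound stabilizes fits at desk scale) and
multi-start over h₀ ∈ {0.8, 1.5, 3}.  EC50 CIs come from the profile
likelihood (χ²₁ cutoff).  The plateau can be fixed to a reference
ligand's value to reproduce the extrapolated-fit convention for weak
ligands that never reach their plateau.  Potency ratios are EC50 ratios
with log-scale error propagation.

**LAT condensates.** Per-frame condensate regions are connected
components of the thresholded band-pass response with a minimum area,
linked by the same LAP linker; tracks must persist ≥4 frames (at the 2 s
lapse) to count.  Per-cell ratios of condensates to binding events are
computed over the first 120 s; cells with zero binding events keep an
undefined ratio with a flag (background condensates exist).  Groups are
compared with the two-sided, tie-corrected Mann-Whitney U test, with
stars at p < 10⁻³ / 10⁻⁴ and "ns" above 0.01.

**Geometry.** Maximum intermembrane spacing = duplex_nt·0.34 nm +
polyT_nt·0.6 nm + protein offset, with the offset (8.56 nm) calibrated so
the 16 nt, no-poly(dT) design returns the 14 nm native pMHC:TCR spacing.
This is the fully extended ("up to") bound; the worm-like-chain height
distribution informs the simulator, not the spacing.  The split of the
14 nm anchor between receptor ectodomain, Fab′ and duplex is not
resolved by the calibration and is not claimed.

## Problem sizes

Recovery runs use: 55,000 one-frame steps (100 molecules × 550 frames at
20 ms) per diffusion fit; 150 single-fluorophore traces of 120 frames;
1,000 dwell events at 10 s lapse (500 for the censored lower bound); 30
rendered cells × 6 frame pairs per fraction-bound condition; 200 cells ×
5 densities per dose-response arm; 30 cells × Poisson(10) events for LAT
scoring.  These sizes match the reported experiments where stated and
otherwise keep every recovery's Monte-Carlo error well inside its
acceptance band.

## What passing tests do and do not show

The simulator produces ideal Brownian motion, ideal exponential dwells,
single-population kinetics, isotropic Gaussian PSFs and stationary
backgrounds.  Passing recovery tests therefore demonstrates that the
estimators are correctly implemented and unbiased under their own model
assumptions at realistic SNR — not that real data satisfy those
assumptions.  Known real-data features deliberately out of scope:
fluorophore blinking, anomalous or multi-population diffusion, membrane
microstructure, rebinding, force-dependent unbinding, uneven
illumination, and learned segmentation of complex cell morphologies.
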