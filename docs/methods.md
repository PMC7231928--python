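# Methods

This note documents the models, simulation conditions, numerical choices and
known limitations of the package, module by module.

## Observation-volume model (`zsted.psf`)

The effective detection profile is phenomenological: a separable Gaussian
with lateral FWHM ω and axial FWHM, normalized to 1 at the focus. All
downstream analysis (FCS transit times, image FWHMs) consumes the profile
only through these FWHMs, so no vectorial focal-field computation is
attempted. The z-STED preset adds two satellite axial Gaussians at
z = ±800 nm with the same axial width as the main lobe and a relative peak
amplitude of 0.15; these reproduce the "shadow" images that undepleted side
lobes cast of a membrane. Defaults:

* confocal: ω = 240 nm (bead-calibrated excitation focus), axial 854 nm
  (measured on a supported lipid bilayer, SLB).
* z_sted: axial 108 nm; ω = 168 nm (= 240 × 0.70, the 30% lateral reduction
  measured by STED-FCS calibration); lobes at ±800 nm.
* 2d_sted: ω = 100 nm, axial unchanged at 854 nm. The 100-nm value is a
  typical doughnut-STED lateral size chosen by this package, not a measured
  constant, and the same holds for the 0.15 lobe amplitude; both are plain
  config parameters (`lateral_fwhm_nm`, `side_lobe_rel_amp`) and no
  quantitative claim of the package rests on them.

Lobe width equal to the main axial FWHM is the simplest choice that
reproduces a displaced shadow image of a membrane; nothing downstream is
sensitive to the exact lobe shape, only to its position and relative
amplitude.

## Membrane diffusion simulator (`zsted.diffusion`)

Point emitters diffuse in one or two planes at fixed axial offsets inside a
periodic square box, observed by a fixed observation volume centred in the
box. Per time bin each particle takes an isotropic 2-D Gaussian step of
per-axis variance 2·D·Δt; expected counts are
Σ brightness_peak·Δt·W(x, y, z_membrane) (+ background·Δt) and realized
counts are Poisson draws. Defaults emulate an SLB calibration measurement:

* D = 5 μm²/s, Δt = 2 μs, duration 5 s (typical SLB acquisition length).
* box 2400 nm = 10 lateral FWHMs (enforced guard against periodic-image
  correlations); 220 particles, giving N ≈ 5 in the confocal observation
  area (effective area π·ω²/(2 ln2) ≈ 0.131 μm²).
* brightness_peak 150 kHz: a bright membrane dye; excitation power is not
  modelled, so this is a free parameter.

Positions update once per bin without sub-bin integration: the r.m.s. step
(≈6 nm) is small against ω (>100 nm) and the bin time is three orders of
magnitude below the transit time, so intra-bin blur is negligible. Path
arithmetic runs in float32 (position round-off ~1e-4 nm).

Triplet blinking is an exact discrete two-state Markov chain parameterized
by the equilibrium dark fraction T and the correlation time
τ_T = 1/(k_on+k_off) (default 5 μs), matching the correlation-model
parameterization; the state update is inherently sequential, so traces with
triplet enabled simulate more slowly and the package uses it at shorter
durations in tests. Axial membrane motion, drift and photobleaching are not
modelled.

## Correlator (`zsted.correlator`)

Classic multi-tau layout: 16 channels in the first stage (lags 1–16 bins),
then per stage a twofold bin coarsening with 8 new channels (lags 9–16 in
coarsened units), emulating the quasi-logarithmic grid of hardware
correlators. The default stage count extends the largest lag to ≥10% of the
trace, capped so every lag still averages ≥10 products. Normalization is
symmetric (each lag divides by the means of the actually overlapping direct
and delayed windows), which suppresses slow-drift bias; the zero-lag
shot-noise channel is excluded. On traces ≤2048 bins the output is tested
to agree with an explicit double-loop correlation to 1e-12.

## FCS fitting and calibration (`zsted.fcs`)

Weighted least squares (via lmfit) of the 2-D diffusion + triplet model
with τ_T fixed at 5 μs by default (releasable), bounds N > 0, 0 ≤ T < 0.9,
τ_xy > 0, and initial guesses taken from the curve (N₀ = 1/g(first lag),
τ₀ = lag at half amplitude). Each point gets σ_i ∝ 1/√n_i with n_i the
number of averaged products at that lag — a pragmatic statistical weighting;
the true covariance of multi-tau estimates is more structured, but the fits
are insensitive to this choice here. The default fit window [2 μs, 0.5 s]
drops nothing at the short end beyond the excluded zero-lag channel and
avoids essentially unsampled long lags; fits were checked to be unbiased
(N and τ_xy within estimator scatter of analytic truth over repeated seeds).

No background term is included in the model: a real STED measurement has
spurious background that depresses curve amplitudes (inflating N), and the
package reproduces that behaviour rather than correcting it. In the
simulations used for acceptance the background rate is zero, so fitted N is
unbiased.

Unit notes: ω in nm, τ in s, D reported in μm²/s via
D = ω²/(8 ln2·τ) × 10⁻⁶. The calibration ω_s = ω_c·√(τ_s/τ_c) assumes free
diffusion (equal D in both recordings), valid for the SLB scenario it is
applied to. `normalized_density` implements (N/ω²)/(N_c/ω_c²); picking the
per-cell confocal reference is the caller's responsibility.

## Membrane scenes and image formation (`zsted.scenes`)

Scenes are collections of planes, spherical shells (vesicles), tubes and
tori. A real bilayer (~5 nm) is far below the 20-nm axial voxel, so all
surfaces rasterize to voxel-thin sheets; voxel values carry membrane area
(nm²) × label density, deposited from deterministic area-weighted point
lattices (golden-spiral lattice for spheres, uniform angular grids with the
exact r(R + r·cosθ) area element for tori) at ~5 nm pitch, so total rendered
intensity equals the analytic surface area to rounding.

Grids follow the acquisition convention: axis order (z, y, x), voxel pitch
(20, 40, 40) nm, voxel values are integrals over the voxel. Plane-scene
grids are sized so multiples of 20 nm are voxel centres (membranes land on
slice centres exactly) and extend ±1810 nm axially, enough to contain the
confocal axial kernel and the z-STED lobes.

Imaging convolves the ground truth with the observation-volume kernel
sampled on the same grid and normalized to unit sum (expected intensity is
conserved), then optionally applies seeded Poisson noise. The kernel extends
2 FWHM per axis (plus the lobe offset axially), where the Gaussian is below
~1e-5. Convolution is implemented as FFT convolution over an explicitly
mirror-padded array: mathematically identical to direct spatial convolution
with reflective boundaries (tested against `scipy.ndimage.convolve` in
mirror mode) but tractable for the ~100-voxel-long z-STED kernels. A kernel
half-extent exceeding the stack raises an error advising padding.

## Image metrics (`zsted.metrics`)

* `fit_fwhm`: four-parameter Gaussian fit (amplitude, centre, σ, constant
  baseline); FWHM = σ√(8 ln2). Profiles with two comparable peaks or a peak
  at the window edge are flagged, not silently fitted. On noiseless plane
  images the estimator recovers the generating 854/108 nm axial FWHMs within
  one 20-nm voxel.
* `resolve_two_peaks`: maxima with prominence ≥ 0.1 of the profile maximum
  (configurable), with an additional pairwise valley-depth requirement —
  two neighbouring maxima are distinct only if the valley between them drops
  ≥ 0.1·max below the lower peak. Without this, two equal peaks separated by
  an arbitrarily shallow dip would count as resolved, because topographic
  prominence of equal twins is measured against the far-field baseline.
  When exactly two peaks remain, their separation comes from a two-Gaussian
  fit (shared width), which beats the 20-nm voxel quantization. When the
  detection window would contain z-STED side-lobe shadows, the pipeline
  restricts it to ±300 nm around the membranes; resolvability is a statement
  about the main lobes, and the shadows are a known artifact 800 nm away.
* `hollowness_contrast`: (mean rim maximum − centre value)/(sum), evaluated
  on a profile crossing the structure centre; ≤ 0 means the lumen looks
  filled. The tube scenes use free geometry parameters (default radius
  150 nm, a plausible membrane nanotube at this scale); only the contrast
  *ordering* across presets is asserted, not its value.
* `richardson_lucy`: standard multiplicative RL updates with mirror-padded
  convolutions, initialized from the observed image; default 20 iterations,
  which suppresses the plane-image lobe/main ratio by far more than 5× while
  conserving total intensity to <1e-3. Each update provably increases the
  Poisson likelihood (tested). The choice of 20 iterations balances lobe
  removal against noise amplification; it is a config knob.

## GP spectral imaging (`zsted.gp`)

GP = (I_G − I_R)/(I_G + I_R) per voxel, computed only where
I_G + I_R ≥ threshold (default 5% of the maximum summed intensity — keeps
membrane voxels, drops empty background). Masked voxels carry an explicit
boolean mask rather than NaN sentinels. No bleed-through or G-factor
correction is applied. The synthetic spectral generator assigns one GP per
primitive and splits intensity as I_G = I(1+GP)/2, I_R = I(1−GP)/2, so the
noiseless round trip is exact; the packaged GP scenario (plane GP 0.3,
vesicle GP −0.1, ~2000 expected photons per membrane voxel, Poisson noise,
z-STED imaging) recovers both values to ~0.01 and their ordering robustly.

## Pipelines and reproducibility (`zsted.pipeline`, `zsted.cli`)

The three composite runners (`run-fcs`, `run-imaging`, `run-gp`) execute the
full simulate→analyze→report chains, write CSV/TIFF outputs plus the
resolved YAML config and a stage-timed log, and are bit-reproducible given
config + seed (deterministic stages exactly; stochastic stages via seeded
generators; per-stage seeds are derived from the base seed by fixed small
offsets).

## Acceptance computation (`scripts/acceptance.py`)

All inputs are simulated at desk scale; problem sizes were chosen as the
package's own defaults:

* FCS criteria: three repeat 5-s acquisitions per condition (D = 5 μm²/s,
  2-μs bins, N ≈ 5), with fitted τ_xy and N averaged over repeats as an
  experiment averages repeated curves. Single-fit scatter is ~5–10% at this
  trace length; averaging brings the ratio estimates within a few percent
  of their analytic values (transit-time ratio (240/168)² ≈ 2.04, density
  ratio 2).
* The two-membrane scenario places equally labeled planes at ±75 nm
  (150 nm apart, as for a thin cell) with the same per-membrane particle
  density as the single-membrane runs; the confocal focus spans both, the
  z-STED focus isolates one.
* Resolvability scans two-plane separations in 20-nm steps (the axial voxel)
  from 40 to 400 nm, noiseless, and reports the smallest separation giving
  two detected maxima under z-STED, cross-checked to remain unresolved
  under confocal.

## What the synthetic data do and do not show

The generators reproduce the statistical structure the estimators rely on —
Poisson photon counting, Brownian 2-D diffusion through a Gaussian focus,
triplet-like blinking, PSF blur with axial side lobes, two-channel spectral
splitting. They do not include membrane undulations or axial drift during
acquisition, photobleaching, detector afterpulsing/dead time, refractive
aberrations at depth, spectral bleed-through, or the background haze of a
real cell. Passing tests therefore validate the estimators and their
calibration chain under the stated model, not the hardware; on real data
the same estimators inherit the usual caveats (e.g. STED background
depressing curve amplitudes, aberration sensitivity of the bottle beam).
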