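# Methods

This note documents the models behind `bhkit`, the defaults and why they
were chosen, and what the synthetic-data pipeline does and does not
demonstrate.

## Weak-shock heating and time-to-boil

When a high-amplitude HIFU pulse develops a shock front at the focus,
absorption at the front dominates heating. The heating rate is

H = β f₀ A_s³ / (6 ρ₀² c₀⁴)   [W/m³]

and, neglecting conduction (valid when boiling takes milliseconds), the
time-to-boil is t_b = ΔT c_v / H with ΔT = 100 °C − baseline.

Constants for the polyacrylamide tissue-mimicking phantom
(`PHANTOM_MEDIUM`): β = 4, f₀ = 1.2 MHz, ρ₀ = 1020 kg/m³, c₀ = 1544 m/s,
c_v = 5.3 × 10⁶ J/(m³·°C), baseline 37.5 °C (the thermometry reference, so
ΔT = 62.5 °C). Attenuation defaults to 0.676 dB/(cm·MHz) (liver-like; use
0.8 for cardiac muscle).

**Shock-amplitude convention.** A_s is the peak-to-peak free-field focal
pressure, p₊ + |p₋|, from the hydrophone table. Peak-positive-only
underestimates the pressure jump across the front; peak-to-peak reproduces
the expected cubic scaling of t_b across all four measured powers to within
0.2 % in ratio and ~2 % absolutely. Pressures are *not* derated for the
closed-form t_b (the hydrophone values are free-field, and the convention is
documented rather than hidden); the simulation layer, by contrast, derates
to in-situ amplitude at the 3 cm sonication depth because it models what
happens inside the phantom.

**Pulse timing.** Pulse length = cycles/f₀; duty cycle = pulse length × PRF.
Treatment consoles print these with truncated (not rounded) decimals
(16 000 cycles / 1.2 MHz = 13.33 ms prints as 13.3; a 6.667 % duty cycle as
6.66), so comparisons against printed values truncate first
(`bhkit.units.truncate`).

**Pattern and schedule.** The 27-focus cube (3×3×3, 1 mm spacing) is
traversed layer-by-layer starting at the transducer-proximal layer
(proximal layers shadow distal ones once fractionated, so they are treated
first), row-major within a layer, one pulse per location per visit.
`schedule()` exposes an optional per-location overhead because real systems
add small switching delays; the default is 0 and the nominal duration is
n_foci × repeats / PRF.

**Layer target area.** The confinement target for lethal dose is the
in-plane footprint of one layer dilated by the −6 dB focal width on each
side: (2 mm + 1.6 mm)² ≈ 13 mm².

## Pulsed-heating simulator

A deliberately simple two-timescale model on a uniform cubic grid:

- **Intra-pulse** (ms): conduction is negligible; every voxel jumps by
  H(A_s(r))·τ/c_v, where A_s(r) is a Gaussian ellipsoid around the active
  focus with σ = (−6 dB half-width)/√(2 ln 2): σ_r ≈ 0.68 mm,
  σ_z ≈ 4.25 mm from the 1.6 × 1.6 × 10 mm focal dimensions. Temperatures
  are clamped at 100 °C (vapor formation absorbs the excess; bubble
  dynamics are not modelled) and voxels whose local time-to-boil is ≤ τ are
  flagged *fractionated*. The flag is monotone in time.
- **Inter-pulse** (s): explicit finite-difference diffusion with thermal
  diffusivity 1.35 × 10⁻⁷ m²/s (water-like; configurable) and no perfusion
  (gel phantom / ex vivo context). Sub-stepping keeps the explicit step
  below dx²/(6D); passing a larger step raises an error naming the limit.
  The default boundary condition holds the box edge at baseline,
  emulating the surrounding bulk as a heat sink; an insulating option
  exists for energy-conservation checks.

Snapshots are recorded at the MR dynamic scan time (1.8 s), starting with a
pre-sonication baseline frame.

The spatial profile of the in-situ shock amplitude is not measured
per-voxel in practice; the Gaussian ellipsoid is a modelling choice, and
absolute simulated temperatures should be read qualitatively. What the
model does reproduce robustly: boiling within one pulse at BH amplitudes,
monotone focal-temperature growth with PRF at fixed pulse length, and a
much cooler slice 7 mm from the focus than at the focus.

## PRFS thermometry

Forward model: each thermometry pixel voxel-averages the fine temperature
field over its 2.5 × 2.5 mm in-plane footprint and 7 mm slice thickness
(3 coronal slices at 0/+7/−7 mm along the beam axis — the third offset is
symmetric since only "7 mm from the focus" is specified for the second —
plus one sagittal slice through the axis). The pixel phase is
φ = φ₀ + 2π γ B₀ α ΔT TE with γ = 42.58 MHz/T, B₀ = 1.5 T,
α = −0.01 ppm/°C, TE = 19 ms (≈ −0.076 rad/°C). Complex Gaussian noise is
calibrated so the *reconstructed* temperature difference (which subtracts a
noisy reference dynamic) has the requested standard deviation.

Reconstruction inverts the same relation on the phase difference to the
first dynamic, unwrapping temporally (per-pixel along time). Spatial
unwrapping is unnecessary for compact focal heating; a warning is issued if
any dynamic-to-dynamic step approaches π. At zero noise the round trip is
exact by construction, and under noise the estimator is unbiased (the
complex noise is circular), which the test suite verifies by Monte Carlo.

**Metrics.** The ROI maximum series takes the per-dynamic maximum inside a
40 × 30 mm window centered on the target. FWHM of the final elevation map
is reported as the equivalent-circle diameter 2√(A/π) of the region whose
elevation is ≥ half the peak elevation — rotation-invariant, defined for
irregular regions, pools disjoint hot spots, and reduces to the 1D profile
FWHM for isotropic peaks (a `profile` method is also exposed). Half-maximum
is relative to elevation above baseline, not absolute temperature.

## CEM43 thermal dose

CEM43 = Σ Δt_min · R^(43 − T) per pixel, with the standard isoeffect rates
R = 0.5 for T ≥ 43 °C and R = 0.25 below, temperature piecewise-constant
over each dynamic interval (matching discrete MR sampling). The exact R
values and breakpoint are convention; the standard ones are assumed and
exposed on `DoseModel`. The lethal area counts pixels *strictly above*
240 CEM43 times the pixel area. Dose is additive over concatenated series
and monotone in temperature. Intra-voxel temperature-distribution
corrections (the focal spot is smaller than the 2.5 × 2.5 × 7 mm voxel) are
out of scope.

## Lesion phantom and segmentation

The phantom is the characteristic BH "tadpole": an ellipsoidal head plus a
cone tail pointing toward the transducer, with exact analytic volume
(4/3 π abc + π r² L/3) as ground truth. Texture is multiplicative gamma
speckle (4 looks, unit mean — an ultrasound-B-mode-like texture, not a
physical speckle simulation) blurred by a small Gaussian PSF. A tail
thinner than a voxel triggers a warning and a degenerate-tail flag.

Segmentation is a deterministic automatic pipeline given one seed point:
median filtering (1.5 mm window — edge-preserving, so speckle is suppressed
without the systematic inward pull that linear smoothing exerts on convex
boundaries), a threshold placed 45 % of the way from the background level
(median of the outer shell) to the seed-region mean (slightly below
half-contrast to offset the residual PSF curvature bias), morphological
closing, the connected component containing the seed, and hole filling. If
the seed-to-background contrast is under 4× the background's robust scale,
a no-lesion-found error is raised instead of returning an empty mask. On
noiseless ellipsoids the volume is recovered within 2 %, and within a few
percent under speckle across the ~1000–1800 mm³ range.

This replaces an interactive contouring workflow; the preserved contract is
"a volume in mm³ from a 3D image plus one seed point". Phantom recovery
does not bound the error of segmenting real ultrasound volumes, whose
artifacts (shadowing, reverberation, anisotropic PSF) the phantom does not
emulate.

## Statistics

One-way ANOVA uses the classical sums of squares, F = MS_between/MS_within
with (k−1, N−k) df. Pairwise comparisons are two-tailed t-tests sharing the
pooled within-group mean square (protected comparisons; pooling across all
groups rather than per-pair is a choice, documented here), with Bonferroni
adjustment p_adj = min(1, m·p_raw), m = k(k−1)/2. Significance is at
p ≤ 0.05 inclusive. A group with zero within-group variance raises an error
naming the group. Pearson correlation and OLS R² come from scipy behind the
module interface. The type-I error rate of the whole ANOVA path is checked
against the exact binomial 99 % interval over 2000 null simulations at the
study's design size (4 groups × 3 replicates).

`summarize_effects` condenses a sweep into a per-factor Yes/No matrix:
"Yes" for an outcome when its ANOVA across levels is significant *and* the
level-mean trend is positive; the lethal-area column reports a significant
positive Pearson correlation between lethal area and lesion volume.

## Orchestration and problem sizes

`run_characterization` ties the stages together per parameter set. Defaults
use a ~25 mm simulation box at 0.6 mm voxels and a handful of cube repeats
— enough to exercise every stage and reproduce the qualitative orderings;
raise `grid_shape` and `repeats` toward the physical schedule (15–30
repeats) for quantitative studies. The lesion phantom's head semi-axes are
derived from the simulated fractionated-region extents plus a fixed growth
margin (3.5 mm): the paper-scale mapping from sonication parameters to
final lesion size involves mechanical emulsification dynamics that are not
modelled, so this mapping is a synthetic stand-in chosen to land in the
observed volume range, not a calibrated prediction.

Every run is fully determined by config + seed; the config and its hash are
serialized next to the outputs, and fixed seeds give byte-identical CSVs.

## Known limitations

- No nonlinear acoustic propagation: the focal field is a parametric
  Gaussian, and absolute simulated temperatures are qualitative.
- Boiling is a clamp + flag; vapor-cavity dynamics, acoustic shielding by
  bubbles, and mechanical fractionation are not modelled.
- No perfusion, no B₀ drift, no motion — appropriate for phantoms and
  ex vivo tissue only.
- The statistics layer assumes normal errors and equal variances within a
  sweep, as the classical ANOVA does.
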