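# Methods

`hybridose` re-creates, end to end, a hybrid planar/SPECT dosimetry analysis
for ⁹⁹ᵐTc-labelled somatostatin-receptor imaging (⁹⁹ᵐTc-HYNIC-TOC): camera
simulation on a digital phantom, quantitative OSEM reconstruction, planar
kinetics, adaptive-threshold SPECT segmentation, time-integrated activity
coefficients (TIACs), and absorbed dose at the voxel level (voxel S-value
convolution) and the organ level (MIRD schema). This note documents the
models, the defaults and why, and what the synthetic studies do and do not
demonstrate.

## Digital phantom and kinetics

The phantom is an elliptical-cylinder torso (adult half-axes 180 × 110 mm)
containing ellipsoidal kidneys (2 × 154 g), liver (1790 g), spleen (182 g),
an optional bladder and spherical tumor, all unit density. A single
`age_scale` multiplies every linear dimension; `age_scale = 0.818` cubes to
the mass ratio of a ~40 kg twelve-year-old to the 73 kg adult. The body
cylinder is longer than the voxel grid: the analytic full-body volume
defines the remainder-of-body mass, and only the in-grid part is voxelized.
Organ placement keeps the organs disjoint in the anteroposterior projection,
because disentangling superimposed organs on planar views is out of scope.

Each organ follows a mono-exponential washout
`A_r(t) = f₀ A_inj 2^(−t/T_eff)`, optionally preceded by an uptake term
`1 − 2^(−t/T_up)`. Default `f₀` values are chosen so that
`f₀ · T_eff / ln 2` reproduces the cohort-mean TIACs (kidneys 0.37 h split
equally, liver 0.56 h, spleen 0.43 h) at the cohort-mean effective
half-lives (4.83 / 5.07 / 5.83 h). A urinary pathway routes `f_u = 0.15` of
the injected activity to the bladder with biologic half-life 1.5 h and a
3.5 h voiding interval; the remainder compartment's `T_eff = 5.189 h` makes
its TIAC 5.01 h. These choices keep the whole-body retention below pure
physical decay at all times, which the generator asserts. The uptake phase
is off by default (the analysis integrates the washout fit only; observed
kidney uptake peaks near 7–10 min, reproduced with `T_up ≈ 0.02 h`, and is
negligible against multi-hour washout).

## Acquisition model

Planar and SPECT acquisitions share one projector: in-plane rotation into
the detector frame by *push* (mass-conserving) bilinear resampling,
per-voxel attenuation weights `exp(−∫μ dy)` toward the detector, summation
along the anteroposterior axis, and a distance-independent Gaussian detector
PSF (default FWHM 10 mm). The adjoint gathers through the same weights, so
forward and backprojection are matched to machine precision. The SPECT orbit
is circular (60 views × 20 s, 128-type matrix, 4.418 mm pixels); planar
dialects (2.21 / 2.88 mm) are supported by count-conserving resampling.
Counts are Poisson-sampled from the expected projections; a seed is
mandatory and identical seeds give bit-identical data. Scatter photons are
not transported; the simulated projections are narrow-beam.

## Reconstruction and calibration

OSEM uses the clinical recipe (2 iterations, 10 interleaved subsets,
Gaussian post-filter standing in for the camera's Hann filter, whose cutoff
is not public). The forward model inside OSEM divides by the number of
views, so a reconstructed voxel carries the counts the whole acquisition
would have collected from it; dividing by sensitivity × total acquisition
time yields MBq. The point-source calibration (4.82 MBq vial, mean of two
heads) closes this loop. `broad_beam_scale` (default 0.75) mimics the
clinical broad-beam rescaling of the CT μ-map that compensates unmodelled
scatter; because the simulator produces scatter-free data, all synthetic
studies set it to 1.0 — using 0.75 on narrow-beam data would bias activity
upward. Rotation-resampling projectors amplify interpolation
high-frequencies at high iteration counts, which is one reason the clinical
low-iteration setting is used; the noiseless uniform-cylinder closure (<5%
interior error) is stated at 2 iterations.

## Planar kinetics

ROI₅₀ = pixels of a manually oversized ROI at or above 50% of its maximum
(inclusive, for deterministic ties), propagated across the series by
integer-shift normalized cross-correlation, with a background ROI adjacent
to the organ (a rind around the oversized ROI, excluding other organs).
Corrected counts are ROI total minus background mean × ROI area, floored at
zero with a flag. Fits are unweighted least squares on log-counts (exact
for two points; with 2–3 points weighting is moot and the log-linear fit is
reproducible without iteration). The anterior view is used by default; a
geometric-mean mode is not needed for the synthetic phantoms because organ
depth is constant over time. `T_bio = T_eff·T_phys/(T_phys − T_eff)`;
fits with `T_eff > 6.0067 h` yield negative `T_bio` and are kept, flagged
as accumulation (spleen-like behavior).

## SPECT segmentation

Dual iterative adaptive thresholding: two thresholds, percent of the object
maximum, each a calibrated function `T(SBR) = a + b/SBR` of the observed
signal-to-background ratio — one recovering true volume, one true activity.
Curves are calibrated on simulated spheres (12–100 mL) in a warm cylinder at
SBR 2–32, reconstructed exactly like patient data, so partial-volume effects
are folded into the thresholds implicitly. The optimal threshold per cell is
found by a fine scan (the recovered volume is a step function of the
threshold, making bisection ill-posed; ties resolve to the lower threshold).
Segmentation iterates threshold ↔ mask until the volume changes < 1% or 20
iterations, with cycle detection. The background shell is a 2-voxel rind at
2 voxels from the seed box; voxels of adjacent hot organs can be excluded
from both the box and the shell, the 3-D analogue of drawing ROIs that avoid
neighbors — without this, kidney spill corrupts the liver maximum on the
torso phantom. Calibrated volume thresholds settle near 36–44% and activity
thresholds near 25% at kidney-like SBR, reproducing the ordering seen
clinically. Activity recovery degrades at SBR ≈ 2 for small spheres (the
1/SBR form under-fits there); volume recovery is robust. Below 12 mL the
thresholds become size-dependent and the phantom validator rejects smaller
tumors.

## TIACs

`ã = (A_SPECT/A_inj) · 2^(t_SPECT/T_eff) · T_eff/ln 2`: the planar fit
supplies the shape, the single quantitative SPECT the absolute scale,
extrapolated to t = 0 (instant uptake) and integrated to infinity. The
whole-body TIAC comes from the total counts of both planar views with the
t = 0 fraction fixed at 1; the remainder is whole body minus organs and
bladder. The bladder TIAC uses a voiding model (defaults f_u 0.5, T_u 2 h,
void every 3.5 h for the standalone operation; the pipeline reuses the
generator's urinary parameters) integrated numerically at ≤ 0.01 h steps,
validated against the no-voiding closed form. The whole-body
mono-exponential overestimates the remainder TIAC by ~15–20% on the
synthetic phantom because the early urinary excretion is faster than the
2–24 h samples can see — a known limitation of single-exponential
whole-body fits, left in deliberately as it mirrors practice.

## Voxel S-value kernel and dose maps

The kernel gives mGy per MBq·h in a source voxel. Electrons (mean 16.8 keV
per decay, conversion + Auger) deposit in the source voxel. Photons (140.5
keV γ and Tc K x-rays) follow an analytic point kernel
`Φ(r) = Σ y E (μ_en/ρ) B(μr) e^(−μr) / 4πr²` with linear buildup
`B = 1 + a_E μr` and `a_E = μ/μ_en − 1` per line, the choice that makes the
kernel's infinite-medium energy integral equal the emitted photon energy —
the standard normalization of analytic dose point kernels, and the property
that matters for cross-organ dose, which is largely scattered radiation in
quasi-equilibrium geometry. The trade-off: near-field (≲1 mean free path)
dose is somewhat overestimated relative to tabulated buildup factors.
Attenuation and energy-absorption coefficients for water are interpolated
log-log from a packaged NIST-derived table; nothing physical is inlined in
code. The self-voxel photon term averages Φ over the pair-distance
distribution of the equal-volume sphere. A 1-D radial quadrature of the
same Φ is the independent energy oracle for the 3-D kernel; boundary escape
on the clinical-size grid (215³ × 4.418 mm) is ~1%, and < 5% from half
extent 60 up.

Dose maps are zero-padded FFT convolutions; an O(N²) double-sum oracle
checks them to 1e-9 on small grids. Self dose of a region is the mean dose
from its own cumulated activity; cross dose is the rest; the two add
exactly. Cumulated-activity maps in the pipeline weight each organ's TIAC
by the reconstructed image inside the segmented mask (uniform fallback);
the remainder is spread at the concentration TIAC / anatomical body volume,
so off-grid limb activity correctly dilutes it. Doses are reported per MBq
injected.

## Organ-level arm

S-factors are *derived from the same phantom and kernel* (mean dose in
target per unit cumulated activity uniform in source, electron/photon split
retained) rather than copying any proprietary table — making the
organ-level and voxel-level arms comparable by construction, which turns
the clinical finding of "no significant difference with adapted masses"
into a testable property (agreement within 2% for uniform activity). Mass
adaptation scales self-dose terms by `m_ref/m` (electrons) and
`(m_ref/m)^(2/3)` (photon self-absorption); cross terms are untouched. The
default-mass variant rescales to reference age-model masses (1/5/10/15
y/adult, ICRP-like) chosen by nearest age. Tumor doses use a unit-density
sphere model (local electrons + Φ integrated over the sphere), which by
construction excludes cross dose and therefore underestimates tumors that
sit near hot organs.

## Reference cross-organ studies

The headline comparison populates the pediatric (age_scale 0.818, 96³ grid)
and adult (128³ grid) phantoms with the cohort-mean TIACs (children:
kidneys 0.37, liver 0.56, spleen 0.43, remainder 5.01 h; adults: 0.35 /
0.75 / 0.43 / 4.34 h) and measures the mean cross-organ fraction over
kidneys, liver and spleen: ~16% pediatric vs ~14% adult. The pediatric
excess is driven by the roughly doubled remainder concentration (similar
TIAC in a half-mass body) and shorter inter-organ distances.

## What the synthetic studies do not show

The phantom is geometric, homogeneous water, with uniform intra-organ
activity and no scatter in projections, no collimator distance dependence,
no patient motion, no organ overlap on planar views, and no CT
heterogeneity. Passing closure tests demonstrates internal consistency of
the method chain under its own assumptions, not clinical accuracy on
patient data. Numbers printed by the tests (cross fractions, recovered
TIACs) are computed at run time on the grids stated above; smaller grids
are used in unit tests purely as a problem-size choice.

## Numerical choices

Threshold ties use ≥; the ROI₅₀ threshold is inclusive; convolution
negatives below 1e-12 of the maximum are clipped (larger residues raise);
OSEM divisions are guarded at 1e-12; the bladder integral runs to 10
physical half-lives; kernel and DVH grids are configurable with the
clinical sizes as defaults. All randomness flows from explicit seeds
through `numpy.random.Generator`; identical seeds give byte-identical
outputs, which the pipeline asserts by hashing its configuration into the
run manifest.
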