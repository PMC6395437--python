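# Methods

## Scope and model

`aptw` quantifies the amide-proton-transfer-weighted (APTW) signal from
CEST z-spectrum acquisitions of the brain and reproduces the cohort-level
statistical analysis used in clinical studies of ischemic stroke. The
measured quantity is the magnetization-transfer-ratio asymmetry at the
amide resonance,

    MTR(offset)        = 1 - S_sat(offset) / S0
    MTRasym(offset)    = MTR(+offset) - MTR(-offset)
                       = [S_sat(-offset) - S_sat(+offset)] / S0
    APTW               = MTRasym(3.5 ppm) x 100   [% of bulk water signal]

which decomposes as `MTRasym(3.5 ppm) = APTR + MTR'asym(3.5 ppm)`: the
amide proton transfer ratio proper plus a residual asymmetry from nuclear
Overhauser enhancement (NOE) of upfield aliphatic protons and the intrinsic
asymmetry of the semisolid magnetization-transfer (MT) pool. Because amide
proton exchange is base-catalyzed, APTR falls with intracellular pH, which
is what makes APTW a surrogate marker of ischemic acidosis: acute lesions
read lower than contralateral tissue, and recovery raises the signal.

No patient data ship with the package. Every stage is instead validated
against a multi-pool Bloch–McConnell simulator whose ground truth is known
exactly, plus a cohort generator that reproduces the published group
statistics of a 43-patient supportive-treatment stroke cohort.

## Saturation-transfer simulator

The simulator evolves the full transverse + longitudinal magnetization of
P pools (3P coupled linear ODEs) under continuous-wave irradiation.
Exchange topology is a star: every solute pool exchanges with water only,
with back-rates fixed by detailed balance (`k_water->i = f_i k_i`). Because
CW saturation makes the coefficients time-invariant, the default propagator
is a single matrix exponential of the augmented (3P+1) system over the
800 ms saturation interval — exact up to floating point — with readout
modeled as an ideal snapshot of water Mz (any uniform readout weighting
cancels in S_sat/S0). A time-stepping LSODA mode (`method="ode"`) exists
purely for cross-validation; the two agree below 1e-6 and a hand-coded
two-pool integration in the test suite confirms the matrix construction
independently.

Default pools (literature-typical values, configurable):

| pool  | shift (ppm) | fraction | T1 (s) | T2      | k (/s)     |
|-------|------------:|---------:|-------:|--------:|-----------:|
| water |         0.0 |      1.0 |    1.2 | 70 ms   | —          |
| MT    |        -2.3 |     0.10 |    1.0 | 10 us   | 25         |
| amide |        +3.5 |   0.0015 |    1.0 | 30 ms   | from pH    |
| NOE   |        -3.5 |    0.015 |    1.0 | 1 ms    | 20         |

The MT pool's microsecond T2 yields a Lorentzian absorption line within the
full Bloch treatment; a super-Lorentzian lineshape is a known refinement we
deliberately omit (the asymmetry analysis is insensitive to the exact far
wing shape at 2 uT). The NOE fraction sets the depth of the negative
asymmetry background; 0.015 puts the amide-rate-to-zero floor of
MTRasym(3.5 ppm) near -5.5% at 2 uT / 800 ms, so every clinically observed
lesion value (down to about -4%) is reachable by modulating the amide
exchange rate alone, which is how target values are embedded in phantoms.
The resulting background is at the strong end of the literature range for
white matter but qualitatively correct (NOE + MT dominated, negative).

Amide exchange is mapped from pH as `k = 5.57 /s x 10^(pH - 6.4)`
(base-catalyzed; reference point literature-typical, not fitted). Phantom
defaults pH 7.0 (background) vs 6.4 (acute lesion) give a negative
lesion-minus-CNAWM contrast at baseline, matching the sign of the
published pre-treatment contrast.

`ground_truth_decomposition` computes APTR as the difference between the
full simulation's asymmetry and the same system with the amide pool
removed; the identity APTW = APTR + MTR'asym is then exact by construction
and is asserted exactly in tests.

## Image phantoms

Phantoms are 64x64 single-slice images (the acceptance scale; size is
configurable) containing a circular lesion in homogeneous background
tissue. S0 carries a smooth radial profile times a seeded, spatially
smoothed random texture (+/-35%, 1.2 px correlation scale). Both factors
multiply every saturated frame equally and cancel in normalization, but
the texture is essential: it gives the rigid registration the
high-frequency common structure a real brain has. Without it a smooth
phantom is pathological for intensity-based registration (the optimizer
aligns the offset-dependent saturation patterns instead of anatomy).

A B0 inhomogeneity field is a low-order 2D polynomial scaled to a +/-0.3
ppm amplitude; a voxel with shift d stores the true spectrum evaluated at
(nominal offset - d). Class spectra are simulated on a dense offset grid
(0.02 ppm, refined to 0.0025 ppm inside +/-1.4 ppm) and interpolated with
a cubic spline: the refinement matters because the water dip bottom is
shallow, and the downstream dip-center estimator is sensitive to
interpolation error at the 1e-5 level. Acquisition repeats are rendered as
separate frames (the scanner-averaging alternative is handled by the
pipeline's repeat-averaging stage being a no-op). Noise is Rician by
default when enabled (magnitude MRI), with a Gaussian mode for
linear-regime tests; sigma is specified relative to S0. Optional per-frame
rigid jitter emulates patient motion. Identical spec + seed is
bit-reproducible.

What the phantoms do *not* emulate: realistic anatomy and tissue
heterogeneity, multi-slice/3D geometry, pulsed saturation trains, B1
inhomogeneity, readout point-spread effects, and physiological drift.
Passing recovery tests therefore demonstrate correctness of the
quantification chain under the stated acquisition model, not robustness to
everything real data can do.

## Processing pipeline

Order: rigid registration -> repeat averaging -> S0 normalization ->
voxelwise B0 estimation and correction -> MTR-asymmetry mapping.
Averaging after registration (it needs per-frame data) and before
normalization is immaterial in the noise-free limit since normalization is
linear.

**Registration.** Three-degree-of-freedom rigid transforms (tx, ty, theta
about the image center), bilinear resampling with edge-value fill,
similarity = mean squared difference of intensity-standardized images
(equivalent to maximizing correlation, so the unsaturated S0 can be
registered with the same machinery). Optimization: phase-correlation
translation initialization, then Powell refinement from three rotation
starts. Frames with |offset| < 1.2 ppm are dominated by direct water
saturation and share almost no anatomical contrast with the +3.5 ppm
reference, so they are registered along a chain — each against the
already-resampled frame nearest in offset — rather than directly. A fit
that fails to improve on the identity residual, or that exceeds
plausibility bounds (8 px, 5 deg), falls back to the nearest-in-offset
successful transform. Estimates below 0.2 px / 0.15 deg snap to exact
identity: they carry no motion information, and resampling is not free
(it smooths the frame relative to the unresampled S0 and perturbs the
normalized spectra). Known limitation: for frames whose contrast differs
strongly from the reference, sub-pixel accuracy is fundamentally limited
by contrast-driven spurious minima; transform recovery to 0.1–0.2 px holds
for same-contrast pairs, and at series level the guarantee is that every
frame's reference residual is improved, never worsened.

**B0 correction.** The z-spectrum restricted to |offset| <= 1 ppm is
interpolated with a cubic spline per voxel. The shift estimator locates
the center about which the interpolated dip is most mirror-symmetric
(squared antisymmetry summed over half-widths 0.05–0.45 ppm, center
searched on a 0.002 ppm grid within +/-0.6 ppm) — a WASSR-style
maximum-symmetry criterion. A plain spline-argmin mode is provided
(`method="argmin"`), but on the default protocol's 0.25 ppm sampling its
interpolation error oscillates with the true shift at the +/-0.01 ppm
level, which alone maps to ~0.2 percentage points of APTW error (the z
slopes at +/-3.5 ppm differ by ~0.2 pp per 0.01 ppm); the symmetry
criterion reduces this to ~0.002 ppm on the same samples. Voxels without
an interior optimum are flagged invalid and excluded from maps and ROI
statistics, never silently zeroed. Correction re-interpolates each voxel's
spectrum (cubic) at (nominal + shift), clamping queries to the sampled
range. End-to-end on a noise-free phantom with the field on, the APTW map
is recovered within 0.1 pp on >99% of voxels.

**Quantification.** `mtr_asym` requires both +/-offset on the nominal grid
(no silent interpolation) and is antisymmetric by construction; the APTW
map is its value at 3.5 ppm in percent. ROI MTRasym spectra report
mean +/- SE per positive offset.

## ROI rules

Lesion ROIs are 100–125 px regions; the automated stand-in for manual
placement tiles the lesion mask with disjoint squares (row-major,
deterministic). The reported lesion value follows the lowest-ROI rule
(minimum ROI mean, ties to the lowest index) — the rationale being that
the lowest APTW plausibly marks the most acidic tissue — with the
whole-lesion mean carried alongside. The CNAWM reference is the mirror of
the selected ROI across the vertical midline (default: image center
column; configurable, since the anatomical midline is not always
centered), or an explicit mask. Contrast = lesion - CNAWM holds exactly by
construction. ROI size bounds are advisory (warning, not error); ROIs with
>20% invalid voxels are flagged. Exclusion of sulci/hemorrhage/vessels is
an input mask concern, not automated detection.

## Cohort simulation and statistics

The cohort generator draws per-scan truth values from group distributions
(defaults = the published reference group means/SDs) and links NIHSS to
the true lesion APTW through a bivariate-normal construction that attains
a target correlation (default r = -0.491) exactly in population before
integer rounding and clipping to [0, 42]; rounding attenuates the sample
correlation by well under 0.01 at the default parameters. Onset and
follow-up times come from a 43-patient demographics template, so the
onset-bin occupancies (30/13 pre-treatment) and the follow-up structure
(26 patients, 44 follow-up scans) are reproduced exactly. Which two
template patients count as treatment-ineffective is a modeling choice (the
published record does not identify them); the template marks the one case
uniquely matching the narrative description plus one early-follow-up case
such that exclusion reproduces the published post-treatment bin sizes.

Time bins are [0, 96 h), [96, 168 h], (168, 504 h], (504 h, inf): a time
recorded as "4 days" belongs to the 4–7 day bin. This is the only edge
rule consistent with the published bin occupancies. The same rule applies
to onset and post-treatment durations; post-treatment duration is
follow-up time minus first-scan time.

Statistics: Pearson correlation (two-sided t transform), pooled-variance
independent-samples t-test (Welch behind a flag), one-way ANOVA with
Fisher's LSD post hoc — pairwise t statistics on the pooled within-group
mean square with N-k degrees of freedom and deliberately no multiplicity
adjustment, which is what LSD means. Groups with n < 2 are reported but
excluded from testing. All tests are checked against brute-force formula
oracles to 1e-10. Ineffective-treatment follow-up scans are excluded from
group statistics; their baselines stay in the pre-treatment group.

## Numerical choices and problem sizes

Phantoms are 64x64 with the 31-offset / 61-acquisition protocol; cohort
recovery studies use 20 replicate cohorts of 43 embedded subjects
(whole-lesion rule, no B0 field — the per-subject embedding isolates
quantification accuracy) and 200 replicate cohorts for correlation
recovery. Amide-rate calibration brackets the target on k in [1e-3, 500]
/s (monotone at 2 uT) and solves with Brent's method to 1e-6. Degenerate
inputs fail loudly: empty ROIs, constant images, unsampled offsets,
out-of-range pH, infeasible correlations, non-positive S0 inside the
analysis mask.

## Known limitations

Single-slice 2D only; no DICOM ingestion; CW saturation only (the clinical
sequence's pseudo-CW pulse train is approximated as CW); Lorentzian MT
lineshape; MSE-based registration limited across strong contrast
differences; the symmetry-based B0 estimator assumes the dip is locally
symmetric, which very asymmetric solute configurations could violate;
lesion masks are inputs (no segmentation). The alternative quantification
families (Lorentzian multi-pool fitting, Bayesian model-based analysis,
extrapolated semisolid-MT reference) are out of scope by design.
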