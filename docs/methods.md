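# Methods

This note documents the models implemented in `fpia_quant`, the defaults
and why they were chosen, what the synthetic phantom does and does not
emulate, and the package's numerical conventions.

## PET kinetic models

**Irreversible two-tissue compartment model.**  Tissue activity is
modelled as

    C_T(t) = (1 − v_b)·(h ⊗ C_p)(t) + v_b·C_b(t),
    h(t)   = K₁[ k₃/(k₂+k₃) + (k₂/(k₂+k₃))·e^{−(k₂+k₃)t} ],

with parent-plasma input C_p, whole-blood C_b and fractional blood
volume v_b.  k₄ is fixed at zero: the tracer is irreversibly trapped on
the time scale of the scan, which is why the net influx constant
K_i = K₁k₃/(k₂+k₃) is the quantity of clinical interest.  A reversible
fit is deliberately not offered; the total distribution volume of the
reversible components is instead reported from spectral analysis
(`VT_rev`, below), since an irreversible 2TC has no finite V_T.

- `K₁` (mL·cm⁻³·min⁻¹): delivery, the product of perfusion and
  first-pass extraction.  Fit bounds [0, 2].
- `k₂`, `k₃` (min⁻¹): efflux and trapping.  Bounds [0, 5].
- `v_b`: blood volume fraction, bounds [0, 0.2], default fitted.  When
  no arterial whole-blood curve is available the sagittal-sinus TAC
  stands in for C_b.

`fit_2tc` minimises duration-weighted least squares (weights
∝ √frame-duration, since longer frames accumulate more counts) with a
multistart strategy (default 10 seeded starts) and reports
non-convergence on the result instead of raising.

**Patlak graphical analysis.**  For an irreversible tracer,
C_T(t)/C_p(t) plotted against ∫₀ᵗC_p/C_p(t) becomes linear once the
reversible compartments equilibrate; the slope is K_i and the intercept
V₀.  Default t\* = 15 min (configurable): on the 2TC simulations used in
the test suite the plot is linear to r² > 0.999 from 10 min onward, and
15 min leaves 11 frames in the regression.  A low r² is surfaced on the
result for curves where linearity fails.

**Spectral analysis.**  The TAC is decomposed as a nonnegative sum of
input-convolved exponentials over a log-spaced grid of decay rates
β ∈ [10⁻³, 10] min⁻¹ (100 points) augmented with β = 0 and a whole-blood
column, solved by non-negative least squares.  The β = 0 weight is the
trapping component `Ki_trap` (it should agree with Patlak K_i); the
reversible components sum to `VT_rev = Σ α/β`.  NNLS makes the recovered
spectrum sparse without explicit regularisation.

## Input functions

The sampling protocol provides continuous arterial counting over the
first 10 min plus discrete samples at 2.5/15/30/45/60 min with plasma
and parent-fraction assays.  Processing:

1. **Cross-calibration**: least-squares scale of the continuous detector
   onto discrete whole-blood samples inside its window (only the 2.5-min
   sample overlaps, so the scale carries that sample's noise).
2. **Metabolite correction**: parent plasma = plasma × parent fraction,
   with pf(0) = 1 enforced and a monotone nonincreasing pf curve.
   Default pf model is piecewise-linear interpolation; a declining
   sigmoid fit is available.  FPIA is essentially non-metabolised, so
   pf ≈ 1 in practice.  Missing plasma values are filled by a constant
   plasma/whole-blood ratio fitted from samples that have both
   (default 1.0).
3. **Merging**: the continuous segment is kept verbatim to 10 min; the
   tail interpolates linearly through the discrete points, anchored at
   the 10-min value for continuity.  Linear interpolation of the convex
   plasma tail biases the Patlak integral slightly; on the noiseless
   phantom this is a ≲6% effect on K_i (tested).
4. **Population template**: measured curves are normalised by injected
   dose per body weight (the SUV normaliser, making the template
   unitless and rescalable to a new patient), averaged on a common grid.
   Parent-plasma curves are averaged, not whole blood.

## Static PET

SUV = C[kBq/mL] / (dose[MBq]/weight[kg]), density 1 g/mL.  Two static
windows: the duration-weighted mean of the last five frames (a 26-min
window on the clinical schedule) and the single frame whose mid-time is
closest to 60 min.  No frame of the printed 28-frame schedule has
mid-time exactly 60 min; the 55.5–60.5 min frame (mid-time 58 min) is
selected, and this choice is deliberate and documented here.

**Blood-pool correction.**  SUVc = SUV − f_b · mean sinus SUV.  The
normalisation of the whole-blood term is not standardised in the
clinical literature this implements; subtracting the full sinus SUV
would over-correct tissue voxels whose blood content is only a few
percent, so the default f_b = 0.05 is a nominal cerebral blood volume
fraction, configurable per study.

**Threshold masks.**  SUV₃₀/SUV₄₀ masks keep voxels ≥ 30%/40% of the
in-region SUVmax, restricted to the 26-connected component containing
the hottest voxel — without that restriction, low-uptake scans select
disconnected background.  Overlap against MRI-defined volumes is scored
with DICE (symmetric) and the signed percent volume variation
((V_mri − V_suv)/V_suv)·100 (not symmetric; the MRI volume is always the
numerator difference).  All overlap metrics are computed on the PET grid
after nearest-neighbour resampling.

## MRI quantification

- **DCE**: spoiled-gradient-echo signal inversion to gadolinium
  concentration (R1(t) from the signal equation, C = (R1 − 1/T10)/r1;
  a linear ΔS/S mode exists), then an extended-Tofts fit
  C_t = v_p·C_p + Kᵗʳᵃⁿˢ∫C_p e^{−k_ep(t−τ)}dτ with kep bounded below at
  10⁻⁴ min⁻¹.  v_e is always reported as Kᵗʳᵃⁿˢ/k_ep.
- **DSC**: ΔR2\*(t) = −ln(S/S₀)/TE.  CBV is the tissue/AIF integral
  ratio.  Leakage correction fits the tissue curve against a
  non-enhancing reference curve and its running integral, adding the
  leakage term back (CBVlc); the reference must share the tissue
  dispersion, so the pipeline uses the CWM curve, not the AIF, and no
  correction is applied when no reference is given.  CBF comes from
  block-circulant SVD deconvolution with singular values below 20% of
  the maximum zeroed — a standard oscillation-suppressing truncation;
  MTT = CBV/CBF and TTP is the ΔR2\* argmax time.
- **pASL**: QUIPSS-II quantification CBF = 6000·λ·ΔM /
  (2·α·M₀·TI₁·e^{−TI₂/T1b}) with 3 T defaults λ = 0.9 mL/g, α = 0.98,
  T1b = 1.65 s, all configurable.
- **DWI**: log-linear ADC over ≥ 2 b-values; exact for noiseless
  mono-exponential decay.
- **Normalisation**: perfusion outputs (CBV, CBVlc, CBF, MTT, TTP,
  ASL-CBF) are reported relative to contralateral white matter, removing
  arbitrary scanner scaling.

DCE/DSC fitting is region-level (region-mean curves), matching how the
per-patient feature table is assembled; voxelwise parametric maps are
out of scope in this version, as is the water-exchange (shutter-speed)
DCE parameter, for which no generating model is defined here.

## Statistics

**Wilcoxon rank-sum** with mid-ranks for ties; exact enumeration of all
C(n+m, n) rank assignments when n+m ≤ 12 (the regime of a 10-patient
cohort), tie-corrected normal approximation with continuity correction
otherwise.  Two-sided p = min(1, 2·min(tail probabilities)).  Note that
with 2 LGG vs 8 HGG the smallest achievable two-sided exact p is
2/C(10,2) = 0.044.  Grade-group comparisons are unpaired; a paired
signed-rank variant is provided for within-patient lesion-vs-CWM
contrasts.  No multiplicity correction is applied by default (a
Benjamini–Hochberg option is easy to add downstream); this matches the
exploratory, hypothesis-generating character of a 10-patient pilot.

**LASSO classification.**  L1-penalised logistic regression (liblinear)
over a log-spaced penalty grid from just above the smallest
all-zeroing λ down three decades; features are z-scored; λ_min minimises
the cross-validated binomial deviance.  With only two patients in the
smaller class, stratification forces 2-fold CV (a warning reports the
fold reduction), so the CV curve is averaged over 8 repeated shuffled
splits to stabilise λ_min.  A linear (squared-error) family exists
primarily because its orthonormal-design solution is the closed-form
soft-threshold, which the test suite uses as an oracle.  Selection among
strongly correlated discriminative features at n = 10 is intrinsically
unstable; cohort-level conclusions should be drawn from repeated
cohorts, which is how the end-to-end tests assert it.

## The phantom

`fpia_quant.phantom` generates a complete study: spherical lesion (FLAIR
and a smaller T1-contrast-enhancing volume), mirrored contralateral
region, CWM reference sphere, and a blood-pool tube standing in for the
superior sagittal sinus, all on a 64×64×48 grid of 2-mm voxels by
default.  PET frames are the forward 2TC curves (driven by a
tri-exponential Feng-type bolus whose slow third exponential sustains
the late plasma tail a non-metabolised tracer shows), integrated over
each frame interval, blurred with a 5-mm Gaussian PSF emulating
reconstruction smoothing, and degraded with zero-mean Gaussian noise
whose relative sd is 3% on a 300-s frame and scales as 1/√duration —
the testable contract of count-limited, decay-corrected frames.  MRI
series come from the same forward models the estimators invert (SPGR
DCE at 5-s resolution, DSC with exponential residues obeying the
central-volume relation, QUIPSS-II ASL differences, three-b-value DWI),
with 3% multiplicative region-level noise.

Grade presets put SUVmax at roughly 0.9 / 1.4 / 2.2 for WHO grades
II/III/IV with K₁ and k₃ rising with grade, v_e elevated only in the
grade-IV preset, and modest perfusion/diffusion grading.  Cohorts add
per-patient lognormal jitter on every preset: 3%/12%/15% for the kinetic
presets of grades II/III/IV (lower-grade lesions cluster tightly;
glioblastoma varies widely) and 25% for MRI parameters, whose
within-grade spread in clinical data is large in every grade.  These
presets and dispersions are configuration — calibrated once against the
qualitative structure of clinical FPIA pilot data — not measured patient
values.

What the phantom does **not** emulate: anatomy (no grey/white parcels,
ventricles or skull), attenuation/scatter/randoms physics, motion,
k-space MRI artefacts, arterial delay/dispersion, or spatially
heterogeneous lesions.  Passing recovery tests therefore demonstrates
estimator correctness under the stated forward models, not robustness to
every failure mode of patient data.

## Numerical conventions

- Frame schedules are stored in seconds; all kinetics run in minutes
  (rate constants are reported per minute).
- Convolutions run on a 1-s uniform grid using an exact first-order IIR
  recursion (trapezoid-consistent), and frame values are interval
  averages of the fine-grid curve — matching how scanners integrate
  counts — rather than point samples at frame mid-times.
- Masks are resampled to the PET grid by nearest neighbour through the
  NIfTI affines; resampling onto the native grid is the identity.
- Activity volumes are assumed decay-corrected to injection time by the
  scanner; no further decay handling is applied.
- All randomness flows from explicit integer seeds
  (`numpy.random.default_rng`); identical seeds give bitwise-identical
  phantoms, pipeline outputs and classifier fits.

## Problem sizes in the test suite

The unit and acceptance tests run phantoms at 32×32×24 (and smaller)
grids with the full 28-frame schedule — the estimators are
region-level, so recovery behaviour is unchanged while each cohort run
stays a few seconds.  Replicate-based checks use 100 TAC-level
replicates (noise recovery, statistical power) and 5 full image-level
cohorts (end-to-end orderings and LASSO selection).
`scripts/acceptance.py` runs its cohort at the default 64×64×48
geometry.

## Known limitations

- Region-level kinetics only; no voxelwise parametric images.
- No arterial delay/dispersion correction for the continuous detector.
- The Patlak/2TC input defaults to parent plasma; whole-blood input is
  available by passing the sinus curve explicitly.
- The merged input function's linear tail interpolation biases K_i by a
  few percent relative to a densely sampled input.
- LASSO selection at n = 10 is seed-sensitive by nature; single-cohort
  selections should not be over-interpreted.
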