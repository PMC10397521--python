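# Methods

## Overview

`lesioncbf` models how cerebral blood flow (CBF) behaves inside chronic
ischemic stroke lesions and how analysis choices affect its measurement.
It implements four connected pieces:

1. **TIGR damage mapping** — a per-voxel tissue-damage score from the
   T2w/T1w intensity ratio, normalized between intact-tissue references.
2. **pCASL CBF quantification** — control/label pair censoring and
   subtraction followed by a single-compartment kinetic model, under three
   placements of a 4 mm FWHM Gaussian blur.
3. **ROI quality metrics** — SNR, coefficient of variation, and grey/white
   contrast-to-noise ratio.
4. **Lesion-CBF statistics** — per-subject CBF-vs-damage regressions with a
   Bonferroni rule, a group factorial model with demographic cross-terms,
   group overlap masks, and voxelwise covariate removal.

All stages are exercised on a synthetic stroke-brain phantom whose ground
truth is known exactly, so recovery properties can be asserted rather than
eyeballed.

## TIGR damage score

Tissue degrading toward cerebrospinal fluid gains T2w signal and loses T1w
signal, so the ratio r = T2w/T1w rises monotonically with damage.  The
score for a lesion voxel is

    c = 0.1 + 0.9 (r - gm_ref) / (csf_ref - gm_ref),

clamped to [0.1, 1.0] and rounded to the nearest multiple of 0.1 with ties
rounded toward higher damage (the conservative direction for flagging
damage).  `gm_ref` is the mean ratio over the contralesional anterior
grey-matter ribbon eroded by one voxel; `csf_ref` the mean over the
contralesional anterior lateral ventricle eroded by one voxel.  Using
within-subject reference tissue makes the scale invariant to global
intensity scaling (coil loading, head size): scaling both images, or the
ratio together with its bounds, leaves every score unchanged.

Choices made where the procedure is underdetermined:

* **Ten discrete scores** 0.1 ... 1.0 (nine intervals).  The ten-point
  per-subject regressions (residual df = 8) are only consistent with ten
  score ROIs.
* **ROI summary**: the mean (recorded in the summary output); median would
  also be defensible.
* **"Anterior"**: the anterior half of the brain mask's bounding box along
  the world +y axis; no anatomical landmark is assumed.
* **Erosion**: 6-connectivity (faces only), one iteration = one voxel — the
  smallest standard structuring element.  Tissue masks are eroded before
  intersection with the hemisphere/anterior restrictions so that voxels at
  the cut planes are not doubly penalized.
* Score 1.0 defines necrotic **cavitation**; 0.1–0.9 the
  **pericavitational** region.  Percent cavitation is
  100 x cavitation volume / lesion volume, reported to one decimal.
* Denoising of the anatomical images prior to the ratio is out of scope;
  the phantom's anatomical noise is set low enough that it is not needed.

## CBF quantification

The difference signal ΔM (control − label, averaged over retained pairs)
converts to CBF via the single-compartment model

    CBF = 6000 λ ΔM exp(PLD_k/T1b) / (2 α T1b[s] M0 (1 − exp(−τ/T1b))),

with λ = 0.9 mL/g, α = 0.85, T1b = 1650 ms, labeling duration τ = 1500 ms
and post-labeling delay PLD = 2200 ms.  For the 2-D ascending readout the
effective delay grows by 37.5 ms per slice: PLD_k = PLD + k·slice_time.
The kinetic constants are the 3T consensus values; they are configuration-
exposed and logged in the provenance record.

**Censoring.** A pair is dropped when either frame exceeds 0.7 mm
translation (Euclidean norm) or 5° rotation (maximum absolute); the
thresholds are read as an either-criterion disjunction (the stricter
reading; configurable).  Fewer than 32 surviving pairs (of 40) is a hard
error.  Motion parameters are referenced to the first frame.  Frame
resampling itself is not performed — inputs are assumed voxel-aligned and
the trace drives censoring only.

**Smoothing placement.** The three pipeline variants are

* `no_blur`: censor → subtract → quantify;
* `blur4_native`: censor → smooth each retained frame → subtract → quantify;
* `blur4_mni`: censor → subtract → quantify → smooth the CBF map.

Smoothing uses σ = FWHM/2.3548 per axis converted to voxels via the
spacing, restricted to the brain mask and renormalized by the smoothed
mask, so a constant field over the brain is preserved exactly and air is
untouched.  Censoring always precedes smoothing, so the censoring decision
is identical across variants.  "Template-space" smoothing coincides with
common-space smoothing here because the package works in a single common
grid (no registration engine; see Limitations).

Why the variants differ on the phantom: smoothing in the difference-signal
domain (`blur4_native`) mixes ΔM across the GM/WM boundary *before* the
division by the tissue-varying M0 and before the slice-dependent decay
correction, which distorts tissue contrast more than smoothing the final
CBF map (`blur4_mni`); leaving the map unsmoothed (`no_blur`) preserves
contrast best.  With the air ROI untouched by brain-masked smoothing, the
GM–WM CNR therefore orders no-blur > template-space blur > native-space
blur, while both blurred variants have markedly lower voxelwise noise than
the unsmoothed map — the qualitative trade-off the three pipelines exist to
expose.  (In acquired data the native-space variant is additionally blurred
by interpolation into template space; that mechanism is absent here.)

## Quality metrics

With μ/σ the ROI mean and sample SD (n−1) of the CBF map:

    SNR = μ_tissue / σ_air,   CoV = σ_tissue / μ_tissue,
    CNR = (μ_GM − μ_WM) / σ_air.

The tissue ROI is a 15 mm sphere at the anterior-cingulate coordinate
(0, 44, 18) intersected with the GM/WM masks; the air ROI a 15 mm sphere
outside the head at a configurable coordinate.  σ_air is taken on the
CBF-scaled map.  Missing voxels (NaN) never enter any mean or SD.

## Statistics

* **Per-subject regression**: OLS of per-score mean CBF on the score;
  R², F with df (1, n−2) (the identity F = (n−2)R²/(1−R²) is asserted in
  tests), two-sided p, slope sign.  Rows are unweighted (voxel-count
  weighting is available as an option); with all ten scores present df is
  (1, 8).
* **Bonferroni rule**: significance at p < α/N with α = 0.01 and N the
  number of subjects; uncorrected p < 0.05 flags are reported alongside.
* **Group factorial model**: per-(subject, score) mean lesion CBF on ten
  terms — sex, age, age×time, age×sex, damage, time since stroke,
  damage×sex, damage×age, damage×time, time×sex.  Sex is effects-coded
  (F = +1, M = −1); continuous factors are mean-centred before forming
  cross-products (raw scale behind a flag).  Damage enters as the
  continuous 0.1–1.0 score.  With 14 subjects × 10 scores the overall F
  has df (10, 129).  An optional variant appends WAB-AQ and its
  cross-terms.  Per-term p-values are reported unadjusted.
* **Group overlap mask**: voxel kept iff ≥ min_n subjects cover it
  (default 10 of 14).
* **Voxelwise covariate removal**: per voxel, CBF across subjects is
  regressed on a lesion-derived scalar (lesion or cavitation volume);
  where the slope is significant at α = 0.05 the values are replaced by
  residuals plus the voxel grand mean, elsewhere untouched.  Under a null
  covariate the altered fraction calibrates to α.  A perfect linear voxel
  is treated as infinitely significant (zero residual variance).
* The multivariate brain-behavior step (sparse canonical correlation) is a
  published external method and is deliberately not reimplemented; the
  package stops at the masked, covariate-residualized CBF stack, which is
  the documented hand-off artifact.

Nested-model note: the intuitive property "the factor model reduces to the
per-subject regression when demographics are constant" cannot hold
literally under mean-centring (a constant factor becomes a zero column and
the design is rank-deficient, which is reported as an error naming the
aliased terms).  The property is instead verified as: with varying but
*ineffective* demographics, the damage coefficient equals the pooled OLS
slope.

## The phantom

One synthetic subject is a 64³ grid at 2 mm isotropic spacing (a desk-scale
stand-in for the 1 mm acquisitions the pipeline targets; all properties
asserted are resolution-independent), centred so the world x = 0 plane is
the midsagittal plane.  The brain is an ellipsoid (semi-axes 50 × 56 × 46
mm): a grey-matter shell (outer 15% of the ellipsoid radius), white-matter
interior, and two paramedian lateral-ventricle ellipsoids of CSF.  Tissue
properties:

| tissue | T1w | T2w | T2w/T1w | proton density | CBF (mL/100g/min) |
|--------|-----|-----|---------|----------------|-------------------|
| GM     | 900 | 720 | 0.8     | 850            | 60 |
| WM     | 1100| 660 | 0.6     | 700            | 20 |
| CSF    | 400 | 1200| 3.0     | 1000           | 0  |
| air    | 40  | 40  | —       | 100            | 0  |

The WM CBF uses the literature value (~20); scanners overestimate it when
tissue subtraction is incomplete, an artifact the phantom does not emulate.

**Lesion.** A sphere (default radius 24 mm) confined to the left
hemisphere.  Damage is 1.0 inside a necrotic core (half the radius) and
ramps linearly down to 0.1 at the rim — the simplest monotone profile with
a cavitated centre.  The lesion's T2w/T1w ratio interpolates linearly from
the GM ratio (damage 0.1) to the CSF ratio (damage 1.0), so TIGR scoring is
exactly invertible at zero noise.  Lesion CBF is
CBF = rim_CBF − s·(damage − 0.1), clipped at zero, with rim_CBF = 40 and
s = 20 mL/100g/min per unit damage; an optional step increase at damage 0.6
emulates a grey-matter transition mid-scale.

**ASL series.** 40 control/label pairs, control first (the interleaving
order is recorded in the series metadata and either order is parsed).  The
difference signal is constructed by inverting the quantification model
voxel by voxel — including the slice-dependent delay — so zero-noise
generation followed by quantification is the identity map.  Additive
Gaussian noise (SD 5 on frame intensities of ~700–1000, i.e. raw SNR of a
few hundred) gives per-voxel CBF noise of roughly 15–35 mL/100g/min, which
per-score averaging reduces to ~1–2 — strong but not trivial power for the
per-subject regressions.  The M0 image is the noise-free proton-density
map (its long-TR acquisition averages noise well below the ASL frames).

**Motion.** A mean-reverting AR(1) wobble (stationary SD ≈ 0.07 mm / 0.3°
per axis, far below the censoring thresholds) plus injected excursions of
1.2 mm or 6°, which are exactly the frames the censoring stage must drop.
Frame 0 is the motion reference and is never corrupted.

**Cohorts.** `make_cohort` varies lesion centre/radius, rim CBF, age
(24–81 y), sex (~4 F / 10 M, at least two per level so sex is always
estimable), months since stroke (9–121), and WAB-AQ (27.4–80.6); the
damage slope is fixed at −20 by default.  Optional additive demographic
effects on rim CBF support sign-recovery tests of the factor model.  Every
generated parameter lands in the manifest; lesion volume is reported in
both mm³ and mL.

**What the phantom does not emulate** (so what passing tests do not show):
labeling physics (bolus dispersion, arterial transit times), background
suppression, hemorrhage, physiological noise or motion-induced artifacts in
the frames themselves (motion exists only in the trace), registration and
interpolation effects, partial-volume structure beyond sharp tissue
boundaries, and real anatomical shape.  Pipeline-variant contrasts on real
data include an interpolation-blur component absent here.

## Numerical choices and degenerate inputs

* Missing data is NaN everywhere and excluded from every mean/SD; CBF is
  marked missing where M0 ≤ threshold (default 1e-6).
* Score binning ties round up; the binning guard (+1e-9) protects exact
  bin-edge values from floating-point round-down.
* Files are reoriented to closest-canonical axes on load; voxel (0,0,0)
  keeps its world coordinate.
* Sample SD (ddof = 1) everywhere; a single-voxel ROI reports σ = 0.
* A lesion straddling the midline beyond 10% tolerance, an empty reference
  ROI after erosion, out-of-order normalization bounds, fewer than 32
  surviving pairs, a constant covariate, and a rank-deficient design are
  all hard errors with named diagnostics.

## Problem sizes used by the shipped checks

The test suite and `scripts/acceptance.py` use 64³ phantoms with 40 pairs,
20 replicate cohorts of 14 subjects for parameter recovery, 20 noise
realizations for the pipeline-variant contrasts, 10,000 draws for the
familywise-error calibration and 500 replicates (14 subjects × 10³ voxels)
for the covariate-removal calibration.
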