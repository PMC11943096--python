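# Methods

## Noise model and calibration

The package models radiographic noise empirically through its first two
moments: within a region of roughly constant attenuation, noise is
zero-mean with standard deviation proportional to the mean grey value,
`sd ≈ k · mean`, and the proportionality constant falls with exposure as
`k ∝ 1/√mAs` (quantum-noise scaling). No attempt is made to separate
noise components (thermal, scatter, electronic) or to model detector
MTF; the single slope `k` absorbs them all.

Calibration estimates `k` per acquisition setting with sliding-window
statistics: 10 × 10 px windows (sample mean, sample SD with ddof = 1),
default stride equal to the window size. Non-overlapping tiling keeps
window statistics independent and is an order of magnitude cheaper than
stride 1; overlapping windows change only the variance of the slope
estimator, not its expectation, so stride is exposed but defaults to
the window size. The regression of SD on mean is forced through the
origin (`slope = Σ mean·sd / Σ mean²`): direct-exposure background has
grey 0 and negligible SD, and the through-origin form lets those
windows contribute nothing rather than bias an intercept. Background
windows are therefore kept, not masked.

Polarity convention throughout: grey 0 = direct exposure, higher grey =
more attenuation. Images flagged `photometric="inverted"` (the
MONOCHROME1 display convention) are flipped before simulation and
flipped back after.

A goal slope for dose fraction *f* of a reference exposure is the
calibration entry at the requested kVp whose mAs is nearest to
`reference_mas · f` (ties go to the lower, noisier mAs — the
conservative choice); log-linear interpolation in mAs is available as
`mode="interp"`. A kVp absent from the table falls back to the nearest
available one with a warning, since clinical fleet-average voltages
rarely coincide with a phantom grid.

## The simulation

Three steps, all deterministic given the seed:

1. **Threshold windows.** The occupied grey range `[min, max]` is split
   into 20 equal-width bins (configurable; the bins can instead span
   the full bit-depth range via `full_range_bins`). Equal-width bins
   over the *occupied* range are the default because clinical images
   rarely occupy their full nominal range.
2. **Mask construction.** Pixels of bin *w* receive
   `mean_w · goal_slope · (u − ½) · 2`, `u ~ Uniform(0,1)` per pixel,
   where `mean_w` is the member-pixel mean (not the bin midpoint). The
   zero-centred form is chosen over raw `Uniform(0,1)` multiplication:
   a one-sided mask only shifts brightness, and the subsequent range
   restoration removes exactly that shift, so the two formulations
   differ by an affine map the pipeline cancels anyway; the symmetric
   form avoids carrying a systematic bias through the intermediate
   stages. The mask is then multiplied by a factor and smoothed with a
   zero-centred Gaussian (σ = 1 default, reflective boundaries). The
   refinement is linear, which the auto-factor search exploits: the
   smoothed unit-factor mask is computed once and rescaled.
3. **Apply and restore.** `minmax` mode rescales the noisy sum affinely
   so its extrema equal the original's exactly, then rounds
   half-to-even and clips to the bit depth; `histogram` mode
   additionally matches the histogram to the original. Both modes are
   provided because "restore the range" admits either reading; `minmax`
   is the default since it is exactly invertible and makes range
   conservation a hard guarantee.

`factor="auto"` bisects the multiplication factor inside [1, 50] until
the output's measured noise slope (same window statistics as
calibration) is within 2% of the goal slope, erroring with diagnostics
when the bracket fails. Named factors are accepted verbatim for runs
that want the hand-tuned historical values (6 and 9); auto is the
default because the goal-slope match is objectively checkable, and on
synthetic phantoms it lands in the same single-digit band (≈ 5–6).
Which historical factor belongs to which dose level is deliberately not
hard-coded. `estimate_factor` exposes the search standalone and errors
when the goal slope does not exceed the image's current slope, since
noise can only be added.

## Quality verification

PSNR uses the bit-depth peak (`2^depth − 1`), not the observed maximum,
so values are comparable across images; identical images return `inf`.
SSIM is scikit-image's single-scale implementation (7 × 7 windows,
standard stabilisation constants scaled to the bit-depth range).
Multi-resolution comparison downscales *both* images (anti-aliased,
fixed target dims 254 × 305 "LR" and 127 × 152 "ULR", plain resize with
no aspect preservation, as classifier inputs are fixed-size) and then
compares. Downscaling averages away high-frequency noise, so PSNR rises
monotonically from full resolution to LR to ULR — the property the
quality report verifies. Resolution-attenuation checks use 1024² px
phantoms: a 512² phantom reaches LR by barely a factor 2 and the PSNR
gradient shrinks to fractions of a dB, whereas 1024² gives the 4×/8×
reduction that makes the mechanism visible.

## Cohort curation

Seven pathologies are eligible (Atelectasis, Cardiomegaly, Edema,
Enlarged Cardiomediastinum, Fracture, Lung Lesion, Pneumonia); requests
for the excluded six (Pneumothorax, Support Devices, Lung Opacity,
Consolidation, Pleural Effusion, Pleural Other) are errors. Filtering
drops uncertain labels (−1) for the target pathology and rows
*positively* labelled under Support Devices; uncertain or missing
support-device values are kept, records lacking the column are treated
as absent. Balanced sets draw `min(cap/2, n_present, n_absent)` per
class without replacement (cap 10,000).

Split sizes follow round-half-to-even for train (0.7) and validation
(0.2) with test taking the remainder, computed on exact rationals: with
binary floats, 7185 × 0.7 evaluates to 5029.5000000000005 and the
outcome would depend on rounding luck; the exact rule gives
5030/1437/718 deterministically, and reproduces every reference set
size (4670 → 3269/934/467, 9614 → 6730/1923/961, 10000 →
7000/2000/1000). Splitting is stratified by class by default: global
sizes come from the rounding rule and odd-sized splits hand their spare
study to alternating classes, keeping within-split balance to ±1 while
preserving the global totals (per-class independent rounding would lose
them: 2335 × 0.7 = 1634.5 rounds to 1634 per class, 3268 ≠ 3269).
Patient-level leakage is *not* prevented by default — the split is
random at study level — but `patient_of` grouping is available; grouped
splits fill greedily, so their sizes can drift a few studies from the
exact rule.

Age at acquisition derives from the de-identified anchor pair:
`anchor_age + (acquisition_year − anchor_year)`, clamped at 0 with a
warning.

## Evaluation harness

AUROC is the midrank estimator, provably equal to pair counting with
half-credit ties. The paired DeLong test computes per-case placement
values for both score vectors and estimates
`Var(ΔAUC) = Var(V10_a − V10_b)/m + Var(V01_a − V01_b)/n`, the
`S11 + S22 − 2S12` form of the DeLong covariance; z is referred to the
standard normal, two-sided. Degenerate zero variance yields p = 1 when
ΔAUC = 0 and p = 0 with a warning otherwise. Two-sided testing is used
throughout because dose effects can move AUROC in either direction. No
multiplicity correction is applied by default across the 28 comparisons
of the full design (7 pathologies × 2 resolutions × 2 dose levels); a
Holm adjustment flag is available. Mann–Whitney comparisons of
continuous metadata use exact enumeration when both groups have ≤ 8
tie-free values and the tie-corrected normal approximation otherwise.

## The synthetic generators

The phantom's signal field is a set of sharp-edged axis-aligned
rectangles (background 0, lung 0.18, soft tissue 0.30, heart 0.42,
bone 0.62 of the dynamic range) with corners snapped to a 20-px grid.
Sharp, grid-aligned edges — rather than blurred shapes — are a
deliberate choice: the tests need a *known* noise-vs-signal
relationship, and any edge gradient falling inside an analysis window
inflates its SD without inflating its mean, biasing the through-origin
slope upward by 5–10% at 512²; snapping edges to multiples of the
default 10-px tiling keeps every window a pure plateau and slope
recovery under 1%. Noise is Gaussian with SD `k · S` — the empirical
model constrains only two moments, so the distributional choice is
free. The default noise coefficient is 0.007 (slope ≈ 0.005 at 2 mAs,
region SNR ≈ 200), chosen so that full-resolution simulation PSNRs land
in the mid-40s-to-50s dB band reported for real chest radiographs and
phantom acquisitions; clipping affects far less than 1% of pixels.

What the phantom does **not** emulate: anatomy and texture (flat
plateaus have no structural detail, so absolute SSIM values run lower
than on real radiographs, where local structure dominates local
variance), scatter, heel effect, detector MTF, spatially correlated
acquisition noise, and any kVp dependence of the slope (the synthetic
noise coefficient is kVp-independent; the kVp axis of the calibration
grid exercises bookkeeping, not physics). Passing tests therefore
demonstrate that the pipeline's estimators and transforms are correct
under the stated noise law — not that the simulation is clinically
indistinguishable from real low-dose acquisitions, which requires
observer studies on real data.

The cohort generator emulates label-table *structure* (1/0/−1 values,
2% uncertainty, support devices, demographics, PA/AP 60/40, anchor
ages 18–90, anchor years 2110–2200), not disease co-occurrence. Paired
scores follow the equal-variance binormal model
(`μ = √2 · Φ⁻¹(AUC)`); alternative conditions add independent Gaussian
perturbations to the same base scores, giving a controllable paired
null/alternative structure.

## Numerical choices and degenerate inputs

- Sample SD everywhere with ddof = 1.
- Rounding to grey levels is round-half-to-even (`np.rint`).
- Constant images: threshold partition collapses to bin 0 (no error);
  through-origin regression errors only when *all* window means are 0.
- Goal-slope nearest-mAs ties break toward the lower mAs.
- The auto-factor search accepts factor 1 when even the minimal
  perturbation overshoots the goal but stays within 10% of it (the
  full-dose near-identity case); otherwise a failed bracket is an
  error, never a silent clamp.
- Seeds: every stochastic routine takes an explicit seed or
  `numpy.random.Generator`; fixed seed implies bit-identical output.

## Problem sizes used in the test suite

Calibration and simulation checks run on 512² phantoms (2,601 analysis
windows each; slope recovery well inside the 5% tolerance), quality
resolution checks on 1024², the DeLong type-I calibration on 2,000
null datasets of 200 cases, and the bootstrap variance cross-check on
500 cases × 1,000 resamples. These sizes keep the statistical
tolerances comfortably met while the full suite runs in well under a
minute.

## Known limitations

- DICOM is read but not written; outputs are 16-bit PNG/TIFF plus a
  JSON provenance sidecar.
- The simulation is population-level: it does not individualise for
  SID, body habitus, or equipment response, and a single goal slope is
  applied to the whole image.
- `histogram` restore mode relies on scikit-image's histogram matching
  and is not exactly idempotent on integer images.
- Grouped (per-patient) splitting trades exact split sizes for leakage
  control.
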