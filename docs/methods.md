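# Methods

This note documents the models, conventions and numerical choices in
`gfcpipe`, in the order the pipeline applies them, together with what
the synthetic-data generator does and does not emulate.

## The GFC statistic

For each gray-matter voxel the statistic is the average correlation of
its time series with every other gray-matter voxel. Two published
conventions exist and both are implemented:

* `mean_z` (default): Fisher z-transform each pairwise correlation,
  then average. This matches the "z-scores matrix" convention and is
  the mode used for group inference unless configured otherwise.
* `mean_r`: average raw correlations. This admits an O(n·T) algorithm
  (the sum of correlations of voxel *a* is the inner product of its
  standardized series with the sum of all standardized series) and is
  used as the fast cross-check path.

Self-correlation is excluded from the average (divisor n − 1); a flag
re-includes it for sensitivity checks. Correlations are clipped to
±(1 − 10⁻⁷) before `atanh`, so duplicated columns produce a large
finite value (≈ 8.1) instead of infinity. Zero-variance voxels get
GFC = 0 and a QC flag rather than propagating NaN. Negative
correlations enter the average as-is; no positivity threshold is
applied (some global-connectivity variants threshold at r > 0 — that
variant is deliberately not implemented, as a documented difference).
`gfc_bruteforce` is a naive double loop kept as the oracle;
`gfc_fast` must match it to 10⁻¹⁰ (tested).

## Preprocessing chain

Fixed stage order: drop initial volumes → motion QC → spatial smoothing
→ linear detrend → band-pass → nuisance regression → scrubbing.
Scrubbing runs last because temporally filtering a non-contiguous
series is ill-defined; deleting frames after filtering means removed
frames cannot leak back in.

* **Volume dropping**: first 10 volumes (steady-state magnetization).
* **Motion QC**: a subject fails if any frame's |translation| exceeds
  2 mm on any axis or |rotation| exceeds 2° on any axis, applied to
  the parameters themselves (displacement from the reference frame,
  the common toolbox convention). Failing subjects are excluded with a
  logged reason; reported subject counts reflect exclusions.
* **Smoothing**: per-frame isotropic Gaussian,
  σ = FWHM/(2√(2 ln 2)) per axis in voxel units (0.566 voxels at 4 mm
  FWHM on a 3 mm grid), reflecting boundaries.
* **Detrend**: OLS residuals on [intercept, frame index]. Note that a
  finite window of a pure sinusoid is not orthogonal to a ramp, so
  detrending distorts a k-cycle oscillation by ≈ amplitude/(π·k)
  (≈ 5% for 20 cycles); this is a property of linear detrending
  itself, not an implementation artifact.
* **Band-pass** (0.01–0.08 Hz): ideal rectangular filter on discrete
  FFT bins, DC excluded, real output. A Butterworth alternative is
  available behind `bandpass_filter`'s caller by configuration of the
  band only; the ideal filter is the default convention here.
* **Nuisance regression**: intercept + Friston-24 motion expansion
  (parameters, one-frame lags, both squared; lags zero-padded at
  t = 0) + mean white-matter signal + mean CSF signal = 27 columns.
  The global signal is *retained* — deliberately, matching the
  analysis convention the pipeline implements. WM/CSF mean signals are
  extracted from the smoothed image, passed through the same detrend +
  band-pass stages as the data, and the WM mask is eroded by one voxel
  (when erosion leaves a non-empty mask) so the mean comes from a
  white-matter-centered region. Rank-deficient designs drop dependent
  columns with a warning naming them.
* **FD and scrubbing**: Power's convention,
  FD_t = Σ|Δtranslation| + 50 mm × Σ|Δrotation (rad)|, FD₁ = 0.
  Frames with FD strictly > 0.2 mm are deleted (no backward/forward
  augmentation). If fewer than `scrub_floor` (default 30) frames would
  remain, the subject is excluded with a logged reason.

## Group inference

Per-voxel OLS of the subject GFC maps on
[intercept, group, mean FD, age], group coded patient = 1 so negative
t means lower connectivity in patients. Family-wise error across
voxels is controlled by the permutation distribution of the maximum
|t| under the Freedman–Lane scheme: the maps are regressed on the
nuisance columns only, residuals are permuted across subjects, the
full model is refit, and the maximum |t| over voxels recorded per
permutation. Adjusted p(v) = (1 + #{max ≥ |t_obs(v)|})/(P + 1);
significance at adjusted p < α (default 0.05, P = 1000). Testing is
two-sided. This permutation mechanism is a deliberate substitution for
random-field-theory FWE: it is assumption-light and exactly testable
at desk scale (its type-I calibration is itself a test). Voxel-level
FWE is the inference; clusters (26-connectivity components of the
significance mask, peaks in affine mm) are descriptive.

## Clinical correlation and demographics

Cluster-mean GFC (Fisher-z units) is correlated with illness duration
within the patient group only, using the product-moment r and the
exact two-sided p from t = r√(n−2)/√(1−r²). Bonferroni correction
multiplies by the number of clusters. Demographic comparisons use
Student's pooled-variance two-sample t-test (Welch available by flag)
and a Pearson chi-square *without* continuity correction for the sex
table — the no-correction convention reproduces the printed cohort
p-value (0.19) where the Yates-corrected variant does not, which pins
the convention and is asserted in a test.

## Classification

Each cluster's mean GFC is evaluated separately as a diagnostic
feature (patients = positive class). An RBF-kernel soft-margin SVM is
trained with leave-one-out cross-validation over the grid
log₂C ∈ {−5, …, 15}, log₂γ ∈ {−15, …, 3} (step 2), the feature
standardized with training-fold statistics only. The best grid point
maximizes LOOCV accuracy (ties → smaller C, then smaller γ);
confusion counts pool the held-out predictions at that point.
Selection is deliberately non-nested — the same LOOCV that scores the
grid is reported, mirroring the accuracy-surface practice this
emulates; the resulting optimism is quantified (permuted labels yield
mean best-grid accuracy of roughly 55–65%, not 50%) rather than
hidden, and a nested outer/inner mode exists for comparison.

The SVM dual is solved by an in-package SMO solver (second-order
working-set selection with shrinking and warm starts along the C path,
plus alpha-seeding of leave-one-out folds from the full-data
solution), compiled with numba. This makes the million-fit permutation
studies tractable on one CPU; the solver's predictions are validated
against an independent SVM implementation across the grid in the test
suite. ROC analysis uses the rank (Mann–Whitney) AUC with tie
correction on the *raw* feature — the cut-off is reported in feature
(Fisher-z) units, which only makes sense on that scale — sweeping
midpoints of adjacent sorted values; the cut-off maximizes the Youden
index, ties broken toward higher specificity, with lower-is-positive
as the default direction (connectivity is reduced in patients).

## Synthetic cohort generator

Each gray-matter voxel follows

```
x_v(t) = b_g(v)·g(t) + b_r(v)·s_k(t) + σ·ε_v(t)
```

with a global latent signal g shared by all voxels, per-effect-region
latents s_k, and white noise. Latents are sums of 12 sinusoids with
random phases at frequencies drawn in [0.012, 0.078] Hz — inside the
analysis band by construction, so ≥ 90% of latent power survives
filtering (tested). Coupling is attenuated toward the brain edge via
the gray-matter probability. The gray-matter probability map is a
smooth sigmoid ball with two low-probability pockets carved out; those
pockets are the WM and CSF masks and carry their own latent signals,
so the nuisance regressors are structured but orthogonal to the
retained global signal.

Default study conditions: 20 patients vs 23 controls, 250 volumes at
TR 2 s, 3 mm voxels on a 24³ grid, ages ≈ N(52.6, 8.7²) /
N(49.7, 6.5²) truncated to [18, 65] and rounded, education and sex
ratios matching the emulated cohort table, per-subject target mean FD
≈ N(0.31, 0.10²) for patients and N(0.39, 0.10²) for controls.

**Effect design.** Two spherical effect regions are implanted (a deep
"thalamus-like" blob, ~65 voxels at 24³, and an inferior
"cerebellum-like" blob, ~33 voxels) — sizes chosen to mirror a
two-cluster result, with no anatomical claim. Controls have global
coupling 1.0 everywhere; patients have coupling 0.4 inside the effect
regions, jittered per subject by a standardized severity z with SD
0.25 (patient-only heterogeneity; outside the regions the groups are
statistically identical). Illness duration is generated as
20.75 + 15·z + N(0, 5²) months, rounded and floored at 1 — slope and
residual chosen so the implied duration SD (√(15² + 5²) ≈ 15.8 months)
matches the emulated cohort's printed 15.37, and so the severity
signal dominates the duration variance. With these choices the
per-voxel between-group difference is ≈ 0.2 in mean-correlation units
(t ≈ 5–9 at n = 43), the blob-mean GFC correlates with duration at
r ≈ 0.6–0.9 in the patient group, and single-feature classification
lands at 85–95% accuracy — the regime of a clearly detectable but not
degenerate effect. These effect sizes are free parameters of the
generator (no real-data calibration target exists for them); they
were fixed once from this signal-to-noise argument.

**Motion model.** The six rigid-body parameters follow a mean-reverting
AR(1) walk (ρ = 0.8) whose per-frame steps are modulated by an i.i.d.
truncated log-normal burst envelope (σ = 1.2, |z| ≤ 2), giving the
right-skewed FD distribution of real traces — a low median with
occasional spikes — while keeping positions inside the 2 mm/2° QC box
for ≈ 99% of subjects. The trace is rescaled so realized mean FD
equals the target exactly (FD is 1-homogeneous in the parameters);
with a positive spike rate at least one frame is guaranteed over the
0.2 mm scrubbing threshold. Note a consequence the emulated cohort
table implies: with mean FD ≈ 0.31–0.39 mm and a 0.2 mm threshold,
roughly half the frames are scrubbed; subjects retain ~90–130 of 240
frames, which the GFC estimates tolerate.

**What the generator does not emulate**: scanner drift beyond a linear
trend, physiological noise spectra, spatial autocorrelation of the
noise (noise is white across voxels; smoothing induces some), EPI
distortion, anatomical variability, or registration error. Passing
tests therefore validate the statistical machinery — estimator
identities, error control, recovery under the assumed generative
model — not robustness to every artifact of real acquisitions.

## Problem sizes used in tests and the acceptance script

Cohort-level studies (type-I calibration, effect recovery, duration
correlation, and the end-to-end acceptance run) use a reduced 16³ grid
(~1,400 gray-matter voxels) with the full 43-subject cohort, full
250-volume runs and full permutation counts (500–1000); the
type-I study runs 100 null cohorts, effect recovery 10 seeds, duration
recovery 20 seeds, and the classifier permutation studies 200 (LOOCV)
and 1000 (AUC) repetitions. These sizes keep each study's Monte-Carlo
error well inside the asserted bands. Unit tests run on toy grids
(≤ 16³) and small matrices.

## Known limitations

* The permutation FWE replaces random-field theory; results on real
  data would differ slightly from an SPM-style analysis in the
  adjusted p-values, though both control the same error rate.
* Scrubbing position in the chain (last) is a documented design
  choice; the emulated study does not state where scrubbing occurred.
* No slice-timing correction, realignment, or spatial normalization:
  inputs must already share one grid, and grid mismatch is an error,
  never a silent resample.
* The non-nested grid selection in classification is optimistically
  biased by construction; treat reported accuracies as the surface
  practice they mirror, not as unbiased generalization estimates
  (use the nested mode for that).
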