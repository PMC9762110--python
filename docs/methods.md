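# Methods

This note records the models implemented in `dceprost`, the numerical and
design choices behind them, what the digital phantom does and does not
emulate, and the known limitations.

## Arterial input functions

Two population AIFs are provided, with their published constants stored in
`src/dceprost/aif_constants.json` (versioned, with units):

* **Parker** — sum of two Gaussians (first pass and recirculation) plus a
  sigmoid-modulated exponential washout, constants defined per minute at a
  reference dose of 0.1 mmol/kg.  The form is treated as whole-blood
  concentration; plasma concentration is blood / (1 − Hct).
* **Weinmann** — biexponential plasma clearance
  `Cp(t) = D (a1 e^{−m1 t} + a2 e^{−m2 t})` with D in mmol/kg; whole-blood
  concentration is plasma × (1 − Hct).

Both are normalised to a common plasma domain through a configurable
haematocrit (default 0.42, the standard adult value) because the Tofts model
consumes plasma concentration.  Concentration is defined as identically zero
before the bolus-arrival offset, matching injection semantics; all public
interfaces work in seconds and the per-minute constants are converted once
at load.  The amplitude scales linearly with dose; the dose itself is
configuration (clinical protocols may use a fixed-volume bolus rather than a
per-kg dose, so no single value is "correct").

## SPGR signal ↔ concentration

The spoiled-gradient-echo steady state
`S = S0 sin α (1 − E)/(1 − cos α E)`, `E = exp(−TR·R1)`,
`R1 = 1/T10 + r1·C`, links concentration to signal.  Fixed constants:
relaxivity r1 = 3.5 L mmol⁻¹ s⁻¹, pre-contrast T1 = 1.597 s in prostate
tissue and 1.664 s in arterial blood, flip angle 20°.  TR is not part of the
fixed protocol description and defaults to 4 ms (typical for time-resolved
view-sharing prostate DCE); it is an explicit field, never hidden.

The inverse uses only the signal-to-baseline ratio, so the scanner scale S0
cancels; it is the exact algebraic inversion, not a linearisation, giving a
round-trip identity at numerical precision (~1e-14 mM).  The baseline is the
mean of the first `n_baseline` frames (default 5 — enough frames for a
stable mean with little risk of bolus contamination).  Degenerate cases are
contracts, not exceptions: a non-positive baseline marks the voxel
unconvertible; enhancement ratios outside the invertible SPGR branch
(saturated or negative signal) are flagged per sample and clamped into
[0, 50] mM; sub-baseline noise inverts to a small negative value that is
clamped to zero with the raw value retained for diagnostics.

## Standard Tofts model

`Ct(t) = Ktrans ∫ Cp(τ) e^{−kep (t−τ)} dτ` with `kep = Ktrans/Ve`; kep is
always derived, never independently stored.  The convolution runs on a
uniform internal grid (0.5 s) where the integral of a linearly interpolated
Cp against the exponential kernel is evaluated exactly per interval via a
first-order recursion; off-grid measurement times are reached by one exact
partial step rather than by interpolating the result (the result's curvature
near bolus arrival would otherwise dominate the error).  At 0.5 s the
discrepancy against closed-form solutions under exponential AIFs stays below
1e-4 mM over the whole fitting box — a 1 s grid was measured at ~2e-4 mM
near the upper Ktrans bound, hence the finer default.

Two fitters share this forward model:

* `fit_tofts` — per-curve bounded nonlinear least squares on (Ktrans, Ve),
  bounds Ktrans ∈ [0, 5] min⁻¹, Ve ∈ (1e-3, 1], deterministic multi-start
  from (0.1, 0.2), (0.5, 0.3), (1.5, 0.5); lowest final SSE wins, ties break
  toward the smaller Ktrans (parsimony).  All-zero or all-flagged curves
  return Ktrans = 0 with Ve not estimable and `converged=False` so
  whole-volume maps survive bad voxels.
* `fit_tofts_volume` — for maps and cohort-scale tables.  For fixed kep the
  model is linear in Ktrans, so the 2-D problem collapses to a 1-D kep
  search: each curve is projected onto a dense log-spaced dictionary of unit
  responses (400 points, kep ∈ [0.005, 30] min⁻¹), kep is refined
  parabolically in log space, and Ktrans is re-projected at the refined kep.
  This is orders of magnitude faster than per-voxel multi-start optimisation
  and a test pins its agreement with `fit_tofts`.  Out-of-bounds solutions
  are flagged (`converged=False`) and clamped only for map display.

iAUGC60 is the trapezoidal integral of the measured concentration curve over
[t_start, t_start + 60 s], reported in mM·min, with interpolated window
endpoints.  t_start defaults to the protocol bolus-arrival time (the AIF
onset), not a per-voxel onset, matching the "post-injection" definition; a
window truncated by the end of acquisition is integrated to the last sample
with a warning.

## Semi-quantitative piecewise-linear parameterisation

Each voxel's signal is normalised as (S − S_base)/S_base — invariant under
any positive rescaling of the raw signal — and fitted with a continuous
four-segment model: zero baseline until Tonset, linear rise with slope IRE
to ME at Tonset + TTP, flat plateau (exactly zero slope) until Twashout,
then linear decline with slope IRW ≤ 0.  A three-segment no-washout variant
competes on SSE; when it wins, the sentinel pair (Twashout = 0, IRW = 0)
records that the agent had not washed out within the acquisition.

Breakpoints are searched exhaustively on the sampling grid (minimum two
samples per segment).  Given breakpoints the model is linear in (ME, IRW),
so each triple reduces to a closed-form 2×2 least squares assembled from
prefix sums — O(1) per candidate after an O(n²) table build, deterministic,
and globally optimal at grid resolution (verified against brute-force
enumeration in the tests).  Sign constraints define the model class: an
unconstrained solution with IRW > 0 is covered exactly by the no-washout
candidate of the same pair; one with ME < 0 describes a curve with no
positive enhancement and is represented by the flat, non-enhancing outcome.
AUC is the signed trapezoidal area of the *data* curve (a data functional,
deliberately not a property of the fitted model).  Tonset, Twashout and IRW
are computed and exported but excluded from the downstream statistics and
classifiers, where they are unstable (washout often absent within the
acquisition window, onset sensitive to noise).

The search cost scales roughly with n³ in the number of frames, so
whole-volume work favours the 60 × 7.2 s protocol (~2 ms/curve) over the
120 × 3.6 s protocol (~60 ms/curve); both are exercised in tests.

## Tissue labelling

Tumour annotations are dilated by a registration-uncertainty margin
(default 3.3 mm) implemented as Euclidean distance-transform thresholding on
voxel centres with anisotropy-aware sampling — exact metric semantics, not
iterated structuring elements.  Prostate voxels inside the ring are excluded
from all analysis; the rest are benign.  Grade strata: grade group ≤ 2 low,
≥ 3 high.  The labelling is validated against a brute-force pairwise
distance oracle and satisfies partition and margin-monotonicity invariants.

## Statistics and classifiers

Cohen's d uses the pooled standard deviation and is reported as |d| with the
conventional bins (negligible < 0.2, small < 0.5, medium < 0.8, large
beyond).  KS tests use the asymptotic two-sample p-value — exact p-values
are meaningless at 10⁵–10⁶ voxels.  Voxels are pooled across patients, as
in the study design this reproduces; voxel non-independence within patients
is knowingly ignored and `patient_id` is kept for future clustered analyses.

Correlation pruning is greedy: while any |Pearson r| exceeds the threshold
(default 0.65), drop the feature with the most supra-threshold partners,
ties broken toward the larger mean |r| (then lexicographically).  The rule
is validated by reproducing the expected retained set
{Ktrans, Ve, TTP, AUC} on data generated with the reported correlation
structure.

Classifiers: scikit-learn logistic regression (L2, C = 1) and random forest
(500 trees, unlimited depth, seeded); hyperparameters are fixed and
recorded, not tuned.  Benign voxels are seeded-down-sampled to 1:1 with
tumour voxels before a stratified 80/20 voxel split; standardisation uses
training-split statistics only.  Voxel-level splits are optimistic relative
to patient-level splits (neighbouring voxels of one patient can straddle the
split); a patient-grouped split is available via `group_by_patient`.

## Digital phantom

The phantom generates what the pipeline consumes: per patient an
ellipsoidal prostate (≈0.4 of each grid dimension, jittered per patient) on
a 64 × 64 × 16 grid of 0.8 mm isotropic voxels, two spherical tumour foci
with grade groups drawn from a realistic cohort mix (GG 1/2/3/5 at
6.6/50.8/32.8/9.8%), voxel-wise (Ktrans, Ve) from truncated-normal class
distributions, Parker-AIF Tofts concentration curves, SPGR signal synthesis
(S0 = 5000, baseline ≈ 68 units) with additive Gaussian noise (sd 6 units
≈ 0.02 mM in concentration), and directly drawn ADC and T2w values.  The
focus radius is solved by bisection on the actual label counts so the
analysed benign:tumour ratio matches ≈4.6:1 within a few percent — the class
imbalance structure of the emulated cohort at reduced scale.  The default
cohort is 8 patients on the 60 × 7.2 s protocol: desk-scale for the full
pipeline, and one of the study's three real protocols.

**Effect-size calibration.**  Targets are signed tumour-minus-benign Cohen's
d values per stratum.  ADC and T2w are calibrated analytically (tumour mean
shifted by d times the common sd; exact in population).  The kinetic chain
has exactly two knobs per tumour class — the mean Ktrans and mean Ve — and
they are tuned against the *fitted* Ktrans effect size and the TTP effect
size (kep = Ktrans/Ve controls time-to-peak) by damped Newton iterations on
common-random-number estimates (n = 1000 voxels per class per iteration,
tolerance 0.05), with a 2×2 Jacobian probed numerically.  Unreachable
targets raise an error naming the parameter.

Because two knobs cannot pin eleven features, the remaining derived features
(IRE, iAUGC60, ME, AUC, fitted Ve, and the Weinmann-AIF re-fits) land where
the kinetics put them.  Their magnitudes are kept moderate by design — the
tumour classes are markedly more heterogeneous (wide Ktrans/Ve spreads) than
benign gland, which is also physiologically sensible — but they are not
individually calibrated, and the Weinmann-fitted Ktrans in particular
absorbs part of the kep separation and can exceed the Parker-fitted effect
size, unlike in real data where inter-patient nuisance variability dilutes
it.  Ordering claims on the calibrated phantom are therefore made over the
direct features plus the Parker-pipeline features that the downstream
classifier analysis consumes.

**What the phantom does not emulate:** anatomically realistic prostate or
zonal anatomy, registration error, per-patient AIF/dose/arrival variability,
spatial correlation of kinetics between neighbouring voxels, Rician
magnitude noise (Gaussian is adequate at prostate DCE SNR and has a simpler
inverse), or scanner drift.  Passing tests on the phantom therefore
demonstrate correctness of the computations and the qualitative
discriminability structure — not clinical performance on real cohorts.

## Problem sizes used in the shipped checks

The test suite and `scripts/acceptance.py` run at desk scale, chosen once:
50 random draws for the convolution oracle; a 3×3 truth grid with 200 (tests)
or 50 (script) noisy replicates per cell for Tofts recovery; ≤30-frame
curves for brute-force search optimality; 32³ grids for the mask oracle;
10⁵ voxels per class for direct-feature effect sizes; 8000-voxel feature
tables for the measured effect sizes; and 20 replicates of ~4000 voxels for
the classifier comparison.

## Known limitations

* Fixed T1 and population AIFs propagate systematic (patient-independent)
  biases into Ktrans and Ve; this mirrors the analysis being reproduced.
* The vendor software originally used for such analyses is closed; its
  plateau convention, normalisation and fitting internals are unknown, so
  the conventions here (zero-slope plateau, data-curve AUC, exact SPGR
  inversion) are documented choices rather than replications.
* iAUGC60 with a protocol-level t_start charges pre-enhancement baseline to
  voxels with late arrival; a per-voxel alternative is available via the
  `t_start` argument.
* The phantom's effect-size calibration controls four features per stratum;
  the others follow from the kinetics (see above).
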