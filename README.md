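# dceprost

Voxel-wise dynamic contrast-enhanced (DCE) MRI analysis for prostate tumour
imaging-biomarker studies.

In biologically targeted radiation-therapy planning, each prostate voxel must
be characterised as tumour or benign from multiparametric MRI (T2-weighted,
diffusion ADC, and DCE).  This package implements the full voxel-level
analysis chain used to rank MRI parameters as tumour biomarkers against
histology-validated labels:

* **Semi-quantitative curve shape** — a continuous piecewise-linear model
  (flat baseline, linear wash-in, plateau, linear washout) fitted to each
  voxel's baseline-normalised signal by exhaustive breakpoint search, yielding
  Tonset, IRE, TTP, ME, Twashout, IRW and AUC.
* **Quantitative pharmacokinetics** — conversion of the spoiled-gradient-echo
  (SPGR) signal to gadolinium concentration with fixed relaxation constants
  (r1 = 3.5 L mmol⁻¹ s⁻¹, T1 = 1597 ms tissue / 1664 ms blood), then the
  standard Tofts model

      Ct(t) = Ktrans ∫₀ᵗ Cp(τ) e^{-(Ktrans/Ve)(t-τ)} dτ

  fitted per voxel under two population arterial input functions (the Parker
  mixture-of-Gaussians + sigmoid-exponential form and the Weinmann
  biexponential), plus iAUGC60, the initial area under the concentration
  curve over the first 60 s post-injection.
* **Histology-style labelling** — tumour masks with Gleason grade groups;
  a 3.3 mm Euclidean uncertainty ring around tumours is excluded and the
  remaining prostate labelled benign; strata split at grade group ≤ 2 vs ≥ 3.
* **Biomarker statistics** — two-sample Kolmogorov–Smirnov tests, pooled-SD
  Cohen's d per parameter and stratum, Pearson correlation matrices, and
  greedy pruning of features correlated above 0.65.
* **Classifier comparison** — logistic-regression and random-forest
  tumour/benign classifiers over five nested feature sets (T2w+ADC up to
  T2w+ADC+Ktrans+Ve+TTP+AUC), with seeded benign down-sampling, an 80/20
  voxel split, and sensitivity/specificity/accuracy plus RF feature
  importance.
* **Digital phantom** — a synthetic cohort with ellipsoidal prostates,
  spherical graded tumour foci, voxel-wise Tofts kinetics and a ~4.6:1
  benign:tumour imbalance, calibrated so that per-stratum effect sizes match
  configurable targets; every downstream estimate has stored ground truth.

## Worked example

Fit the Tofts model to a noisy tumour-like voxel (`examples/03_tofts_fitting.py`):

```
truth : Ktrans 0.350 /min, Ve 0.300, kep 1.17 /min
fitted: Ktrans 0.356 /min, Ve 0.299, kep 1.19 /min (rmse 15.5 uM, converged=True)
iAUGC60: 0.410 mM*min
```

With 0.02 mM concentration noise at 3.6 s sampling the bounded multi-start
fit recovers the transfer constant within ~2%; iAUGC60 is a model-free
integral of the measured curve.

Run the whole study on a calibrated phantom (`examples/05_phantom_study.py`):

```
|Cohen's d| vs benign (high grade):
  adc             0.979
  ktrans_parker   0.768
  ire             0.569
  ttp             0.498
  ...
RF T2w+ADC                      sens 0.56 spec 0.53 acc 55%
RF T2w+ADC+Ktrans+Ve+TTP+AUC    sens 0.70 spec 0.67 acc 68%
```

ADC is the most discriminating single parameter for high-grade disease,
Ktrans the strongest DCE parameter, and adding the DCE features lifts the
random-forest accuracy well above the T2w+ADC baseline.

The `examples/` directory holds one short script per capability; the
`dceprost` CLI (`phantom`, `quantify`, `labels`, `study` subcommands) chains
the same stages over a directory of NIfTI volumes.

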