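# fmtheta

Simulation and analysis pipeline for **individualized frontal-midline theta
(fm-theta) EEG neurofeedback**, with prediction of training success from
regional brain morphometry.

Fm-theta is a 4–8 Hz oscillation, maximal over fronto-central midline
electrodes, tied to cognitive control and generated chiefly in the
midcingulate cortex (MCC). In an individualized neurofeedback protocol,
each participant's personal theta peak frequency is first determined from
task EEG, then fed back in real time over eight training sessions so the
participant learns to up-regulate it. People differ widely in how well they
learn this; a central question is whether that *responsiveness* is grounded
in the anatomy of the fm-theta generators — MCC gray matter and the white
matter tracts beneath it.

Raw EEG/MRI from such studies is typically not public, so this package makes
the entire protocol *simulatable*: a synthetic cohort with a known
ground-truth responsiveness ρ runs through the exact analysis chain, and
every stage can be validated against that ground truth.

## What is implemented

* **Synthetic cohort generator** — subjects with an individual theta peak in
  4–8 Hz (stable across sessions), 1/f background EEG at seven electrodes
  (Fz, FC1, FCz, FC2, Cz, Fp1, Fp2; 250 Hz; µV), frontopolar-dominant eye
  blinks, and a 40-column ROI morphometry table (GM/WM × volume/concentration
  × region × hemisphere) whose predictive columns carry ρ with configurable
  signs. Theta amplitude during feedback block *b* of session *s* follows
  `A = A₀ · (1 + ρ(w·b + a·(s−1)))`.
* **Theta profiling** — event-related spectral perturbation (ERSP; short-time
  Hamming FFT, dB re pre-stimulus baseline) per task condition, 4–8 Hz peak
  detection, and the individual theta as the mean of the four condition peaks.
* **Neurofeedback loop** — per-session EOG calibration (individualized
  artifact band from thresholded Fp1/Fp2 frames), sliding 2-s Hamming FFT
  every 200 ms, artifact-window rejection, and the 40-step color mapping
  (gray at the start-baseline mean, maximal red/blue at its 97.5th/2.5th
  percentiles, updated every 250 ms).
* **Learning indices** — L1 (within-session enhancement per segment, re
  session 1's start baseline, averaged over sessions) and L2 (per-session
  block mean re session 1), plus scalar success summaries.
* **Inference layer** — one-way repeated-measures ANOVA, Kolmogorov–Smirnov
  normality check, one-tailed Pearson correlation, stepwise multiple
  regression (entry p = .05 / removal p = .10) with standardized β, adjusted
  R² `= 1 − (1−R²)(n−1)/(n−k−1)` and the model F — all written from explicit
  sums of squares and cross-checked against independent oracles in the tests.
* **I/O** — EDF+ (minimal writer, reading via MNE), lossless matrix+JSON,
  ROI tables as TSV with an atlas-alias map, YAML study configs, and a
  `fmtheta` CLI (`simulate`, `train`, `indices`, `correlate`, `regress`,
  `run-study`).

## Worked example

The numbered drivers under `analysis/` run a 40-subject cohort through the
whole protocol (shortened 20-s segments; see `docs/methods.md`):

```bash
cd analysis
python 01_simulate_cohort.py
python 02_profile_theta.py
python 03_run_training.py
python 04_learning_curves.py
python 05_early_vs_final.py
python 06_structure_regressions.py
python 07_printed_consistency.py
```

Output of a full run (seed 7):

```
profiled 40 subjects: MAE = 0.123 Hz, max |error| = 0.430 Hz
trained 40 subjects x 8 sessions; 21.4% of windows rejected as eye artifacts
mean L1 (uV): [0.056, 0.51, 0.613, 0.712, 0.81, 0.937, 1.045, 0.07]
mean L2 (uV): [0.0, 0.105, 0.182, 0.296, 0.408, 0.511, 0.62, 0.706]
ANOVA block:   F(7, 273) = 75.00, p = 6.22e-60
ANOVA session: F(7, 273) = 70.08, p = 2.42e-57
early vs final training success: r = 0.685, t(38) = 5.79, one-tailed p = 5.47e-07
L1_gm: F(1, 38) = 26.18, adj R^2 = 0.392, beta_std {gm_vol_mcc_r: +0.64}
L1_wm: no predictor met the entry criterion (n.s.)
```

Reading this: profiling recovers each subject's theta peak to ~0.1 Hz; the
within-session curve (L1) shows the six feedback blocks clearly above the
two no-feedback baselines, while the across-session curve (L2) accumulates
from 0 to ~0.7 µV over eight sessions — both confirmed by the
repeated-measures ANOVAs. Early success (session 2) predicts final success
(session 8), and the stepwise regression on gray-matter morphometry selects
right-MCC volume with a positive standardized β as the predictor of
within-session training success. The white-matter model needs larger samples
than n = 40 (the suppression-driven cingulate-bundle pair has weak marginal
correlations); it is recovered reliably at n = 200.

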