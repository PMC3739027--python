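# Methods

This note documents the models, the numerical choices, and what the
synthetic-data experiments can and cannot show.

## The simulated protocol

A cohort of subjects undergoes an eight-session neurofeedback protocol.
Each session has eight five-minute segments in fixed order: a start
baseline, six feedback blocks, and an end baseline. EEG is simulated at
seven electrodes (Fz, FC1, FCz, FC2, Cz, Fp1, Fp2) at 250 Hz in microvolt.

### Subject model

Each subject carries:

* an individual theta peak frequency, drawn uniformly from 4–8 Hz and held
  fixed across sessions (individual theta peaks are stable within a person
  over time);
* a baseline theta amplitude `A₀` (default 2.0 ± 0.4 µV at FCz);
* a latent *responsiveness* ρ — how strongly the person's theta responds to
  feedback training;
* a blink rate (default 0.1 Hz: participants in feedback training are
  instructed to suppress blinking, so resting blink rates of ~0.2–0.4 Hz are
  roughly halved).

The theta amplitude during feedback block `b` (1–6) of session `s` (1–8) is

    A(b, s) = A₀ · max(0, 1 + ρ · (w·b + a·(s−1)))

with within-session gain `w = 0.05`/block and across-session gain
`a = 0.05`/session. Growth linear in block and session index is the simplest
shape consistent with monotone accumulation of training effects; the gains
give a ~30 % within-session and ~35 % across-course enhancement for ρ = 1,
a plausible effect for a successful trainee. Baseline segments carry the
plain `A₀` — feedback-driven enhancement is expressed only while feedback is
given, which is what makes blocks rise above both baselines in the L1 curve.

ρ is Gaussian around 1.0 (SD of its independent component 0.5), so the
cohort contains both responders and (ρ ≤ 0) non-responders, with a positive
population mean — matching the observation that group-level enhancement is
significant while individuals vary widely.

### Background EEG, theta and blinks

Each channel is an independent 1/f^α noise process (α = 1, SD 5 µV), the
standard EEG surrogate, plus the theta oscillator scaled by a fixed
fronto-central topography (maximal at FCz), plus eye blinks: ~400 ms smooth
biphasic transients with lognormal amplitude (mean 150 µV, CV 0.2) and a
frontopolar-dominant topography with frontal-to-central falloff. Blink times
are Poisson. Event times are recorded as ground truth for validating the
artifact-rejection stage.

### Morphometry coupling

The morphometry table has 40 columns: {GM: MCC, superior/middle frontal,
IFC pars triangularis/orbitalis/opercularis; WM: cingulate bundle, SLF II,
anterior/superior corona radiata} × {left, right} × {volume, concentration}.
Latent z-scores per column are drawn per subject; volumes are log-normal
around region-typical means and concentrations are `0.5 + 0.08·z` clipped to
[0, 1], after adding measurement noise (SD 0.1).

ρ is a weighted sum of three z-scores plus noise: right-MCC GM volume
(+0.5), left cingulate-bundle WM volume (+0.5) and right cingulate-bundle WM
concentration (−0.5). The two cingulate-bundle measures are correlated at
0.6, so the WM regression is a *suppression* configuration: opposite-signed
true effects on positively correlated predictors. This is what allows the
fitted standardized β of one predictor to exceed its marginal correlation
(and in small samples even |β| > 1) once the other is in the model. No
published effect size exists for this coupling; the weights are calibration
choices producing marginal correlations of ~0.6 (MCC) and ~±0.24 (bundle
measures), i.e. a GM effect detectable at small n and a WM pair that needs
n in the low hundreds — the regressions on the default n = 40 cohort
reproduce exactly this contrast (GM model significant, WM model n.s.).

## Theta profiling (ERSP)

Four task conditions each provide epochs of [−1, 2] s around a stimulus;
the post-stimulus interval contains a Hann-enveloped theta burst at a
condition-specific frequency near the subject's peak (offsets ±0.1/±0.3 Hz,
kept a margin inside 4–8 Hz; see below). The ERSP is a short-time FFT
(1-s Hamming window, 90 % overlap, zero-padded to a ~0.12 Hz grid) averaged
over epochs, in dB relative to the mean pre-stimulus baseline power per
frequency. Blink-contaminated epochs are excluded before averaging
(standing in for the ICA-based ocular correction used on real battery EEG,
which is not re-implemented).

The condition peak is the largest local maximum of the time-averaged
post-stimulus perturbation inside 4–8 Hz, requiring ≥ 1 dB prominence
(ties resolve to the lower frequency; no qualifying maximum flags the
condition as no-peak and the subject as unprofiled). The individual theta is
the mean of the four condition peaks. The profiling electrode is FCz
(fm-theta convention), configurable.

Numerical caveat, and why the bursts keep a margin: dB-normalizing against a
1/f baseline skews a detected peak upward by ~0.1 Hz (the ratio burst/noise
grows with frequency across the burst's bandwidth). Burst frequencies are
therefore clipped to [4.4, 7.5] Hz so estimated peaks stay interior to the
4–8 Hz search band. Profiling accuracy over a cohort: MAE ≈ 0.12 Hz,
bias ≈ +0.06 Hz.

## The online feedback chain

**Band amplitude.** One estimate per 200 ms from a sliding 2-s Hamming
window: `a = 2·sqrt(Σ_band |X_k|² / (N·Σw²))` — the amplitude of the
sinusoid whose power equals the taper-corrected spectral power summed over
the FFT bins inside the band. For a pure tone at a band-interior bin this is
exact (a 10 µV sinusoid reads 10.000 µV), and the estimator is linear in
signal scale. A per-bin *mean* amplitude was rejected because it dilutes a
narrowband oscillation by the number of band bins. The feedback band is the
individual theta ± 1 Hz; the feedback channel is FCz. In-band 1/f noise adds
to the estimate in quadrature (~1.5 µV at the defaults); the learning
indices are differences, so this bias largely cancels.

**EOG calibration.** Per-window frontopolar peak amplitude
`max(|Fp1|, |Fp2|)` is thresholded at its 0.99 quantile (windows sharing a
blink's peak sample form plateaus, so the comparison is ≥); the exceeding
windows are pooled, their mean FFT amplitude spectrum gives the artifact
spectral peak, and the artifact band is that peak ± 1 Hz (blink energy is
low-frequency, so the band lands below ~4 Hz). The rejection threshold is
the maximum artifact-band amplitude among *clean* windows — those whose
peak stays below twice the median window peak, a robust rule that keeps
sub-threshold blinks out of the reference set even when blinks are sparse
or frequent.

**Rejection.** A window is rejected when either frontopolar channel's
artifact-band amplitude exceeds the calibrated threshold. Rejection (unlike
estimation) uses an *untapered* FFT window: a Hamming taper would suppress a
blink sitting at the window edge and let that window pass as artifact-free.
With the default generator, ~20 % of windows are rejected; a segment with
> 50 % rejected is flagged low-quality with a warning.

**Color mapping.** The session's start-baseline window amplitudes define the
reference (mean, 2.5th, 97.5th percentile). The mean maps to 0 (gray);
amplitudes map linearly onto ±20 steps reaching maximal red at the 97.5th
and maximal blue at the 2.5th percentile, clamped beyond — 41 attainable
values. "95 % of the power range" is interpreted as percentiles of the
start-baseline window-amplitude distribution, the only distribution the
online chain has at its disposal. Colors update on a 250-ms clock by
sample-and-hold of the latest *completed* 200-ms-grid estimate (the two
rates are otherwise incommensurable); artifact frames are forced to gray.
Baseline segments produce no feedback frames.

## Learning indices

* **L1** (within-session dynamics): per segment, the mean over sessions of
  the segment amplitude minus the reference. The reference is session 1's
  start baseline by default — constant across sessions, so baseline segments
  have nonzero L1 values; each session's own start baseline is available as
  an option since the verbal definition is ambiguous.
* **L2** (across-session maintenance): per session, the mean over blocks 1–6
  minus the same quantity for session 1, so L2(session 1) ≡ 0. Baselines are
  excluded from the session summary by default (a "training session" change
  is most naturally a change in the trained state), with a flag to include
  them.
* Success scalars: `success_L1` = mean L1 over the six blocks (the "gain of
  dynamical changes" criterion for the regressions); early/final success =
  L2 at sessions 2 and 8.

Both indices are invariant to adding a constant to every amplitude and scale
linearly with the signal — tested properties.

## Inference layer

All statistics are computed from explicit formulas (and cross-checked in the
tests against statsmodels/scipy and hand-written brute-force oracles):

* one-way repeated-measures ANOVA with subjects as a blocking factor,
  F = MS_factor/MS_error, df = (k−1, (n−1)(k−1)); no sphericity correction
  (uncorrected df are what the consistency checks require);
* one-sample KS test against a normal with the sample's mean/SD, asymptotic
  p (reported alongside the correlation, not gating it);
* Pearson r with a one-tailed Student-t test, t = r√(n−2)/√(1−r²);
* stepwise regression: enter the candidate with the smallest coefficient
  p-value below 0.05, then remove any included predictor above 0.10, iterate
  to a fixed point (the conventional entry/removal defaults of commercial
  stepwise implementations). Standardized β = b·s_x/s_y; adjusted
  R² = 1 − (1−R²)(n−1)/(n−k−1); model F from R². An empty selection is a
  valid outcome. Candidates that would push the standardized design's
  condition number above 1e8 are skipped with a warning. Note the known
  hazard: under a global null with 40 candidates at entry p = .05, *some*
  predictor enters in roughly 1 − 0.95⁴⁰ ≈ 85 % of datasets — stepwise
  selection at n ≪ p is an uncertainty regime, which is why the consistency
  relations (below), not the selections themselves, are the primary check at
  n = 19;
* closed-form consistency: F from adjusted R² (inverting its definition) and
  F = t² from a single predictor's standardized β. For the published values
  (n = 19): adj R² = 0.361, k = 1 → F = 11.17; β = 0.630 → F = 11.19
  (printed: 11.186); adj R² = 0.724, k = 2 → F = 24.61 (printed: 24.651);
  r = 0.607 → one-tailed p = 0.0029 (< .01). The printed "r = 607",
  "β = 630" and "R² = 724" are read as 0.607/0.630/0.724 (dropped decimal
  points); the consistency relations confirm all three readings.

## Problem sizes

The protocol's 300-s segments are simulated in full where segment structure
itself is under test. Cohort-level experiments use 20-s segments — segment
duration only sets how many 2-s windows are averaged per segment mean (91 at
20 s vs 1491 at 300 s), and every downstream quantity is defined on those
means. Cohorts: n = 40 (analysis drivers; curve shapes, correlations,
rank-correlation of ρ with measured success ≈ 0.8) and n = 200 (stepwise
recovery of the white-matter suppression pair). Monte-Carlo checks use
10 000–50 000 replicates where a rate is asserted.

## What the synthetic experiments do and do not show

They show that the implementation is faithful: ground-truth parameters are
recovered through the full chain (theta peak to ~0.1 Hz, responsiveness
ordering with rank correlation ~0.8, morphometry effect signs through the
stepwise regressions), the printed-statistic consistency relations hold, and
the estimators hit their closed-form anchors. They do not show anything
about real brains: the generator has independent stationary 1/f channels (no
alpha rhythm, no drifts, no muscle or line noise, no volume-conduction
correlation structure), blinks are the only artifact class, amplitude growth
is exactly linear, and the morphometry coupling is linear with known signs.
Passing here means the machinery is correct, not that the scientific effect
would replicate.

## Known limitations

* The EDF writer is minimal (EDF+C, 1-s records, 16-bit): sufficient for
  round trips through standard readers, not a general-purpose encoder.
* ICA-based ocular correction is not implemented; profiling discards
  contaminated epochs instead.
* No responder/non-responder classification and no sphericity correction —
  both out of scope by design.
* With entry/removal p-value selection at n ≪ p, stepwise results on small
  cohorts are unstable by nature; the package reports the full selection
  trace so that instability is visible.
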