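# Methods

`phonokit` analyzes multimodal phonation measurements of the kind
produced by excised-larynx experiments: a subglottal pressure signal and
a supraglottal acoustic signal (2 s at 96 kHz in the reference protocol),
plus a high-speed video of the vibrating vocal folds (4 kHz frame rate,
600 ms) from which the glottal area waveform (GAW) is extracted.  This
note documents the models, the estimators, the numerical choices, and
what the synthetic generator does and does not emulate.

## The measurement protocol and exclusion rules

A study cohort is a full factorial grid: larynges x posterior gap sizes
(0/1/2 mm shim plates) x asymmetric adduction torque pairs
(5:15, 5:25, 15:25 mNm) x airflow steps (phonation onset plus six 5 SLM
increments), i.e. 9 x 3 x 3 x 7 = 567 cells for the reference protocol.
Records are excluded before statistics when (a) the fundamental
frequency is undetectable in at least one of the three channels
(erratic, non-periodic oscillation), or (b) the whole configuration
series shows aberrant glottal flow resistance, indicating an air leak in
the mounting.  No numeric leakage criterion is established in the
literature for this setup, so the rule is ours: a series is flagged when
its median R_B exceeds the within-larynx median by more than `k` median
absolute deviations (default `k = 5`).  The rule operates on series, not
single records, because a mounting leak affects every airflow step of
that configuration.  `k` is configurable and the flagged series are
reported with reasons.

## Synthetic phonation generator

The generator is *kinematic*: it does not solve a self-oscillating
tissue model, it renders signals with prescribed, recoverable parameter
values.  That is exactly what validating the metric battery requires —
every quantity the analysis estimates (F0, jitter, shimmer, noise level,
gap, symmetry) is an explicit input.

Each hemilarynx contributes one area pulse per cycle:

    A_s(t) = gap/2 + a_i,s * pulse((t - E_i - d_s) / w),      s in {L, R}

* Cycle start events `E_i` accumulate periods `T_i = (1/f0)(1 + eps_i)`,
  `eps_i ~ N(0, jitter_cv)` truncated at 3 sigma (an error is raised for
  `jitter_cv >= 0.33`, where truncation would distort the realized CV).
  Optionally a random-walk drift (`f0_drift_cv`) makes the record
  erratic, for exclusion-rule fixtures.
* Per-cycle amplitudes are `a_i,s = amp_s (1 + eta_i)`,
  `eta_i ~ N(0, shimmer_cv)`, with the same relative fluctuation on both
  sides so shimmer does not masquerade as left-right asymmetry.
* The pulse is `sin(pi phi)^q` on the opening half and
  `sin(pi phi)^q_c` on the closing half (C1-continuous at the peak).
  The default closing exponent `q_c = 1` ends the pulse with non-zero
  slope — the abrupt, Rosenberg-style closure of real glottal flow —
  which gives the acoustic channel its slowly decaying (~1/f) harmonic
  comb.  A smooth symmetric `sin^2` pulse that tiles the whole period is
  a single Fourier component and would make cepstral measures blind.
* The pulse width is **fixed** at `w = open_quotient / f0` (clipped to
  the shortest period), anchored at `E_i`; period perturbation modulates
  the closed interval between pulses.  This is deliberate: if the pulse
  stretched with each cycle, any event marker at a fraction `c` of the
  cycle would observe a `(1-c, c)` moving average of the period
  sequence, and the injected jitter CV would be unrecoverable *in
  principle* (we measured ~0.7x with peak markers).  With fixed-shape
  pulses, event times carry the full period jitter and any consistent
  marker recovers it.
* The right side lags the left by `phase_offset_cycles` of the nominal
  period (phase asymmetry); unequal `amp_L`/`amp_R` give amplitude
  asymmetry.  A baseline `gap` area models the posterior pre-phonatory
  gap (incomplete closure).

The three channels derive from one realized cycle sequence:

* **GAW**: `A_L + A_R` sampled at the video rate (4 kHz), hemi-areas
  retained; the kinematic model is evaluated analytically at each rate
  rather than resampled.
* **Acoustic**: `scale * dA/dt` (flow-derivative source) at 96 kHz.
* **Subglottal pressure**: DC plus a modulated component anti-correlated
  with the opening, `alpha (mean(A) - A) - beta dA/dt`, at 96 kHz.  The
  small inertive `dA/dt` term gives the pressure channel the sharp
  closure feature real subglottal recordings show; without it the
  channel's harmonic comb is too weak for cepstral analysis to resolve.

Measurement noise has two parts: *turbulence* noise, band-limited to
50 Hz - 5 kHz (glottal jet noise concentrates at low-to-mid audio
frequencies, not at the instrumental Nyquist of 48 kHz) and scaled to a
requested level in dB relative to the harmonic RMS; and a *white sensor
floor* across the whole band (defaults 2e-4 Pa acoustic, 0.2 Pa
subglottal).  The split matters: a noise-free ultrasonic band would make
cepstral peak prominence pathologically sensitive to sub-0.2% jitter,
while a band-limited sensor floor is simply unphysical.

**Frame rendering.**  Each video frame shows a dark lens-shaped glottis
(two half-ellipses sharing a vertical midline of fixed length) on a
brighter textured background.  Rasterization is greedy-coverage: the
analytic pixel coverage of each half-lens is sorted and exactly
`round(area)` pixels are taken, so the mask pixel count matches the
requested area to one pixel per side and the mask stays connected even
for the sub-pixel-wide slivers near closure (pixel-center rasterization
drops them entirely).  Ground-truth masks are returned with the stack.

**What the generator does not emulate**: self-sustained fluid-structure
dynamics, vocal-tract or tracheal acoustics, mucosal-wave imaging
texture, camera motion or specular glare, higher-order oscillation modes
(no 2:1 F0 ratios between channels by default).  Passing tests therefore
demonstrate that the *measurement chain* is correct and calibrated on
signals with known structure — not that the chain is robust to every
artifact of real tissue recordings.

## Glottis segmentation

Threshold plus connected components, adequate for clean ex vivo imagery:
the intensity threshold is learned on the temporal-minimum composite.
The default rule is the midpoint between the composite's dark tail (1st
percentile) and background (median); classic Otsu is selectable but
collapses into the dark mode when the glottis covers a small fraction of
the frame (the well-known small-foreground failure — on our stacks it
returned a threshold inside the glottis intensity range).  Per frame,
the connected component overlapping the seed region (centroid of
below-threshold composite pixels) is kept and holes are filled.  The
left/right split uses the principal axis of the union of all masks
(dominant eigenvector of the pixel covariance, anchored at the
centroid; isotropic ties break toward the image vertical).  On-axis
pixels count half to each side, so `A_L + A_R` equals the total mask
area exactly.

## Glottal dynamic indices (30-cycle window)

Cycle boundaries sit at local area minima near the positions an
autocorrelation-based coarse F0 predicts; the analysis window is the
first 30 consecutive cycles (all cycles, with a warning, when fewer
exist).  Boundary times are refined to sub-sample precision by
cross-correlating each cycle against the ensemble-mean cycle: at 4 kHz
one sample is 2-5% of a period, and without refinement quantization
noise swamps the cycle-to-cycle variability that the periodicity indices
measure.

| index | definition | range / polarity |
|---|---|---|
| GGI | mean over cycles of (min area)/(max area) | 0 = full closure |
| CQ  | mean fraction of the cycle with area > 2% of the cycle max | 1 = completely open |
| AP  | mean over consecutive cycle pairs of min/max of peak-to-peak amplitudes | 1 = periodic |
| TP  | same on periods | 1 = periodic |
| ASI | mean per-cycle min/max of left vs right hemi amplitudes | 1 = symmetric |
| PAI | mean abs(right peak time - left peak time) / (T/2), wrapped into half a period | 0 = symmetric |

These definitions satisfy the published ranges and polarities; where the
literature leaves the exact formula open they are fixed as above and
documented here.  CQ is implemented in its open-quotient reading (the
"1 = completely open" polarity supports it); a closing-phase-duration
variant would be a different quantity and is not what the range
description implies.  All indices are ratios, hence invariant to
uniform area rescaling; peak-location ties break toward the earlier
sample.

## Acoustic and subglottal signal metrics (whole 2 s record)

Both channels run byte-identical code: zero-phase 4th-order Butterworth
band-pass 20 Hz - 20 kHz, then cycle detection, then the metric battery.
The whole record is analyzed so that at the lowest study F0 (~50 Hz) at
least 100 cycles enter.

**Cycle detection.**  Coarse F0 from the normalized autocorrelation
peak inside the configured band (default 40-400 Hz; detectability
threshold 0.3, below it the record is flagged F0-undetectable and feeds
the exclusion rule).  Marks are then placed per expected period on a
differentiated, F0-proportionate band-passed copy (0.3-12 x F0): the
closure transient carries the timing, and differentiation plus
band-limiting keeps the correlation peak sharp under in-band noise
(raw-waveform matching has a flat peak and scatters marks by several
samples at 20 dB SNR).  Two waveform-matching passes align every mark
to the ensemble-mean cycle, with parabolic interpolation of the
correlation maximum for sub-sample precision — at 96 kHz and 100 Hz,
integer marks alone would quantize jitter at ~0.1%.

**Jitter / shimmer** are the local variants: `100 * mean|T_i - T_{i+1}|
/ mean(T_i)` on periods, the same on per-cycle peak amplitudes (each
amplitude read at a fixed offset from its mark, parabolic-refined).  For
iid Gaussian period noise the expected local jitter is
`100 * cv * 2/sqrt(pi)`, the closed form the recovery tests check.

**HNR / NNE** use a cycle-ensemble decomposition: cycles are extracted
mark-to-mark at integer samples and truncated to the common minimum
length; `H` is the energy of the ensemble-mean cycle, `N` the mean
residual energy; `HNR = 10 log10(H/N)` capped at +60 dB,
`NNE = 10 log10(N/(H+N))` floored at -60 dB.  Cycles are deliberately
*not* resampled onto a fixed grid: interpolating ~960-sample cycles onto
256 points destroys a position-dependent fraction of broadband noise
energy (2/3 variance for linear interpolation, far worse for
band-limited resampling) and biases HNR by about +1.8 dB, outside the
metric's own calibration tolerance.  `resample_len` remains available
for callers who want the fixed-grid variant.

**CPP** follows the standard cepstral-peak-prominence recipe: 81.92 ms
Hann frames with 50% hop (>= 4 periods at 48 Hz), real cepstrum of the
dB power spectrum per frame, straight-line regression of cepstrum
against quefrency from 1 ms to the period of the band's lower edge, and
the prominence of the tallest cepstral value inside the expected-period
band above that line, averaged over frames.

**SPL** is `20 log10(RMS / 20 uPa)` of the raw acoustic signal; the
**glottal flow resistance** is `R_B = mean(P_sub) / mean(Q)` in Pa/SLM.

## Statistics battery

* **Grouping**: GGI uses the fixed intervals [0, 0.01] (full closure
  during vibration), (0.01, 0.4) (partial closure), [0.4, 1] (no
  contact).  Every other parameter is split into low/medium/high by
  **exact 1-D k-means**: optimal clusters of sorted scalars are
  contiguous, so dynamic programming over prefix sums finds the global
  within-cluster-SS optimum — no seeds, no restarts, reproducible by
  construction (property-tested against exhaustive search for n <= 12
  and against 100 Lloyd restarts).
* **Normality screen**: Lilliefors-corrected Kolmogorov-Smirnov (the
  correction applies because mean and variance are estimated from the
  sample); constant samples are flagged degenerate.
* **Group comparison**: Kruskal-Wallis at alpha = 0.05; when
  significant, all three pairwise two-sided Mann-Whitney U tests at the
  Bonferroni level 0.05/3 (reported rounded to 0.017).  The U test uses
  the exact distribution for tie-free samples up to n = 20 per group and
  the tie-corrected normal approximation otherwise.
* **Channel correlation**: Pearson r per larynx, then the unweighted
  mean, SD, min and max across larynges (a Fisher-z averaging flag
  exists; plain averaging is the default).  Zero-variance larynges are
  skipped with a warning.
* **Simple regression**: OLS of the acoustic parameter on its
  subglottal counterpart, with R^2, coefficient standard errors, and the
  F test.
* **Stepwise multiple regression**: forward entry (partial-F p < 0.05)
  and backward elimination (p > 0.10), ties broken by larger
  adjusted-R^2 gain then name; the larynx identifier enters and leaves
  as one indicator block, counting as a single candidate; perfectly
  collinear candidates are skipped with a warning.  Each step records
  the adjusted R^2, its increment, the partial F with degrees of
  freedom, and p.  The final model is refit with all selected variables
  entered simultaneously, and the tests assert the significance pattern
  is unchanged — the standard robustness check against stepwise
  inflation of type-I error.  Diagnostics report the max pairwise
  predictor |r| against a 0.65 advisory threshold, Lilliefors residual
  normality, Breusch-Pagan homoscedasticity, the Durbin-Watson
  statistic, and optional residual plots.
* Missing metric values are dropped pairwise per analysis.

## Study-cohort preset (end-to-end validation)

`phonokit.cohort.run_cohort` maps the protocol grid onto generator
settings, optionally renders and re-segments the video for every record,
and returns the flat measurement table.  The mapping encodes the
physical hypotheses the protocol manipulates:

* the posterior gap sets the baseline open area (GGI) **and** the
  turbulence level (-38 dB + 12 dB/mm): incomplete closure produces
  broadband jet noise — precisely the mechanism linking closure to
  signal quality;
* cycle-to-cycle period variability (jitter, hence TP) is drawn
  log-uniformly per configuration cell, independent of the larynx and
  of the gap;
* left-right amplitude ratio and phase lag vary per cell independently
  of the noise level, so symmetry has no constructed pathway to signal
  quality;
* the closed-phase fraction (open quotient 0.7-0.95) varies per cell
  independently of the gap, so CQ is not a duplicate closure indicator;
* F0 rises with total adduction torque (elongation), subglottal
  pressure and oscillation amplitude rise with airflow.

On this cohort the full pipeline (simulate -> segment -> analyze ->
stepwise) selects TP and GGI before any symmetry index and yields a
strongly positive mean per-larynx correlation between the subglottal
and acoustic cepstral peak prominence; the behaviour is stable across
generator seeds.

## Problem sizes and numerical choices

Validation runs use sizes chosen to keep statistical error well below
the tolerances being checked: 500-cycle records for perturbation
recovery (relative SE of local jitter ~3%), 200-frame stacks for
segmentation, 1000 replicates for the type-I calibration, and a
9-larynx x 9-configuration x 2-flow-step cohort (162 records, 2 s
signals, 400-frame video at 128 px) for the end-to-end study.  Caps of
+60 dB (HNR) and -60 dB (NNE) keep noiseless fixtures finite.  All
randomness flows from explicit integer seeds; identical seeds give
bit-identical channels.

## Known limitations

* The segmentation pipeline targets clean, high-contrast ex vivo
  imagery; in vivo endoscopy artifacts (motion, glare, occlusion) are
  out of scope.
* The generator's channel coupling is phenomenological; it reproduces
  parameter values and their statistical relations, not tissue
  mechanics, so effect sizes in the synthetic cohort are design choices,
  not predictions.
* CPP values depend on frame length, spectral floor and band choices;
  comparisons are meaningful within one configuration of the analysis,
  not across tools.
* Jitter/shimmer are the local variants only; PPQ/APQ-style smoothed
  variants are not implemented.
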