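# Methods

`sleepvol` quantifies the volatility of neural dynamics around sleep-stage
transitions from multimodal polysomnography (two EEG channels, horizontal
EOG, submental EMG at 100 Hz with 30-s R&K hypnograms), and asks how that
volatility differs between age groups and between a sedative (drug) night
and a placebo night.  Because the package must be verifiable without
external recordings, it ships a synthetic cohort generator whose
statistical structure is known exactly; every downstream stage is then
validated by parameter- and direction-recovery against that ground truth.
This note documents the models, the defaults and why, and what the
synthetic validation does and does not establish.

## Synthetic polysomnography

**Hypnograms.** Stage sequences follow a first-order Markov chain over
{W, S1, S2, S3, S4, R} at 30-s epoch resolution.  A Markov chain is the
simplest generative structure that produces realistic bout-length
distributions (geometric within stage) and controllable stage proportions.
The base transition matrix favors long consolidated bouts (self-transition
probabilities 0.79–0.93).  Age modulation multiplies transitions into W
(older groups wake more: factors 1.0/1.6/2.4) and scales transitions into
S3/S4 down (1.0/0.75/0.5); the drug night multiplies the probability of
leaving S2 or S3 by 0.7.  Rows are renormalized after modulation.
Movement epochs ("M") overlay the chain with probability 0.002 per epoch;
they split stage bouts and are excluded from all downstream windows,
mirroring how marker epochs are treated in telemetry recordings without
modeling telemetry errors.

**Signals.** Each EEG channel is a sum of band-limited Gaussian-noise
oscillators (delta 0.5–4, theta 4–8, alpha 8–13, beta 14–30, gamma 30–45,
SWA 0.5–2, spindle 12–16 Hz) whose per-epoch amplitudes are the product of
a base amplitude (µV RMS), a stage gain table (delta/SWA largest in S3/S4,
spindles in S2, alpha in wake, theta in S1/REM), an age-group gain
(delta/SWA/spindle decline 1.0/0.8/0.6 with age), and a common volatility
multiplier (below) — plus a 1/f background, a 0.25 Hz cardiorespiratory
sinusoid (the high-pass filter's target), and 1 µV white sensor noise.
The gamma synthesis band is capped at 45 Hz because Nyquist at 100 Hz
sampling is 50 Hz.  Band carriers are carved from a single white Fourier
spectrum per channel; disjoint bands are therefore mutually independent.
EMG is 20–49 Hz noise whose tone falls with sleep depth (10 µV in W down
to 3 µV in S4, 1.5 µV in REM, 25 µV in movement epochs); EOG is slow
0.3–3 Hz activity largest during REM (rapid eye movements).

**Volatility injection.** Per channel, a GARCH(1,1) observation series
`y_t = mu + sigma_t z_t` with `sigma2_t = alpha0 + alpha1 eps2_{t-1} +
beta1 sigma2_{t-1}` is simulated over epochs with mean level `mu = 1`
(clipped below at 0.05), and the epoch's whole neural waveform
(oscillators plus 1/f background; sensor noise and the cardiac sinusoid
are amplitude-stable) is multiplied by it.  Using the *observation* series
rather than the latent `sigma_t` path makes the epoch-RMS series itself a
GARCH(1,1) realization, so fitting the model to measured epoch amplitudes
is a well-posed recovery problem (verified to ±0.1 on alpha1/beta1 at
5000 epochs).  Placebo truth is `alpha0=0.02, alpha1=0.25, beta1=0.65`
(persistence 0.9, unconditional sd ≈ 0.45); the drug night halves
`alpha1`, i.e. reduced amplitude volatility is *built in* and downstream
recovery of that direction is a pipeline test, not a discovery.

**Planted directed coupling.** During S3 epochs the occipital channel
(Pz-Oz) receives 1.5× the frontal (Fpz-Cz) delta component delayed by
0.25 s.  This plants a frontal-to-occipital information flow in the delta
band during deep sleep that transfer entropy should (and does) detect as
an asymmetry between directions.

**Randomness.** All randomness flows from one root seed through
`numpy.random.SeedSequence` splits per subject, night, and channel;
identical spec and seed reproduce a cohort bit-for-bit.

## Signal conditioning

Filters are equiripple (Parks–McClellan) linear-phase FIRs with default
1 dB passband ripple, 40 dB stopband attenuation, and transition widths of
0.5 Hz or 10% of the band edge, whichever is larger (a lower edge under
0.5 Hz narrows its transition to `[low/2, low]`; where remez will not
converge at such narrow relative transitions a Kaiser-window design is
substituted, checked against the same measured-response spec).  Filters
are applied with exact zero phase: the symmetric FIR is convolved once via
FFT on a reflection-padded signal and the group delay compensated by
alignment.  A forward–backward pass would square the magnitude response
and double the passband ripple, so the single compensated pass is used
instead; the no-phase-shift property is asserted in tests.  Welch PSDs use
11-s Hamming windows with 50% overlap; the actual frequency resolution is
the grid spacing 1/11 ≈ 0.091 Hz and is reported as such.  Band powers
are trapezoidal integrals with interpolated band edges, so adjacent bands
add exactly.  EMG conditioning band-passes 20–49 Hz (the conventional
upper edge of 50 Hz collides with Nyquist), rectifies, smooths at 7.5 Hz;
EOG band-passes 0.1–15 Hz, rectifies, smooths at 5 Hz.  Envelope smoothers
are normalized to unit DC gain and scaled by π/2 so a pure sinusoid's
envelope equals its amplitude.  Ocular artifacts are removed by spatial
FastICA on the 1–45 Hz band-passed observation matrix (EEG channels plus
the EOG reference): components whose absolute correlation with the
filtered EOG exceeds 0.7 (configurable) are subtracted — an automated
criterion standing in for visual component inspection.  Non-convergent
ICA returns the input unchanged with a flagged status.  With only two
referential EEG channels a reference-standardization step cannot be
meaningfully implemented; it is a documented pass-through.  A 60 Hz notch
is omitted (above Nyquist) but remains a config option for
higher-rate inputs.

## Tensor and stage-transition windows

Preprocessed cohorts are organized as a 5-axis tensor (subject × modality
× band × frequency bin × time); with defaults that is 22 × 3 × 7 × 100 ×
T, where an 8-h night at 100 Hz gives T = 2,880,000 samples.  Seven bands
form the default band axis; sigma (12–15 Hz) is computed as a feature band
but left off the axis because it is almost entirely contained in the
spindle band.  The content of the frequency-bin axis is not canonically
defined for band-limited signals; the package's documented stand-in is
the short-time Fourier magnitude (Welch window settings) at 100 uniform
sub-band center frequencies, interpolated onto the sample grid.  A fully
materialized default tensor is ~530 TB, so `build_tensor` materializes
values only for small configurations and otherwise returns axis metadata;
the pipeline processes full nights band-wise instead.  A flattened
time × modality × (band·bin) view is available per subject.

Stage-transition features are computed on the last 30-s epoch of each
stage bout (a maximal run of identical labels, split by movement epochs) —
the minimum stage duration the scoring resolution supports.

## Wavelet features

The Morlet mother wavelet `pi^(-1/4) exp(i w0 t) exp(-t^2/2)` with
`w0 = 6` (the standard admissibility-respecting choice) is evaluated by
FFT convolution with `a^(-1/2)` normalization; a scale `a` seconds maps to
frequency `w0/(2 pi a)` Hz.  Scales for a band are log-spaced so their
analysis frequencies span the band (default 16 scales for window features,
10 for per-epoch series).  From each window's scalogram three features are
computed with per-coefficient importance weights `b_i ∈ [0,1]` (all ones
by default, binary rows of the selection matrix when feature selection has
run): energy `Σ|W|² b`, mean `(1/N) Σ W b` (magnitudes reported, complex
mean exposed), and entropy `-Σ p log(p b)` with `p = |W|²/Σ|W|²`.  Terms
with `b_i = 0` or `p_i = 0` are excluded from entropy sums — the logarithm
is undefined there, and an epsilon floor was rejected as
tolerance-dependent.  Shannon entropies of each feature's distribution
across windows (SEEN/SEM/SEE) use 10 quantile bins and natural logs;
inputs with fewer than two distinct values are degenerate and return 0.

## Feature selection

Between-stage discrimination uses plug-in mutual information on
quantile-binned features (invariant to monotone transforms),
random-forest impurity importances (normalized to sum to 1), and
linear-SVM |weight| rankings on z-scored features (zero-variance columns
get weight 0; ties break to the lower column index).  Recursive feature
elimination drops the lowest-|w| feature per iteration, recording a
cross-validated accuracy trace, until `n_keep` remain (default 20 — the
"desired number of features" is a free choice).  One binary selection row
is produced per unordered stage pair (a one-vs-rest mode is available);
a stage's `b_i` weights are the union of its pairs' rows.

## GARCH volatility

GARCH(1,1) is fitted by Gaussian quasi-maximum likelihood under
`alpha0 > 0`, `alpha1, beta1 >= 0`, `alpha1 + beta1 <= 1 - 1e-6`, with
`sigma2_1` initialized at the sample variance and the mean level estimated
jointly.  The variance recursion is evaluated as a linear IIR filter, and
SLSQP runs from five documented `(alpha1, beta1)` starts; the series is
internally rescaled by its standard deviation for conditioning and mapped
back exactly, so conditional variances keep the input's scale (demeaned
but never variance-standardized).  Maximum likelihood wins across starts,
except when the maximum sits in the no-ARCH regime (`alpha1 < 0.01`):
there `beta1` is unidentified — the `(alpha0, beta1)` ridge is flat and
spurious near-integrated solutions can beat the flat one by a
statistically meaningless margin — so among candidates within the 5%
chi-square(1) likelihood-ratio bound the least persistent is chosen.
This keeps i.i.d. inputs from reporting artefactual persistence while
leaving identified fits exactly at the MLE (the fitted likelihood is never
below the truth's on simulated data).

**Input series.** The per-recording GARCH input is the per-30-s-epoch
*log wavelet energy* of the delta band on Fpz-Cz, centered within stage.
Two considerations force this default.  First, wavelet entropy — the
feature one might prefer for its information richness — is invariant to
the overall scalogram scale by construction, so a multiplicative
epoch-amplitude volatility process is mathematically invisible to it
(empirically R² ≈ 0.01 against epoch amplitude); energy is the feature
that carries amplitude volatility, and the log makes the multiplicative
process additive while taming energy's heavy tails.  Second, without
stage-centering the series variance is dominated by deterministic
stage-level differences, i.e. by sleep architecture rather than neural
volatility.  Entropy, mean, and raw energy remain selectable for users
who want them.  Per-epoch sampling (rather than only bout-end windows) is
used because GARCH fitting needs at least 50 observations and short
recordings have far fewer bouts.

**Mean conditional volatility (MCV)** averages fitted conditional
variances over time per recording and then over recordings per cell
(age group × condition, optionally × stage; equal-length inputs make this
the grand mean of the stacked values).  Movement epochs are excluded.

## Causality

Transfer entropy `T_{X→Y}` is estimated by plug-in histogram: both series
quantile-discretized (default 4 bins), the conditional mutual information
`I(y_{t+1}; x_t | y_t)` computed from lag-1 triplet counts as an entropy
combination.  The plug-in estimate is non-negative; tiny negative rounding
(or Miller–Madow-corrected values — the correction is available but off by
default) is clipped to 0 and flagged.  Constant series return 0.  The
causality index of a (band, stage, age-group) cell is the mean of
per-window transfer entropies over that cell's stage-bout windows, with
the across-window standard deviation as its variability; the per-window
series are band-limited Hilbert amplitude envelopes resampled to 4 Hz
(120 points per 30-s window).  The default direction is frontal to
occipital (Fpz-Cz → Pz-Oz) with the reverse always computed.  Plug-in TE
carries a positive small-sample bias (~(cells−1)/2N nats); it affects both
directions equally, so direction *contrasts* are meaningful where absolute
values are inflated — which is why the pipeline always reports both
directions rather than a single number.

## Statistics

Multiway ANOVA uses type-II sums of squares (robust to the unbalanced
designs small cohorts produce) with optional two-way interactions and
Bonferroni correction over the tested family; a zero-variance response
yields F = 0, p = 1 for every effect.  Tukey HSD wraps the studentized
range test (family-wise control is built in, so corrected = raw);
t-tests are pooled-variance; chi-square tests are Pearson without
continuity correction.  MANOVA reports Pillai's trace (the robust default
among the four classical statistics) with Bonferroni over effects; a
single response reduces exactly to the ANOVA F, and an exactly null
between-group effect returns F = 0, p = 1.  Type-I error of every test is
calibrated on pure-null data in the acceptance suite (empirical rate in
[0.02, 0.09] at α = 0.05 over 200 replicates).

## Problem sizes used in tests

The test and acceptance suites run the full pipeline at desk scale: unit
fixtures use 2-subject, 30-minute cohorts; the integration pipeline runs
4 subjects × 1 h; direction-recovery acceptance uses twenty 8-subject,
2-h cohorts; GARCH recovery uses n = 10,000 observations × 50 seeds; the
tensor-arithmetic check generates one full 8-h subject.  These sizes were
chosen so the whole suite completes in minutes while every stochastic
criterion retains a comfortable margin (piloted at 8/8 successes before
freezing).

## What synthetic validation shows — and does not

Passing tests establish that the pipeline recovers *known* structure:
injected GARCH parameters, the built-in drug-volatility reduction, the
planted coupling direction, and the stage-dependent spectral contracts.
They do not establish that real sleep EEG satisfies the generator's
assumptions — band-limited Gaussian oscillators (no waveform morphology,
no discrete spindle/K-complex events), stagewise-constant amplitude with
a single shared volatility process per channel, Markovian stage dynamics,
and linear lagged coupling.  Results on real Sleep-EDF-style recordings
(readable through the EDF interface) therefore inherit only the
*correctness* of the computations, not the *effect sizes* seen here.

## Known limitations

- GARCH innovations are Gaussian quasi-likelihood only; Student-t
  innovations, higher-order GARCH(p,q) and multivariate GARCH are out of
  scope.
- The transfer-entropy estimator is histogram plug-in; k-NN (KSG)
  estimators, conditional TE and spectral Granger causality are not
  implemented.
- Spindle activity is continuous band noise, not discrete bursts; EOG
  saccades are slow-band noise, not ballistic waveforms.
- The EDF writer emits plain EDF with a sidecar CSV hypnogram rather than
  EDF+ embedded annotations; the reader accepts either a written pair or
  a compatible external EDF plus CSV.
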