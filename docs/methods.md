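# Methods

This note documents the models and procedures the package implements, the
parameter defaults and why they were chosen, what the synthetic generator
does and does not emulate, and the numerical choices a maintainer would
want to know about.

## Signal model and preprocessing

All streams live on one session clock (seconds from session start) with a
30-s epoch grid of half-open windows [k·30, (k+1)·30), 0-based.
Synchronization between streams is expressed as explicit per-stream second
offsets in the session manifest; hardware-specific event-beep detection is
out of scope.

The 1 Hz vitals are rebuilt onto a complete grid; gaps up to `max_gap_s`
(default 30 s) are linearly interpolated and flagged, longer gaps are left
as NaN and masked invalid — interpolation never fabricates long stretches
of data. Beat screening flags JJ intervals outside [300, 2000] ms (spanning
30–200 BPM) and beats differing from the previous valid beat by more than
30%, a standard ectopy/motion screen; masked beats are **removed**, not
interpolated, because fabricated intervals distort variability metrics.
Exponential smoothing y(t) = (1−k)·y(t−1) + k·x(t) with k ∈ (0, 1] is used
on the stroke-volume series before computing respiration depth; k defaults
to 0.1 (a ~10-sample time constant at 1 Hz, long relative to a breath) and
is configurable because no canonical value exists for this device class.

HRV features are computed over a causal 5-min window ending at each
epoch's end, stepped by 30 s, so every epoch gets exactly one feature row.
The first 9 windows of a session are left-truncated and flagged partial
rather than dropped, keeping the row-per-epoch alignment the sequence
model requires.

## HRV features

Time domain: mean JJ, SDNN (sample SD), RMSSD, pNN50, CV. Frequency
domain: the irregular beat series is cubic-spline resampled to 4 Hz,
detrended, and a Welch spectrum taken with 120-s Hanning segments at 50%
overlap; LF = 0.04–0.15 Hz and HF = 0.15–0.40 Hz per the short-term HRV
standards. The estimator and band edges are recorded in the feature
dictionary; both are configurable.

Poincaré geometry scatters (JJᵢ, JJᵢ₊₁): SD1 = σ(JJᵢ₊₁−JJᵢ)/√2 and
SD2 = σ(JJᵢ₊₁+JJᵢ)/√2. Asymmetry about the line of identity (LOI, y = x)
uses the standard literature forms: Porta = % of off-LOI points below the
LOI; Guzik = % of total perpendicular LOI distance carried by points
above; Ehlers = Σd³/(Σd²)^{3/2} on successive differences d; phase = mean
angular deviation (degrees) from 45° over above-LOI points; area = % of
summed circular-sector areas (½r²|Δθ|) contributed by above-LOI points.
Points exactly on the LOI are excluded from all ratio denominators, which
sidesteps the zero-distance ambiguity; a series entirely on the LOI is
flagged undefined, never silently zero.

Sequential trend analysis operates on successive-difference pairs
(ΔJJₙ, ΔJJₙ₊₁): quadrant assignment by sign, per-quadrant mean radial
distance √(ΔJJₙ² + ΔJJₙ₊₁²), and occupancy fractions among off-axis pairs.
The feature matrix carries the four quadrant distances plus the Q1/Q4
occupancies (the remaining occupancies are determined up to one degree of
freedom; six STA columns keep the matrix at its fixed width).

Rényi entropy embeds the beat series in m = 2 dimensional delay vectors,
builds a Gaussian-kernel density ρᵢ ∝ Σⱼ exp(−‖xᵢ−xⱼ‖²/2σ²) over **all**
embedded subsequences, normalizes Σρᵢ = 1, and reports
H_α = log₂(Σρᵢ^α)/(1−α) in bits for α ∈ {0.25, 2, 5} (α = 1 is available
and routed to the Shannon limit). σ defaults to the SD of the pairwise
embedded distances; a constant series degenerates to the uniform density,
giving H_α = log₂ n for every order. SampEn/ApEn use m = 2, r = 0.2·SD,
Chebyshev distance; SampEn excludes self-matches and reports +inf
(flagged) when no template matches. DFA integrates the centered series,
removes a least-squares line per non-overlapping box, and fits the
log–log fluctuation slope over 4–16 (α₁) and 16–64 (α₂) beats.

Device-style HRV: R-depth is the mean absolute stroke-volume residual
after exponential smoothing, optionally normalized by mean |SV|, and is
multiplied by the HF/LF band-power ratio. The HF/LF orientation is the
device convention implemented here; a `conventional_ratio` switch exposes
LF/HF.

## Cardiopulmonary coupling

Both the JJ tachogram and the respiration-rate series (mean-removed — a
spectral estimator needs a fluctuation signal, not a rate level) are
cubic-spline resampled to 2 Hz. Each 1024-sample (512-s) window splits
into three 512-sample sub-windows at offsets 0/256/512; each is linearly
detrended, Hanning-windowed and Fourier transformed, and the auto- and
cross-spectra averaged across sub-windows before forming
C_xy = |P_xy|²/(P_xx·P_yy). Sub-window averaging is essential: a
single-segment magnitude-squared coherence is identically 1. The
per-frequency CPC index |P_xy|²·C_xy is integrated over LF = 0.01–0.10 Hz
and HF = 0.10–0.40 Hz, the bands used in the CPC literature. Windows are
right-aligned to each epoch's end, mirroring the causal HRV convention;
truncated early windows are flagged partial, and windows shorter than one
sub-window give NaN features. With three half-overlapped segments the
coherence of independent signals has a known positive small-sample bias
(~0.3–0.4 on average); CPC features are therefore informative as
contrasts, not absolute zeros.

Near-constant segments (fluctuation power at numerical-residue level) are
reported with coherence 0 rather than the residue ratio.

## Audio features

A 2048-sample Hanning spectrogram at 50% overlap (frame rate
F_r = sample_rate/1024 ≈ 43.07 frames/s at 44.1 kHz) supports three
families: (i) the spectral-centroid instantaneous frequency summarized as
mean/SD/median/IQR; (ii) respiration cycle features from the
autocorrelation of the breathing envelope; (iii) intensity statistics —
energies in 0–100/100–300/300–800/800–2000/2000–8000 Hz bands (truncated
at Nyquist) plus dBFS sound-pressure statistics over 100-ms RMS frames,
floored at −120 dB since no microphone calibration constant exists.

Breath periods of 3–8 s cannot be read off raw 44.1 kHz samples; the
envelope — rectified audio, low-passed at 2 Hz, sampled at the frame rate
— carries them. Peaks of the normalized autocorrelation within physiologic
lags (1.5–15 s, i.e. 4–40 breaths/min) qualify if their prominence is
≥ 0.1 **and** their amplitude is ≥ 0.25: 30-s envelopes have ~1/√N
fluctuations of ≈ 0.07, and prominence alone (being peak-to-valley) fires
on unstructured noise, while the height floor holds the false-detection
rate on noise below a few percent and clears real breathing peaks
(amplitude ≈ 0.8) by a wide margin. The first qualifying lag t₁ gives the
cycle period t₁/F_r seconds (a raw frame-count product is available behind
a flag), its amplitude the cycle intensity, and the SD of all peak
amplitudes the cycle consistency. Audio features use the epoch's own 30 s,
not the 5-min window.

An optional spectral-subtraction noise gate replaces interactive audio
denoising: the noise profile's mean STFT magnitude per bin is subtracted
from the recording's magnitudes (floored at 5% of the original), phase
kept, signal resynthesized at input length.

## Feature assembly

The 62-column enumeration (43 BCG + 19 audio) is fixed in a versioned
feature dictionary exported beside every matrix, making the
dimensionality reproducible by construction. Missing cells (too few valid
beats, absent audio) are represented in an explicit validity mask and
imputed only at model-input time (carry-forward with column-median
fallback by default); normalization is z-scoring with statistics fit on
training-fold subjects only, applied unchanged to held-out data, with
zero-variance columns left unscaled under a warning.

## Staging model

Sequence-to-sequence over whole sessions (one feature vector per epoch):
biLSTM(125) → dropout(0.2) → biLSTM(100) → dropout(0.2) → four residual
blocks → fully-connected(5) → softmax. Each block holds two causal dilated
1-D convolutions (64 filters, kernel 5, dilation 2^(block−1)), each
followed by per-channel layer normalization (offset + scale, 2×64
parameters), ReLU and spatial dropout (0.005); block 1 lifts its skip path
with a 1×1 convolution because 200 input channels meet 64 output channels.
Four blocks and this normalization are the unique small configuration
whose closed-form parameter sums reproduce all three published counts
simultaneously (169,093 TCN-only / 469,805 LSTM-only / 690,885 combined
at 62 input features); the derivation is committed as a test. The
receptive-field formula R = (f−1)(2^K−1)+1 is reported with K counting
stacked convolutional layers under per-layer dilation doubling (f = 5,
K = 8 gives R = 1021 epochs); the per-block dilation schedule actually
built yields a smaller field, and reporting states which convention is
used.

The layers are implemented directly on numpy with analytic backward
passes, each gradient-checked against central finite differences in the
test suite. Training: Adam (lr 1e-3), whole sequences as batches, sleep
cycles kept intact (never shuffled or concatenated across sessions),
class-weighted cross-entropy with inverse-frequency weights renormalized
over present classes, optional early stopping, a maximum of 40 passes by
default, and one integer seed controlling initialization, dropout and
sequence order — the same seed reproduces the loss log bitwise. Inference
runs with dropout inactive and is deterministic. Bidirectionality is
retained as published even though it breaks online causality; the
TCN-only variant is strictly causal (asserted by perturbation tests).

## Evaluation

One LOSO fold per subject; all sessions of a subject travel together, and
the train/held-out intersection is asserted empty at runtime. Metrics:
accuracy (confusion-matrix trace over total), Cohen's
κ = (p_o − p_e)/(1 − p_e) with p_e from marginal products (defined as 1
when both raters are constant and identical), and one-vs-rest per-stage
sensitivity/specificity/precision/F1. Stages absent from a fold give NaN
metrics excluded from averaging rather than zero-filled, which would bias
small folds. Folds aggregate as mean ± sample (n−1) SD — folds are a
sample of subjects — with the fold-mean accuracy as the headline and
pooled-over-epochs figures also reported. The 3-class relabeling maps
{N1, N2, N3} → NREM and keeps W and REM. Per-stage significance columns
from the source system are not reproduced (the underlying test is
unspecified); κ against the permuted-label control serves as the
chance-level reference instead.

## Synthetic generator

The generator emulates the *structure* the pipeline exploits, not
physiology. A first-order Markov chain at 30-s pitch (starting in W)
produces the hypnogram; the default transition matrix makes N2 the most
frequent stage (stationary weight ≈ 0.45) with wake bouts flanking the
session. Per stage, beats follow
JJₙ = 60000/HR + A_LF·sin(2π·0.09·tₙ+φ₁) + g·A_HF·sin(2π·f_resp·tₙ+φ₂) + ε:
the 0.09 Hz component sits unambiguously inside the LF analysis band, the
respiratory component at the stage's breathing frequency is scaled by the
coupling gain g, and the same oscillation (same phase) modulates the 1 Hz
respiration-rate series and the stroke-volume amplitude — this shared
component is what makes CPC informative and recoverable. Default stage
parameters are well separated and physiologically plausible: W fast and
erratic (HR 70, jitter 25 ms), N3 slow with strong vagal coupling (HR 55,
g 1.5), REM fast with LF dominance (HR 66, A_LF 40 ms). Vitals samples
are dropped at a configurable rate (default 1%) to exercise gap handling.
Audio (8 kHz by default; all feature bands live below 4 kHz) superimposes
raised-cosine breath envelopes over 300–1800 Hz band-limited noise, with
optional 60–300 Hz snore bursts and a stationary noise floor. Cohorts add
correlated per-subject shifts of heart rate, respiratory rate, oscillation
amplitudes and snore propensity; everything is a pure function of
(config, seed).

What passing tests therefore show: the implementation recovers structure
it can reach through the published feature set when that structure is
present and stages are separable. What they do not show: performance on
real BCG data with movement artifacts, posture changes, apnea events,
inter-night variability or subtle N2/N3 differences — none of which the
generator models.

## Problem sizes and numerical choices

The acceptance run and the closed-loop tests use a 6-subject cohort of
one-hour sessions (120 epochs each) and a narrowed training configuration
(biLSTM 32/16 units, two blocks of 16 filters, kernel 3, 25 passes) —
sizes chosen so the full pipeline runs comfortably on one CPU while
leaving the learning problem non-trivial; the full published widths are
instantiated for the parameter-count checks, which are independent of
training. On this cohort the pipeline reaches ≈ 84% 3-class LOSO accuracy
(κ ≈ 0.6) while the permuted-label control sits at chance (κ ≈ 0).

Other numerical conventions: spectra integrate by the trapezoid rule over
band masks; the coherence is clipped to [0, 1] against rounding; SampEn
returns +inf (flagged) with no matches; DFA uses ~10 geometrically spaced
box sizes per range and needs ≥ 3 valid sizes for a slope; 16-bit WAV
round-trips are exact to one quantization step; all epoch windows are
half-open so windows compose without overlap ambiguity.

## Known limitations

- The 62-feature enumeration is a fixed, documented reconstruction; other
  enumerations with the same total are possible.
- The breathing-envelope detector assumes one dominant breath period per
  30-s segment; irregular breathing yields `detected=false` rather than a
  period estimate.
- The numpy training loop is single-threaded and intended for
  research-scale cohorts, not large clinical datasets.
- CPC features inherit the three-segment coherence bias; compare them
  across conditions, not against zero.
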