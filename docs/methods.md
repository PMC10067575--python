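# Methods

`ecogkit` analyzes continuous two-channel rodent electrocorticography
(ECoG) with a concurrent EMG channel, recorded around an acute drug
administration.  This note documents the models and procedures, the
parameters that matter, the synthetic-data model used for validation,
and the numerical choices made where the design was open.

## Session model and analysis blocks

A session is a 4-h recording with drug administration at the 2-h mark.
The first 30 min of the recording and the first 30 min after the drug
are treated as acclimation and discarded, leaving two 1.5-h analysis
blocks: pre = [1800 s, drug time) and post = [drug + 1800 s, drug +
1800 s + 5400 s).  A recording too short for the post block is an error,
never a silent clip.  `acclimation_s` and `block_len_s` are parameters
so that scaled-down studies (below) use the same code path.

The acquisition sampling rate is not a protocol constant; the package
default is 1000 Hz, chosen because the canonical band edges fall on the
0.9766 Hz bin grid of 1024-point transforms at that rate (512-point
transforms give the same grid at 500 Hz, which the scaled studies use).

## Epoching and spectral estimation

Each block is divided into 5-s epochs advanced by 2.5 s.  Per-epoch
power spectral densities use Welch's method: Hann window, 50% segment
overlap, default segment length `round(1.024 * fs)` samples, one-sided
density normalized so its integral equals the epoch mean square (no
detrending).  Block-level spectra are arithmetic means of the selected
epochs' densities.

Band powers integrate the density over the five canonical bands (delta
0.9–3.9, theta 4.8–7.8, alpha 8.7–11.7, beta 12.6–29.2, gamma
30.2–99.6 Hz).  A bin belongs to a band iff its center lies within the
inclusive edges; the narrow gaps between bands belong to no band and
are excluded from "total power", which is defined as the sum over the
five bands.  Relative powers are percentages of that total and always
sum to 100.  A configurable check warns when a custom segment length
puts band edges off the bin grid by more than 20% of a bin.

Interhemispheric coupling is magnitude-squared coherence (MSC),

    C(f) = |<P_LR>|^2 / (<P_LL> <P_RR>),

with cross- and auto-spectra pooled over every Welch segment of every
selected epoch before the ratio is formed.  Averaging per-epoch
coherences instead would be badly biased (a single-segment coherence is
identically 1), so the estimator refuses to run on one total segment
unless forced.  Whether the underlying coherence coefficient is
magnitude or magnitude-squared is genuinely ambiguous in this
literature; MSC is the default and `kind="magnitude"` selects the
square root.  The MSC estimator has a positive bias of roughly 1/K on
independent inputs (K = number of averaged segments); with 50%
overlapping segments and 50% overlapping epochs the effective K is
about half the nominal count, so independence tests allow twice the
nominal bias.

## EMG envelope and epoch selection

The EMG is enveloped with the Teager-Kaiser Energy Operator,
psi[n] = x[n]^2 − x[n−1]x[n+1], rectified (absolute value; TKEO goes
negative on noise) and smoothed with a zero-phase 4th-order Butterworth
low-pass at 3 Hz.  TKEO endpoints replicate the nearest interior value
so the envelope aligns sample-for-sample with the EMG.  Even-reflection
padding is used in the zero-phase pass: odd reflection undershoots zero
at the edges of a strictly positive trace.  Residual negative ringing
is floored at zero.

An epoch is accepted iff all three hold strictly:

  i)   its delta power is below the block median delta power;
  ii)  its theta/delta ratio is below the block's 75th percentile
       (type-7 linear-interpolation quantile);
  iii) the EMG envelope stays below twice the block harmonic mean of
       the envelope at every sample of the epoch.

Thresholds are computed over all epochs of the block.  By construction
condition i accepts strictly fewer than half the epochs.  A block is
usable when at least 100 epochs survive (`qc_min_epochs`, lowered
explicitly in scaled studies where a block holds only ~47 epochs).
Manual inspection of selected epochs is replaced by an optional
exclusion list of epoch indices.

The harmonic mean is extremely sensitive to near-zero samples: a single
zero-clipped ringing sample next to a movement burst would collapse it
(and hence the limit) by orders of magnitude.  Envelope samples are
therefore floored at max(1e−12, 1% of the block median envelope) before
the harmonic mean.  The relative part leaves the limit essentially
unchanged on real-looking envelopes (≲15% even with hundreds of floored
samples) while keeping the statistic meaningful; the absolute part
keeps it defined on identically zero envelopes.

Selection is invariant to a common positive gain on the ECoG (median
and quantile thresholds scale with the features) and on the EMG (TKEO
is exactly quadratic, so envelope and harmonic mean scale together).

## Spike detection

Interictal spikes are detected on the 0.5–60 Hz band-passed ECoG of a
whole block (4th-order Butterworth, zero-phase).  The threshold is
`multiplier × SD` of the filtered block, multiplier in [4, 5] with
default 4.5; the SD deliberately includes the events themselves (no
robust variant by default; a median-absolute-deviation alternative is a
one-line configuration).  Detection runs on |x| by default because the
transients are biphasic; single-polarity detection is available.

An event opens at the first supra-threshold sample; its window spans
[crossing − 50 ms, crossing − 50 ms + 250 ms].  All crossings inside an
open window belong to that event, and a new event may open only after
the window closes, so windows never overlap and a biphasic transient
counts once.  Events carry the trigger time, the time and signed value
of the window extremum, and the supra-threshold duration (≤ 250 ms).
Manual artifact rejection is replaced by an optional exclusion list of
event times.  Both ECoG channels are detected independently and
reported; per-subject statistics use one configurable channel (left by
default).

On synthetic spike-ins at 8× background SD the detector's sensitivity
is ≥ 95% with peak localization within a few ms.  False events are
dominated by rare slow excursions of the 1/f^2 background crossing
4.5 SD; across seeds this contributes roughly 0.03–0.08 false events
per injected event at 1 event/min (about 1 false event per 10 min of
background), dropping an order of magnitude at a 5.0 multiplier.

## Drug-effect metrics and cohort statistics

Each subject contributes one pre and one post value per metric (the
epoch-averaged block values).  The effect on a metric is the change
ratio post/pre; a nonpositive pre value makes that ratio undefined
without affecting the others, and a zero pre-drug spike rate excludes
the subject from ratio analyses.  Derived band ratios are
theta/beta and theta/(beta+gamma) on relative powers.

Responder categories bin the spike-rate ratio: >50% reduction
(ratio < 0.5), 20–50% (0.5–0.8), 10–20% (0.8–0.9), no change/small
(0.9–1.1 inclusive), increase (> 1.1).  These bins are reconstructions
of narratively reported categories and are fully configurable.
Category proportions between two drug groups are compared with a
two-sided Fisher exact test after collapsing to a 2×2 table (reduction
vs non-reduction by default); general R×C exact tests are out of scope.

The cross-metric dependence structure is a matrix of Spearman rank
correlations over subjects (pairwise-complete; a pair needs ≥ 3
complete subjects).  Rho uses average ranks for ties.  Two-sided
p-values use the exact permutation distribution (all n! orderings) for
n ≤ 9 and the t-approximation above that.  Multiple-testing correction
across the matrix is deliberately off by default (per-pair significance
is reported); a Benjamini-Hochberg flag can be applied downstream.

## Synthetic data model

The generator exists so that every pipeline stage can be validated
against known ground truth; its defaults mirror the study conditions.

**Background.**  Channels are built in the frequency domain: a 1/f^a
spectrum (default a = 2, flattened below 0.5 Hz, no DC) whose
coefficients are rescaled band-by-band so each canonical band holds
exactly its target share of the variance (defaults delta 40, theta 20,
alpha 10, beta 20, gamma 10%); the inter-band gaps keep 5% of the
in-band total so spectra are hole-free.  Hemispheric coupling uses a
shared-source mixture, L = √a·s + √(1−a)·n1 and R = √a·s + √(1−a)·n2
with i.i.d. sources, giving MSC = a² at every frequency (default shared
fraction 0.5 → MSC 0.25).  Per-channel RMS defaults to 50 µV, a typical
awake rodent epidural amplitude.

**Spikes.**  Difference-of-Gaussians biphasic templates (sharp 4 ms-σ
positive phase, slower half-amplitude opposite phase 12 ms later;
~40 ms total) at Poisson times thinned to ≥ 300 ms separation, injected
at the same times into both channels and scaled to a multiple (default
8) of each channel's SD.  The phase proportions keep the extremum of
the 0.5–60 Hz-filtered waveform on the sharp phase, so detected peak
times align with the injection log.  Default rate 6/min, within the
range seen in spontaneously spiking epileptic mice.

**EMG.**  White noise with scheduled movement bursts that multiply the
amplitude by a gain > 1; TKEO scales with gain², so a gain of a few
reliably trips condition iii.

**Drug effect.**  The post half is generated from transformed specs:
total power × `power_scale`, band shares tilted multiplicatively and
renormalized, spike rate × `spike_rate_multiplier`, shared fraction
shifted additively.  Cohorts draw log-normal per-subject multipliers
(defaults: spike multiplier median 0.6, σ_log 0.5; power scale median
0.8, σ_log 0.35) whose rank dependence is planted through a Gaussian
copula (Pearson ρ = 2 sin(π ρ_s/6) reproduces a target Spearman ρ_s
exactly).  Everything is reproducible from a single seed at the session
and the cohort level.

**What the generator does not emulate:** sleep/wake state alternation
beyond scheduled EMG bursts, seizure (ictal) dynamics, mains hum and
electrode artifacts, non-stationary drug pharmacokinetics (the effect
switches instantaneously at the midpoint), and spike waveform
variability.  Passing recovery tests therefore demonstrates estimator
correctness under the generative model, not robustness to every
real-recording pathology.

## Problem sizes

Protocol-scale validations (drug-effect ratio recovery) use the full
4-h session at 1000 Hz: two 1.5-h blocks, 2159 epochs each, ~540
pre-drug spikes at 6/min.  Cohort-level validations (rank-correlation
recovery across 20 subjects, repeated over 100 master seeds) use
2×240-s blocks at 500 Hz with 15 spikes/min (~60 events per block) and
a 10-epoch QC minimum — change ratios are duration-invariant in
expectation, so the short blocks trade per-subject precision for the
ability to study the cross-subject estimator across many replicates.
Spike-count Poisson noise attenuates the planted Spearman 0.9 to a
median estimate near 0.85 at this scale (0.79 at 120-s blocks); under
the null the estimate stays within ±0.45 in ≳ 90% of seeds.

## Numerical choices and degenerate inputs

- Filters are Butterworth in second-order sections, zero-phase
  (`sosfiltfilt`) by default; order 4 per pass.
- Quantiles are type-7 (linear interpolation); the even-count median is
  the mean of the two central order statistics; all selection
  inequalities are strict, so ties reject.
- Bin membership uses a 1e−9 Hz tolerance at band edges.
- Zero total band power, a single coherence segment, an empty feature
  list, a zero pre-drug rate, and a correlation pair with < 3 complete
  subjects are all explicit errors or flagged not-computable values,
  never silent NaNs.
- EDF output is 16-bit with symmetric physical ranges per channel, so a
  round trip is exact to |x|_max/32767; the stored 8-character physical
  maximum is re-parsed before quantization so write/read scaling
  inverts exactly.
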