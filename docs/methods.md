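# Methods

This note documents the models, parameters and numerical choices behind
`gradespike`: what the synthetic generator emulates, how each analysis stage
is defined, and where the design was genuinely open.

## The measurement problem

CSF-contacting neurons fire Ca²⁺-channel-mediated action potentials of graded
amplitude. Two instruments observe them: two-photon GCaMP6f imaging of the
soma (30–120 Hz frames, ΔF/F spikes of ~0.1–3) and loose-seal cell-attached
current recordings (≥10 kHz), where each action potential appears as an
extracellular waveform (EAP) with a primary depolarizing lobe, a repolarizing
lobe, and a variably recruited secondary depolarizing lobe attributed to HVA
Ca²⁺ channels. The running integral of the EAP tracks the intracellular
action-potential waveform, so the peak of ∫EAP is a relative measure of spike
size, and the Ca²⁺ spike amplitude is modelled as linear in it.

## Synthetic recordings

The generator is phenomenological — no conductance-based simulation — and
exists so each pipeline stage can be scored against known ground truth.

**Event times.** Homogeneous Poisson trains (i.i.d. exponential intervals),
default rate 0.148 Hz — the population median reported for spontaneous
activity. Population runs draw per-cell rates log-normal(ln 0.148, σ = 0.5),
which reproduces the reported IQR of roughly 0.1 Hz. Electrode contact
multiplies the rate 3-fold (superposition of an independent train, exact for
Poisson processes).

**Secondary scales and classes.** Each event draws a secondary-lobe scale
from one log-normal with median 0.23; its σ = 0.899 is set so the quartile
*ratio* matches the reported quartiles 0.11–0.37 (one log-normal cannot hit
both quartiles exactly with the median fixed; the geometric compromise is
used). An event is labelled "large" iff its scale exceeds the distribution's
(1 − p_large) quantile (default p_large = 0.5), so labels are
Bernoulli(p_large) marginally and the large class is exactly the set of
events with strong HVA recruitment — the same linkage the paired recordings
show. Note one consequence: the mean waveform's secondary amplitude estimates
the *mean* scale (≈0.33 with these defaults), which exceeds the scale
*median* of 0.23; the generator encodes the distribution median, as the
per-event quantity is what the template parameter names.

**Amplitudes.** Log-normal within class: small median 0.3 ΔF/F, large median
1.5 ΔF/F, both σ = 0.3 (log scale). The class medians are not reported
quantities; they are chosen to give a clearly bimodal mixture of realistic
ΔF/F magnitude, and every analysis that asserts a number normalizes per cell
or uses ranks. In paired scenarios amplitudes are instead
`coupling_slope × ∫EAP_peak + N(0, coupling_noise_sd)` with slope 12 ΔF/F per
pA·s and noise 0.05 ΔF/F, which lands amplitudes in the same range.

**Ca²⁺ transients.** Unit-peak double exponential,
`exp(−t/τ_d) − exp(−t/τ_r)` with τ_r = 50 ms, τ_d = 400 ms
(literature-typical GCaMP6f; the recordings themselves do not constrain the
kinetics — an open point, so both are configurable). Transients add linearly;
additive white noise, default SD 0.05 ΔF/F (spike SNR ≈ 6–30, the range the
paired analysis explores). Default frame rate 30 Hz: the derivative-threshold
detector is most reliable at the low end of the 30–120 Hz acquisition range,
because the per-frame signal step shrinks faster than the smoothed noise as
the frame rate rises.

**EAP template.** Sum of three Gaussian lobes (primary +50 pA, σ 0.5 ms;
repolarizing −30 pA at 1.5 ms, σ 0.6 ms; secondary +scale × 50 pA at 3 ms,
σ 0.8 ms), sampled at 25 kHz with 1 pA noise. The geometry is invented to
match the qualitative morphology (two depolarizing peaks bracketing a
repolarization) while keeping the closed form integrable, so the ∫EAP peak
and the secondary/primary ratio have analytic oracles. Because the lobes are
Gaussians, the running integral's peak is strictly increasing in the
secondary scale for every scale ≥ 0 — the property the ∫EAP statistics rely
on.

**Condition transforms.** TTx is the identity (spikes are Ca²⁺-based). Cd²⁺
re-labels large events small, redraws their amplitudes from the small class,
and zeroes all secondary scales. ML218 thins events binomially (default
survival 0.05, encoding "decimated"). ACh/ATP create evoked events only
inside declared stimulus windows, large-class-only or small-class-only.
Transforms never reorder events and never create events outside stimulus
windows.

**Reproducibility.** All randomness flows from one integer seed through
`numpy.random.SeedSequence` spawn keys; identical config + seed gives
bit-identical traces and byte-identical result files (float formatting is
fixed at write time; the output directory is excluded from the config hash).

## Detection and measurement

**ΔF/F.** F₀ is the 15th percentile of the whole raw trace (linear
interpolation between order statistics), one scalar per recording; drug
epochs share the recording's baseline. Non-positive F₀ is rejected.

**Derivative conditioning.** Savitzky-Golay (order 3, 300 ms) → first
difference (left-aligned, first sample zero) → 5-point running median →
Savitzky-Golay (order 3, 166 ms). Window lengths round to the nearest odd
sample count ≥ order + 2, so 30 Hz and 120 Hz runs are comparable.

**Threshold.** 5 × the median-absolute-difference. Two ambiguities are
exposed as configuration rather than resolved silently:

- *estimator* (`mad_mode`): median absolute deviation about the median
  (default) or median of |successive differences|;
- *stage* (`threshold_stage`): which conditioning stage the MAD is computed
  on. The default is the **median-filtered differentiated signal**; the
  fully conditioned derivative has a systematically smaller MAD (the final
  smoothing removes most point-to-point variance), which at a fixed k = 5
  admits a measurable false-alarm rate on event-free traces, while the raw
  difference's larger MAD costs small-spike sensitivity. All three stages
  are selectable; the false-alarm/sensitivity trade-off is documented by the
  benchmark.

Spikes are local maxima of the conditioned derivative strictly above
threshold, ≥2 samples apart (ties keep the earlier sample). A degenerate
zero threshold (noise-free traces) is floored at 10⁻⁴ of the derivative's
peak so numerical ripple is not detected. Each spike reports the
derivative-peak time and the onset (last sub-threshold sample before it).

**Amplitude and SNR.** Amplitude = max ΔF/F in a 333 ms window centred on
the spike minus the mean of the 100 ms preceding the window; the window is
truncated at both neighbouring spikes' times so summated spikes are measured
on their own rise. Whether the 333 ms window is centred on or starts at the
spike is not fully pinned down by its description; centred is used. SNR =
amplitude / SD of the 180 ms preceding the window; per-cell SNR is the mean
over spikes (infinite values from zero-variance baselines are excluded).

**EAP detection.** On the 6–1500 Hz band-passed trace (2nd-order Butterworth
applied forward-backward, so event times are not skewed; reflection padding
of one settling length). The initial threshold is 5 × MAD; because loose-seal
recordings set thresholds per cell, an automatic per-cell refinement then
splits candidate peak heights at the widest gap (≥ half a decade) between
the near-threshold floor group and the event group. Suprathreshold peaks
within one event window group into a single event anchored on the *first*
qualifying peak — the primary lobe precedes the secondary even when the
secondary is taller.

**∫EAP.** Mean of the 1 ms before the event window subtracted, cumulative
trapezoid over the window (2 ms pre / 15 ms post, invented bounds, exposed in
config), maximum reported.

**Secondary peak.** On the (mean) waveform: differentiate, smooth
(Savitzky-Golay, 0.5 ms), find zero-crossings of the second derivative.
Crossings are gated at 10⁻⁴ of the peak curvature, and counting starts at the
last inflection before the primary peak, so baseline wiggle and the
zero-phase filter's pre-ringing cannot shift the count. The secondary
amplitude is the waveform maximum after the third inflection (the end of the
initial repolarization), which accommodates the secondary peak's variable
delay; fewer than three inflections flags "no secondary lobe". On the
noise-free template the measured ratio matches the analytic local-maximum
ratio to < 10⁻³ absolute over scales 0.05–1.0.

**Event matching (paired runs).** The Ca²⁺ timestamp (derivative peak) lags
the electrical event by a cell-constant ≈1.4 frames at 30 Hz; a wide first
pass (6 frames) estimates the median lag per cell and matching then runs
within ±2 frames of it (configurable). One imaging frame proved too tight for
derivative-peak timestamps — the residual jitter after lag correction is
≈0.6 frames — hence the 2-frame default.

**Pharmacology runs.** One continuous recording per cell with the condition
applied to the generating process at the drug time (default: mid-recording);
the per-cell detection threshold is computed on the control epoch only, since
the drug alters the very signal statistics the threshold is estimated from.
Reported: per-cell pre/post rates (signed-rank), pooled per-cell
mean-normalized amplitude histograms (two-sample KS), the mean rate
reduction, and for Cd²⁺ the secondary-peak shift between mean waveforms of
50 pre/post events.

**Detector benchmark.** Scoring is attribution-based and symmetric: a true
event is recovered if any detection lies within ±3 frames; a detection is
genuine if any true event does. Sensitivity is computed over events with
true amplitude ≥ 5 × noise SD (the stated SNR regime); amplitude bias and
coupling R² are computed on isolated events (previous gap > 3 decay
constants, next gap > the measurement window), because an unresolvable
neighbour inside the window corrupts the amplitude and that failure mode is
already captured by sensitivity. The noise sweep reuses the same simulated
cells at every level (common random numbers), so the R²-vs-SNR curve is not
confounded by cell resampling.

## Statistics

- Rate = count/duration; ISI CV = sample SD / mean of intervals (n − 1
  denominator), undefined below 3 events. Exponential intervals give CV 1.
- JB uses biased (population) moment estimators — the classical statistic;
  small-sample corrections are out of scope. Critical values are empirical
  (1 − α) quantiles over Monte-Carlo replicates of n standard-normal draws
  (default 10⁵ per n, seeded per (seed, n) and cached), so the multimodality
  flag is calibrated at α by construction rather than by asymptotics.
- Amplitude pooling divides every amplitude by that cell's mean control
  amplitude, removing cell-to-cell gain before histograms/KS.
- The activity index is the sum of detected spike amplitudes per unit time
  (the reading consistent with its ΔF/F·s⁻¹ unit); a mean-positive-derivative
  mode is provided because the quantity's definition is not otherwise stated,
  and neither is asserted as canonical.
- Condition tests: Wilcoxon signed-rank (paired; all-zero difference vectors
  report p = 1), Mann-Whitney U (unpaired), two-sample KS (distributions).
  Two-sided, no multiple-testing correction. Summaries are median ± IQR for
  non-normal quantities, mean ± SD otherwise.

## What the synthetic data does and does not establish

The generator reproduces the statistical structure the analyses consume —
Poisson timing, bimodal amplitudes, a variably recruited secondary EAP lobe,
linear Ca↔∫EAP coupling, white imaging noise — so green tests establish that
the chain recovers known structure at realistic SNR, rates and sample sizes.
It does not emulate photobleaching or baseline drift, correlated (shot)
noise, motion artefacts, bursting or rate nonstationarity, cell-to-cell
kernel variability, or electrode drift; performance on real recordings with
those features is not certified by these tests. Two structural limits
surface honestly in the results: events closer than the derivative smoothing
window cannot be separated at 30 Hz (a few percent of Poisson events at
0.148–0.44 Hz), and summated events bound the full-chain coupling R² well
below 1 even noise-free — consistent with the moderate per-cell R² values
such paired recordings yield in practice.

## Problem sizes

Defaults used by the analysis drivers and tests: 127 cells × 300 s for the
population survey, 5 × 240 s for paired runs, 20–65 cells × 480 s per
pharmacology condition, 4 cells × 240 s per benchmark noise level, 10⁴–10⁵
null replicates per JB critical value. These sizes put Monte-Carlo error
comfortably inside every asserted tolerance while keeping any single driver
under a minute on one core.
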