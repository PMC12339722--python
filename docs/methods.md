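# Methods

This note documents the models, estimators and numerical choices behind
`thetalock`, what the synthetic data do and do not emulate, and the
design decisions taken where the procedure was genuinely open.

## Signal model and conditioning

The LFP is treated as a sum of an aperiodic 1/f-like background,
transient narrowband theta bursts, line noise, occasional pathological
transients, and the extracellular signatures of the recorded units
themselves. Conditioning proceeds in the order waveform subtraction →
resampling → line-noise removal → demeaning → artifact masking.

**Spike-waveform subtraction.** Each unit's mean waveform is estimated
from the 100–3000 Hz band-passed trace (4 ms window centred on the
spike) and subtracted at every spike time, with the first and last 10%
of the snippet linearly tapered to zero. Subtraction is additive across
units, so overlapping spikes of different units are handled
order-independently. The taper fraction is configurable; 10% suppresses
edge steps without eating into the spike body at 2 kHz.

**Line-noise removal.** A zero-phase FIR band-stop (odd tap count ≈ the
sampling rate, applied by FFT convolution with the group delay
compensated and reflective padding) attenuates 48–52, 98–102 and
148–152 Hz by well over 30 dB while leaving the band below 40 Hz within
1 dB. The output mean is pinned to zero so that band-stop filtering and
demeaning commute exactly; a filter-order-style specification would be
ambiguous here, so the attenuation contract is normative.

**IED-like artifact masking.** A sample is flagged when any of three
robust z-scores (median/MAD) exceeds its threshold: the amplitude
envelope (>6), the signed first difference (|z| > 6), or the log10 of
the 25–80 Hz band power smoothed over 100 ms (>5). Two numerical points
matter. First, the difference signal is z-scored *before* taking the
absolute value: folding first shrinks the robust scale and silently
turns a 6σ threshold into roughly 4σ. Second, band power is z-scored on
a log scale because its raw distribution is so right-skewed that a
MAD-based z fires on perfectly clean noise. Flagged samples are padded
by ±250 ms and merged; on pure pink noise well under 1% of samples end
up masked, while an injected 8-SD biphasic transient is always
contained. The thresholds are exposed in the API because the criteria
are a parameterized stand-in, not a clinical detector.

## Generalized phase

Phase is the angle of the Hilbert analytic signal of the 1–10 Hz
FIR-filtered trace (order 6000 at 2 kHz, scaled proportionally at other
rates; zero-phase by delay compensation). Instantaneous frequency is
the centred difference of the unwrapped phase divided by 2π (one-sided
at the edges). Samples with frequency below 1 Hz — including negative
frequencies, where phase progression reverses — are removed from the
unwrapped phase and refilled by monotone (PCHIP) interpolation through
the neighbouring valid samples, then rewrapped; the interpolation mask
records exactly which samples were replaced, and untouched samples are
bitwise identical to the raw analytic-signal angle. Runs touching a
trace boundary have no anchor on one side and are filled by linear
extension of the nearest valid trend (flagged in the mask). Power is
the squared analytic magnitude. Convention throughout: phase 0 at
peaks, ±π at troughs, so trough locking appears at ±π in all polar
summaries. Only these steps are implemented — no additional smoothing
of the analytic signal — and the Hilbert transform runs once over the
full trace.

Each spike maps to the temporally closest sample; an exact midpoint
goes to the earlier sample, with a 10⁻⁹-sample guard absorbing float
noise at the boundary. Spikes inside artifact intervals are dropped
before any statistic is computed.

## Cycle segmentation and oscillation bouts

Peaks are upward zero crossings of the phase, troughs the +π → −π
wraps. When extrema repeat without alternating (incomplete phase
reversals), the larger-valued peak / smaller-valued trough on the
filtered trace is kept, so the sequence strictly alternates. Cycles run
peak → peak with the trough between defining the decay and rise flanks;
edge half-cycles are discarded. Cycle amplitude is the mean of the two
flank excursions.

Scores: amplitude consistency is the worst min/max ratio among the
within-cycle flank pair and the flank pairs shared with each neighbour;
period consistency the worse of the min/max period ratios with the two
neighbours; monotonicity the mean fraction of correctly-signed
sample-to-sample differences on the two flanks. A cycle is oscillatory
when all three scores pass (0.3 / 0.5 / 0.6) and its amplitude exceeds
the 20th percentile of all cycle amplitudes on that wire — the
percentile population is the whole session, matching the session-wide
framing of every other statistic. Machine-level amplitude ties at the
percentile cut are tolerated so that an ideal constant-amplitude
sinusoid is not rejected wholesale by float jitter. Runs of ≥2
oscillatory cycles form bouts, half-open in samples, with frequency
`n_cycles / duration`; spikes on a bout's end boundary are outside it.

At the generator's default conditions (burst amplitude twice the noise
SD), bouts cover ~84% of true burst samples and are ~3.3× denser inside
bursts than outside, pooled over sessions; the residual outside
coverage reflects genuine 1–10 Hz stretches of pink noise that satisfy
the thresholds, not a detector fault.

## Time-resolved spectral parameterization

Short-time spectra use 1-s Hann windows with 50% overlap; each frame
averages five consecutive windows and steps by 500 ms, spanning 3 s (a
60-s trace yields 115 frames). Frames overlapping any artifact interval
are invalid and carry no parameters. The aperiodic component is fitted
in log-log space by least squares followed by a refit on the points in
the lower half of the residuals, which suppresses peak contamination
(peaks only push residuals up); the fit is exact on noiseless power
laws and scale-equivariant. Up to three Gaussian peaks are extracted
largest-first from the flattened spectrum with height > 0.5, SNR > 2
(height over the SD of the flattened residual — the SNR definition was
open and this is the choice), SD within 2–6 Hz, and a proximity rule
discarding peaks within one SD of a larger peak's centre or of the
1/40 Hz edges. Log base 10 throughout. "High slope" always means larger
exponent χ (steeper negative log-log slope).

Short windows carry a known bias: with steep spectra (χ near 2) the
mainlobe of a 1-s window integrates the strong sub-1 Hz power into the
lowest bins, steepening the apparent slope by ~0.2. Slope *ranks*
across time windows — all the pipeline's conditioning uses — are
unaffected; for absolute exponent recovery the package provides
`average_spectrum` (8-s Welch segments on the same 1–40 Hz grid), which
recovers χ ∈ {0.5, 1, 1.5, 2} within ±0.15. Each spike inherits the
exponent of the frame whose 500-ms step contains it; spikes in invalid
frames are excluded from slope-conditioned analyses. No objective
goodness-of-fit threshold is asserted; the per-frame RMS error is
reported so users can filter.

## Circular statistics and surrogate inference

PPC is the mean cosine of all pairwise phase differences, computed via
`(R² − n)/(n(n−1))` with `R` the modulus of the summed unit vectors;
this matches the O(n²) enumeration to 10⁻¹² and is unbiased by spike
count (mean |PPC| < 0.01 under uniformity at n = 25–400), whereas
Rayleigh `z = n·r²` grows linearly with n at fixed locking strength.
The Rayleigh path is kept for the Δz analyses for fidelity, with that
bias in mind: its shuffle null preserves exact group sizes in every
surrogate round. The Watson–Williams F uses the standard concentration
correction `1 + 3/(8κ̂)` (κ̂ from the Fisher approximation) with no
assumption gating — validity comes from the surrogate rank, not the
parametric F distribution.

Four surrogate constructions, all seeded:

1. **Circular shift** (per-unit locking): the phase trace is rotated by
   a uniform lag in [1, N−1] samples (never 0) and PPC recomputed at
   fixed spike samples; 1001 surrogates by default.
2. **Pooled reassignment** (Δz and spike-level Watson–Williams):
   pooled phases are permuted into groups of the original sizes.
3. **Segment shuffle** (encoding–retrieval phase shift): condition
   labels are permuted over *segments*, so all spikes of a segment move
   together and within-segment phase dependence is preserved;
   surrogates that leave a group with fewer than two spikes are redrawn
   so the surrogate count stays exact.
4. **Condition swap** (cohort-level paired contrasts): each unit's
   condition pair is independently swapped with probability ½ and the
   paired t recomputed; 10,001 surrogates by default.

Significance is declared when the empirical statistic exceeds the 95th
percentile of its surrogates; the reported p is the rank
`(1 + #{surr ≥ emp}) / (n_surr + 1)` with exact ties carrying half
weight (identical for continuous statistics, and giving p ≈ 0.5 rather
than 1 in fully degenerate all-tie cases). Median splits send values
equal to the median to the low group; this tie rule is shared by the
location-recall success classification. All engines hit their nominal
5% false-positive level within ±2 points under their own nulls.

A caution that the test suite enforces: a perfectly periodic phase
trace makes the circular-shift null degenerate — every shift is a pure
rotation and PPC is rotation-invariant — so locking tests are only
meaningful on aperiodic (real or pink-noise-derived) phase traces.

## Spike-field coherence

Segments are 1 s of the cleaned 2 kHz trace centred on each spike
(spikes within 500 ms of a trace end are dropped, not reflected),
resampled to 250 Hz (251 samples). Numerator and denominator use the
same multitaper estimate — 7 Slepian tapers from time-bandwidth 4
(1 s × 4 Hz smoothing), zero-padded to a 0.1 Hz grid and read at 1–100
Hz in 1 Hz steps — which is the only internally consistent choice given
that SFC must reach exactly 100% when every segment equals the STA.
Condition contrasts subsample the larger condition to the smaller's
spike count, averaging over 100 repetitions.

## Behaviour

Object recall is the fraction of correct recalls. Location drop errors
are ranked within uniformly sampled potential response locations over
the arena interior (per true object location, making the metric
location-dependent as ranking implies; geometry rectangular by default,
disc supported): the normalized value is the fraction of potential
errors strictly larger, so 1 is best. A location recall is successful
when its normalized value strictly exceeds the session median (the
median-valued recall is unsuccessful, consistent with the global
median-split tie rule); encoding segments inherit the success of their
paired recall. Trend tests compare first- and second-half trial means
per session with a paired t across sessions; an odd middle trial joins
the first half.

## The synthetic-session generator

The generator exists to give every stage a recovery test, not to model
biophysics. It emulates: pink-noise LFP by spectral synthesis (random
phases, amplitude ∝ f^(−χ/2)), which hits the target exponent exactly
in expectation and is circularly stationary (making the circular-shift
null exact on it); additive non-overlapping theta bursts of uniformly
drawn frequency (3–8 Hz default) and cycle count (4–12), Hann-tapered
on and off over one cycle with a flat top, optional bounded linear
frequency drift; 50 Hz line noise with optional harmonics; IED-like
biphasic transients; and three spiking regimes. Phase-locked trains are
inhomogeneous Poisson by thinning with intensity
`base_rate · 2π · vonMises(θ(t); μ, κ)`, which reduces exactly to
homogeneous Poisson at κ = 0 and keeps the mean rate near `base_rate`
under uniform phase occupancy; μ may vary by condition (encoding vs
retrieval segments) or apply only inside bursts. Resonant trains sit on
a jittered 1/f₀ grid with dropout to the target rate and never see the
LFP. Trials hold 2–3 encoding events, a 6.6-s distractor and one recall
segment per object, alternating object- and location-recall trials,
with Bernoulli success probability rising linearly across trials;
location errors mix a Rayleigh-small-error component (accurate) with
uniform guesses. All randomness flows from one integer seed through
spawned substreams per wire, unit and table, so sessions are
bit-reproducible.

Defaults are chosen once as the study conditions: burst occupancy ~38%
of the trace (14 bursts/min at the default cycle counts), matching the
fraction of time theta oscillations are typically detected in human MTL
microwires; burst amplitude twice the broadband noise SD; unit rates
1–3 Hz. What the generator does *not* emulate — correlated noise across
wires, spike-sorting noise, nonstationary behaviour, realistic IED
morphology — bounds what passing tests show: they demonstrate that the
estimators recover known ground truth under the stated signal model,
not that the pipeline is robust to every pathology of real recordings.

## Analysis scale

The analysis drivers and test suite run at desk scale on one CPU:
sessions of 2–12 minutes, cohorts of 8–100 units, 200–2001 surrogates
per unit test and 200 surrogate datasets in the chance-level control
(with 200 inner surrogates per test). These sizes keep every
calibration within a ±2-point band of its nominal level while the full
suite completes in about two minutes; production analyses would raise
the surrogate counts to the 1001/10,001 defaults, which only narrows
the rank-p resolution.

## Known limitations

- The aperiodic exponent from the 500-ms frames is upward-biased for
  χ ≳ 1.5 (short-window leakage); use `average_spectrum` for absolute
  slopes.
- Peak fitting extracts Gaussians greedily rather than refitting all
  peaks jointly; heavily overlapping peaks can trade height.
- The Watson–Williams correction is undefined when the pooled resultant
  is ~0 with tiny samples; the implementation raises rather than
  guessing, and the surrogate engines redraw rather than skip.
- Monotonicity is weakly discriminative on a 1–10 Hz filtered trace
  (flanks are smooth by construction); the burden of oscillation
  specificity falls on the consistency scores and amplitude floor.
- The IED detector is a parameterized stand-in; its thresholds should
  be re-validated before any use on clinical data.
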