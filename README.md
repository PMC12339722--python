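# thetalock

Spike–field theta phase-locking analysis for human single-neuron
electrophysiology, built as a tested, end-to-end pipeline over synthetic
sessions with known ground truth.

During spatial memory tasks, neurons in the human medial temporal lobe
tend to fire at consistent phases of the local field potential (LFP)
filtered in a broad 1–10 Hz theta range — even though human theta comes
in short bouts of rapidly changing frequency rather than the sustained
rhythm seen in rodents. Quantifying that coupling raises a chain of
methodological problems this package addresses for researchers working
with microwire recordings (or anyone wanting a reference implementation
to validate their own):

- **LFP conditioning** — subtracting each unit's mean spike waveform from
  the trace (so the spike itself does not masquerade as locking),
  resampling to 2 kHz, zero-phase band-stop removal of 50/100/150 Hz
  line noise, demeaning, and masking of interictal epileptiform
  discharge (IED)-like artifacts.
- **Generalized phase** — the angle of the analytic signal of the 1–10 Hz
  filtered trace, with epochs whose instantaneous frequency falls below
  1 Hz (including reversals) replaced by shape-preserving cubic
  interpolation. Convention: phase 0 at peaks, ±π at troughs.
- **Oscillation detection** — phase-derived peak/trough segmentation into
  cycles scored for amplitude consistency (≥0.3), period consistency
  (≥0.5), flank monotonicity (≥0.6) and an amplitude floor (20th
  percentile); runs of ≥2 passing cycles form bouts with frequency
  `n_cycles / duration`.
- **Time-resolved spectral parameterization** — 3-s spectra every 500 ms
  decomposed into an aperiodic component `log10 P(f) = b − χ·log10 f`
  (offset `b`, exponent `χ`; steeper slope = larger `χ`) plus up to
  three Gaussian peaks, with per-spike slope annotation.
- **Circular statistics with bespoke surrogate nulls** — pairwise phase
  consistency `PPC = mean cos(θᵢ − θⱼ)` over all spike pairs (computed
  via the closed form `(R² − n)/(n(n−1))`, unbiased by spike count),
  mean resultant length `r`, Rayleigh `z = n·r²`, and the Watson–Williams
  F for phase-shift tests — each validated by rank within its matched
  surrogate construction: circular shifts of the phase trace, pooled
  label shuffles with preserved group sizes, segment-label shuffles
  that move whole segments, and per-unit condition swaps.
- **Spike-field coherence** — `SFC(f) = 100 · P_STA(f) / ⟨P_i(f)⟩` from
  multitaper spectra of spike-centred 1-s segments, with matched
  spike-count subsampling for condition contrasts.
- **Memory metrics** — object-recall accuracy and location drop errors
  normalized by ranking within uniformly sampled potential responses,
  plus encoding/retrieval segmentation with success labels.

Because no raw human recordings ship with the method, the package
includes a first-class synthetic-session generator (`thetalock.synth`):
pink-noise LFP with theta bursts at realistic (~38%) occupancy, line
noise, IED-like transients, and spike trains that are von Mises
phase-locked (optionally only inside bursts, optionally with different
preferred phases in encoding vs retrieval), Poisson, or theta-resonant
yet independent of the field. Every downstream stage has a
parameter-recovery test against this ground truth.

## Worked example

`analysis/` holds the numbered drivers; each regenerates its inputs
from a fixed seed and writes small tables under `results/`.

```bash
python analysis/01_simulate_session.py
python analysis/05_phase_shift.py
```

prints (abridged):

```
session: 360 s, 8 units, 76 segments, 32 recall events
object-recall performance: 0.588
wire 0: 82 theta bursts, occupancy 0.36, 7 IEDs

shifted cohort: 20/20 units flagged (binomial p vs 5% chance = 9.5e-27)
recovered shift: median 90.2 deg (ground truth +90 deg, positive = later phase at retrieval)
chance-level control (null cohort): mean flagged 6.22% across 100 surrogate datasets (nominal 5%)
```

Reading this: the generator produced a 6-minute session whose behaviour
table scores 58.8% correct object recalls. In a cohort of 20 units
built to shift their preferred theta phase from 0 at encoding to +π/2
at retrieval, the segment-shuffle Watson–Williams test flags every
unit, and the recovered angular difference lands on the built-in +90°
(the sign convention reports a shift toward a *later* phase at
retrieval as positive). On a cohort with no built-in shift, the
circular-shift reassignment control flags units at close to the nominal
5% alpha level, confirming the test is calibrated.

The other drivers cover LFP conditioning and per-spike annotation
(`02`), per-unit locking tests with the power / aperiodic-slope /
oscillation condition splits (`03`), and the memory-success contrasts
with spike-field coherence (`04`).

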