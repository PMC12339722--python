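#!/usr/bin/env python
"""Generate the reference synthetic session and write its tables.

The session emulates a human spatial-memory microwire recording: two
wires of pink-noise LFP with theta bursts (~38% occupancy), 50 Hz line
noise and occasional IED-like transients; eight units spanning the
three spiking regimes (von Mises phase-locked, Poisson, and
theta-resonant-but-field-independent); and 12 trials of encoding /
distractor / recall segments with linearly improving memory
performance. Ground truth (burst intervals, unit parameters, success
flags) is saved alongside so later stages can be scored against it.

Writes: results/session_*.csv (+ ground-truth JSON), scratch/session.h5
"""

from pathlib import Path

import numpy as np

from thetalock import behavior, io, synth

RESULTS = Path(__file__).resolve().parent.parent / "results"
SCRATCH = Path(__file__).resolve().parent.parent / "scratch"

SESSION_SEED = 20260921


def default_units() -> list:
    u = []
    for w in (0, 1):
        u.append(synth.UnitSpec(mode="locked", base_rate=2.5, kappa=3.0,
                                mu_encoding=np.pi, mu_retrieval=np.pi,
                                lock_only_in_bursts=True, wire=w))
        u.append(synth.UnitSpec(mode="locked", base_rate=2.0, kappa=2.0,
                                mu_encoding=0.0, mu_retrieval=np.pi / 2, wire=w))
        u.append(synth.UnitSpec(mode="poisson", base_rate=2.5, wire=w))
        u.append(synth.UnitSpec(mode="resonant", base_rate=2.0,
                                resonance_freq=4.0, wire=w))
    return u


def build_session() -> synth.SynthSession:
    cfg = synth.SynthConfig(
        duration_s=360.0,
        n_trials=12,
        units=default_units(),
        line_noise_amp=5.0,
        ied_rate=1.0,
        seed=SESSION_SEED,
    )
    return synth.gen_session(cfg)


def main() -> None:
    RESULTS.mkdir(exist_ok=True)
    SCRATCH.mkdir(exist_ok=True)
    ses = build_session()
    io.save_session(ses, SCRATCH / "session.h5")
    # keep the small tables with the results; the waveform-level HDF5
    # container stays in scratch
    for name in ("segments", "behavior", "units", "ground_truth"):
        src = SCRATCH / f"session_{name}.{'json' if name == 'ground_truth' else 'csv'}"
        src.replace(RESULTS / src.name)

    beh = ses.behavior
    obj_perf = behavior.object_recall_performance(beh)
    print(f"session: {ses.config.duration_s:.0f} s, {len(ses.config.units)} units, "
          f"{len(ses.segments)} segments, {len(beh)} recall events")
    print(f"object-recall performance: {obj_perf:.3f}")
    for w, ivs in ses.ground_truth.burst_intervals.items():
        occ = sum(b - a for a, b in ivs) / ses.lfp[w].n_samples
        print(f"wire {w}: {len(ivs)} theta bursts, occupancy {occ:.2f}, "
              f"{len(ses.ground_truth.ied_intervals[w])} IEDs")


if __name__ == "__main__":
    main()
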