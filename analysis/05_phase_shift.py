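#!/usr/bin/env python
"""Encoding-to-retrieval theta-phase shifts and the chance-level control.

Two cohorts on one synthetic wire: a shifted cohort whose units move
their preferred phase from 0 at encoding to +pi/2 at retrieval (a
later phase), and a null cohort with identical preferred phases. The
per-unit Watson-Williams segment-shuffle test should flag most shifted
units with a recovered angular difference near +90 degrees, and the
circular-shift reassignment control on the null cohort should flag
units at the nominal 5% level.

Writes: results/phase_shift.csv, results/phase_shift_summary.json
"""

import json
from pathlib import Path

import numpy as np

from thetalock import circstats, pipeline

RESULTS = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    RESULTS.mkdir(exist_ok=True)

    shifted = pipeline.build_locked_cohort(
        20, kappa=2.0, mu_encoding=0.0, mu_retrieval=np.pi / 2, seed=2026
    )
    df = pipeline.phase_shift_analysis(shifted, n_surr=1001, seed=13)
    df.to_csv(RESULTS / "phase_shift.csv", index=False)
    tested = df[df["tested"]]
    flagged = tested[tested["significant"]]
    shift_deg = np.rad2deg(flagged["shift"].to_numpy())
    print(f"shifted cohort: {len(flagged)}/{len(tested)} units flagged "
          f"(binomial p vs 5% chance = {df.attrs['binomial_p']:.2g})")
    print(f"recovered shift: median {np.median(shift_deg):.1f} deg "
          f"(ground truth +90 deg, positive = later phase at retrieval)")

    null = pipeline.build_locked_cohort(
        40, kappa=2.0, mu_encoding=np.pi / 2, mu_retrieval=np.pi / 2, seed=2027
    )
    control = pipeline.phase_shift_chance_control(
        null, n_datasets=100, n_surr_inner=200, rng=31
    )
    print(f"chance-level control (null cohort): mean flagged "
          f"{control['mean_percent']:.2f}% across {control['n_datasets']} "
          f"surrogate datasets (nominal 5%)")

    summary = dict(
        n_tested=int(len(tested)),
        n_flagged=int(len(flagged)),
        binomial_p=float(df.attrs["binomial_p"]),
        median_shift_deg=round(float(np.median(shift_deg)), 1),
        chance_mean_percent=round(control["mean_percent"], 2),
        chance_sd_percent=round(control["sd_percent"], 2),
    )
    with open(RESULTS / "phase_shift_summary.json", "w") as fh:
        json.dump(summary, fh, indent=1)


if __name__ == "__main__":
    main()
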