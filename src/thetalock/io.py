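"""Session container I/O.

Sessions are stored as an HDF5 file (datasets ``/lfp/<wire>`` and
``/spikes/<unit>`` with ``fs``/``region`` attributes) alongside CSV
tables (``segments.csv``, ``behavior.csv``, ``units.csv``) and a JSON
ground-truth sidecar when the session is synthetic.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .preprocess import LfpTrace
from .synth import GroundTruth, SynthSession

__all__ = ["save_session", "load_session_arrays"]


def save_session(session: SynthSession, out_path) -> Path:
    """Write LFP + spikes to HDF5 and the tables/ground truth beside it."""
    out = Path(out_path)
    out.parent.mkdir(parents=True, exist_ok=True)
    with h5py.File(out, "w") as h5:
        grp = h5.create_group("lfp")
        for wire, trace in session.lfp.items():
            ds = grp.create_dataset(str(wire), data=trace.samples)
            ds.attrs["fs"] = trace.fs
            ds.attrs["region"] = trace.region
        spk = h5.create_group("spikes")
        for i, times in enumerate(session.spike_times):
            spk.create_dataset(str(i), data=np.asarray(times))
        h5.attrs["duration_s"] = session.config.duration_s
        h5.attrs["fs"] = session.config.fs

    stem = out.with_suffix("")
    session.segments.to_csv(f"{stem}_segments.csv", index=False)
    session.behavior.to_csv(f"{stem}_behavior.csv", index=False)
    units = pd.DataFrame(
        [
            dict(unit=i, wire=u.wire, mode=u.mode, base_rate=u.base_rate,
                 kappa=u.kappa, mu_encoding=u.mu_encoding,
                 mu_retrieval=u.mu_retrieval)
            for i, u in enumerate(session.config.units)
        ]
    )
    units.to_csv(f"{stem}_units.csv", index=False)
    _save_ground_truth(session.ground_truth, f"{stem}_ground_truth.json")
    return out


def _save_ground_truth(gt: GroundTruth, path) -> None:
    payload = {
        "burst_intervals": {str(k): [list(map(int, iv)) for iv in v]
                            for k, v in gt.burst_intervals.items()},
        "burst_frequencies": {str(k): list(map(float, v))
                              for k, v in gt.burst_frequencies.items()},
        "ied_intervals": {str(k): [list(map(int, iv)) for iv in v]
                          for k, v in gt.ied_intervals.items()},
        "segment_success": {str(k): v for k, v in gt.segment_success.items()},
        "units": [
            dict(mode=u.mode, base_rate=u.base_rate, kappa=u.kappa,
                 mu_encoding=u.mu_encoding, mu_retrieval=u.mu_retrieval,
                 wire=u.wire)
            for u in gt.unit_specs
        ],
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)


def load_session_arrays(path) -> dict:
    """Load the raw arrays back from an HDF5 session container."""
    out: dict = {"lfp": {}, "spikes": {}}
    with h5py.File(path, "r") as h5:
        for wire, ds in h5["lfp"].items():
            out["lfp"][wire] = LfpTrace(
                samples=ds[()], fs=float(ds.attrs["fs"]),
                wire_id=wire, region=str(ds.attrs.get("region", "")),
            )
        for unit, ds in h5["spikes"].items():
            out["spikes"][int(unit)] = ds[()]
        out["fs"] = float(h5.attrs["fs"])
        out["duration_s"] = float(h5.attrs["duration_s"])
    return out
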