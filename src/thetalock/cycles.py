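"""Cycle segmentation and oscillation-bout detection in the 1-10 Hz band.

Cycles run from one peak of the filtered trace to the next, with peaks
and troughs located from the generalized-phase estimate rather than
from local extrema of the waveform: peaks at upward zero crossings of
the phase, troughs at the +pi -> -pi wraps. A cycle counts as part of
an oscillation when its amplitude consistency, period consistency and
flank monotonicity all pass their thresholds and its amplitude exceeds
the 20th percentile of all cycle amplitudes on the wire; runs of at
least two such cycles form bouts whose frequency is the cycle count
divided by the bout duration.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .gphase import PhaseSeries

logger = logging.getLogger(__name__)

__all__ = [
    "OscillationBout",
    "find_extrema_from_phase",
    "score_cycles",
    "oscillation_summary",
    "flag_spikes_in_oscillation",
]


@dataclass
class OscillationBout:
    """A run of >= 2 consecutive oscillatory cycles, half-open in samples."""

    start: int
    end: int
    n_cycles: int
    frequency: float  # Hz, = n_cycles / duration_s

    @property
    def duration_samples(self) -> int:
        return self.end - self.start


def find_extrema_from_phase(
    phase_series: PhaseSeries, filtered: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Peak and trough sample indices from the phase estimate.

    Peaks sit where the phase crosses zero going upward; troughs where
    the wrapped phase jumps from +pi to -pi. When the sequence fails to
    alternate (incomplete phase reversals), repeated peaks keep the one
    with the maximum filtered value and repeated troughs the one with
    the minimum, so the output strictly alternates.
    """
    ph = phase_series.phase
    x = np.asarray(filtered, dtype=float)
    d = np.diff(ph)
    # peak: sign change - up through 0, not a wrap
    up = np.flatnonzero((ph[:-1] < 0) & (ph[1:] >= 0) & (d > 0) & (d < np.pi))
    peaks = up + 1
    # trough: wrap from +pi to -pi
    wraps = np.flatnonzero(d < -np.pi)
    troughs = np.where(np.abs(ph[wraps]) >= np.abs(ph[wraps + 1]), wraps, wraps + 1)

    if peaks.size < 2:
        logger.info("fewer than two peaks found; empty cycle set")
        return peaks, troughs

    events = sorted(
        [(int(i), 0) for i in peaks] + [(int(i), 1) for i in troughs]
    )
    out: list[tuple[int, int]] = []
    for idx, kind in events:
        if out and out[-1][1] == kind:
            prev_idx = out[-1][0]
            if kind == 0:  # repeated peaks: keep the larger value
                if x[idx] > x[prev_idx]:
                    out[-1] = (idx, kind)
            else:  # repeated troughs: keep the smaller value
                if x[idx] < x[prev_idx]:
                    out[-1] = (idx, kind)
        else:
            out.append((idx, kind))
    peaks = np.array([i for i, k in out if k == 0], dtype=np.int64)
    troughs = np.array([i for i, k in out if k == 1], dtype=np.int64)
    return peaks, troughs


def _minmax_ratio(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    hi = np.maximum(a, b)
    with np.errstate(divide="ignore", invalid="ignore"):
        r = np.minimum(a, b) / hi
    return np.where(hi <= 0, 0.0, r)


def score_cycles(
    filtered: np.ndarray,
    peaks: np.ndarray,
    troughs: np.ndarray,
    fs: float,
    amp_consistency: float = 0.3,
    period_consistency: float = 0.5,
    monotonicity: float = 0.6,
    min_cycles: int = 2,
    amp_percentile: float = 20.0,
) -> tuple[pd.DataFrame, list[OscillationBout]]:
    """Score cycles and group consecutive oscillatory cycles into bouts.

    A cycle spans peak_i -> peak_{i+1} with exactly one trough between;
    its decay flank is peak_i -> trough, its rise flank trough ->
    peak_{i+1}, and its amplitude the mean of the two flank voltage
    excursions. Consistency scores are min/max ratios against both
    neighbours, taking the worse; monotonicity is the fraction of
    correctly-signed sample-to-sample differences on the two flanks.
    """
    for name, thr in (
        ("amp_consistency", amp_consistency),
        ("period_consistency", period_consistency),
        ("monotonicity", monotonicity),
    ):
        if not 0.0 <= thr <= 1.0:
            raise ValueError(f"{name} threshold must lie in [0, 1]")
    x = np.asarray(filtered, dtype=float)
    empty = pd.DataFrame(
        columns=[
            "peak", "next_peak", "trough", "amplitude", "period",
            "amp_consistency", "period_consistency", "monotonicity",
            "amp_rank", "is_oscillatory", "bout_id",
        ]
    )
    if peaks.size < 2:
        return empty, []

    # keep only troughs strictly between the first and last peak, one per cycle
    rows = []
    for i in range(peaks.size - 1):
        p0, p1 = int(peaks[i]), int(peaks[i + 1])
        between = troughs[(troughs > p0) & (troughs < p1)]
        if between.size != 1:
            continue  # malformed cycle (should not occur after alternation)
        tr = int(between[0])
        decay_amp = x[p0] - x[tr]
        rise_amp = x[p1] - x[tr]
        rows.append((p0, p1, tr, (decay_amp + rise_amp) / 2.0, (p1 - p0) / fs,
                     decay_amp, rise_amp))
    if not rows:
        return empty, []
    df = pd.DataFrame(
        rows, columns=["peak", "next_peak", "trough", "amplitude", "period",
                       "decay_amp", "rise_amp"]
    )
    nc = len(df)

    periods = df["period"].to_numpy()
    pc = np.full(nc, np.nan)
    if nc >= 2:
        left = np.r_[np.nan, _minmax_ratio(periods[1:], periods[:-1])]
        right = np.r_[_minmax_ratio(periods[:-1], periods[1:]), np.nan]
        pc = np.fmin(np.nan_to_num(left, nan=np.inf), np.nan_to_num(right, nan=np.inf))
        pc[~np.isfinite(pc)] = np.nan

    rise = df["rise_amp"].to_numpy()
    decay = df["decay_amp"].to_numpy()
    # flank-amplitude consistency: within-cycle decay vs rise, plus the
    # flanks shared with each neighbour; take the worst ratio
    within = _minmax_ratio(decay, rise)
    with_prev = np.r_[np.nan, _minmax_ratio(decay[1:], rise[:-1])]
    with_next = np.r_[_minmax_ratio(rise[:-1], decay[1:]), np.nan]
    ac = np.fmin(within, np.fmin(
        np.nan_to_num(with_prev, nan=np.inf), np.nan_to_num(with_next, nan=np.inf)
    ))
    ac[~np.isfinite(ac)] = np.nan

    mono = np.empty(nc)
    for i, row in enumerate(df.itertuples()):
        dec = np.diff(x[row.peak : row.trough + 1])
        ris = np.diff(x[row.trough : row.next_peak + 1])
        frac_dec = np.mean(dec <= 0) if dec.size else 1.0
        frac_ris = np.mean(ris >= 0) if ris.size else 1.0
        mono[i] = (frac_dec + frac_ris) / 2.0

    amps = df["amplitude"].to_numpy()
    amp_cut = np.percentile(amps, amp_percentile)
    amp_rank = np.searchsorted(np.sort(amps), amps, side="left") / max(nc - 1, 1)
    # tolerate machine-level amplitude ties (ideal sinusoids) at the cut
    amp_tol = 1e-9 * float(np.max(np.abs(amps), initial=0.0))

    is_osc = (
        (np.nan_to_num(ac, nan=-1.0) >= amp_consistency)
        & (np.nan_to_num(pc, nan=-1.0) >= period_consistency)
        & (mono >= monotonicity)
        & (amps > amp_cut - amp_tol)
    )

    df["amp_consistency"] = ac
    df["period_consistency"] = pc
    df["monotonicity"] = mono
    df["amp_rank"] = amp_rank
    df["is_oscillatory"] = is_osc
    df["bout_id"] = -1

    bouts: list[OscillationBout] = []
    i = 0
    while i < nc:
        if not is_osc[i]:
            i += 1
            continue
        j = i
        while j + 1 < nc and is_osc[j + 1] and df["peak"].iat[j + 1] == df["next_peak"].iat[j]:
            j += 1
        run = j - i + 1
        if run >= min_cycles:
            start = int(df["peak"].iat[i])
            end = int(df["next_peak"].iat[j])
            duration = (end - start) / fs
            bout = OscillationBout(
                start=start, end=end, n_cycles=run, frequency=run / duration
            )
            df.loc[df.index[i : j + 1], "bout_id"] = len(bouts)
            bouts.append(bout)
        else:
            df.loc[df.index[i : j + 1], "is_oscillatory"] = False
        i = j + 1
    df = df.drop(columns=["decay_amp", "rise_amp"])
    return df, bouts


def oscillation_summary(
    bouts: list[OscillationBout], duration_samples: int, fs: float
) -> dict:
    """Occupancy fraction, integer mode frequency and 0.5 Hz histogram."""
    occupied = sum(b.duration_samples for b in bouts)
    occupancy = occupied / duration_samples if duration_samples else 0.0
    edges = np.arange(0.75, 10.76, 0.5)  # bins centred on 1.0, 1.5, ..., 10.5
    if not bouts:
        return {
            "occupancy": 0.0,
            "mode_frequency": None,
            "hist_edges": edges,
            "hist": np.zeros(edges.size - 1),
        }
    freqs = np.array([b.frequency for b in bouts])
    rounded = np.clip(np.round(freqs).astype(int), 1, 10)
    mode = int(np.bincount(rounded).argmax())
    hist, _ = np.histogram(freqs, bins=edges)
    total = hist.sum()
    hist = hist / total if total else hist.astype(float)
    return {
        "occupancy": float(occupancy),
        "mode_frequency": mode,
        "hist_edges": edges,
        "hist": hist,
    }


def flag_spikes_in_oscillation(
    spike_table: pd.DataFrame, bouts: list[OscillationBout]
) -> pd.DataFrame:
    """Add an ``in_oscillation`` flag (half-open bout intervals [start, end))."""
    out = spike_table.copy()
    samples = out["sample"].to_numpy()
    flag = np.zeros(samples.size, dtype=bool)
    for b in bouts:
        flag |= (samples >= b.start) & (samples < b.end)
    out["in_oscillation"] = flag
    return out
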