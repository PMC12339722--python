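"""LFP conditioning ahead of phase estimation.

Order of operations in the standard pipeline: subtract each unit's mean
spike waveform from the raw trace, resample to 2 kHz, band-stop the
50 Hz line and its harmonics, demean, then detect interictal
epileptiform discharge (IED)-like artifacts whose intervals are masked
out of every downstream statistic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from fractions import Fraction

import numpy as np
from scipy import signal

logger = logging.getLogger(__name__)

__all__ = [
    "LfpTrace",
    "ArtifactMask",
    "subtract_spike_waveforms",
    "compute_mean_waveforms",
    "resample_trace",
    "remove_line_noise",
    "demean",
    "detect_ieds",
]


@dataclass
class LfpTrace:
    """A single microwire LFP trace in microvolts."""

    samples: np.ndarray
    fs: float
    wire_id: str = ""
    region: str = ""

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=float)
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("LFP samples must be finite")

    @property
    def n_samples(self) -> int:
        return self.samples.size

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    def copy_with(self, samples: np.ndarray) -> "LfpTrace":
        return LfpTrace(samples=samples, fs=self.fs, wire_id=self.wire_id, region=self.region)


@dataclass
class ArtifactMask:
    """Sorted, disjoint half-open sample intervals flagged as artifact."""

    intervals: list = field(default_factory=list)
    fs: float = 2000.0

    def __post_init__(self):
        self.intervals = merge_intervals(self.intervals)

    @property
    def total_masked_s(self) -> float:
        return sum(b - a for a, b in self.intervals) / self.fs

    def contains(self, samples) -> np.ndarray:
        """Boolean array: which of the given sample indices fall in a masked interval."""
        s = np.asarray(samples)
        out = np.zeros(s.shape, dtype=bool)
        for a, b in self.intervals:
            out |= (s >= a) & (s < b)
        return out

    def overlaps(self, start: int, end: int) -> bool:
        return any(a < end and start < b for a, b in self.intervals)


def merge_intervals(intervals) -> list:
    """Sort and merge half-open intervals; idempotent."""
    ivs = sorted((int(a), int(b)) for a, b in intervals if b > a)
    merged: list[tuple[int, int]] = []
    for a, b in ivs:
        if merged and a <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], b))
        else:
            merged.append((a, b))
    return merged


def _taper_waveform(wf: np.ndarray, frac: float = 0.1) -> np.ndarray:
    """Linear ramp of the first/last ``frac`` of the snippet to zero."""
    wf = np.asarray(wf, dtype=float).copy()
    k = max(1, int(round(frac * wf.size)))
    ramp = np.linspace(0.0, 1.0, k + 1)[1:]
    wf[:k] *= ramp
    wf[-k:] *= ramp[::-1]
    return wf


def compute_mean_waveforms(
    lfp: LfpTrace, spike_times_per_unit: dict, window_s: float = 0.004
) -> dict:
    """Mean spike waveform per unit from the 100-3000 Hz band-passed trace.

    The window is centred on each spike; spikes too close to the trace
    edges are skipped.
    """
    ny = lfp.fs / 2.0
    hi = min(3000.0, 0.95 * ny)
    sos = signal.butter(4, [100.0, hi], btype="bandpass", fs=lfp.fs, output="sos")
    bp = signal.sosfiltfilt(sos, lfp.samples)
    half = int(round(window_s * lfp.fs / 2))
    out = {}
    for unit, times in spike_times_per_unit.items():
        idx = np.round(np.asarray(times) * lfp.fs).astype(int)
        idx = idx[(idx - half >= 0) & (idx + half < lfp.n_samples)]
        if idx.size == 0:
            out[unit] = np.zeros(2 * half)
            continue
        snippets = np.stack([bp[i - half : i + half] for i in idx])
        out[unit] = snippets.mean(axis=0)
    return out


def subtract_spike_waveforms(
    lfp: LfpTrace,
    spike_times_per_unit: dict,
    mean_waveforms: dict,
    taper_frac: float = 0.1,
) -> LfpTrace:
    """Subtract each unit's mean waveform at its spike times.

    Waveform edges are linearly tapered to zero to avoid step
    artifacts; subtraction is additive across units so overlapping
    spikes of different units are handled order-independently. Spikes
    whose window extends past the trace are skipped with a warning.
    """
    y = lfp.samples.copy()
    n = y.size
    for unit, times in spike_times_per_unit.items():
        wf = _taper_waveform(mean_waveforms[unit], taper_frac)
        if wf.size >= int(0.005 * lfp.fs):
            raise ValueError("waveform longer than 5 ms of samples")
        half = wf.size // 2
        idx = np.round(np.asarray(times) * lfp.fs).astype(int)
        skipped = 0
        for i in idx:
            a, b = i - half, i - half + wf.size
            if a < 0 or b > n:
                skipped += 1
                continue
            y[a:b] -= wf
        if skipped:
            logger.warning("unit %s: skipped %d spikes beyond trace edges", unit, skipped)
    return lfp.copy_with(y)


def resample_trace(lfp: LfpTrace, target_fs: float = 2000.0) -> LfpTrace:
    """Polyphase antialiased resampling (downsampling only)."""
    if target_fs > lfp.fs:
        raise ValueError("upsampling not supported")
    if target_fs == lfp.fs:
        return lfp.copy_with(lfp.samples.copy())
    frac = Fraction(target_fs / lfp.fs).limit_denominator(10000)
    y = signal.resample_poly(lfp.samples, frac.numerator, frac.denominator)
    return LfpTrace(samples=y, fs=target_fs, wire_id=lfp.wire_id, region=lfp.region)


def remove_line_noise(
    lfp: LfpTrace,
    stop_bands=((48.0, 52.0), (98.0, 102.0), (148.0, 152.0)),
) -> LfpTrace:
    """Zero-phase FIR band-stop at the line frequency and harmonics.

    Contract: >= 30 dB attenuation at the band centres, < 1 dB ripple
    below 40 Hz, zero phase shift (theta features undelayed). Bands
    above Nyquist are skipped.
    """
    if lfp.fs <= 320:
        raise ValueError("sampling rate too low for line-noise removal")
    ny = lfp.fs / 2.0
    y = lfp.samples.copy()
    ntaps = int(lfp.fs) | 1  # odd tap count, order ~ fs
    delay = ntaps // 2
    for lo, hi in stop_bands:
        if hi >= ny:
            continue
        taps = signal.firwin(ntaps, [lo, hi], fs=lfp.fs)  # pass_zero -> band-stop
        pad = np.r_[y[delay:0:-1], y, y[-2 : -delay - 2 : -1]]
        y = signal.fftconvolve(pad, taps, mode="full")[2 * delay : 2 * delay + y.size]
    # anchor the output mean at zero so band-stop filtering and
    # demeaning commute exactly regardless of edge effects
    return lfp.copy_with(y - y.mean())


def demean(lfp: LfpTrace) -> LfpTrace:
    """Centre the trace around zero."""
    return lfp.copy_with(lfp.samples - lfp.samples.mean())


def _robust_z(x: np.ndarray) -> np.ndarray:
    med = np.median(x)
    mad = np.median(np.abs(x - med)) * 1.4826
    if mad == 0:
        mad = np.std(x) or 1.0
    return (x - med) / mad


def detect_ieds(
    lfp: LfpTrace,
    amp_thresh: float = 6.0,
    grad_thresh: float = 6.0,
    power_thresh: float = 5.0,
    pad_s: float = 0.25,
) -> ArtifactMask:
    """Flag IED-like transients by an OR of three robust z-scores.

    A sample is flagged if any of (a) the amplitude envelope, (b) the
    absolute first difference, or (c) the mean 25-80 Hz band power in a
    100 ms window exceeds its threshold in robust (median/MAD) z units.
    The band power is z-scored on a log10 scale — its raw distribution
    is so right-skewed that a MAD-based z fires constantly on clean
    noise. Flagged samples are padded by +/-``pad_s`` and merged into
    half-open intervals.
    """
    x = lfp.samples
    fs = lfp.fs
    if x.size < fs:
        raise ValueError("trace shorter than 1 s")

    envelope = np.abs(signal.hilbert(x))
    # z-score the signed difference: folding first would shrink the
    # robust scale and turn the threshold into an effective ~4 sigma
    grad_z = np.abs(_robust_z(np.diff(x, prepend=x[0])))
    hi = min(80.0, 0.45 * fs)
    sos = signal.butter(4, [25.0, hi], btype="bandpass", fs=fs, output="sos")
    bb = signal.sosfiltfilt(sos, x) ** 2
    win = max(1, int(round(0.1 * fs)))
    kernel = np.ones(win) / win
    bb_power = signal.fftconvolve(bb, kernel, mode="same")

    flagged = (
        (_robust_z(envelope) > amp_thresh)
        | (grad_z > grad_thresh)
        | (_robust_z(np.log10(bb_power + 1e-300)) > power_thresh)
    )
    if not flagged.any():
        return ArtifactMask(intervals=[], fs=fs)

    pad = int(round(pad_s * fs))
    idx = np.flatnonzero(flagged)
    starts = np.maximum(idx - pad, 0)
    ends = np.minimum(idx + pad + 1, x.size)
    mask = ArtifactMask(intervals=list(zip(starts, ends)), fs=fs)
    logger.info(
        "IED detector: %d intervals, %.2f s masked", len(mask.intervals), mask.total_masked_s
    )
    return mask
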