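"""Broadband (1-10 Hz) generalized phase estimation and spike annotation.

The phase estimate is the angle of the analytic signal of the 1-10 Hz
filtered LFP (convention: phase 0 at signal peaks, +/-pi at troughs).
Epochs in which the instantaneous frequency of the unwrapped phase
drops below a cutoff (default 1 Hz, including negative frequencies
where phase progression reverses) are treated as intrusions from
outside the band: their phase values are removed and replaced by
shape-preserving piecewise cubic (PCHIP) interpolation through the
neighbouring valid samples, then rewrapped. The interpolation mask
records exactly which samples were replaced.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal
from scipy.interpolate import PchipInterpolator

from .preprocess import ArtifactMask, LfpTrace

logger = logging.getLogger(__name__)

__all__ = ["PhaseSeries", "bandpass_theta", "generalized_phase", "assign_spikes"]


@dataclass
class PhaseSeries:
    """Per-sample generalized phase, analytic magnitude and power."""

    phase: np.ndarray  # radians in (-pi, pi]
    magnitude: np.ndarray  # uV
    power: np.ndarray  # uV^2 (= magnitude**2)
    interp_mask: np.ndarray  # True where phase was replaced by interpolation
    fs: float

    @property
    def n_samples(self) -> int:
        return self.phase.size

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs


def bandpass_theta(
    lfp: LfpTrace, lo: float = 1.0, hi: float = 10.0, order: int = 6000
) -> LfpTrace:
    """Zero-phase FIR band-pass in the broad theta range.

    ``order`` is specified at fs = 2 kHz and scaled proportionally for
    other sampling rates. The linear-phase FIR is applied by FFT
    convolution with the constant group delay compensated, so filtered
    theta features stay aligned with the raw trace; DC is rejected by
    the pass-band lower edge.
    """
    fs = lfp.fs
    ntaps = int(round(order * fs / 2000.0))
    ntaps += ntaps % 2  # even order -> odd tap count -> integer delay
    x = np.asarray(lfp.samples, dtype=float)
    if x.size < 3 * (ntaps + 1):
        raise ValueError("trace shorter than 3x the filter length")
    taps = signal.firwin(ntaps + 1, [lo, hi], pass_zero=False, fs=fs)
    delay = ntaps // 2
    y = signal.fftconvolve(x, taps, mode="full")[delay : delay + x.size]
    return LfpTrace(samples=y, fs=fs, wire_id=lfp.wire_id, region=lfp.region)


def generalized_phase(
    filtered: LfpTrace | np.ndarray,
    fs: float | None = None,
    min_freq: float = 1.0,
) -> PhaseSeries:
    """Generalized phase of a broadband-filtered, zero-centred trace.

    Steps: analytic signal via the Hilbert transform (single pass over
    the full trace); instantaneous frequency as the centred difference
    of the unwrapped phase divided by 2*pi (forward/backward
    differences at the edges); samples whose frequency falls below
    ``min_freq`` (including negative frequencies) are removed from the
    unwrapped phase and refilled by PCHIP interpolation through the
    surrounding valid samples, then rewrapped to (-pi, pi].

    Runs of invalid samples touching a trace boundary have no anchor on
    one side; there the nearest valid unwrapped-phase trend is extended
    linearly. Power is the squared magnitude of the analytic signal.
    """
    if isinstance(filtered, LfpTrace):
        x = np.asarray(filtered.samples, dtype=float)
        fs = filtered.fs
    else:
        x = np.asarray(filtered, dtype=float)
        if fs is None:
            raise ValueError("fs required when passing a bare array")
    if x.size == 0 or np.allclose(x, 0.0):
        raise ValueError("all-zero input: phase undefined")

    analytic = signal.hilbert(x)
    magnitude = np.abs(analytic)
    power = magnitude**2
    phase = np.angle(analytic)

    unwrapped = np.unwrap(phase)
    freq = np.empty_like(unwrapped)
    freq[1:-1] = (unwrapped[2:] - unwrapped[:-2]) * fs / (4.0 * np.pi)
    freq[0] = (unwrapped[1] - unwrapped[0]) * fs / (2.0 * np.pi)
    freq[-1] = (unwrapped[-1] - unwrapped[-2]) * fs / (2.0 * np.pi)

    bad = freq < min_freq
    interp_mask = bad.copy()
    if bad.any() and not bad.all():
        idx = np.arange(x.size)
        good = ~bad
        interp = PchipInterpolator(idx[good], unwrapped[good], extrapolate=False)
        filled = unwrapped.copy()
        filled[bad] = interp(idx[bad])
        # boundary runs: extend the nearest valid trend linearly
        nan_left = bad & (idx < idx[good][0])
        nan_right = bad & (idx > idx[good][-1])
        if nan_left.any():
            g0, g1 = idx[good][0], idx[good][min(1, good.sum() - 1)]
            slope = (unwrapped[g1] - unwrapped[g0]) / max(g1 - g0, 1)
            filled[nan_left] = unwrapped[g0] + slope * (idx[nan_left] - g0)
        if nan_right.any():
            g0, g1 = idx[good][max(-2, -good.sum())], idx[good][-1]
            slope = (unwrapped[g1] - unwrapped[g0]) / max(g1 - g0, 1)
            filled[nan_right] = unwrapped[g1] + slope * (idx[nan_right] - g1)
        new_phase = np.angle(np.exp(1j * filled))
        phase = np.where(bad, new_phase, phase)
    elif bad.all():
        logger.warning("every sample below the frequency cutoff; phase left as-is")

    return PhaseSeries(
        phase=phase, magnitude=magnitude, power=power, interp_mask=interp_mask, fs=fs
    )


def assign_spikes(
    spike_times,
    phase_series: PhaseSeries,
    artifact_mask: ArtifactMask | None = None,
) -> pd.DataFrame:
    """Annotate each spike with the temporally closest phase and power.

    Spikes map to the nearest sample (exact midpoints go to the earlier
    sample); spikes inside artifact intervals or outside the trace are
    dropped, with the dropped counts logged. Returns one row per
    retained spike with columns ``time, sample, phase, power,
    log_power`` ready for downstream condition labelling.
    """
    t = np.asarray(spike_times, dtype=float)
    fs = phase_series.fs
    n = phase_series.n_samples
    # nearest sample; ties (exact .5) resolve to the earlier sample —
    # the 1e-9-sample guard absorbs float noise in t * fs at the boundary
    samples = np.floor(t * fs + 0.5 - 1e-9).astype(np.int64)
    inside = (samples >= 0) & (samples < n)
    n_outside = int((~inside).sum())
    if n_outside:
        logger.info("dropped %d spikes outside the trace", n_outside)
    t, samples = t[inside], samples[inside]

    if artifact_mask is not None and len(artifact_mask.intervals) > 0:
        in_artifact = artifact_mask.contains(samples)
        n_art = int(in_artifact.sum())
        if n_art:
            logger.info("dropped %d spikes inside artifact intervals", n_art)
        t, samples = t[~in_artifact], samples[~in_artifact]

    power = phase_series.power[samples]
    with np.errstate(divide="ignore"):
        log_power = np.log10(power)
    return pd.DataFrame(
        {
            "time": t,
            "sample": samples,
            "phase": phase_series.phase[samples],
            "power": power,
            "log_power": log_power,
        }
    )
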