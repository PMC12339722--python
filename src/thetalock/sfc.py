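"""Frequency-resolved spike-field coherence (SFC).

SFC(f) is the percentage of the power spectrum of the spike-triggered
average (STA) relative to the mean power spectrum of the individual
spike-centred LFP segments, so it lies in [0, 100] at every frequency.
Segments are 1 s of the cleaned 2 kHz trace centred on each spike,
resampled to 250 Hz; numerator and denominator spectra use the same
multitaper estimate (Slepian tapers, 4 Hz smoothing, 7 tapers) at
1-100 Hz in 1 Hz steps. Condition contrasts equalise spike counts by
repeated random subsampling of the larger condition.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import signal

from .preprocess import LfpTrace

logger = logging.getLogger(__name__)

__all__ = [
    "SfcSpectrum",
    "spike_triggered_segments",
    "sfc_spectrum",
    "matched_subsample_contrast",
]

SFC_FREQS = np.arange(1.0, 101.0)  # Hz
_SEG_FS = 250.0
_SEG_LEN = 251  # 1 s at 250 Hz, centre sample included
_NW = 4.0  # time-bandwidth: 1 s window x 4 Hz smoothing
_N_TAPERS = 7  # 2*NW - 1
_NFFT = 2500  # zero-padded length -> 0.1 Hz grid, exact 1 Hz bins


@dataclass
class SfcSpectrum:
    frequencies: np.ndarray
    sfc: np.ndarray  # percent, in [0, 100]
    n_spikes: int
    n_subsamples: int = 1


def spike_triggered_segments(
    lfp: LfpTrace, spike_times, halfwin_s: float = 0.5
) -> np.ndarray:
    """Spike-centred 1-s LFP segments resampled to 250 Hz.

    Spikes closer than ``halfwin_s`` to either trace end are dropped
    (and counted in the log) rather than reflected.
    """
    t = np.asarray(spike_times, dtype=float)
    fs = lfp.fs
    half = int(round(halfwin_s * fs))
    centre = np.round(t * fs).astype(int)
    ok = (centre - half >= 0) & (centre + half < lfp.n_samples)
    dropped = int((~ok).sum())
    if dropped:
        logger.info("dropped %d spikes within %.0f ms of trace edges", dropped, halfwin_s * 1e3)
    centre = centre[ok]
    if centre.size == 0:
        raise ValueError("no usable spikes")
    raw = np.stack([lfp.samples[c - half : c + half + 1] for c in centre])
    down = int(round(fs / _SEG_FS))
    segs = signal.resample_poly(raw, 1, down, axis=1)
    # resample_poly(2*half+1 samples, 1/down) -> ceil((2*half+1)/down) = 251 at 2 kHz
    return segs[:, :_SEG_LEN]


def _multitaper_power(x: np.ndarray) -> np.ndarray:
    """Multitaper power of each row at the SFC frequency grid."""
    n = x.shape[-1]
    tapers = signal.windows.dpss(n, _NW, Kmax=_N_TAPERS)
    # (rows, tapers, samples)
    tapered = x[:, None, :] * tapers[None, :, :]
    fx = np.fft.rfft(tapered, n=_NFFT, axis=-1)
    power = (np.abs(fx) ** 2).mean(axis=1)
    bin_idx = np.round(SFC_FREQS * _NFFT / _SEG_FS).astype(int)
    return power[:, bin_idx]


def sfc_spectrum(segments: np.ndarray) -> SfcSpectrum:
    """SFC(f) = 100 * P_STA(f) / mean_i P_i(f)."""
    segs = np.atleast_2d(np.asarray(segments, dtype=float))
    if segs.shape[0] < 2:
        raise ValueError("need at least two segments")
    sta = segs.mean(axis=0, keepdims=True)
    p_sta = _multitaper_power(sta)[0]
    p_mean = _multitaper_power(segs).mean(axis=0)
    if np.any(p_mean <= 0):
        raise ValueError("degenerate LFP: zero power in a frequency bin")
    sfc = 100.0 * p_sta / p_mean
    return SfcSpectrum(
        frequencies=SFC_FREQS.copy(),
        sfc=np.clip(sfc, 0.0, 100.0),
        n_spikes=segs.shape[0],
    )


def matched_subsample_contrast(
    segments_a: np.ndarray,
    segments_b: np.ndarray,
    n_rep: int = 100,
    rng=None,
) -> tuple[SfcSpectrum, SfcSpectrum]:
    """Equal-spike-count SFC spectra for two conditions.

    The condition with more spikes is subsampled (without replacement)
    to the smaller condition's count; the SFC is recomputed for each of
    ``n_rep`` subsamples and averaged. The smaller condition's SFC is
    computed once at its full size.
    """
    rng = np.random.default_rng(rng)
    a = np.atleast_2d(segments_a)
    b = np.atleast_2d(segments_b)
    na, nb = a.shape[0], b.shape[0]
    n_min = min(na, nb)

    def _mean_subsampled(segs):
        if segs.shape[0] == n_min:
            out = sfc_spectrum(segs)
            out.n_subsamples = 1
            return out
        acc = np.zeros(SFC_FREQS.size)
        for _ in range(n_rep):
            pick = rng.choice(segs.shape[0], size=n_min, replace=False)
            acc += sfc_spectrum(segs[pick]).sfc
        return SfcSpectrum(
            frequencies=SFC_FREQS.copy(),
            sfc=acc / n_rep,
            n_spikes=n_min,
            n_subsamples=n_rep,
        )

    return _mean_subsampled(a), _mean_subsampled(b)
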