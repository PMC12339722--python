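"""Time-resolved parameterization of the LFP power spectrum.

Short-time Fourier spectra (1-s Hann windows, 50% overlap) are averaged
in groups of five, yielding one spectral frame every 500 ms that spans
3 s of signal. Each frame's 1-40 Hz spectrum is decomposed into an
aperiodic component ``log10 P(f) = b - chi * log10 f`` (offset b,
exponent chi; the log-log slope is -chi) plus up to three Gaussian
peaks. Frames overlapping artifact intervals are marked invalid and
excluded, and spikes inherit the exponent of the 500-ms step that
contains them.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, signal, stats

from .preprocess import ArtifactMask, LfpTrace

logger = logging.getLogger(__name__)

__all__ = [
    "SpectralPeak",
    "SpectralFrame",
    "average_spectrum",
    "timefreq_spectra",
    "fit_aperiodic",
    "fit_peaks",
    "fit_frames",
    "assign_spike_slopes",
    "slope_frequency_correlation",
]

FREQS = np.arange(1.0, 41.0)  # 1-40 Hz at 1 Hz resolution


@dataclass
class SpectralPeak:
    center: float  # Hz
    height: float  # log10 power above the aperiodic fit
    width: float  # Hz (Gaussian SD)


@dataclass
class SpectralFrame:
    """One 3-s spectral estimate centred every 500 ms."""

    time: float  # centre time, s
    spectrum: np.ndarray  # power at FREQS
    valid: bool = True
    offset: float = np.nan
    exponent: float = np.nan
    error: float = np.nan
    peaks: list = field(default_factory=list)


def timefreq_spectra(
    lfp: LfpTrace, artifact_mask: ArtifactMask | None = None
) -> list[SpectralFrame]:
    """Stream of averaged short-time spectra.

    Hann-tapered 1-s windows with 50% overlap; each frame averages five
    consecutive window spectra and steps by 500 ms, so a frame spans
    3 s. Frames whose span overlaps an artifact interval are invalid.
    """
    fs = lfp.fs
    nper = int(round(fs))
    if lfp.n_samples < 3 * nper:
        raise ValueError("trace shorter than 3 s")
    step = nper // 2
    x = lfp.samples
    n_windows = (lfp.n_samples - nper) // step + 1
    window = np.hanning(nper)
    scale = 1.0 / (fs * (window**2).sum())
    freq_idx = FREQS.astype(int)  # rfft bin k = k Hz for a 1-s window

    # window spectra at the 1-40 Hz bins only
    specs = np.empty((n_windows, FREQS.size))
    for w in range(n_windows):
        seg = x[w * step : w * step + nper] * window
        fx = np.fft.rfft(seg)
        specs[w] = (np.abs(fx[freq_idx]) ** 2) * 2.0 * scale

    frames: list[SpectralFrame] = []
    for k in range(n_windows - 4):
        start = k * step
        end = start + 3 * nper
        centre = (start + end) / 2.0 / fs
        valid = True
        if artifact_mask is not None and artifact_mask.overlaps(start, end):
            valid = False
        frames.append(
            SpectralFrame(time=centre, spectrum=specs[k : k + 5].mean(axis=0), valid=valid)
        )
    return frames


def average_spectrum(lfp: LfpTrace, nperseg_s: float = 8.0) -> np.ndarray:
    """Session-average power spectrum at the 1-40 Hz / 1 Hz grid.

    Uses Welch segments long enough (default 8 s) that mainlobe leakage
    from the steep sub-1 Hz part of the spectrum does not bias the
    lowest bins — the short (1-s) windows of the time-resolved frames
    slightly steepen apparent slopes for exponents near 2.
    """
    nper = int(round(nperseg_s * lfp.fs))
    f, p = signal.welch(lfp.samples, fs=lfp.fs, nperseg=nper)
    idx = np.round(FREQS / (f[1] - f[0])).astype(int)
    return p[idx]


def fit_aperiodic(spectrum, freqs=FREQS) -> tuple[float, float, float]:
    """Robust power-law fit of the 1-40 Hz spectrum in log-log space.

    Initial least squares of log10 P on log10 f, then a refit using
    only the points whose residuals lie in the lower half — peaks sit
    above the aperiodic line, so this suppresses their contamination.
    Returns (offset b, exponent chi, RMS error in log10 units).
    """
    p = np.asarray(spectrum, dtype=float)
    if np.any(p <= 0) or not np.all(np.isfinite(p)):
        raise ValueError("spectrum must be strictly positive and finite")
    lf = np.log10(np.asarray(freqs, dtype=float))
    lp = np.log10(p)
    slope, intercept = np.polyfit(lf, lp, 1)
    resid = lp - (intercept + slope * lf)
    keep = resid <= np.median(resid)
    if keep.sum() >= 2:
        slope, intercept = np.polyfit(lf[keep], lp[keep], 1)
    rms = float(np.sqrt(np.mean((lp - (intercept + slope * lf)) ** 2)))
    return float(intercept), float(-slope), rms


def _gauss(f, center, height, sd):
    return height * np.exp(-0.5 * ((f - center) / sd) ** 2)


def fit_peaks(
    spectrum,
    aperiodic: tuple[float, float],
    freqs=FREQS,
    max_peaks: int = 3,
    snr_min: float = 2.0,
    height_min: float = 0.5,
    width_range: tuple[float, float] = (2.0, 6.0),
    proximity_sd: float = 1.0,
) -> list[SpectralPeak]:
    """Iterative Gaussian peak extraction from the flattened spectrum.

    Peaks are pulled out largest-residual-first from
    ``log10 P - (b - chi log10 f)``; each candidate must clear the
    height floor, an SNR floor (height over the SD of the flattened
    residual), and the width bounds. A peak is then discarded if its
    centre lies within ``proximity_sd`` of its own SD from a larger
    peak's centre or from the frequency-range edges.
    """
    b, chi = aperiodic
    f = np.asarray(freqs, dtype=float)
    flat = np.log10(np.asarray(spectrum, dtype=float)) - (b - chi * np.log10(f))
    work = flat.copy()
    candidates: list[SpectralPeak] = []
    for _ in range(max_peaks):
        i = int(np.argmax(work))
        height_guess = work[i]
        if height_guess <= height_min:
            break
        # half-height extent as width guess
        half = height_guess / 2.0
        lo = i
        while lo > 0 and work[lo] > half:
            lo -= 1
        hi = i
        while hi < work.size - 1 and work[hi] > half:
            hi += 1
        fwhm = max(f[hi] - f[lo], 1.0)
        sd_guess = float(np.clip(fwhm / 2.355, *width_range))
        try:
            popt, _ = optimize.curve_fit(
                _gauss,
                f,
                work,
                p0=[f[i], height_guess, sd_guess],
                bounds=([f[0], 0.0, width_range[0]], [f[-1], np.inf, width_range[1]]),
                maxfev=2000,
            )
        except RuntimeError:
            break
        peak = SpectralPeak(center=float(popt[0]), height=float(popt[1]), width=float(popt[2]))
        work = work - _gauss(f, *popt)
        candidates.append(peak)

    resid_sd = float(np.std(work))
    kept: list[SpectralPeak] = []
    for pk in sorted(candidates, key=lambda q: -q.height):
        if pk.height <= height_min:
            continue
        if resid_sd > 0 and pk.height / resid_sd <= snr_min:
            continue
        if pk.center - f[0] < proximity_sd * pk.width:
            continue
        if f[-1] - pk.center < proximity_sd * pk.width:
            continue
        if any(abs(pk.center - q.center) < proximity_sd * pk.width for q in kept):
            continue  # too close to a relatively larger peak
        kept.append(pk)
    return kept[:max_peaks]


def fit_frames(frames: list[SpectralFrame]) -> list[SpectralFrame]:
    """Fit aperiodic + peak parameters in place for every valid frame."""
    for fr in frames:
        if not fr.valid:
            continue
        if np.any(fr.spectrum <= 0):
            fr.valid = False
            continue
        fr.offset, fr.exponent, fr.error = fit_aperiodic(fr.spectrum)
        fr.peaks = fit_peaks(fr.spectrum, (fr.offset, fr.exponent))
    return frames


def frames_to_table(frames: list[SpectralFrame]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "time": [fr.time for fr in frames],
            "valid": [fr.valid for fr in frames],
            "offset": [fr.offset for fr in frames],
            "exponent": [fr.exponent for fr in frames],
            "error": [fr.error for fr in frames],
            "n_peaks": [len(fr.peaks) for fr in frames],
        }
    )


def _frame_index(times: np.ndarray, frames: list[SpectralFrame]) -> np.ndarray:
    """Index of the frame whose 500-ms step contains each time (or -1)."""
    t0 = frames[0].time
    step = 0.5
    idx = np.round((np.asarray(times) - t0) / step).astype(int)
    idx[(idx < 0) | (idx >= len(frames))] = -1
    return idx


def assign_spike_slopes(
    spike_table: pd.DataFrame, frames: list[SpectralFrame]
) -> pd.DataFrame:
    """Annotate each spike with the aperiodic exponent of its 500-ms step.

    Spikes falling in invalid frames (or outside the framed part of the
    trace) get NaN and are excluded from slope-conditioned analyses.
    """
    out = spike_table.copy()
    if not frames:
        out["slope"] = np.nan
        return out
    idx = _frame_index(out["time"].to_numpy(), frames)
    slopes = np.full(idx.size, np.nan)
    exps = np.array([fr.exponent if fr.valid else np.nan for fr in frames])
    ok = idx >= 0
    slopes[ok] = exps[idx[ok]]
    out["slope"] = slopes
    return out


def slope_frequency_correlation(
    sessions: list[dict],
) -> tuple[pd.DataFrame, float, float]:
    """Spearman correlation between aperiodic exponent and cycle frequency.

    ``sessions`` is a list of dicts mapping wire -> (frames, cycle_table,
    fs). Per wire, each valid frame's exponent is paired with the mean
    frequency (1/period) of the cycles whose midpoint falls in the
    frame's 500-ms step; wires with fewer than 3 valid pairs are
    skipped. Per-session mean rho is tested against zero with a
    two-sided one-sample t across sessions.
    """
    rows = []
    for s_idx, wires in enumerate(sessions):
        rhos = []
        for wire, (frames, cycle_table, fs) in wires.items():
            if not frames or cycle_table.empty:
                continue
            mid = (cycle_table["peak"].to_numpy() + cycle_table["next_peak"].to_numpy()) / 2 / fs
            cyc_freq = 1.0 / cycle_table["period"].to_numpy()
            idx = _frame_index(mid, frames)
            exps = np.array([fr.exponent if fr.valid else np.nan for fr in frames])
            pairs_x, pairs_y = [], []
            for k, fr in enumerate(frames):
                if not fr.valid or np.isnan(exps[k]):
                    continue
                sel = idx == k
                if sel.any():
                    pairs_x.append(exps[k])
                    pairs_y.append(cyc_freq[sel].mean())
            if len(pairs_x) < 3:
                logger.info("wire %s skipped: <3 valid frames with cycles", wire)
                continue
            rho, _ = stats.spearmanr(pairs_x, pairs_y)
            rhos.append(rho)
        if rhos:
            rows.append({"session": s_idx, "mean_rho": float(np.mean(rhos)), "n_wires": len(rhos)})
    table = pd.DataFrame(rows)
    if len(table) < 2:
        raise ValueError("group test requires >= 2 sessions with valid wires")
    t, p = stats.ttest_1samp(table["mean_rho"], 0.0)
    return table, float(t), float(p)
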