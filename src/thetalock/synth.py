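"""Synthetic session generator with known ground truth.

Emulates the structure of a human single-neuron spatial-memory session:
pink-noise LFP carrying transient theta bursts of drifting frequency
(1-10 Hz), 50 Hz line noise with optional harmonics, optional IED-like
transients, spike trains that are von-Mises phase-locked to the LFP's
generalized phase (with condition-dependent preferred phases), Poisson,
or theta-resonant-but-field-independent, plus a trial table of
encoding / distractor / recall segments with improving memory
performance. Every random draw flows from a single integer seed
through spawned substreams (one per wire, unit and behavioral table),
so identical configs reproduce bit-identical sessions.

The generator is deliberately simple where the real data are not:
additive non-overlapping bursts, white trial structure, no correlated
noise between wires. Its purpose is parameter recovery, not biophysics.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .behavior import Arena
from .gphase import PhaseSeries, bandpass_theta, generalized_phase
from .preprocess import LfpTrace

__all__ = [
    "UnitSpec",
    "SynthConfig",
    "GroundTruth",
    "SynthSession",
    "gen_pink_noise",
    "gen_theta_bursts",
    "gen_spikes_phase_locked",
    "gen_spikes_resonant",
    "gen_session",
    "make_waveform_template",
]


@dataclass
class UnitSpec:
    """Ground-truth description of one synthetic unit."""

    mode: str = "locked"  # locked | poisson | resonant
    base_rate: float = 2.0  # Hz
    kappa: float = 2.0  # von Mises concentration (locked mode)
    mu_encoding: float = np.pi  # preferred phase during encoding, rad
    mu_retrieval: float = np.pi  # preferred phase during retrieval, rad
    lock_only_in_bursts: bool = False
    resonance_freq: float = 4.0  # Hz (resonant mode)
    wire: int = 0
    waveform_template: np.ndarray | None = None

    def __post_init__(self):
        if self.mode not in ("locked", "poisson", "resonant"):
            raise ValueError(f"unknown unit mode {self.mode!r}")
        if self.base_rate <= 0:
            raise ValueError("base_rate must be positive")
        if self.kappa < 0:
            raise ValueError("kappa must be non-negative")
        for mu in (self.mu_encoding, self.mu_retrieval):
            if not (-np.pi < mu <= np.pi):
                raise ValueError("preferred phases must lie in (-pi, pi]")


@dataclass
class SynthConfig:
    duration_s: float = 600.0
    fs: float = 2000.0
    pink_exponent: float = 1.0  # chi: power ~ f^-chi
    noise_sd_uv: float = 10.0
    line_noise_amp: float = 0.0  # uV at 50 Hz
    line_harmonics: bool = False
    # ~14 bursts/min of 4-12 cycles at 3-8 Hz occupies ~38% of the
    # trace, matching the fraction of time theta oscillations are
    # typically detected in human MTL microwire recordings
    burst_rate: float = 14.0  # bursts / min
    burst_freq_range: tuple = (3.0, 8.0)  # Hz, within [1, 10]
    burst_cycles_range: tuple = (4, 12)
    burst_snr: float = 2.0  # burst amplitude / noise SD
    burst_drift_hz: float = 0.0  # peak-to-peak linear frequency drift
    ied_rate: float = 0.0  # events / min
    units: list = field(default_factory=list)
    n_trials: int = 20
    success_p_start: float = 0.4
    success_p_end: float = 0.8
    arena: Arena = field(default_factory=Arena)
    seed: int = 0

    def __post_init__(self):
        if self.duration_s <= 0:
            raise ValueError("duration_s must be positive")
        if self.fs < 1000:
            raise ValueError("fs must be >= 1000 Hz")
        lo, hi = self.burst_freq_range
        if not (1.0 <= lo <= hi <= 10.0):
            raise ValueError("burst_freq_range must lie within [1, 10] Hz")
        for name in ("burst_rate", "ied_rate"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


@dataclass
class GroundTruth:
    burst_intervals: dict = field(default_factory=dict)  # wire -> [(start, end)]
    burst_frequencies: dict = field(default_factory=dict)  # wire -> [Hz]
    ied_intervals: dict = field(default_factory=dict)  # wire -> [(start, end)]
    unit_specs: list = field(default_factory=list)
    segment_success: dict = field(default_factory=dict)  # segment_id -> bool


@dataclass
class SynthSession:
    config: SynthConfig
    lfp: dict  # wire -> LfpTrace (with spike waveforms embedded)
    clean_lfp: dict  # wire -> LfpTrace before waveform embedding
    phase: dict  # wire -> PhaseSeries of the clean trace
    spike_times: list  # one array per unit
    segments: pd.DataFrame
    behavior: pd.DataFrame
    ground_truth: GroundTruth


def gen_pink_noise(n_samples: int, fs: float, exponent: float, seed) -> np.ndarray:
    """Unit-SD coloured noise via spectral synthesis.

    Random Fourier phases with amplitude proportional to f^(-chi/2)
    give a periodogram whose log-log slope is exactly -chi in
    expectation. Zero mean, SD normalised to 1.
    """
    if n_samples <= 0:
        raise ValueError("n_samples must be positive")
    if exponent < 0:
        raise ValueError("exponent must be non-negative")
    rng = np.random.default_rng(seed)
    freqs = np.fft.rfftfreq(n_samples, d=1.0 / fs)
    amp = np.zeros(freqs.size)
    amp[1:] = freqs[1:] ** (-exponent / 2.0)
    phases = rng.uniform(0, 2 * np.pi, size=freqs.size)
    spectrum = amp * np.exp(1j * phases)
    x = np.fft.irfft(spectrum, n=n_samples)
    x -= x.mean()
    sd = x.std()
    return x / sd if sd > 0 else x


def gen_theta_bursts(
    duration_s: float,
    fs: float,
    freq_range=(3.0, 8.0),
    burst_rate: float = 6.0,
    cycles_range=(4, 12),
    amplitude: float = 1.0,
    drift_hz: float = 0.0,
    seed=None,
) -> tuple[np.ndarray, list]:
    """Additive flat-top sinusoidal bursts, Hann-tapered on and off.

    The burst count is Poisson with mean ``burst_rate * duration_min``;
    each burst has a uniformly drawn frequency and integer cycle count
    and an optional linear frequency drift bounded to stay inside
    [1, 10] Hz. Bursts are rejection-resampled so they never overlap.
    Returns the trace and a list of dicts with exact onset/offset
    samples and frequency.
    """
    lo, hi = freq_range
    if not (1.0 <= lo <= hi <= 10.0):
        raise ValueError("freq_range must lie within [1, 10] Hz")
    if cycles_range[0] < 2:
        raise ValueError("bursts must span at least 2 cycles to be detectable")
    if amplitude <= 0:
        raise ValueError("amplitude must be positive")
    rng = np.random.default_rng(seed)
    n = int(round(duration_s * fs))
    trace = np.zeros(n)
    bursts: list[dict] = []
    if burst_rate == 0:
        return trace, bursts
    n_bursts = rng.poisson(burst_rate * duration_s / 60.0)
    occupied: list[tuple[int, int]] = []
    for _ in range(n_bursts):
        f = rng.uniform(lo, hi)
        n_cycles = int(rng.integers(cycles_range[0], cycles_range[1] + 1))
        dur = n_cycles / f
        length = int(round(dur * fs))
        if length >= n:
            continue
        placed = False
        for _attempt in range(200):
            start = int(rng.integers(0, n - length))
            end = start + length
            if all(end <= a or start >= b for a, b in occupied):
                placed = True
                break
        if not placed:
            continue
        t = np.arange(length) / fs
        if drift_hz > 0:
            f0 = np.clip(f - drift_hz / 2, 1.0, 10.0)
            f1 = np.clip(f + drift_hz / 2, 1.0, 10.0)
            inst_f = f0 + (f1 - f0) * t / dur
            phase = 2 * np.pi * np.cumsum(inst_f) / fs
        else:
            phase = 2 * np.pi * f * t
        # flat-top envelope with Hann on/off ramps over one cycle, so the
        # burst interior keeps its nominal amplitude
        ramp = min(int(round(fs / f)), length // 2)
        envelope = np.ones(length)
        half_hann = np.hanning(2 * ramp)[:ramp]
        envelope[:ramp] = half_hann
        envelope[-ramp:] = half_hann[::-1]
        trace[start:end] += amplitude * envelope * np.cos(phase)
        occupied.append((start, end))
        bursts.append(
            {"start": start, "end": end, "frequency": f, "n_cycles": n_cycles}
        )
    bursts.sort(key=lambda b: b["start"])
    return trace, bursts


def _burst_mask(n: int, bursts: list) -> np.ndarray:
    mask = np.zeros(n, dtype=bool)
    for b in bursts:
        mask[b["start"] : b["end"]] = True
    return mask


def gen_spikes_phase_locked(
    phase_series: PhaseSeries,
    base_rate: float,
    kappa: float,
    mu,
    lock_only_in_bursts: bool = False,
    bursts: list | None = None,
    seed=None,
) -> np.ndarray:
    """Inhomogeneous-Poisson spikes locked to the LFP phase by thinning.

    The intensity is ``base_rate * 2*pi * vonMisesDensity(theta(t); mu,
    kappa)``, i.e. ``base_rate * exp(kappa cos(theta - mu)) / I0(kappa)``;
    with kappa = 0 this reduces exactly to a homogeneous Poisson train
    at ``base_rate``. Under uniform phase occupancy the normalisation
    keeps the mean rate near ``base_rate``. ``mu`` may be a scalar or a
    per-sample array (condition-dependent preferred phase). When
    ``lock_only_in_bursts`` is set, modulation applies inside the given
    bursts only and the rate is ``base_rate`` elsewhere.
    """
    if phase_series.n_samples == 0:
        raise ValueError("empty phase series")
    if kappa < 0:
        raise ValueError("kappa must be non-negative")
    rng = np.random.default_rng(seed)
    fs = phase_series.fs
    n = phase_series.n_samples
    duration = n / fs
    i0 = np.i0(kappa)
    lam_max = base_rate * np.exp(kappa) / i0
    n_cand = rng.poisson(lam_max * duration)
    t_cand = np.sort(rng.uniform(0, duration, size=n_cand))
    idx = np.minimum((t_cand * fs).astype(np.int64), n - 1)
    theta = phase_series.phase[idx]
    mu_arr = np.broadcast_to(np.asarray(mu, dtype=float), (n,)) if np.ndim(mu) else None
    mu_at = mu_arr[idx] if mu_arr is not None else float(mu)
    # acceptance probability lambda(t) / lambda_max
    p_locked = np.exp(kappa * (np.cos(theta - mu_at) - 1.0))
    if lock_only_in_bursts:
        mask = _burst_mask(n, bursts or [])
        in_burst = mask[idx]
        p_flat = i0 / np.exp(kappa)  # base_rate / lambda_max
        p_accept = np.where(in_burst, p_locked, p_flat)
    else:
        p_accept = p_locked
    keep = rng.uniform(size=n_cand) < p_accept
    return t_cand[keep]


def gen_spikes_resonant(
    duration_s: float,
    rate: float,
    resonance_freq: float,
    jitter_sd: float = 0.01,
    seed=None,
) -> np.ndarray:
    """Theta-resonant but field-independent spike train.

    Spikes sit at multiples of ``1/resonance_freq`` with Gaussian
    jitter; random dropout brings the mean rate down to ``rate`` when
    the resonance frequency exceeds it. The train never sees the LFP.
    """
    if not (1.0 <= resonance_freq <= 10.0):
        raise ValueError("resonance_freq must lie in [1, 10] Hz")
    if jitter_sd < 0:
        raise ValueError("jitter_sd must be non-negative")
    rng = np.random.default_rng(seed)
    grid = np.arange(1.0 / resonance_freq, duration_s, 1.0 / resonance_freq)
    keep_p = min(1.0, rate / resonance_freq)
    keep = rng.uniform(size=grid.size) < keep_p
    times = grid[keep]
    if jitter_sd > 0:
        times = times + rng.normal(0, jitter_sd, size=times.size)
    times = np.sort(times[(times >= 0) & (times < duration_s)])
    return times


def make_waveform_template(fs: float, amp_uv: float = 40.0) -> np.ndarray:
    """A simple biphasic extracellular spike shape (~2 ms)."""
    n = max(8, int(round(0.002 * fs)))
    t = np.linspace(0, 1, n)
    wf = -np.sin(2 * np.pi * t) * np.exp(-4 * t)
    return amp_uv * wf / np.max(np.abs(wf))


def _build_segments(cfg: SynthConfig, rng) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Trial timeline (segments) and behavioral outcomes.

    Each trial holds 2-3 encoding events, a ~6.6 s distractor, and one
    recall segment per encoded object; object- and location-recall
    trials alternate. Success probability rises linearly across trials.
    """
    if cfg.n_trials < 2:
        raise ValueError("need at least 2 trials for first/second-half contrasts")
    trial_len = cfg.duration_s / cfg.n_trials
    seg_rows, beh_rows = [], []
    seg_id = 0
    for trial in range(cfg.n_trials):
        t0 = trial * trial_len
        n_obj = int(rng.integers(2, 4))
        enc_dur, enc_gap, rec_dur, rec_gap, distract = 2.5, 1.0, 3.0, 0.5, 6.6
        needed = 1.0 + n_obj * (enc_dur + enc_gap) + distract + n_obj * (rec_dur + rec_gap)
        if needed > trial_len:
            raise ValueError("duration_s too short for the requested trial structure")
        kind = "object" if trial % 2 == 0 else "location"
        p = cfg.success_p_start + (cfg.success_p_end - cfg.success_p_start) * (
            trial / max(cfg.n_trials - 1, 1)
        )
        cursor = t0 + 1.0
        enc_ids = []
        for _ in range(n_obj):
            seg_rows.append(
                dict(segment_id=seg_id, type="encoding", start=cursor,
                     end=cursor + enc_dur, trial=trial)
            )
            enc_ids.append(seg_id)
            seg_id += 1
            cursor += enc_dur + enc_gap
        seg_rows.append(
            dict(segment_id=seg_id, type="distractor", start=cursor,
                 end=cursor + distract, trial=trial)
        )
        seg_id += 1
        cursor += distract
        for k in range(n_obj):
            seg_rows.append(
                dict(segment_id=seg_id, type=f"recall_{kind}", start=cursor,
                     end=cursor + rec_dur, trial=trial)
            )
            success = bool(rng.uniform() < p)
            if kind == "object":
                beh_rows.append(
                    dict(trial=trial, kind="object", correct=success,
                         drop_error=np.nan, normalized=np.nan,
                         encoding_segment=enc_ids[k], recall_segment=seg_id,
                         response_time=rng.uniform(1.0, rec_dur))
                )
            else:
                if success:  # accurate: small Rayleigh-distributed error
                    err = rng.rayleigh(0.05 * cfg.arena.diameter)
                else:  # guess: uniform over the arena
                    true = cfg.arena.sample(1, rng)[0]
                    guess = cfg.arena.sample(1, rng)[0]
                    err = float(np.hypot(*(guess - true)))
                beh_rows.append(
                    dict(trial=trial, kind="location", correct=np.nan,
                         drop_error=err, normalized=np.nan,
                         encoding_segment=enc_ids[k], recall_segment=seg_id,
                         response_time=rng.uniform(1.0, rec_dur))
                )
            seg_rows.append(dict(segment_id=-1, type="_success", start=success,
                                 end=0.0, trial=trial))  # placeholder, stripped below
            seg_id += 1
            cursor += rec_dur + rec_gap
    segments = pd.DataFrame([r for r in seg_rows if r["segment_id"] >= 0])
    success_flags = [bool(r["start"]) for r in seg_rows if r["segment_id"] < 0]
    behavior = pd.DataFrame(beh_rows)
    behavior["true_success"] = success_flags
    # normalized performance: rank drop errors within the guess distribution
    loc = behavior["kind"] == "location"
    if loc.any():
        ref = _drop_error_reference(cfg.arena, rng)
        errs = behavior.loc[loc, "drop_error"].to_numpy()
        behavior.loc[loc, "normalized"] = np.mean(
            ref[None, :] > errs[:, None], axis=1
        )
    return segments, behavior


def _drop_error_reference(arena: Arena, rng, n: int = 20000) -> np.ndarray:
    a = arena.sample(n, rng)
    b = arena.sample(n, rng)
    return np.hypot(a[:, 0] - b[:, 0], a[:, 1] - b[:, 1])


def _label_segment_success(segments: pd.DataFrame, behavior: pd.DataFrame) -> pd.DataFrame:
    """Propagate recall success to recall and paired encoding segments."""
    segments = segments.copy()
    segments["success"] = pd.NA
    for _, row in behavior.iterrows():
        flag = bool(row["true_success"])
        for col in ("encoding_segment", "recall_segment"):
            segments.loc[segments["segment_id"] == row[col], "success"] = flag
    return segments


def gen_session(config: SynthConfig) -> SynthSession:
    """Generate a complete synthetic session from a single seed."""
    root = np.random.SeedSequence(config.seed)
    beh_seed, wire_root, unit_root = root.spawn(3)
    rng_beh = np.random.default_rng(beh_seed)

    segments, behavior = _build_segments(config, rng_beh)
    segments = _label_segment_success(segments, behavior)

    n = int(round(config.duration_s * config.fs))
    wires = sorted({u.wire for u in config.units}) or [0]
    gt = GroundTruth(unit_specs=list(config.units))
    gt.segment_success = dict(
        zip(segments["segment_id"], [bool(s) if s is not pd.NA else None
                                     for s in segments["success"]])
    )

    # per-sample preferred-phase array support: encoding mu inside
    # encoding segments, retrieval mu inside recall segments
    enc_mask = np.zeros(n, dtype=bool)
    rec_mask = np.zeros(n, dtype=bool)
    for _, seg in segments.iterrows():
        a = int(seg["start"] * config.fs)
        b = min(int(seg["end"] * config.fs), n)
        if seg["type"] == "encoding":
            enc_mask[a:b] = True
        elif str(seg["type"]).startswith("recall"):
            rec_mask[a:b] = True

    clean_lfp, lfp, phase = {}, {}, {}
    wire_seeds = wire_root.spawn(len(wires))
    for w, wseed in zip(wires, wire_seeds):
        s_pink, s_burst, s_ied = wseed.spawn(3)
        x = gen_pink_noise(n, config.fs, config.pink_exponent, s_pink) * config.noise_sd_uv
        burst_trace, bursts = gen_theta_bursts(
            config.duration_s,
            config.fs,
            config.burst_freq_range,
            config.burst_rate,
            config.burst_cycles_range,
            amplitude=config.burst_snr * config.noise_sd_uv,
            drift_hz=config.burst_drift_hz,
            seed=s_burst,
        )
        x = x + burst_trace
        if config.line_noise_amp > 0:
            t = np.arange(n) / config.fs
            x = x + config.line_noise_amp * np.sin(2 * np.pi * 50.0 * t)
            if config.line_harmonics:
                x = x + 0.5 * config.line_noise_amp * np.sin(2 * np.pi * 100.0 * t)
                x = x + 0.25 * config.line_noise_amp * np.sin(2 * np.pi * 150.0 * t)
        ied_intervals = []
        if config.ied_rate > 0:
            rng_ied = np.random.default_rng(s_ied)
            n_ied = rng_ied.poisson(config.ied_rate * config.duration_s / 60.0)
            width = int(0.15 * config.fs)
            for _ in range(n_ied):
                start = int(rng_ied.integers(0, n - 2 * width))
                tt = np.arange(2 * width) / config.fs
                shape = np.sin(2 * np.pi * tt / (2 * tt[-1]))  # biphasic half-sine pair
                x[start : start + 2 * width] += 12 * config.noise_sd_uv * shape * np.hanning(2 * width)
                ied_intervals.append((start, start + 2 * width))
        gt.burst_intervals[w] = [(b["start"], b["end"]) for b in bursts]
        gt.burst_frequencies[w] = [b["frequency"] for b in bursts]
        gt.ied_intervals[w] = ied_intervals

        trace = LfpTrace(samples=x, fs=config.fs, wire_id=str(w))
        clean_lfp[w] = trace
        phase[w] = generalized_phase(bandpass_theta(trace))
        lfp[w] = trace.copy_with(x.copy())
        # stash bursts for the units on this wire
        gt.burst_intervals[w] = [(b["start"], b["end"]) for b in bursts]
        clean_lfp[w]._bursts = bursts  # internal handle used below

    spike_times = []
    unit_seeds = unit_root.spawn(max(len(config.units), 1))
    for spec, useed in zip(config.units, unit_seeds):
        ps = phase[spec.wire]
        if spec.mode == "locked":
            if spec.mu_encoding == spec.mu_retrieval:
                mu = spec.mu_encoding
            else:
                mu = np.full(n, spec.mu_encoding)
                mu[rec_mask] = spec.mu_retrieval
            times = gen_spikes_phase_locked(
                ps,
                spec.base_rate,
                spec.kappa,
                mu,
                lock_only_in_bursts=spec.lock_only_in_bursts,
                bursts=clean_lfp[spec.wire]._bursts,
                seed=useed,
            )
        elif spec.mode == "poisson":
            times = gen_spikes_phase_locked(ps, spec.base_rate, 0.0, 0.0, seed=useed)
        else:
            times = gen_spikes_resonant(
                config.duration_s, spec.base_rate, spec.resonance_freq, seed=useed
            )
        spike_times.append(times)
        wf = (
            spec.waveform_template
            if spec.waveform_template is not None
            else make_waveform_template(config.fs)
        )
        half = wf.size // 2
        y = lfp[spec.wire].samples
        for s in np.round(times * config.fs).astype(int):
            a, b = s - half, s - half + wf.size
            if 0 <= a and b <= n:
                y[a:b] += wf

    return SynthSession(
        config=config,
        lfp=lfp,
        clean_lfp=clean_lfp,
        phase=phase,
        spike_times=spike_times,
        segments=segments,
        behavior=behavior,
        ground_truth=gt,
    )
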