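"""Synthetic-session generator: spectral, temporal and locking ground
truth must be recoverable by construction."""

import numpy as np
import pytest

from thetalock import circstats as cs
from thetalock import gphase, preprocess, synth


def _spectral_slope(x, fs, fmin=1.0, fmax=40.0):
    from scipy import signal as sps

    f, p = sps.welch(x, fs=fs, nperseg=int(4 * fs))
    sel = (f >= fmin) & (f <= fmax)
    return np.polyfit(np.log10(f[sel]), np.log10(p[sel]), 1)[0]


class TestPinkNoise:
    def test_white_noise_flat_spectrum(self):
        x = synth.gen_pink_noise(2**16, 2000.0, 0.0, seed=0)
        assert abs(_spectral_slope(x, 2000.0)) < 0.1

    def test_target_exponent_recovered(self):
        x = synth.gen_pink_noise(2**18, 2000.0, 1.0, seed=1)
        assert -1.15 < _spectral_slope(x, 2000.0) < -0.85

    def test_deterministic_given_seed(self):
        a = synth.gen_pink_noise(4096, 2000.0, 1.0, seed=42)
        b = synth.gen_pink_noise(4096, 2000.0, 1.0, seed=42)
        np.testing.assert_array_equal(a, b)

    def test_invalid_length_raises(self):
        with pytest.raises(ValueError):
            synth.gen_pink_noise(0, 2000.0, 1.0, seed=0)


class TestBursts:
    def test_zero_rate_silent(self):
        trace, bursts = synth.gen_theta_bursts(60.0, 2000.0, burst_rate=0.0, seed=0)
        assert not bursts and not trace.any()

    def test_burst_duration_matches_cycles(self):
        trace, bursts = synth.gen_theta_bursts(
            600.0, 2000.0, freq_range=(4.0, 4.0), burst_rate=0.2,
            cycles_range=(8, 8), seed=3,
        )
        for b in bursts:
            assert b["end"] - b["start"] == pytest.approx(2.0 * 2000, abs=1)

    def test_burst_count_near_rate(self):
        counts = [
            len(synth.gen_theta_bursts(600.0, 1000.0, burst_rate=6.0, seed=s)[1])
            for s in range(100)
        ]
        assert 30 < np.mean(counts) < 90  # 60 expected, +/-50%

    def test_bursts_disjoint(self):
        _, bursts = synth.gen_theta_bursts(300.0, 2000.0, burst_rate=20.0, seed=5)
        for a, b in zip(bursts[:-1], bursts[1:]):
            assert a["end"] <= b["start"]

    def test_min_cycles_guard(self):
        with pytest.raises(ValueError):
            synth.gen_theta_bursts(60.0, 2000.0, cycles_range=(1, 4), seed=0)


@pytest.fixture(scope="module")
def pink_phase():
    x = synth.gen_pink_noise(600 * 2000, 2000.0, 1.0, seed=11)
    filt = gphase.bandpass_theta(preprocess.LfpTrace(x, 2000.0))
    return gphase.generalized_phase(filt)


class TestLockedSpikes:
    def test_kappa_zero_is_poisson(self, pink_phase):
        times = synth.gen_spikes_phase_locked(pink_phase, 2.0, 0.0, 0.0, seed=2)
        n = times.size
        assert abs(n - 1200) < 3 * np.sqrt(1200)
        ph = pink_phase.phase[(times * 2000).astype(int)]
        z, p = cs.rayleigh(ph)
        assert p > 0.001  # no spurious locking

    def test_mu_recovered(self, pink_phase):
        times = synth.gen_spikes_phase_locked(pink_phase, 2.0, 4.0, np.pi, seed=3)
        assert times.size > 500
        ph = pink_phase.phase[np.minimum((times * 2000).astype(int), pink_phase.n_samples - 1)]
        mu, r = cs.circ_mean_r(ph)
        assert abs(cs.circ_dist(mu, np.pi)) < np.deg2rad(10)

    def test_kappa_ppc_monotone(self, pink_phase):
        # averaged over seeds, PPC rises strictly with concentration
        kappas = [0.0, 0.5, 1.0, 2.0, 4.0]
        mean_ppc = []
        for k in kappas:
            vals = []
            for s in range(20):
                t = synth.gen_spikes_phase_locked(pink_phase, 2.0, k, 0.0, seed=100 + s)
                idx = np.minimum((t * 2000).astype(int), pink_phase.n_samples - 1)
                vals.append(cs.ppc(pink_phase.phase[idx]))
            mean_ppc.append(np.mean(vals))
        assert all(a < b for a, b in zip(mean_ppc[:-1], mean_ppc[1:]))

    def test_empty_phase_series_rejected(self):
        empty = gphase.PhaseSeries(
            phase=np.array([]), magnitude=np.array([]), power=np.array([]),
            interp_mask=np.array([], dtype=bool), fs=2000.0,
        )
        with pytest.raises(ValueError):
            synth.gen_spikes_phase_locked(empty, 2.0, 1.0, 0.0, seed=0)


class TestResonantSpikes:
    def test_no_jitter_perfectly_periodic(self):
        t = synth.gen_spikes_resonant(60.0, 4.0, 4.0, jitter_sd=0.0, seed=0)
        assert t.size == 239  # grid 1/f..<60 s
        np.testing.assert_allclose(np.diff(t), 0.25, atol=1e-12)

    def test_negative_jitter_rejected(self):
        with pytest.raises(ValueError):
            synth.gen_spikes_resonant(60.0, 2.0, 4.0, jitter_sd=-1.0, seed=0)

    def test_dropout_hits_target_rate(self):
        t = synth.gen_spikes_resonant(600.0, 2.0, 8.0, seed=1)
        assert abs(t.size / 600.0 - 2.0) < 0.3


class TestSession:
    def test_deterministic(self):
        units = [synth.UnitSpec(mode="locked", kappa=2.0, wire=0)]
        a = synth.gen_session(synth.SynthConfig(duration_s=90.0, n_trials=3, units=units, seed=5))
        b = synth.gen_session(synth.SynthConfig(duration_s=90.0, n_trials=3, units=units, seed=5))
        np.testing.assert_array_equal(a.lfp[0].samples, b.lfp[0].samples)
        np.testing.assert_array_equal(a.spike_times[0], b.spike_times[0])
        assert a.segments.equals(b.segments)

    def test_segments_tile_and_label(self, small_session):
        seg = small_session.segments
        assert (seg["end"] > seg["start"]).all()
        enc = seg[seg["type"] == "encoding"]
        assert enc["success"].notna().all()
        # encoding inherits paired recall success
        beh = small_session.behavior
        for _, row in beh.iterrows():
            flag = seg.loc[seg["segment_id"] == row["encoding_segment"], "success"].iloc[0]
            assert bool(flag) == bool(row["true_success"])

    def test_min_trials_guard(self):
        with pytest.raises(ValueError):
            synth.gen_session(synth.SynthConfig(duration_s=60.0, n_trials=1, units=[]))

    def test_flat_success_probability_no_trend(self):
        from thetalock import behavior as beh_mod

        sessions = []
        for s in range(8):
            cfg = synth.SynthConfig(
                duration_s=120.0, n_trials=4, units=[], seed=200 + s,
                success_p_start=0.6, success_p_end=0.6,
            )
            sessions.append(synth.gen_session(cfg).behavior)
        res = beh_mod.performance_trend(sessions)
        assert res["object"][1] > 0.01  # flat slope: no significant trend
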