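"""Spectral parameterization: frame geometry, power-law recovery,
peak extraction rules, slope annotation."""

import numpy as np
import pytest

from thetalock import preprocess, specparam, synth
from thetalock.specparam import FREQS

FS = 2000.0


class TestFrames:
    def test_frame_count_60s(self):
        lfp = preprocess.LfpTrace(np.random.default_rng(0).normal(size=int(60 * FS)), FS)
        frames = specparam.timefreq_spectra(lfp)
        assert len(frames) == 115  # floor((60 - 3) / 0.5) + 1

    def test_artifact_frames_invalid(self):
        lfp = preprocess.LfpTrace(np.random.default_rng(0).normal(size=int(20 * FS)), FS)
        mask = preprocess.ArtifactMask(intervals=[(10000, 12000)], fs=FS)
        frames = specparam.timefreq_spectra(lfp, mask)
        overlapping = [f for f in frames if not f.valid]
        assert overlapping
        for f in frames:
            start, end = f.time - 1.5, f.time + 1.5
            assert f.valid != (start < 6.0 and 5.0 < end)

    def test_sinusoid_peak_bin(self):
        t = np.arange(int(20 * FS)) / FS
        lfp = preprocess.LfpTrace(np.sin(2 * np.pi * 6.0 * t), FS)
        frames = specparam.timefreq_spectra(lfp)
        for f in frames:
            assert FREQS[np.argmax(f.spectrum)] == 6.0

    def test_short_trace_rejected(self):
        with pytest.raises(ValueError):
            specparam.timefreq_spectra(preprocess.LfpTrace(np.zeros(1000), FS))


class TestAperiodicFit:
    def test_noiseless_power_law_exact(self):
        spectrum = 10.0**2 * FREQS**-1.5
        b, chi, err = specparam.fit_aperiodic(spectrum)
        assert b == pytest.approx(2.0, abs=1e-6)
        assert chi == pytest.approx(1.5, abs=1e-6)
        assert err < 1e-9

    def test_white_noise_flat(self):
        lfp = preprocess.LfpTrace(np.random.default_rng(3).normal(size=int(60 * FS)), FS)
        frames = specparam.fit_frames(specparam.timefreq_spectra(lfp))
        exps = [f.exponent for f in frames if f.valid]
        assert abs(np.mean(exps)) < 0.1

    def test_peak_contamination_suppressed(self):
        rng = np.random.default_rng(4)
        truth = 1.2
        spectrum = 10.0 ** (1.0 - truth * np.log10(FREQS)
                            + 0.8 * np.exp(-0.5 * ((FREQS - 5.0) / 2.0) ** 2))
        _, chi, _ = specparam.fit_aperiodic(spectrum)
        assert chi == pytest.approx(truth, abs=0.15)

    def test_scale_equivariance(self):
        spectrum = 10.0 * FREQS**-1.0 * (1 + 0.05 * np.sin(FREQS))
        b0, chi0, _ = specparam.fit_aperiodic(spectrum)
        b1, chi1, _ = specparam.fit_aperiodic(spectrum * 10.0**3)
        assert b1 == pytest.approx(b0 + 3.0, abs=1e-9)
        assert chi1 == pytest.approx(chi0, abs=1e-9)

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            specparam.fit_aperiodic(np.zeros(FREQS.size))

    @pytest.mark.parametrize("chi", [0.5, 1.0, 1.5, 2.0])
    def test_exponent_recovery_on_pink_noise(self, chi):
        errs = []
        for s in range(20):
            x = synth.gen_pink_noise(int(60 * FS), FS, chi, seed=1000 + s)
            spec = specparam.average_spectrum(preprocess.LfpTrace(x, FS))
            _, est, _ = specparam.fit_aperiodic(spec)
            errs.append(est - chi)
        assert abs(np.mean(errs)) < 0.15


class TestPeaks:
    aperiodic = (1.0, 1.0)

    def _spectrum(self, peaks=()):
        log_p = 1.0 - 1.0 * np.log10(FREQS)
        for c, h, sd in peaks:
            log_p = log_p + h * np.exp(-0.5 * ((FREQS - c) / sd) ** 2)
        return 10.0**log_p

    def test_flat_residual_no_peaks(self):
        assert specparam.fit_peaks(self._spectrum(), self.aperiodic) == []

    def test_single_peak_recovered(self):
        peaks = specparam.fit_peaks(
            self._spectrum([(5.0, 1.0, 3.0)]), self.aperiodic
        )
        assert len(peaks) == 1
        assert peaks[0].center == pytest.approx(5.0, abs=0.5)

    def test_edge_peak_removed(self):
        peaks = specparam.fit_peaks(
            self._spectrum([(2.0, 1.0, 3.0)]), self.aperiodic
        )
        assert all(abs(p.center - 2.0) > 1.0 for p in peaks)

    def test_max_three_peaks(self):
        spec = self._spectrum([(8.0, 1.5, 2.0), (16.0, 1.2, 2.0),
                               (24.0, 1.0, 2.0), (32.0, 0.9, 2.0)])
        peaks = specparam.fit_peaks(spec, self.aperiodic)
        assert len(peaks) <= 3


class TestSlopeAssignment:
    def _frames(self, exps):
        return [
            specparam.SpectralFrame(
                time=1.5 + 0.5 * k, spectrum=np.ones(FREQS.size),
                valid=not np.isnan(e), exponent=e,
            )
            for k, e in enumerate(exps)
        ]

    def test_spike_inherits_frame_exponent(self):
        import pandas as pd

        frames = self._frames([1.0, 2.0, 3.0])
        tab = pd.DataFrame({"time": [1.5, 2.0, 2.5]})
        out = specparam.assign_spike_slopes(tab, frames)
        assert list(out["slope"]) == [1.0, 2.0, 3.0]

    def test_invalid_frame_gives_nan(self):
        import pandas as pd

        frames = self._frames([1.0, np.nan, 3.0])
        tab = pd.DataFrame({"time": [2.0]})
        out = specparam.assign_spike_slopes(tab, frames)
        assert np.isnan(out["slope"].iloc[0])


class TestSlopeFrequencyCorrelation:
    def test_constructed_negative_dependence(self):
        # within one wire: a steep-slope half carrying slow (2-4 Hz)
        # bursts followed by a flat-slope half carrying fast (6-9 Hz)
        # bursts; the frame exponent must anticorrelate with the mean
        # cycle frequency
        from thetalock import cycles, gphase

        sessions = []
        for s in range(3):
            steep, _ = synth.gen_theta_bursts(
                60.0, FS, (2.0, 4.0), 20.0, amplitude=20.0, seed=300 + s
            )
            fast, _ = synth.gen_theta_bursts(
                60.0, FS, (6.0, 9.0), 20.0, amplitude=20.0, seed=400 + s
            )
            x = np.r_[
                synth.gen_pink_noise(int(60 * FS), FS, 2.0, 500 + s) * 10 + steep,
                synth.gen_pink_noise(int(60 * FS), FS, 0.6, 600 + s) * 10 + fast,
            ]
            trace = preprocess.LfpTrace(x, FS)
            filt = gphase.bandpass_theta(trace)
            ps = gphase.generalized_phase(filt)
            peaks, troughs = cycles.find_extrema_from_phase(ps, filt.samples)
            ct, _ = cycles.score_cycles(filt.samples, peaks, troughs, FS)
            frames = specparam.fit_frames(specparam.timefreq_spectra(trace))
            sessions.append({0: (frames, ct, FS)})
        table, t, p = specparam.slope_frequency_correlation(sessions)
        assert (table["mean_rho"] < 0).all()
        assert t < 0

    def test_rank_invariance_to_monotone_transform(self):
        from scipy import stats

        rng = np.random.default_rng(5)
        slopes = rng.uniform(0.5, 2.0, 50)
        freqs = 6 - 2 * slopes + rng.normal(0, 0.3, 50)
        r1 = stats.spearmanr(slopes, freqs).statistic
        r2 = stats.spearmanr(np.exp(slopes), freqs).statistic
        assert r1 == pytest.approx(r2)
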