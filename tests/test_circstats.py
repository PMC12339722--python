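"""Circular statistics: closed forms against hand-computed oracles,
surrogate engines against their own nulls, and symmetry invariants."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from thetalock import circstats as cs


class TestDescriptive:
    def test_circ_mean_point_mass(self):
        mu, r = cs.circ_mean_r([np.pi / 3] * 5)
        assert mu == pytest.approx(np.pi / 3)
        assert r == pytest.approx(1.0)

    def test_circ_mean_antipodal_r_zero(self):
        _, r = cs.circ_mean_r([0.0, np.pi])
        assert r == pytest.approx(0.0, abs=1e-12)

    def test_circ_mean_two_points(self):
        # vector sum of unit vectors at 0 and pi/2
        mu, r = cs.circ_mean_r([0.0, np.pi / 2])
        assert mu == pytest.approx(np.pi / 4)
        assert r == pytest.approx(np.cos(np.pi / 4))

    @pytest.mark.parametrize(
        "phases,expected",
        [
            ([0.3] * 8, 1.0),
            ([0.0, np.pi], -1.0),
            ([0.0, np.pi / 2, np.pi, 3 * np.pi / 2], -1 / 3),  # 6 pairs by hand
        ],
    )
    def test_ppc_known_values(self, phases, expected):
        assert cs.ppc(phases) == pytest.approx(expected, abs=1e-12)

    def test_ppc_closed_form_matches_bruteforce(self, rng):
        for _ in range(100):
            n = int(rng.integers(2, 501))
            ph = rng.uniform(-np.pi, np.pi, n)
            assert cs.ppc(ph) == pytest.approx(cs.ppc_bruteforce(ph), abs=1e-12)

    def test_rayleigh_z_formula(self):
        z, _ = cs.rayleigh(np.full(10, 0.7))
        assert z == pytest.approx(10.0)
        # n=100, r=0.5 synthesised from two clusters
        ph = np.r_[np.zeros(75), np.full(25, np.pi)]
        z, _ = cs.rayleigh(ph)
        assert z == pytest.approx(100 * 0.5**2)

    def test_rayleigh_null_z_small(self, rng):
        hits = sum(cs.rayleigh(rng.uniform(-np.pi, np.pi, 1000))[0] > 3 for _ in range(100))
        assert hits <= 10  # z above 3 is ~ the 5% tail

    @given(
        st.lists(st.floats(-np.pi, np.pi), min_size=2, max_size=50),
        st.floats(-np.pi, np.pi),
    )
    @settings(max_examples=50, deadline=None)
    def test_rotation_invariance(self, phases, delta):
        ph = np.asarray(phases)
        assert cs.ppc(ph + delta) == pytest.approx(cs.ppc(ph), abs=1e-9)
        _, r0 = cs.circ_mean_r(ph)
        _, r1 = cs.circ_mean_r(ph + delta)
        assert r1 == pytest.approx(r0, abs=1e-9)

    def test_ppc_bounds(self, rng):
        for _ in range(50):
            ph = rng.uniform(-np.pi, np.pi, int(rng.integers(2, 100)))
            assert -1.0 <= cs.ppc(ph) <= 1.0


class TestWatsonWilliams:
    def test_identical_samples_f_near_zero(self, rng):
        ph = rng.vonmises(0.0, 3.0, 500)
        assert cs.watson_williams(ph, ph) == pytest.approx(0.0, abs=1e-9)

    def test_separated_means_large_f(self, rng):
        a = rng.vonmises(0.0, 4.0, 500)
        b = rng.vonmises(np.pi / 2, 4.0, 500)
        assert cs.watson_williams(a, b) > 100

    def test_common_rotation_invariance(self, rng):
        a = rng.vonmises(0.3, 2.0, 200)
        b = rng.vonmises(1.0, 2.0, 150)
        f0 = cs.watson_williams(a, b)
        f1 = cs.watson_williams(
            np.angle(np.exp(1j * (a + 1.1))), np.angle(np.exp(1j * (b + 1.1)))
        )
        assert f1 == pytest.approx(f0, rel=1e-9)


class TestSurrogateEngines:
    @staticmethod
    def _pink_phase(seed, n=300000, fs=1000.0):
        # aperiodic phase trace: broadband-filtered pink noise; a
        # periodic ramp would make circular shifts pure rotations and
        # the surrogate null degenerate under rotation-invariant PPC
        from thetalock import gphase, preprocess, synth

        x = synth.gen_pink_noise(n, fs, 1.0, seed)
        filt = gphase.bandpass_theta(preprocess.LfpTrace(x, fs))
        return gphase.generalized_phase(filt).phase

    def test_circshift_detects_locked_unit(self, rng):
        phase = self._pink_phase(31)
        samples = np.flatnonzero(np.abs(cs.circ_dist(phase, np.pi)) < 0.3)
        samples = rng.choice(samples, 500, replace=False)
        res = cs.circshift_locking_test(samples, phase, rng=rng)
        assert res.significant and res.p <= 0.002
        assert abs(cs.circ_dist(res.mu, np.pi)) < np.deg2rad(10)

    def test_circshift_degenerate_phase_raises(self):
        with pytest.raises(ValueError):
            cs.circshift_locking_test([10, 20], np.zeros(5000))

    def test_rayleigh_diff_null_and_signal(self, rng):
        a = rng.vonmises(0.0, 2.0, 1000)
        b = rng.uniform(-np.pi, np.pi, 1000)
        res = cs.rayleigh_diff_shuffle_test(a, b, n_surr=1001, rng=rng)
        assert res.p <= 0.001 * 2  # locked minus uniform: extreme rank
        assert res.significant

    def test_condition_swap_zero_differences(self, rng):
        pairs = np.column_stack([np.linspace(0.1, 0.5, 10)] * 2)
        res = cs.ppc_condition_swap_test(pairs, n_surr=501, rng=rng)
        assert res.value == 0.0
        assert 0.3 < res.p < 0.7

    def test_condition_swap_sign_flip_antisymmetry(self, rng):
        pairs = rng.uniform(0, 0.5, size=(12, 2))
        r1 = cs.ppc_condition_swap_test(pairs, n_surr=101, rng=1)
        r2 = cs.ppc_condition_swap_test(pairs[:, ::-1], n_surr=101, rng=1)
        assert r2.value == pytest.approx(-r1.value)

    def test_ww_spike_reassign_detects_shift(self, rng):
        a = rng.vonmises(0.0, 2.0, 300)
        b = rng.vonmises(np.pi / 2, 2.0, 300)
        res = cs.ww_surrogate_test(
            np.r_[a, b], np.r_[np.zeros(300), np.ones(300)],
            mode="spike_reassign", n_surr=1001, rng=rng,
        )
        assert res.significant and res.p < 0.01

    def test_ww_segment_shuffle_moves_segments_together(self, rng):
        # phases constant within segments: the segment-shuffle null must
        # keep the within-segment dependence, so F stays comparable and
        # a spurious shift is NOT declared
        n_seg = 30
        seg_mu = rng.uniform(-np.pi, np.pi, n_seg)
        phases, segs, labels = [], [], []
        for s in range(n_seg):
            k = 20
            phases.append(rng.vonmises(seg_mu[s], 8.0, k))
            segs.append(np.full(k, s))
            labels.append(np.full(k, s % 2))
        res = cs.ww_surrogate_test(
            np.concatenate(phases), np.concatenate(labels),
            mode="segment_shuffle", segment_ids=np.concatenate(segs),
            n_surr=501, rng=rng,
        )
        assert res.p > 0.01  # no systematic condition difference

    def test_surrogate_null_rates_nominal(self, rng):
        # each engine under its own null: ~5% false positives
        hits_shift = hits_reassign = 0
        n_runs = 100
        null_phase = self._pink_phase(77, n=120000)
        for i in range(n_runs):
            r = np.random.default_rng(1000 + i)
            samples = np.sort(r.choice(null_phase.size, 100, replace=False))
            res = cs.circshift_locking_test(samples, null_phase, n_surr=201, rng=r)
            hits_shift += res.significant
            ph = r.vonmises(0.0, 1.0, 200)
            lab = np.r_[np.zeros(100), np.ones(100)]
            res2 = cs.ww_surrogate_test(ph, lab, mode="spike_reassign", n_surr=201, rng=r)
            hits_reassign += res2.significant
        assert hits_shift / n_runs < 0.12
        assert hits_reassign / n_runs < 0.12


class TestHelpers:
    @pytest.mark.parametrize(
        "k,n,p0,expected",
        [
            (0, 10, 0.05, 1.0),
            (10, 10, 0.05, 0.05**10),
        ],
    )
    def test_binomial_closed_forms(self, k, n, p0, expected):
        assert cs.binomial_exceedance(k, n, p0) == pytest.approx(expected, rel=1e-9)

    def test_binomial_cohort_exceedance(self):
        # 62 significant of 666 at 5% chance is far beyond chance
        assert cs.binomial_exceedance(62, 666) < 0.001

    def test_median_split_tie_rule(self):
        assert list(cs.median_split([1, 2, 3, 4])) == ["low", "low", "high", "high"]
        assert list(cs.median_split([1, 2, 3])) == ["low", "low", "high"]

    def test_median_split_degenerate(self):
        with pytest.raises(ValueError):
            cs.median_split([2.0, 2.0, 2.0])

    def test_median_split_balance(self, rng):
        labels = cs.median_split(rng.normal(size=400))
        assert abs((labels == "high").sum() - 200) <= 1
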