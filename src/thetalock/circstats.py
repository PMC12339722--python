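"""Circular statistics and surrogate inference for spike-phase data.

Implements the descriptive statistics (circular mean, mean resultant
vector length, pairwise phase consistency, Rayleigh z) and the four
surrogate-null constructions used throughout the pipeline:

* circular-shift of the phase trace relative to the spike train
  (per-unit locking test),
* pooled-phase label shuffles preserving group sizes (Rayleigh-z
  difference test, spike-reassignment Watson-Williams test),
* segment-label shuffles that move all spikes of a segment together
  (encoding/retrieval phase-shift test),
* per-unit condition swaps (paired-t contrasts on PPC or firing rate).

All surrogate p-values follow the rank convention
``p = (1 + #{surrogate >= empirical}) / (n_surrogates + 1)`` and
significance is declared when the empirical statistic exceeds the 95th
percentile of the surrogate distribution.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = [
    "LockingResult",
    "ContrastResult",
    "circ_mean_r",
    "ppc",
    "ppc_bruteforce",
    "rayleigh",
    "circ_kappa",
    "watson_williams",
    "circshift_locking_test",
    "rayleigh_diff_shuffle_test",
    "ppc_condition_swap_test",
    "ww_surrogate_test",
    "binomial_exceedance",
    "median_split",
    "circ_dist",
]

ALPHA = 0.05


@dataclass
class LockingResult:
    """Per-unit phase-locking test outcome."""

    n: int
    ppc: float
    r: float
    mu: float
    p: float
    significant: bool
    n_surrogates: int


@dataclass
class ContrastResult:
    """Condition-contrast outcome with a surrogate-rank p-value."""

    statistic: str
    value: float
    p: float
    significant: bool
    sided: str
    n_surrogates: int
    correction: int = 1
    extra: dict = field(default_factory=dict)

    @property
    def p_corrected(self) -> float:
        return min(1.0, self.p * self.correction)


def _as_phase_array(phases) -> np.ndarray:
    arr = np.asarray(phases, dtype=float).ravel()
    if arr.size == 0:
        raise ValueError("empty phase array")
    return arr


def circ_mean_r(phases) -> tuple[float, float]:
    """Circular mean direction and mean resultant vector length.

    Returns ``(mu, r)`` with ``mu`` in (-pi, pi] and ``r`` in [0, 1].
    """
    arr = _as_phase_array(phases)
    z = np.mean(np.exp(1j * arr))
    return float(np.angle(z)), float(np.abs(z))


def ppc(phases) -> float:
    """Pairwise phase consistency: mean cosine over all spike pairs.

    Uses the closed form ``(R^2 - n) / (n (n - 1))`` with ``R`` the
    modulus of the summed unit vectors, which equals the average dot
    product over all n(n-1)/2 pairs.
    """
    arr = _as_phase_array(phases)
    n = arr.size
    if n < 2:
        raise ValueError("PPC requires at least two phases")
    R2 = np.abs(np.sum(np.exp(1j * arr))) ** 2
    return float((R2 - n) / (n * (n - 1)))


def ppc_bruteforce(phases) -> float:
    """O(n^2) PPC by explicit pair enumeration (reference oracle)."""
    arr = _as_phase_array(phases)
    n = arr.size
    if n < 2:
        raise ValueError("PPC requires at least two phases")
    diffs = arr[:, None] - arr[None, :]
    iu = np.triu_indices(n, k=1)
    return float(np.mean(np.cos(diffs[iu])))


def rayleigh(phases) -> tuple[float, float]:
    """Rayleigh statistic z = n * r^2 and its approximate p-value.

    The p-value uses the standard large-sample approximation with the
    finite-n correction (Zar 1999, eq. 27.4).
    """
    arr = _as_phase_array(phases)
    n = arr.size
    _, r = circ_mean_r(arr)
    z = n * r * r
    p = np.exp(np.sqrt(1.0 + 4.0 * n + 4.0 * (n * n - (n * r) ** 2)) - (1.0 + 2.0 * n))
    return float(z), float(min(1.0, p))


def circ_kappa(r: float) -> float:
    """Maximum-likelihood-style von Mises concentration from r (Fisher 1993)."""
    if r < 0.53:
        return 2.0 * r + r**3 + 5.0 * r**5 / 6.0
    if r < 0.85:
        return -0.4 + 1.39 * r + 0.43 / (1.0 - r)
    denom = r**3 - 4.0 * r**2 + 3.0 * r
    if denom <= 0:
        return 1e6
    return 1.0 / denom


def circ_dist(a, b):
    """Signed circular difference a - b wrapped to (-pi, pi]."""
    d = np.angle(np.exp(1j * (np.asarray(a) - np.asarray(b))))
    return d


def watson_williams(phases_a, phases_b) -> float:
    """Two-sample Watson-Williams F for equality of mean directions.

    Applies the usual concentration correction factor
    ``K = 1 + 3 / (8 kappa_hat)``. No assumption gating is performed:
    in this pipeline validity comes from the surrogate rank, not from
    the parametric F distribution.
    """
    a = _as_phase_array(phases_a)
    b = _as_phase_array(phases_b)
    if a.size < 2 or b.size < 2:
        raise ValueError("Watson-Williams requires n >= 2 per group")
    n1, n2 = a.size, b.size
    N = n1 + n2
    R1 = np.abs(np.sum(np.exp(1j * a)))
    R2 = np.abs(np.sum(np.exp(1j * b)))
    R = np.abs(np.sum(np.exp(1j * a)) + np.sum(np.exp(1j * b)))
    Rw = R1 + R2
    rw = Rw / N
    if rw < 1e-12:
        raise ValueError("pooled resultant ~0: concentration correction undefined")
    kappa = circ_kappa(rw)
    K = 1.0 + 3.0 / (8.0 * kappa)
    denom = N - Rw
    if denom <= 1e-12:
        return float("inf")
    return float(K * ((N - 2) * (Rw - R)) / denom)


def _ww_f_from_sums(n1, n2, R1, R2, R):
    """Vectorised Watson-Williams F from group resultant moduli.

    All arguments may be arrays of matching shape; returns F with the
    concentration correction applied elementwise.
    """
    n1 = np.asarray(n1, dtype=float)
    n2 = np.asarray(n2, dtype=float)
    N = n1 + n2
    Rw = R1 + R2
    rw = Rw / N
    kappa = np.empty_like(rw)
    lo = rw < 0.53
    mid = (rw >= 0.53) & (rw < 0.85)
    hi = rw >= 0.85
    kappa[lo] = 2 * rw[lo] + rw[lo] ** 3 + 5 * rw[lo] ** 5 / 6
    kappa[mid] = -0.4 + 1.39 * rw[mid] + 0.43 / (1 - rw[mid])
    denom_hi = rw[hi] ** 3 - 4 * rw[hi] ** 2 + 3 * rw[hi]
    kappa[hi] = np.where(denom_hi > 0, 1.0 / np.maximum(denom_hi, 1e-12), 1e6)
    K = 1.0 + 3.0 / (8.0 * np.maximum(kappa, 1e-12))
    with np.errstate(divide="ignore", invalid="ignore"):
        F = K * ((N - 2) * (Rw - R)) / (N - Rw)
    return np.where(N - Rw <= 1e-12, np.inf, F)


def rank_p(empirical: float, surrogates: np.ndarray, sided: str = "one") -> float:
    """Rank-based p-value: (1 + #{surr >= emp}) / (n_surr + 1).

    Exact ties with the empirical value carry half weight, which leaves
    continuous statistics untouched and gives p ~ 0.5 in fully
    degenerate cases (all surrogates equal to the empirical value).
    ``sided='two'`` doubles the smaller tail (capped at 1).
    """
    surr = np.asarray(surrogates, dtype=float)
    n = surr.size
    ties = 0.5 * np.sum(surr == empirical)
    p_hi = (1 + np.sum(surr > empirical) + ties) / (n + 1)
    if sided == "one":
        return float(p_hi)
    p_lo = (1 + np.sum(surr < empirical) + ties) / (n + 1)
    return float(min(1.0, 2.0 * min(p_hi, p_lo)))


def _significant(empirical: float, surrogates: np.ndarray) -> bool:
    return bool(empirical > np.quantile(surrogates, 0.95))


def circshift_locking_test(
    spike_samples,
    phase_array,
    n_surr: int = 1001,
    rng=None,
    alpha: float = ALPHA,
) -> LockingResult:
    """Phase-locking test by circularly shifting the phase trace.

    Each surrogate rotates the full phase array by a uniform random lag
    in [1, N-1] samples and recomputes the PPC at the fixed spike
    samples. Significance: empirical PPC above the 95th percentile of
    the surrogate PPCs.
    """
    rng = np.random.default_rng(rng)
    spikes = np.asarray(spike_samples, dtype=np.int64)
    phases = np.asarray(phase_array, dtype=float)
    N = phases.size
    if spikes.size < 2:
        raise ValueError("need at least two spikes")
    if np.allclose(phases, phases[0]):
        raise ValueError("constant phase array: degenerate null")
    emp_phases = phases[spikes]
    mu, r = circ_mean_r(emp_phases)
    emp_ppc = ppc(emp_phases)

    lags = rng.integers(1, N, size=n_surr)
    n = spikes.size
    surr = np.empty(n_surr)
    # chunked to bound memory for long spike trains
    chunk = max(1, int(2_000_000 // max(n, 1)))
    unit = np.exp(1j * phases)
    for start in range(0, n_surr, chunk):
        block = lags[start : start + chunk]
        idx = (spikes[None, :] + block[:, None]) % N
        R2 = np.abs(unit[idx].sum(axis=1)) ** 2
        surr[start : start + chunk] = (R2 - n) / (n * (n - 1))
    p = rank_p(emp_ppc, surr, sided="one")
    return LockingResult(
        n=int(n),
        ppc=emp_ppc,
        r=r,
        mu=mu,
        p=p,
        significant=bool(emp_ppc > np.quantile(surr, 1 - alpha)),
        n_surrogates=n_surr,
    )


def rayleigh_diff_shuffle_test(
    phases_a,
    phases_b,
    n_surr: int = 10001,
    sided: str = "one",
    rng=None,
) -> ContrastResult:
    """Rayleigh-z difference test with pooled label shuffles.

    Surrogates permute the pooled phases into groups of the original
    sizes, so the spike-count bias of z is identical in every
    surrogate round.
    """
    rng = np.random.default_rng(rng)
    a = _as_phase_array(phases_a)
    b = _as_phase_array(phases_b)
    na, nb = a.size, b.size
    z_a, _ = rayleigh(a)
    z_b, _ = rayleigh(b)
    emp = z_a - z_b
    pooled = np.exp(1j * np.concatenate([a, b]))
    n = na + nb
    surr = np.empty(n_surr)
    chunk = max(1, int(4_000_000 // max(n, 1)))
    for start in range(0, n_surr, chunk):
        m = min(chunk, n_surr - start)
        order = np.argsort(rng.random((m, n)), axis=1)
        shuffled = pooled[order]
        Ra2 = np.abs(shuffled[:, :na].sum(axis=1)) ** 2
        Rb2 = np.abs(shuffled[:, na:].sum(axis=1)) ** 2
        surr[start : start + m] = Ra2 / na - Rb2 / nb
    p = rank_p(emp, surr, sided=sided)
    return ContrastResult(
        statistic="delta_z",
        value=float(emp),
        p=p,
        significant=_significant(emp, surr),
        sided=sided,
        n_surrogates=n_surr,
    )


def _paired_t(diffs: np.ndarray) -> float:
    n = diffs.shape[-1]
    mean = diffs.mean(axis=-1)
    sd = diffs.std(axis=-1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean / (sd / np.sqrt(n))
        degenerate = np.where(mean == 0, 0.0, np.sign(mean) * np.inf)
    return np.where(sd == 0, degenerate, t)


def ppc_condition_swap_test(
    pairs,
    n_surr: int = 10001,
    sided: str = "one",
    rng=None,
    statistic_name: str = "t",
) -> ContrastResult:
    """Paired t-test across units with condition-swap surrogates.

    ``pairs`` is an (n_units, 2) array of per-unit statistics (e.g. PPC
    under condition 1 and condition 2); rows with NaN are dropped.
    Each surrogate independently swaps the pair for each unit with
    probability 1/2 (sign flip of the difference).
    """
    rng = np.random.default_rng(rng)
    arr = np.asarray(pairs, dtype=float)
    arr = arr[~np.isnan(arr).any(axis=1)]
    if arr.shape[0] < 2:
        raise ValueError("need at least two units with both conditions")
    d = arr[:, 0] - arr[:, 1]
    emp = float(_paired_t(d[None, :])[0])
    signs = rng.integers(0, 2, size=(n_surr, d.size)) * 2 - 1
    surr = np.asarray(_paired_t(signs * d[None, :]))
    p = rank_p(emp, surr, sided=sided)
    return ContrastResult(
        statistic=statistic_name,
        value=emp,
        p=p,
        significant=_significant(emp, surr),
        sided=sided,
        n_surrogates=n_surr,
        extra={"n_units": int(d.size)},
    )


def ww_surrogate_test(
    phases,
    labels,
    mode: str = "spike_reassign",
    n_surr: int = 10001,
    segment_ids=None,
    rng=None,
) -> ContrastResult:
    """Watson-Williams test validated by surrogate rank.

    mode='spike_reassign': surrogates reassign each spike to a group,
    keeping the two group sizes fixed (pooled permutation).
    mode='segment_shuffle': surrogates permute the condition labels
    over segments, so all spikes of one segment move together; this
    preserves within-segment phase dependence. Surrogates that leave a
    group without spikes are redrawn.
    """
    rng = np.random.default_rng(rng)
    ph = _as_phase_array(phases)
    lab = np.asarray(labels)
    uniq = np.unique(lab)
    if uniq.size != 2:
        raise ValueError("labels must take exactly two values")
    mask_a = lab == uniq[0]
    a, b = ph[mask_a], ph[~mask_a]
    emp = watson_williams(a, b)
    unit = np.exp(1j * ph)

    if mode == "spike_reassign":
        na, nb = a.size, b.size
        n = na + nb
        Z = unit.sum()
        R = np.abs(Z)
        surr = np.empty(n_surr)
        chunk = max(1, int(4_000_000 // max(n, 1)))
        for start in range(0, n_surr, chunk):
            m = min(chunk, n_surr - start)
            order = np.argsort(rng.random((m, n)), axis=1)
            shuffled = unit[order]
            Za = shuffled[:, :na].sum(axis=1)
            R1 = np.abs(Za)
            R2 = np.abs(Z - Za)
            surr[start : start + m] = _ww_f_from_sums(na, nb, R1, R2, R)
    elif mode == "segment_shuffle":
        if segment_ids is None:
            raise ValueError("segment_shuffle mode requires segment_ids")
        seg = np.asarray(segment_ids)
        seg_codes, inv = np.unique(seg, return_inverse=True)
        n_seg = seg_codes.size
        seg_sum = np.zeros(n_seg, dtype=complex)
        np.add.at(seg_sum.real, inv, unit.real)
        np.add.at(seg_sum.imag, inv, unit.imag)
        seg_n = np.bincount(inv, minlength=n_seg).astype(float)
        # each segment has one condition label
        seg_lab = np.zeros(n_seg, dtype=bool)
        seg_lab[inv[mask_a]] = True
        n_seg_a = int(seg_lab.sum())
        if n_seg_a == 0 or n_seg_a == n_seg:
            raise ValueError("both conditions must contain segments")
        Z = seg_sum.sum()
        R = np.abs(Z)
        N = float(seg_n.sum())
        surr = np.empty(n_surr)
        n_redraw = 0
        filled = 0
        while filled < n_surr:
            m = min(2 * (n_surr - filled) + 16, 4 * n_surr)
            order = np.argsort(rng.random((m, n_seg)), axis=1)
            pick = order[:, :n_seg_a]
            Za = seg_sum[pick].sum(axis=1)
            n1 = seg_n[pick].sum(axis=1)
            n2 = N - n1
            ok = (n1 >= 2) & (n2 >= 2)
            n_redraw += int((~ok).sum())
            vals = _ww_f_from_sums(n1[ok], n2[ok], np.abs(Za[ok]), np.abs(Z - Za[ok]), R)
            take = min(vals.size, n_surr - filled)
            surr[filled : filled + take] = vals[:take]
            filled += take
    else:
        raise ValueError(f"unknown mode: {mode}")

    p = rank_p(emp, surr, sided="one")
    return ContrastResult(
        statistic="F",
        value=float(emp),
        p=p,
        significant=_significant(emp, surr),
        sided="one",
        n_surrogates=n_surr,
    )


def binomial_exceedance(k: int, n: int, p0: float = 0.05) -> float:
    """One-sided exact binomial tail P(X >= k) for X ~ Binomial(n, p0)."""
    if not 0 <= k <= n:
        raise ValueError("require 0 <= k <= n")
    return float(stats.binom.sf(k - 1, n, p0))


def median_split(values) -> np.ndarray:
    """Label values 'high'/'low' about their median; ties go to 'low'."""
    arr = np.asarray(values, dtype=float)
    if arr.size < 2:
        raise ValueError("median split needs n >= 2")
    if np.all(arr == arr[0]):
        raise ValueError("all values identical: split undefined")
    med = np.median(arr)
    return np.where(arr > med, "high", "low")
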