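"""Marginalized likelihoods against hand values and brute-force enumeration."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as hst
from scipy import stats

from hiermcmc.marginal_lik import (
    NRange,
    dynocc_marginal_ll,
    dynocc_marginal_ll_sites,
    nmix_range,
    nmix_zip_marginal_ll,
    occ_marginal_ll,
)


def brute_occ(y, psi, p):
    p = np.broadcast_to(p, np.shape(y)).astype(float)
    tot = 0.0
    for z in (0, 1):
        pr = psi if z else 1 - psi
        for yj, pj in zip(y, p):
            pr *= (pj if yj else 1 - pj) if z else (0.0 if yj else 1.0)
        tot += pr
    return math.log(tot)


def brute_dynocc(Y, psi1, phi, gamma, p):
    Y = np.asarray(Y, dtype=float)
    T, J = Y.shape
    p = np.broadcast_to(p, Y.shape).astype(float)
    tot = 0.0
    for zs in itertools.product((0, 1), repeat=T):
        pr = psi1 if zs[0] else 1 - psi1
        for t in range(1, T):
            rate = phi[t - 1] if zs[t - 1] else gamma[t - 1]
            pr *= rate if zs[t] else 1 - rate
        for t in range(T):
            for j in range(J):
                if zs[t]:
                    pr *= p[t, j] if Y[t, j] else 1 - p[t, j]
                elif Y[t, j]:
                    pr = 0.0
        tot += pr
    return math.log(tot) if tot > 0 else -np.inf


class TestOccMarginal:
    @pytest.mark.parametrize("y,psi,p,expected", [
        ((1, 0), 1.0, (0.5, 0.5), math.log(0.25)),
        ((0, 0), 0.4, (0.5, 0.5), math.log(0.7)),
        ((1, 0, 1), 0.3, (0.2, 0.6, 0.9), math.log(0.3 * 0.2 * 0.4 * 0.9)),
    ])
    def test_hand_values(self, y, psi, p, expected):
        assert occ_marginal_ll(np.array(y), psi, p) == pytest.approx(expected)

    def test_detection_on_masked_visit_rejected(self):
        with pytest.raises(ValueError):
            occ_marginal_ll(np.array([1, 0]), 0.5, (0.5, 0.5), mask=(0, 1))

    def test_masked_visits_contribute_nothing(self):
        full = occ_marginal_ll(np.array([0, 0]), 0.4, (0.5, 0.9), mask=(1, 0))
        short = occ_marginal_ll(np.array([0]), 0.4, (0.5,))
        assert full == pytest.approx(short)

    @settings(derandomize=True, max_examples=50)
    @given(hst.integers(0, 2**32 - 1))
    def test_matches_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        J = int(rng.integers(1, 5))
        psi = rng.uniform(0.05, 0.95)
        p = rng.uniform(0.05, 0.95, J)
        y = (rng.random(J) < 0.4).astype(int)
        expect = brute_occ(y, psi, p)
        assert occ_marginal_ll(y, psi, p) == pytest.approx(expect, rel=1e-12)

    def test_normalizes_over_all_outcomes(self):
        psi, p = 0.37, np.array([0.6, 0.25])
        tot = sum(math.exp(occ_marginal_ll(np.array(y), psi, p))
                  for y in itertools.product((0, 1), repeat=2))
        assert tot == pytest.approx(1.0, abs=1e-8)


class TestDynOccMarginal:
    def test_single_season_degenerates_to_occupancy(self):
        Y = np.array([[1, 0]])
        v1 = dynocc_marginal_ll(Y, 0.4, [], [], 0.3)
        v2 = occ_marginal_ll(Y[0], 0.4, 0.3)
        assert v1 == pytest.approx(v2)

    def test_two_season_hand_value(self):
        # psi1=.5, phi=.8, gamma=.1, p=.5, Y=((0),(1)):
        # occupied path .5*.5*.8*.5 + colonized path .5*1*.1*.5 = 0.125
        Y = np.array([[0], [1]])
        v = dynocc_marginal_ll(Y, 0.5, [0.8], [0.1], 0.5)
        assert v == pytest.approx(math.log(0.125))

    def test_forced_trajectory_all_detected(self):
        rng = np.random.default_rng(0)
        p = rng.uniform(0.3, 0.9, (3, 2))
        Y = np.ones((3, 2))
        v = dynocc_marginal_ll(Y, 1.0, [1.0, 1.0], [0.0, 0.0], p)
        assert v == pytest.approx(np.log(p).sum())

    @settings(derandomize=True, max_examples=25)
    @given(hst.integers(0, 2**32 - 1))
    def test_matches_exhaustive_paths(self, seed):
        rng = np.random.default_rng(seed)
        T, J = 4, 2
        psi1 = rng.uniform(0.1, 0.9)
        phi = rng.uniform(0.1, 0.9, T - 1)
        gamma = rng.uniform(0.1, 0.9, T - 1)
        p = rng.uniform(0.1, 0.9, (T, J))
        Y = (rng.random((T, J)) < 0.3).astype(int)
        expect = brute_dynocc(Y, psi1, phi, gamma, p)
        assert dynocc_marginal_ll(Y, psi1, phi, gamma, p) == pytest.approx(
            expect, rel=1e-12, abs=1e-12)

    def test_visit_order_invariance_within_season(self):
        Y = np.array([[1, 0, 0], [0, 1, 0]])
        p = np.array([[0.3, 0.3, 0.3], [0.6, 0.6, 0.6]])
        a = dynocc_marginal_ll(Y, 0.5, [0.7], [0.2], p)
        b = dynocc_marginal_ll(Y[:, ::-1], 0.5, [0.7], [0.2], p)
        assert a == pytest.approx(b)

    def test_sites_version_matches_per_site(self):
        rng = np.random.default_rng(5)
        I, T, J = 6, 4, 3
        det = rng.integers(0, J + 1, (I, T)).astype(float)
        vis = np.full((I, T), float(J))
        psi1, phi, gamma = 0.5, rng.uniform(0.2, 0.8, T - 1), rng.uniform(0.1, 0.5, T - 1)
        p = rng.uniform(0.2, 0.8, T)
        v = dynocc_marginal_ll_sites(det, vis, psi1, phi, gamma, p)
        for i in range(I):
            Y = np.zeros((T, J))
            for t in range(T):
                Y[t, : int(det[i, t])] = 1
            expect = dynocc_marginal_ll(Y, psi1, phi, gamma,
                                        np.broadcast_to(p[:, None], (T, J)))
            assert v[i] == pytest.approx(expect, rel=1e-12)

    def test_normalizes_over_all_outcomes(self):
        psi1, phi, gamma, p = 0.45, [0.7], [0.2], 0.55
        tot = 0.0
        for flat in itertools.product((0, 1), repeat=4):
            Y = np.array(flat).reshape(2, 2)
            tot += math.exp(dynocc_marginal_ll(Y, psi1, phi, gamma, p))
        assert tot == pytest.approx(1.0, abs=1e-8)


class TestNmixRange:
    def test_perfect_detection_pins_n(self):
        r = nmix_range(np.array([3, 5]), 2.0, (1.0, 1.0))
        assert (r.nmin, r.nmax) == (5, 5)

    def test_zero_counts_quantile_bound(self):
        r = nmix_range(np.array([0, 0]), 2.0, (0.5, 0.5))
        assert r.nmin == 0
        assert r.nmax == int(stats.poisson.ppf(1 - 1e-5, 1.0))

    def test_all_masked_is_error(self):
        with pytest.raises(ValueError):
            nmix_range(np.array([0, 0]), 2.0, (0.5, 0.5), mask=(0, 0))

    def test_truncation_captures_essentially_all_mass(self):
        """Sum over the quantile range is >= (1 - 1e-4) of a wide-range sum."""
        rng = np.random.default_rng(8)
        for _ in range(100):
            J = int(rng.integers(1, 4))
            lam = rng.uniform(0.5, 50.0)
            p = rng.uniform(0.05, 0.95, J)
            y = rng.poisson(lam * p)
            r = nmix_range(y, lam, p)
            hi = int(10 * (lam + y.max())) + 1
            trunc = math.exp(nmix_zip_marginal_ll(y, 1.0, lam, p, r))
            wide = math.exp(nmix_zip_marginal_ll(
                y, 1.0, lam, p, NRange(int(y.max()), hi)))
            assert trunc >= (1 - 1e-4) * wide


class TestNmixZipMarginal:
    def test_forced_n_perfect_detection(self):
        v = nmix_zip_marginal_ll(np.array([2, 2]), 1.0, 3.0, (1.0, 1.0),
                                 NRange(2, 2))
        assert v == pytest.approx(math.log(math.exp(-3) * 9 / 2))

    def test_zero_counts_closed_form(self):
        # sum_N Pois(N|2) 0.25^N = e^{-2} e^{0.5} = e^{-1.5}
        v = nmix_zip_marginal_ll(np.array([0, 0]), 0.7, 2.0, (0.5, 0.5),
                                 NRange(0, 80))
        assert v == pytest.approx(math.log(0.3 + 0.7 * math.exp(-1.5)))

    def test_nmin_below_max_count_is_error(self):
        with pytest.raises(ValueError):
            nmix_zip_marginal_ll(np.array([4]), 1.0, 2.0, (0.5,), NRange(2, 30))

    @settings(derandomize=True, max_examples=50)
    @given(hst.integers(0, 2**32 - 1))
    def test_recursive_matches_direct_summation(self, seed):
        rng = np.random.default_rng(seed)
        J = int(rng.integers(1, 4))
        lam = rng.uniform(0.5, 30.0)
        p = rng.uniform(0.05, 0.95, J)
        theta = rng.uniform(0.3, 1.0)
        y = rng.poisson(lam * p)
        hi = int(10 * (lam + y.max())) + 1
        direct = sum(stats.poisson.pmf(N, lam)
                     * np.prod(stats.binom.pmf(y, N, p))
                     for N in range(0, hi + 1))
        expect = math.log((1 - theta) * float(y.sum() == 0) + theta * direct)
        got = nmix_zip_marginal_ll(y, theta, lam, p, NRange(int(y.max()), hi))
        assert got == pytest.approx(expect, rel=1e-10)

    def test_normalizes_over_all_outcomes(self):
        """Exponentiated likelihood sums to one over count space (wide range,
        J=2, small lambda so the outcome sum can be truncated far out)."""
        lam, theta = 1.2, 0.8
        p = np.array([0.55, 0.35])
        tot = 0.0
        for y1 in range(40):
            for y2 in range(40):
                y = np.array([y1, y2])
                tot += math.exp(nmix_zip_marginal_ll(
                    y, theta, lam, p, NRange(int(y.max()), 120)))
        assert tot == pytest.approx(1.0, abs=1e-8)
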