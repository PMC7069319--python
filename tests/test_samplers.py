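"""Sampler correctness: invariant distributions, adaptation, reproducibility."""

import math

import numpy as np
import pytest
from scipy import integrate, stats

import hiermcmc.samplers as S
from hiermcmc.model_core import (
    HierModel,
    LogDensityTerm,
    ModelInconsistencyError,
    ModelState,
    ParamSpec,
    Support,
)

from conftest import make_mvn_model, make_occupancy_toy, make_std_normal_model


def run_scalar(sampler, model, x0, niter, seed):
    st = ModelState(model, {sampler.name: x0})
    rng = np.random.default_rng(seed)
    out = np.empty(niter)
    for i in range(niter):
        sampler.step(st, rng)
        out[i] = st.get(sampler.name)
    return out


class TestARWMH:
    def test_tiny_scale_accepts_almost_always(self, std_normal_model, rng):
        s = S.ARWMHSampler("x", scale=1e-8, adapt=False)
        st = ModelState(std_normal_model, {"x": 0.3})
        acc = sum(s.step(st, rng) for _ in range(2000))
        assert acc > 1990

    def test_acceptance_rate_matches_quadrature_oracle(self):
        """Fixed scale 2.4 on N(0,1): empirical acceptance matches
        E[min(1, phi(x + 2.4 eps) / phi(x))] by 2-D numerical integration."""
        scale = 2.4

        def inner(e, x):
            ratio = math.exp(-0.5 * (x + scale * e) ** 2 + 0.5 * x**2)
            return (stats.norm.pdf(x) * stats.norm.pdf(e) * min(1.0, ratio))

        expected, _ = integrate.dblquad(inner, -8, 8, -8, 8, epsabs=1e-6)
        s = S.ARWMHSampler("x", scale=scale, adapt=False)
        xs = run_scalar(s, make_std_normal_model(), 0.0, 50_000, seed=7)
        rate = s.total_accepts / s.steps
        assert rate == pytest.approx(expected, abs=0.02)

    def test_stationary_distribution_is_target(self):
        s = S.ARWMHSampler("x", scale=2.4, adapt=False)
        xs = run_scalar(s, make_std_normal_model(), 0.0, 100_000, seed=3)
        thin = xs[1000::25]  # near-independent draws
        stat, pval = stats.kstest(thin, "norm")
        assert pval > 0.01

    def test_adaptation_reaches_target_rate(self):
        s = S.ARWMHSampler("x", scale=25.0)
        model = make_std_normal_model()
        st = ModelState(model, {"x": 0.0})
        rng = np.random.default_rng(5)
        accepts = []
        for i in range(200_000):
            accepts.append(s.step(st, rng))
        tail_rate = np.mean(accepts[-50_000:])
        assert tail_rate == pytest.approx(0.44, abs=0.05)

    def test_adapt_fixed_point_and_monotonicity(self):
        s = S.ARWMHSampler("x", scale=1.0)
        s.window_steps = s.window_accepts = 200
        s.window_accepts = int(200 * 0.44)
        s.adapt_scale()
        assert s.scale == pytest.approx(1.0)
        prev = s.scale
        for _ in range(5):
            s.window_steps = 200
            s.window_accepts = 200  # persistent full acceptance
            s.adapt_scale()
            assert s.scale > prev
            prev = s.scale


class TestSlice:
    def test_uniform_target_returns_uniform(self):
        p = ParamSpec("x", (), Support.unit_interval())
        m = HierModel([p], [LogDensityTerm("t", ("x",), lambda v: 0.0)])
        s = S.SliceSampler("x", width=1.5, adapt=False)
        xs = run_scalar(s, m, 0.5, 20_000, seed=9)
        stat, pval = stats.kstest(xs[::5], "uniform")
        assert pval > 0.01

    def test_normal_target_moments(self):
        s = S.SliceSampler("x")
        xs = run_scalar(s, make_std_normal_model(), 0.0, 50_000, seed=11)
        assert abs(xs.mean()) < 0.03
        assert 0.95 < xs.var() < 1.05

    def test_returned_point_always_on_slice(self):
        """Postcondition: the accepted point's log density >= slice level.
        Verified indirectly: chain of a bounded target never leaves support."""
        p = ParamSpec("x", (), Support.interval(-2.0, 2.0))
        m = HierModel([p], [LogDensityTerm("t", ("x",), lambda v: 0.0)])
        xs = run_scalar(S.SliceSampler("x"), m, 0.0, 5000, seed=2)
        assert np.all((xs >= -2) & (xs <= 2))


class TestDiscreteGibbs:
    def test_occupancy_conditional_probability(self):
        """z | y=(0,0), psi=.4, p=.5: P(z=1) = .4*.25/(.4*.25+.6) = 1/7."""
        m = make_occupancy_toy(psi=0.4, p=0.5, y=(0, 0))
        st = ModelState(m, {"z": 0.0})
        g = S.DiscreteGibbsSampler("z")
        rng = np.random.default_rng(13)
        hits = sum(g.step(st, rng) == 1 for _ in range(100_000))
        assert hits / 100_000 == pytest.approx(0.1 / 0.7, abs=0.004)

    def test_detection_forces_occupancy(self):
        m = make_occupancy_toy(psi=0.4, p=0.5, y=(1, 0))
        st = ModelState(m, {"z": 1.0})
        g = S.DiscreteGibbsSampler("z")
        rng = np.random.default_rng(1)
        assert all(g.step(st, rng) == 1 for _ in range(200))

    def test_flat_likelihood_samples_prior(self):
        m = make_occupancy_toy(psi=0.3, p=0.0, y=(0, 0))
        st = ModelState(m, {"z": 0.0})
        g = S.DiscreteGibbsSampler("z")
        rng = np.random.default_rng(17)
        hits = sum(g.step(st, rng) == 1 for _ in range(100_000))
        assert hits / 100_000 == pytest.approx(0.3, abs=0.005)

    def test_all_impossible_raises(self):
        p = ParamSpec("z", (), Support.binary(), role="latent")
        m = HierModel([p], [LogDensityTerm("t", ("z",), lambda v: -np.inf)])
        st = ModelState.__new__(ModelState)  # bypass finite-init check
        st.model = m
        st.values = m.pack_values({"z": 0.0})
        st.term_vals = np.array([-np.inf])
        st.logp = -np.inf
        with pytest.raises(ModelInconsistencyError):
            S.DiscreteGibbsSampler("z").step(st, np.random.default_rng(0))


def _latent_abundance_model(lam=4.0, y=(2, 1), p=0.5):
    from scipy.special import gammaln

    spec = ParamSpec("N", (), Support.nonneg_integer(), role="latent")
    y = np.asarray(y, dtype=float)
    loglam, lp = math.log(lam), (math.log(p) if p > 0 else -np.inf)
    l1mp = math.log1p(-p) if p < 1 else -np.inf

    def ev(v):
        n = float(v["N"])
        if np.any(y > n):
            return -np.inf
        pois = n * loglam - lam - gammaln(n + 1)
        if p >= 1.0:
            return float(pois) if np.all(y == n) else -np.inf
        binom = np.sum(gammaln(n + 1) - gammaln(y + 1) - gammaln(n - y + 1)
                       + y * lp + (n - y) * l1mp)
        return float(pois + binom)

    return HierModel([spec], [LogDensityTerm("t", ("N",), ev)])


class TestDiscreteSlice:
    def test_point_mass_returns_that_value(self):
        m = _latent_abundance_model(lam=3.0, y=(2, 2), p=1.0)  # N pinned at 2
        st = ModelState(m, {"N": 2.0})
        s = S.DiscreteSliceSampler("N")
        rng = np.random.default_rng(3)
        assert all(s.step(st, rng) == 2 for _ in range(100))

    def test_matches_enumerated_conditional(self):
        """Empirical law over many updates vs the enumerated conditional on
        [2, 60]: total variation < 0.01."""
        m = _latent_abundance_model()
        st = ModelState(m, {"N": 3.0})
        s = S.DiscreteSliceSampler("N")
        rng = np.random.default_rng(19)
        counts = {}
        n_draws = 100_000
        for _ in range(n_draws):
            v = s.step(st, rng)
            counts[v] = counts.get(v, 0) + 1
        grid = np.arange(2, 61)
        lp = np.array([stats.poisson.logpmf(n, 4.0)
                       + stats.binom.logpmf([2, 1], n, 0.5).sum() for n in grid])
        pr = np.exp(lp - lp.max())
        pr /= pr.sum()
        emp = np.array([counts.get(int(n), 0) for n in grid]) / n_draws
        assert 0.5 * np.abs(emp - pr).sum() < 0.01

    def test_chain_leaves_conditional_invariant(self):
        """Chi-square goodness of fit of the update chain against the exact
        conditional passes at alpha = 0.01 (thinned draws)."""
        m = _latent_abundance_model()
        st = ModelState(m, {"N": 3.0})
        s = S.DiscreteSliceSampler("N")
        rng = np.random.default_rng(23)
        draws = np.array([s.step(st, rng) for _ in range(60_000)])[::3]
        grid = np.arange(2, 25)
        lp = np.array([stats.poisson.logpmf(n, 4.0)
                       + stats.binom.logpmf([2, 1], n, 0.5).sum() for n in grid])
        pr = np.exp(lp - lp.max())
        pr /= pr.sum()
        obs = np.array([(draws == n).sum() for n in grid])
        keep = pr * draws.size >= 5
        chi2 = (((obs[keep] - pr[keep] * draws.size) ** 2)
                / (pr[keep] * draws.size)).sum()
        crit = stats.chi2.ppf(0.99, keep.sum() - 1)
        assert chi2 < crit


class TestBlockRW:
    def test_recovers_strong_correlation(self):
        m = make_mvn_model(rho=0.95)
        st = ModelState(m, {"x": np.zeros(2)})
        s = S.BlockRWSampler([("x", 0), ("x", 1)])
        rng = np.random.default_rng(29)
        xs = np.empty((80_000, 2))
        for i in range(xs.shape[0]):
            s.step(st, rng)
            xs[i] = st.values["x"]
        corr = np.corrcoef(xs[20_000:].T)[0, 1]
        assert corr == pytest.approx(0.95, abs=0.03)
        prop_corr = s.cov[0, 1] / math.sqrt(s.cov[0, 0] * s.cov[1, 1])
        assert prop_corr == pytest.approx(0.95, abs=0.1)

    def test_dimension_one_reduces_to_scalar_rw(self):
        """A 1-block random walk on N(0,1) has the scalar sampler's
        stationary distribution."""
        m = make_std_normal_model()
        st = ModelState(m, {"x": 0.0})
        s = S.BlockRWSampler([("x", 0)], scale=2.4, adapt=False)
        rng = np.random.default_rng(31)
        xs = np.array([(s.step(st, rng), st.get("x"))[1] for _ in range(60_000)])
        stat, pval = stats.kstest(xs[1000::25], "norm")
        assert pval > 0.01


class TestAFSS:
    def test_leading_factor_aligns_with_principal_axis(self):
        m = make_mvn_model(rho=0.99)
        st = ModelState(m, {"x": np.zeros(2)})
        s = S.AFSSSampler([("x", 0), ("x", 1)])
        rng = np.random.default_rng(37)
        for _ in range(6000):
            s.step(st, rng)
        lead = s.factors[:, 0]
        cos = abs(lead @ np.array([1.0, 1.0]) / math.sqrt(2))
        assert cos > 0.99

    def test_axis_aligned_target_variances(self):
        m = make_mvn_model(rho=0.0)
        st = ModelState(m, {"x": np.zeros(2)})
        s = S.AFSSSampler([("x", 0), ("x", 1)])
        rng = np.random.default_rng(41)
        xs = np.empty((30_000, 2))
        for i in range(xs.shape[0]):
            s.step(st, rng)
            xs[i] = st.values["x"]
        v = xs[5000:].var(axis=0)
        assert np.all(np.abs(v - 1.0) < 0.05)


class TestCommonProperties:
    @pytest.mark.parametrize("factory", [
        lambda: S.ARWMHSampler("x"),
        lambda: S.SliceSampler("x"),
    ])
    def test_bitwise_reproducible(self, factory):
        runs = []
        for _ in range(2):
            xs = run_scalar(factory(), make_std_normal_model(), 0.1, 2000, seed=99)
            runs.append(xs)
        assert np.array_equal(runs[0], runs[1])

    def test_block_samplers_reproducible(self):
        for cls in (S.BlockRWSampler, S.AFSSSampler):
            runs = []
            for _ in range(2):
                m = make_mvn_model(0.5)
                st = ModelState(m, {"x": np.zeros(2)})
                s = cls([("x", 0), ("x", 1)])
                rng = np.random.default_rng(7)
                xs = np.empty((500, 2))
                for i in range(500):
                    s.step(st, rng)
                    xs[i] = st.values["x"]
                runs.append(xs)
            assert np.array_equal(runs[0], runs[1])

    def test_adaptation_settles(self):
        """Tuning parameters drift < 1% (relative) over the last tenth of a
        long run: the diminishing-gain schedule terminates adaptation."""
        s = S.ARWMHSampler("x", scale=10.0)
        m = make_std_normal_model()
        st = ModelState(m, {"x": 0.0})
        rng = np.random.default_rng(43)
        scales = []
        for i in range(200_000):
            s.step(st, rng)
            if i % 1000 == 0:
                scales.append(s.scale)
        tail = np.array(scales[-len(scales) // 10:])
        assert np.ptp(tail) / tail.mean() < 0.01
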