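"""Model builders: declared size contracts, priors, and the equivalence of
latent-state-integrated and latent-state-sampled formulations."""

import itertools
import math

import numpy as np
import pytest

import hiermcmc as hm
from hiermcmc.case_models import default_priors
from hiermcmc.model_core import log_posterior


def _build(kind, H, marg, seed=1, **dims):
    cfg = hm.ModelConfig.for_kind(kind, **dims)
    cfg.hierarchical = H
    cfg.marginalize = marg
    sim = hm.simulate_for(cfg, seed=seed)
    return hm.build_model(cfg, sim.data), sim, cfg


def _random_top_values(model, rng):
    """In-support values for everything except discrete latents."""
    out = {}
    for p in model.params:
        if p.role == "latent":
            continue
        if p.support.kind == "unit_interval":
            out[p.name] = rng.uniform(0.15, 0.85, p.shape)
        elif p.support.kind == "interval":
            out[p.name] = rng.uniform(0.3, 2.0, p.shape)
        else:
            out[p.name] = rng.normal(0.0, 0.5, p.shape)
        out[p.name] = np.asarray(out[p.name]).reshape(p.shape)
    return out


TINY = dict(
    dynocc_single=dict(nsite=3, nyear=3, nvisit=2),
    occ_multisp=dict(nspecies=2, nsite=4, nvisit=3),
    dynocc_multisp=dict(nspecies=2, nsite=2, nyear=3, nvisit=2),
    nmix_zip=dict(nsite=2, nvisit=2),
)


class TestSizeContracts:
    @pytest.mark.parametrize("kind,counts", [
        ("dynocc_single", (7, 4)),
        ("occ_multisp", (20, 10)),
        ("dynocc_multisp", (38, 27)),
        ("nmix_zip", (28, 25)),
    ])
    def test_top_level_counts(self, kind, counts):
        """Declared top-level parameter totals for +H / -H variants."""
        for H, expect in zip((True, False), counts):
            for marg in (True, False):
                m, _, _ = _build(kind, H, marg, **TINY[kind])
                assert m.top_level_count() == expect

    @pytest.mark.parametrize("kind", list(TINY))
    def test_marginalized_variants_have_zero_latents(self, kind):
        for H in (True, False):
            m, _, _ = _build(kind, H, True, **TINY[kind])
            assert m.latent_count() == 0

    def test_detection_forced_latents_not_sampled(self):
        m, sim, _ = _build("dynocc_single", False, False, nsite=8, nyear=4,
                           nvisit=3)
        anydet = sim.data.y.any(axis=2)
        assert m.param_map["z"].size == int((~anydet).sum())
        assert m.meta["latents_to_sample"] == sim.realized["latents_to_sample"]


class TestPriors:
    def test_sd_hyperprior_vanishes_beyond_bound(self):
        m, _, _ = _build("dynocc_single", True, True, **TINY["dynocc_single"])
        rng = np.random.default_rng(0)
        vals = _random_top_values(m, rng)
        vals["sd_phi"] = np.asarray(101.0)
        assert log_posterior(m, vals) == -np.inf

    def test_mean_hyperprior_is_flat_normal(self):
        pr = default_priors("dynocc_single")["mean"]
        assert pr.family == "normal"
        assert pr.param("sd") == 100.0
        m, _, _ = _build("dynocc_single", True, True, **TINY["dynocc_single"])
        term = next(t for t in m.terms if t.name == "prior:mu_phi")
        rng = np.random.default_rng(0)
        vals = _random_top_values(m, rng)
        vals["mu_phi"] = np.asarray(0.0)
        expect = -math.log(100.0) - 0.5 * math.log(2 * math.pi)
        assert term.eval(vals) == pytest.approx(expect)

    def test_probability_scalars_have_flat_unit_priors(self):
        m, _, _ = _build("dynocc_single", False, True, **TINY["dynocc_single"])
        term = next(t for t in m.terms if t.name == "prior:psi1")
        assert term.eval({"psi1": np.asarray(0.31)}) == pytest.approx(0.0)

    def test_nmix_uses_narrower_coefficient_priors(self):
        assert default_priors("nmix_zip")["coef"].param("sd") == 10.0


class TestMarginalizationEquivalence:
    """Log posterior of the integrated variant equals the log of the exact
    latent-summed posterior of the sampled variant, at random parameter
    points on tiny designs."""

    def _enumerate_binary(self, model, vals, names=("z",)):
        sizes = [model.param_map[n].size for n in names]
        tot = -np.inf
        for bits in itertools.product((0.0, 1.0), repeat=sum(sizes)):
            v2 = dict(vals)
            off = 0
            for n, sz in zip(names, sizes):
                v2[n] = np.array(bits[off:off + sz])
                off += sz
            lp = log_posterior(model, v2)
            if np.isfinite(lp):
                tot = np.logaddexp(tot, lp)
        return tot

    @pytest.mark.parametrize("kind", ["dynocc_single", "occ_multisp",
                                      "dynocc_multisp"])
    @pytest.mark.parametrize("H", [True, False])
    def test_occupancy_families(self, kind, H):
        mm, sim, cfg = _build(kind, H, True, **TINY[kind])
        cfg.marginalize = False
        ml = hm.build_model(cfg, sim.data)
        rng = np.random.default_rng(12)
        n_points = 20 if kind == "dynocc_single" else 5
        for _ in range(n_points):
            vals = _random_top_values(mm, rng)
            lp_marg = log_posterior(mm, vals)
            lp_enum = self._enumerate_binary(ml, vals)
            assert lp_enum == pytest.approx(lp_marg, rel=1e-10, abs=1e-9)

    @pytest.mark.parametrize("H", [True, False])
    def test_nmix_family(self, H):
        """Brute force over (suitability, N) pairs; the integrated variant
        truncates N at extreme conditional quantiles, so agreement is at the
        truncation level rather than machine precision."""
        mm, sim, cfg = _build("nmix_zip", H, True, **TINY["nmix_zip"])
        cfg.marginalize = False
        ml = hm.build_model(cfg, sim.data)
        rng = np.random.default_rng(13)
        vals = _random_top_values(mm, rng)
        vals["lam_coef"] = vals["lam_coef"] * 0.4
        vals["det_coef"] = vals["det_coef"] * 0.4
        lp_marg = log_posterior(mm, vals)
        nsuit = ml.param_map["suit"].size
        I = ml.param_map["N"].size
        tot = -np.inf
        for bits in itertools.product((0.0, 1.0), repeat=nsuit):
            for Ns in itertools.product(range(0, 45), repeat=I):
                v2 = dict(vals)
                v2["suit"] = np.array(bits)
                v2["N"] = np.array(Ns, dtype=float)
                lp = log_posterior(ml, v2)
                if np.isfinite(lp):
                    tot = np.logaddexp(tot, lp)
        assert tot == pytest.approx(lp_marg, abs=2e-4)

    def test_single_species_reduces_to_sitewise_occupancy(self):
        """occ_multisp with one species at fixed coefficients equals the sum
        of per-site single-season marginal likelihoods."""
        mm, sim, cfg = _build("occ_multisp", True, True, nspecies=1, nsite=5,
                              nvisit=3)
        rng = np.random.default_rng(3)
        vals = _random_top_values(mm, rng)
        lik_term = next(t for t in mm.terms if t.name == "lik")
        got = lik_term.eval(vals)
        x_occ = sim.data.covariates["x_occ"]
        x_det = sim.data.covariates["x_det"]
        from scipy.special import expit

        expect = 0.0
        for i in range(5):
            psi = expit(vals["occ_coef"][0, 0]
                        + x_occ[i] @ vals["occ_coef"][1:, 0])
            p = expit(vals["det_coef"][0, 0]
                      + x_det[i] @ vals["det_coef"][1:, 0])
            expect += hm.occ_marginal_ll(sim.data.y[0, i], psi, p,
                                         mask=sim.data.mask[0, i])
        assert got == pytest.approx(expect, rel=1e-10)
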