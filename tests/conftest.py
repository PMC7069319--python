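"""Shared fixtures: tiny toy models and reduced-dimension case models."""

import numpy as np
import pytest

from hiermcmc.model_core import HierModel, LogDensityTerm, ParamSpec, Support


def make_std_normal_model():
    """Single real parameter with a standard-normal log density."""
    p = ParamSpec("x", (), Support.real())
    t = LogDensityTerm("lik", ("x",),
                       lambda v: float(-0.5 * float(v["x"]) ** 2
                                       - 0.5 * np.log(2 * np.pi)))
    return HierModel([p], [t])


def make_occupancy_toy(psi=0.4, p=0.5, y=(0, 0)):
    """One site, one season: z ~ Bern(psi), y_j ~ Bern(z * p)."""
    y = np.asarray(y, dtype=float)
    z = ParamSpec("z", (), Support.binary(), role="latent")

    def state_ev(v):
        return float(np.log(psi) if v["z"] == 1 else np.log1p(-psi))

    def obs_ev(v):
        if v["z"] == 0:
            return 0.0 if y.sum() == 0 else -np.inf
        with np.errstate(divide="ignore"):
            return float(np.sum(np.where(y > 0, np.log(p), np.log1p(-p))))

    return HierModel([z], [LogDensityTerm("state", ("z",), state_ev),
                           LogDensityTerm("obs", ("z",), obs_ev)])


def make_mvn_model(rho=0.95, d=2):
    """Zero-mean bivariate normal with unit variances and correlation rho."""
    cov = np.full((d, d), rho) + (1 - rho) * np.eye(d)
    prec = np.linalg.inv(cov)
    p = ParamSpec("x", (d,), Support.real())

    def ev(v):
        x = v["x"]
        return float(-0.5 * x @ prec @ x)

    return HierModel([p], [LogDensityTerm("lik", ("x",), ev)])


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture
def std_normal_model():
    return make_std_normal_model()


@pytest.fixture
def occupancy_toy():
    return make_occupancy_toy()
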