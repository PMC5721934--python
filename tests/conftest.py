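"""Shared fixtures: small ground-truth models and simulated cohorts."""

import numpy as np
import pytest

import colreg.synthetic_data as sd
from colreg.basis import BernsteinBasis, SupportWindow
from colreg.likelihood_fit import FitOptions, fit
from colreg.model_core import ModelSpec, ParameterVector


def two_cov_config(n: int, seed: int) -> sd.GeneratorConfig:
    """Two strata (sex), two standard-normal covariates with true odds
    ratios 1.25 and 0.8 — the canonical recovery setting."""
    covs = (
        sd.CovariateSpec("z1", "continuous", beta=(np.log(1.25),), mean=0.0, sd=1.0),
        sd.CovariateSpec("z2", "continuous", beta=(np.log(0.8),), mean=0.0, sd=1.0),
    )
    probs = {"Never:Female": 0.5, "Never:Male": 0.5}
    return sd.GeneratorConfig(n=n, seed=seed, strata_probs=probs, covariates=covs)


def exact_observations(config: sd.GeneratorConfig):
    sim = sd.generate(config)
    frame = sd.apply_scheme(sim.frame, sd.MeasurementScheme("exact"))
    return sd.to_observations(frame, config), sim


@pytest.fixture(scope="session")
def toy_model():
    """Fixed two-stratum model with hand-picked increasing coefficients."""
    window = SupportWindow(10.0, 50.0, 0.0, np.inf)
    spec = ModelSpec(
        strata=("a", "b"),
        covariate_names=("x1", "x2"),
        basis=BernsteinBasis(5, window),
        link="logit",
    )
    params = ParameterVector(
        theta=np.array(
            [[-6.5, -3.0, -0.5, 1.0, 2.5, 4.5], [-7.0, -3.5, -1.0, 0.5, 2.0, 4.0]]
        ),
        beta=np.array([0.3, -0.2]),
    )
    return spec, params


@pytest.fixture(scope="session")
def small_exact_fit():
    """One seeded 2,000-subject exact-scale cohort and its fit (with vcov)."""
    config = two_cov_config(2000, 42)
    obs, sim = exact_observations(config)
    result = fit(obs, sim.spec)
    return {"config": config, "obs": obs, "sim": sim, "fit": result}


@pytest.fixture(scope="session")
def single_stratum_fit():
    """Covariate-free single-stratum fit of n=2,000 exact draws."""
    config = sd.GeneratorConfig(
        n=2000, seed=7, strata_probs={"Never:Female": 1.0}
    )
    obs, sim = exact_observations(config)
    result = fit(obs, sim.spec, options=FitOptions(compute_vcov=False))
    return {"config": config, "obs": obs, "sim": sim, "fit": result}
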