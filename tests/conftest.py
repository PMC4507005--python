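"""Shared fixtures: small seeded synthetic datasets."""

import numpy as np
import pytest
from hypothesis import settings

from cellqtl import eqtl, preprocess, simulate

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def small_genotypes():
    """100 samples x 500 variants over two synthetic chromosomes."""
    return simulate.simulate_genotypes(100, 500, seed=11)


@pytest.fixture(scope="session")
def small_probes(small_genotypes):
    return simulate.make_probes(small_genotypes, 30, seed=12)


@pytest.fixture(scope="session")
def null_expression(small_genotypes, small_probes):
    """Expression with no genetic effects, 4 latent confounders."""
    E, truth = simulate.simulate_expression(
        small_genotypes, small_probes, [], n_confounders=4,
        confounder_sd=1.0, noise_sd=1.0, seed=13)
    return E, truth


@pytest.fixture(scope="session")
def covariates(null_expression):
    E, _ = null_expression
    pcs = preprocess.compute_pcs(E, 5)
    return eqtl.make_covariates(E.n_samples, pcs)


@pytest.fixture()
def rng():
    return np.random.default_rng(2026)
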