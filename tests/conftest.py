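"""Shared fixtures: small simulated populations reused across test modules.

Everything is generated programmatically at test time; sizes are kept small
enough that the whole suite stays within an interactive budget while still
exercising the real pipeline end to end.
"""

import numpy as np
import pytest

from mdagwas import simpop
from mdagwas.phenoadjust import LMMSpec, fit_lmm, split_groups


def tiny_config(seed: int, **overrides) -> simpop.SimConfig:
    """A miniature population: 1,500 SNPs / 15 QTLs, 6 sires x 120 dams,
    360 genotyped animals."""
    base = dict(
        n_snps=1500,
        n_qtls=15,
        morgans_per_chrom=0.05,
        n_hist_generations=40,
        hist_pop_size=120,
        n_sires=6,
        n_dams=120,
        n_recent_generations=4,
        n_genotyped_generations=3,
        seed=seed,
    )
    base.update(overrides)
    return simpop.SimConfig(**base)


@pytest.fixture(scope="session")
def tiny_population():
    cfg = tiny_config(42)
    founders = simpop.simulate_historical(cfg)
    pop = simpop.simulate_recent(founders, cfg)
    effects = simpop.assign_effects(pop, cfg)
    simpop.compute_phenotypes(pop, effects, cfg)
    return pop, cfg


@pytest.fixture(scope="session")
def tiny_dataset(tiny_population):
    pop, cfg = tiny_population
    return simpop.subsample(pop, 100, seed=5)


@pytest.fixture(scope="session")
def tiny_groups(tiny_dataset):
    fit = fit_lmm(
        tiny_dataset.phenotypes,
        LMMSpec(fixed_factors=["generation", "sex"]),
        geno=tiny_dataset.genotypes,
    )
    return split_groups(fit.residuals)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
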