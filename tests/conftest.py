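"""Shared fixtures: generated at test time, seeded, reused across modules."""

from __future__ import annotations

import numpy as np
import pytest

from sigmanet import (SimParams, generate_fixture_dataset, init_population,
                      run_spatial_epoch, train_on_bundle)
from sigmanet.ancestry import init_ancestral_diversity, overlay_mutations_until_m


@pytest.fixture(scope="session")
def tiny_bundle():
    """Smoke-scale training bundle (30 sims, m=500, n=10)."""
    return generate_fixture_dataset("tiny", seed=1)


@pytest.fixture(scope="session")
def small_bundle():
    """Desk-scale baseline-regime bundle (300 sims, m=1000, n=20)."""
    return generate_fixture_dataset("small", seed=1)


@pytest.fixture(scope="session")
def tiny_model(tiny_bundle):
    return train_on_bundle(tiny_bundle, patience=12, seed=0, batch_size=10)


@pytest.fixture(scope="session")
def equilibrium_pop():
    """One settled spatial simulation used by several structural tests."""
    params = SimParams(sigma_f=0.6, sigma_m=0.6, sigma_c=0.6, K=5, W=12,
                       T_spatial=120, genome_length=2.5e7, seed=42)
    pop = run_spatial_epoch(params)
    assert pop.extinct_at is None
    return pop


@pytest.fixture(scope="session")
def site_pool(equilibrium_pop):
    """Sampled individuals plus an overlaid SNP pool from one simulation."""
    pop = equilibrium_pop
    rng = np.random.default_rng(7)
    sample = rng.choice(pop.alive_indices, size=12, replace=False)
    record = init_ancestral_diversity(pop, sample, mode="unlinked", seed=5)
    pool = overlay_mutations_until_m(record, 1200, seed=6)
    return pop, sample, pool


@pytest.fixture(scope="session")
def rousset_sim():
    """Isolation-by-distance dataset with known density for the baseline.

    Small dispersal relative to the habitat, n=100 individuals, m=5000
    SNPs; density is computed from the tracked inbreeding effective size.
    """
    sigma = 0.4
    params = SimParams(sigma_f=sigma, sigma_m=sigma, sigma_c=sigma, K=5, W=15,
                       T_spatial=300, genome_length=2.5e7, seed=99)
    pop = run_spatial_epoch(params)
    assert pop.extinct_at is None
    rng = np.random.default_rng(11)
    # crop one sigma from the edges, as in training-set sampling
    idx = pop.alive_indices
    ok = ((pop.x[idx] > sigma) & (pop.x[idx] < params.W - sigma)
          & (pop.y[idx] > sigma) & (pop.y[idx] < params.W - sigma))
    sample = rng.choice(idx[ok], size=100, replace=False)
    record = init_ancestral_diversity(pop, sample, mode="unlinked", seed=12)
    pool = overlay_mutations_until_m(record, 6000, seed=13)
    return params, pop, sample, pool


def make_pop(positions, W=10.0, **kwargs):
    """Population with founders at fixed positions (helper for unit tests)."""
    defaults = dict(sigma_f=1.0, sigma_m=1.0, sigma_c=1.0, K=5.0, W=W,
                    T_spatial=10, seed=0)
    defaults.update(kwargs)
    params = SimParams(**defaults)
    xs = np.asarray([p[0] for p in positions], dtype=float)
    ys = np.asarray([p[1] for p in positions], dtype=float)
    return init_population(params, founders=(xs, ys))
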