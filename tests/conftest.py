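"""Shared synthetic datasets, built once per session to keep the suite fast."""

import numpy as np
import pytest

from strainpair import sim


@pytest.fixture(scope="session")
def small_ancestor():
    return sim.simulate_ancestor([120_000], gc_content=0.36, seed=11)


@pytest.fixture(scope="session")
def diverged_pair(small_ancestor):
    """120 kb two-strain pair with one SV of each class plus a decoy."""
    model = sim.DivergenceModel(
        snp_rate=0.005,
        small_indel_rate=0.0002,
        sv_counts={c: 1 for c in sim.SV_CLASSES},
        sv_size_dist={c: (500, 1500) for c in sim.SV_CLASSES},
        decoy_collapsed=1,
        seed=12,
    )
    return sim.diverge(small_ancestor, model)


@pytest.fixture(scope="session")
def snp_only_pair():
    """SNP-only divergence of a 150 kb ancestor (no structural events)."""
    anc = sim.simulate_ancestor([150_000], seed=21)
    model = sim.DivergenceModel(snp_rate=0.005, small_indel_rate=0.0, sv_counts={}, seed=22)
    C, R, truth = sim.diverge(anc, model)
    return anc, C, R, truth


@pytest.fixture(scope="session")
def pop_matrix():
    return sim.simulate_populations(
        sim.PopulationSimSpec(
            n_individuals_per_pop=9, n_sites=3000, between_pop_divergence=0.05, seed=31
        )
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(7)
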