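import numpy as np
import pytest

from isopop.containers import GenotypeMatrix, make_individual_table
from isopop.fstats import BlockDefinition, population_frequencies
from isopop.pipeline import (DEMO_FIT_LEAVES, DEMO_SAMPLED_POPS, demo_graph,
                             graph_restricted_to)
from isopop.simulate import (SimulationConfig, sample_diploid_genotypes,
                             simulate_graph_frequencies, synthetic_snp_table)


@pytest.fixture
def rng():
    return np.random.default_rng(20260921)


@pytest.fixture
def small_snps(rng):
    return synthetic_snp_table(200, rng)


def make_genotypes(calls, snps, populations, era=None, ploidy=None):
    """Assemble a GenotypeMatrix from a raw call array and population
    labels (one per row)."""
    calls = np.asarray(calls, dtype=np.int8)
    n = calls.shape[0]
    ids = [f"ind{i}" for i in range(n)]
    table = make_individual_table(
        ids, populations, era=era or ["modern"] * n, ploidy_mode=ploidy)
    return GenotypeMatrix(calls, snps.iloc[:calls.shape[1]]
                          .reset_index(drop=True), table)


def simulate_world(seed, n_snps=20_000, n_per_pop=15,
                   pops=DEMO_SAMPLED_POPS, alpha=0.30):
    """One replicate of the demo study: graph frequencies, diploid panels,
    population frequencies and 5 Mb jackknife blocks."""
    rng = np.random.default_rng(seed)
    graph = demo_graph(alpha)
    cfg = SimulationConfig(n_snps=n_snps, seed=seed)
    freqs = simulate_graph_frequencies(graph, cfg, rng)
    snps = synthetic_snp_table(n_snps, rng)
    g = sample_diploid_genotypes(freqs, {p: n_per_pop for p in pops},
                                 rng, snps=snps)
    pf = population_frequencies(g)
    blocks = BlockDefinition.from_positions(snps)
    fit_leaves = tuple(p for p in DEMO_FIT_LEAVES if p in pops)
    return {"graph": graph, "freqs": freqs, "snps": snps, "genotypes": g,
            "pf": pf, "blocks": blocks, "rng": rng,
            "fit_topology": graph_restricted_to(graph, fit_leaves)}


@pytest.fixture(scope="session")
def world():
    """A single mid-sized replicate shared by read-only tests."""
    return simulate_world(seed=7)
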