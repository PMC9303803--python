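import numpy as np
import pytest

from panelforge import GenotypeMatrix, SimConfig, sim_pedigree, sim_population


def make_matrix(calls, ploidy=None, contig=None, position=None, sample_ids=None):
    """Small literal GenotypeMatrix for unit tests."""
    calls = np.asarray(calls, dtype=np.int8)
    n_samples, n_loci = calls.shape
    if ploidy is None:
        ploidy = np.full(n_samples, 2)
    if contig is None:
        contig = np.array(["c1"] * n_loci, dtype=object)
    if position is None:
        position = np.arange(1, n_loci + 1) * 100
    return GenotypeMatrix(
        sample_ids=sample_ids or [f"s{i}" for i in range(n_samples)],
        locus_ids=[f"m{j}" for j in range(n_loci)],
        calls=calls,
        ploidy=np.asarray(ploidy),
        contig=np.asarray(contig, dtype=object),
        position=np.asarray(position),
    )


@pytest.fixture(scope="session")
def small_population():
    return sim_population(SimConfig(seed=101, n_loci=500, n_pop_samples=40))


@pytest.fixture(scope="session")
def pedigree_sim():
    """Moderate-scale clean crossing design shared across tests."""
    cfg = SimConfig(seed=202, n_loci=10_000, n_pop_samples=18, maf_model=("uniform", 0.08, 0.5))
    founders = sim_population(cfg)
    founders.sample_ids[:] = [f"P{i + 1:02d}" for i in range(18)]
    matrix, pedigree = sim_pedigree(cfg, founders)
    return matrix, pedigree
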