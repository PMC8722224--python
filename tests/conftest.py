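import numpy as np
import pytest

from tadascope.genome import GenomeSequences, find_gatc_sites
from tadascope.simulate import SimConfig, simulate_dataset


@pytest.fixture(scope="session")
def default_sim():
    """Default study-condition simulation: ~2000 fragments, 100 genes,
    20% differential at |log2FC|=2, depth 1e6, dispersion 0.1, 3v3."""
    cfg = SimConfig(seed=1)
    genome, gatc, genes, truth, counts, samples = simulate_dataset(cfg)
    return {
        "config": cfg,
        "genome": genome,
        "gatc": gatc,
        "genes": genes,
        "truth": truth,
        "counts": counts,
        "samples": samples,
    }


@pytest.fixture(scope="session")
def small_sim():
    """Small, fast dataset for IO round-trips."""
    cfg = SimConfig(
        seed=7, contig_length=80_000, n_genes=10, depth=20_000, gene_length=2_000
    )
    genome, gatc, genes, truth, counts, samples = simulate_dataset(cfg)
    return {
        "config": cfg,
        "genome": genome,
        "gatc": gatc,
        "genes": genes,
        "truth": truth,
        "counts": counts,
        "samples": samples,
    }


@pytest.fixture()
def toy_genome():
    seq = "AATTGATCCCGGGATCTTAAGGATCAA"
    return GenomeSequences([("chr1", seq)])


@pytest.fixture()
def toy_gatc(toy_genome):
    return find_gatc_sites(toy_genome)


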