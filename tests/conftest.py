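import numpy as np
import pytest

from bathypan import simgenome as sg
from bathypan import validation as V


@pytest.fixture(scope="session")
def small_cfg() -> sg.SimConfig:
    """650-kb BOC chromosome with the study-size 400/500-kb outlier, two
    companion chromosomes; composition parameters at study conditions."""
    return V.boc_pair_config(101)


@pytest.fixture(scope="session")
def boc_pair(small_cfg):
    ancestor, _ = sg.build_ancestor(small_cfg)
    hapl_a, hapl_b, truth = sg.derive_boc_haplotypes(ancestor, small_cfg)
    return ancestor, hapl_a, hapl_b, truth


@pytest.fixture(scope="session")
def boc_alignment(small_cfg, boc_pair):
    """Classified blocks + non-syntenic intervals of the haplotype pair's
    BOC chromosome (shared across alignment/divergence tests)."""
    _anc, hapl_a, hapl_b, truth = boc_pair
    chrom = small_cfg.boc_chrom
    blocks, nonsyn = V.align_chromosome(hapl_a.seq(chrom), hapl_b.seq(chrom),
                                        chrom)
    return blocks, nonsyn


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20_240_901)


def random_dna(rng, n: int) -> str:
    return np.frombuffer(b"ACGT", np.uint8)[
        rng.integers(0, 4, n)].tobytes().decode()
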