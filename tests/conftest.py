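import numpy as np
import pytest
from hypothesis import settings

from guidekit import (make_genome, make_occupancy_track, design_library,
                      design_nontargeting)

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def small_genome():
    """Two 50 kb chromosomes, 100 PAM-seeded genes (seed 1)."""
    return make_genome(n_chrom=2, lengths=50_000, genes_per_chrom=50, seed=1)


@pytest.fixture(scope="session")
def small_library(small_genome):
    genome, genes = small_genome
    lib = design_library(genome, genes, "cas12a", n_per_gene=8)
    lib.guides.extend(design_nontargeting(genome, 20, seed=7))
    return lib


@pytest.fixture(scope="session")
def small_track(small_genome):
    genome, _ = small_genome
    return make_occupancy_track(genome, seed=5)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


def random_seq(rng, n):
    return "".join(rng.choice(list("ACGT"), size=n))
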