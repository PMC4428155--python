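import numpy as np
import pytest

from wgrbench.genotype_sim import (
    COMMON_MARKER_LAW,
    HaplotypePoolSpec,
    simulate_genotypes,
)


@pytest.fixture(scope="session")
def small_panel():
    """500 individuals x 200 loci, moderate block LD."""
    spec = HaplotypePoolSpec(
        n_blocks=8, markers_per_block=25, within_block_switch_prob=0.05,
        maf_law=COMMON_MARKER_LAW, seed=42,
    )
    return simulate_genotypes(spec, 500)


@pytest.fixture(scope="session")
def free_recomb_panel():
    """500 individuals x 60 independent loci (free recombination)."""
    spec = HaplotypePoolSpec(
        n_blocks=1, markers_per_block=60, within_block_switch_prob=0.5, seed=7,
    )
    return simulate_genotypes(spec, 500)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
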