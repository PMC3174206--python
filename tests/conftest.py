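import numpy as np
import pytest

from atskew import SynthConfig, generate_genome
from atskew.datasets import (
    tw20_leading_composition,
    tw20_leading_rates,
    tw20_leading_singleton_counts,
)


@pytest.fixture(scope="session")
def tw20_counts():
    return tw20_leading_singleton_counts()


@pytest.fixture(scope="session")
def tw20_rates():
    return tw20_leading_rates()


@pytest.fixture(scope="session")
def tw20_composition():
    return tw20_leading_composition()


@pytest.fixture(scope="session")
def small_synth():
    """A ~120 kb synthetic chromosome with the default study-condition
    parameters (78% leading orientation, TW20-derived frequencies)."""
    cfg = SynthConfig(genome_length=120_000, n_genes=80, gene_length_codons=(180.0, 40.0), seed=11)
    return generate_genome(cfg)


@pytest.fixture(scope="session")
def eligible_composition(small_synth):
    """Leading-strand base counts of the eligible ex-operonic sites."""
    cls = small_synth.truth.classification
    idx = np.flatnonzero(cls.class_mask("intergenic_ex"))
    arr = small_synth.genome.base_array()[idx]
    comp = np.array([3, 2, 1, 0])
    lead = np.where(cls.sense[idx] == 1, arr, comp[arr])
    return np.bincount(lead, minlength=4).astype(float)
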