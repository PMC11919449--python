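import numpy as np
import pytest

import esalign
from esalign.tokenizer import train_vocab


@pytest.fixture(scope="session")
def small_genome():
    """100 kb single-chromosome repeat-free genome."""
    genome, _ = esalign.generate_synthetic_genome([100_000], seed=42)
    return genome


@pytest.fixture(scope="session")
def two_chrom_genome():
    genome, _ = esalign.generate_synthetic_genome([60_000, 40_000], seed=7)
    return genome


@pytest.fixture(scope="session")
def small_tokenizer(small_genome):
    return train_vocab(list(small_genome.chromosomes.values()),
                       vocab_size=256, seed=0, max_corpus_bases=60_000)


def random_dna(n, seed):
    rng = np.random.default_rng(seed)
    return "".join("ACGT"[i] for i in rng.integers(0, 4, n))
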