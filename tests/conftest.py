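import numpy as np
import pytest

from cfrag.fragment_io import FragmentFrame, FragmentRecord
from cfrag.synthetic import (
    SyntheticConfig,
    choose_ground_truth,
    simulate_reference,
)


@pytest.fixture(scope="session")
def small_config():
    return SyntheticConfig(
        seed=11,
        n_chromosomes=1,
        chromosome_length=100_000,
        n_genes=20,
        n_expressed_genes=4,
        n_responders=4,
        n_nonresponders=4,
        fragments_per_sample=5_000,
    )


@pytest.fixture(scope="session")
def small_reference(small_config):
    return simulate_reference(small_config)


@pytest.fixture(scope="session")
def small_truth(small_config, small_reference):
    return choose_ground_truth(small_reference, small_config)


def random_fragments(rng, n, chrom="chr1", chrom_length=10_000, max_len=300):
    """Plain random valid fragments for oracle checks."""
    starts = rng.integers(0, chrom_length - max_len, size=n)
    lengths = rng.integers(30, max_len, size=n)
    return FragmentFrame(
        chrom=np.full(n, chrom, dtype=object),
        start=starts,
        end=starts + lengths,
        strand=rng.choice(np.array(["+", "-"], dtype=object), size=n),
        mapq=rng.integers(0, 61, size=n),
        mismatches=rng.integers(0, 8, size=n),
        proper_pair=rng.random(n) < 0.9,
        duplicate=rng.random(n) < 0.05,
        multimapped=rng.random(n) < 0.05,
    )


def random_sequence(rng, length):
    return "".join(rng.choice(list("ACGT"), size=length))
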