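"""Shared fixtures: small, fast simulated scenarios.

The small scenario keeps the full architecture (two paralogs, tandem arrays,
markers) but shrinks the genome so a simulate+classify+map cycle takes a few
seconds; study-scale runs live in the acceptance suite.
"""

import numpy as np
import pytest

import taltfinder as tf


SMALL = dict(
    chrom_length=120_000,
    template_length=3_000,
    pre_alt_telomere_length=2_000,
    coverage=30.0,
)


@pytest.fixture(scope="session")
def small_config() -> tf.SimConfig:
    return tf.SimConfig(seed=1, **SMALL)


@pytest.fixture(scope="session")
def small_alt(small_config):
    return tf.build_alt_genome(small_config)


@pytest.fixture(scope="session")
def small_pre(small_config):
    return tf.build_pre_alt_genome(small_config)


@pytest.fixture(scope="session")
def small_reference(small_config):
    return tf.build_reference_genome(small_config)


@pytest.fixture(scope="session")
def small_index(small_reference):
    return tf.build_seed_index(small_reference, k=15)


@pytest.fixture(scope="session")
def small_alt_reads(small_alt, small_config):
    genome, _ = small_alt
    return tf.simulate_reads(genome, small_config)


@pytest.fixture(scope="session")
def small_pre_reads(small_pre, small_config):
    genome, _ = small_pre
    return tf.simulate_reads(genome, small_config)


@pytest.fixture(scope="session")
def small_alt_classified(small_alt_reads):
    return tf.classify_pairs(small_alt_reads)


@pytest.fixture(scope="session")
def small_pre_classified(small_pre_reads):
    return tf.classify_pairs(small_pre_reads)


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)
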