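import math

import numpy as np
import pytest

from g4splice.synthetic_data import SynthConfig, generate_bundle


@pytest.fixture(scope="session")
def small_bundle():
    """A compact deterministic bundle shared by read-only tests."""
    cfg = SynthConfig(seed=11, n_chroms=2, chrom_length=250_000, n_genes=40,
                      intron_length_logn=(math.log(500), 0.6))
    return generate_bundle(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
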