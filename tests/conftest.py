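import numpy as np
import pytest

from mti.simulate import SimConfig, emit_utrs, generate_truth


@pytest.fixture(scope="session")
def small_config():
    """A scaled-down study: same structure, 250 genes instead of 4,500."""
    return SimConfig(
        n_genes=250,
        n_effective_targets=25,
        n_escape_targets=5,
        n_transcriptome_only=4,
    )


@pytest.fixture(scope="session")
def small_truth(small_config):
    return generate_truth(small_config, 11)


@pytest.fixture(scope="session")
def small_emission(small_truth):
    return emit_utrs(small_truth)


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)
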