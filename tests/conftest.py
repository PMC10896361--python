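import numpy as np
import pytest

from dnaclr import CommunityConfig, EncoderConfig, make_community
from dnaclr.baselines import build_tnfk_kernel
from dnaclr.pairs import build_pairs


@pytest.fixture(scope="session")
def kernel():
    return build_tnfk_kernel()


@pytest.fixture(scope="session")
def tiny_encoder_config():
    return EncoderConfig(k=4, n_layers=2, hidden_dim=16, n_heads=2,
                         max_tokens=64, dropout_rate=0.1)


@pytest.fixture(scope="session")
def small_community():
    """20 species, strong composition signal, compact fragments."""
    return make_community(CommunityConfig(
        n_species=20, genome_length=4000, fragments_per_species=25,
        fragment_length=400, divergence=0.8, seed=11))


@pytest.fixture(scope="session")
def small_pairs(small_community):
    rng = np.random.default_rng(5)
    return build_pairs(small_community.genomes, 60, 250, rng)


def random_dna(rng, length):
    return "".join(rng.choice(list("ACGT"), size=length))
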