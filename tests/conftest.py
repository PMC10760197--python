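import numpy as np
import pytest

import tnvae as tv


@pytest.fixture(scope="session")
def hmm_params():
    return tv.load_preset("hmm_sleep")


@pytest.fixture(scope="session")
def hmm_ts(hmm_params):
    return tv.simulate_hmm(hmm_params, 3000, seed=0)


@pytest.fixture(scope="session")
def spiral_params():
    return tv.SpiralParams(n_points=2000, turns=3.0, noise_sd=0.1, embed_dim=31, embed_seed=0)


@pytest.fixture(scope="session")
def spiral_ts(spiral_params):
    return tv.simulate_spiral(spiral_params, seed=0)


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def tiny_vae():
    cfg = tv.VAEConfig(n_layers=2, layer_dim=8, latent_dim=2, beta=1e-3,
                       batch_size=4, learning_rate=1e-3, seed=7)
    return tv.VAE(cfg, input_dim=5)


def zero_params(vae):
    for k in vae.params:
        vae.params[k][...] = 0.0
    return vae
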