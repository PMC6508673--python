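import numpy as np
import pytest

import ghostbirds as gb


@pytest.fixture(scope="session")
def landscape():
    """A mid-sized default-parameter landscape shared across tests."""
    return gb.simulate_landscape(dims=(300, 300), seed=11)


@pytest.fixture(scope="session")
def metric_table(landscape):
    """A labelled classifier table sampled from the shared landscape."""
    return gb.sample_metric_points(landscape, n_points=248,
                                   min_spacing=100.0, seed=3)


@pytest.fixture(scope="session")
def tiny_fit():
    """A small but informative posterior fit reused by summary-level tests."""
    hyper = gb.default_community_hyper()
    params, y, design = gb.simulate_community_dataset(
        hyper, n_species=12, n_sites=80, n_occasions=3, seed=21)
    cfg = gb.SamplerConfig(chains=3, iterations=3000, burn_in=1000, thin=5)
    post = gb.sample_posterior(y, design, cfg, seed=22)
    return params, y, design, post
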