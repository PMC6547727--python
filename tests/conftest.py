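import numpy as np
import pytest

import polymix as pm
from polymix.likelihood import make_context


@pytest.fixture(scope="session")
def toy_panel():
    """Two 10-SNP AR-correlated blocks: small enough for brute-force oracles."""
    panel, ld = pm.synthetic.make_panel(2, 10, phi=0.85, seed=3)
    return panel, ld


@pytest.fixture(scope="session")
def toy_context(toy_panel):
    panel, ld = toy_panel
    scores = pm.ld_scores(ld, panel)
    return make_context(ld, panel, scores, n1=1e4, n2=1e4, include_neighbors=True)


@pytest.fixture(scope="session")
def medium_study():
    """A 5000-SNP block-LD panel with pruning weights, shared across tests."""
    panel, ld = pm.synthetic.make_panel(100, 50, phi=0.9, seed=7)
    scores = pm.ld_scores(ld, panel)
    weights = pm.random_pruning_weights(ld, r2_thresh=0.1, T=64, seed=7)
    return panel, ld, scores, weights
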