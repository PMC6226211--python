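"""Shared fixtures: small synthetic networks and one full pipeline run.

Everything is generated programmatically with fixed seeds; the session-scoped
pipeline run is reused by every test that only inspects results.
"""

import numpy as np
import pandas as pd
import pytest

from chemgen import pipeline, synthetic


@pytest.fixture(scope="session")
def network():
    """Default-sized modular genetic network (100 strains, 60 queries)."""
    return synthetic.generate_genetic_network(seed=11)


@pytest.fixture(scope="session")
def screen(network):
    gi, ann = network
    return synthetic.generate_screen(gi, ann, seed=12)


@pytest.fixture(scope="session")
def planted_run(network, screen):
    """One full prediction run on the planted-signal screen."""
    gi, ann = network
    cg, truth = screen
    cfg = pipeline.PredictConfig(n_resampled=5000, n_permutations=2000, seed=13)
    result = pipeline.run_predict(cg, gi, ann, cfg)
    return result, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(7)


@pytest.fixture()
def tiny_cg():
    """3 strains x 4 conditions with explicit values and types."""
    from chemgen.containers import ChemGenProfileSet
    scores = pd.DataFrame(
        [[1.0, -2.0, 0.5, 3.0],
         [0.0, 1.5, -1.0, -4.0],
         [2.0, 0.0, 2.5, 1.0]],
        index=["s1", "s2", "s3"],
        columns=["t1", "t2", "c1", "c2"],
    )
    types = pd.Series(["treatment", "treatment", "control", "control"],
                      index=scores.columns)
    return ChemGenProfileSet(scores, types)
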