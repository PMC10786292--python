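import numpy as np
import pytest

import plastconn as pc


@pytest.fixture(scope="session")
def toy_regions():
    """20-region bilateral table (8 cortical + 2 CC per hemisphere)."""
    return pc.toy_parcellation(8, 2)


@pytest.fixture(scope="session")
def paper_regions():
    return pc.language_parcellation()


@pytest.fixture(scope="session")
def small_cohort(toy_regions):
    """Null cohort, 12 participants, no dropout (fast shared fixture)."""
    cfg = pc.SimulationConfig(n_participants=12, dropout_per_period=(0, 0),
                              seed=42)
    return cfg, pc.simulate_connectomes(cfg, toy_regions)


@pytest.fixture(scope="session")
def study_cohort(paper_regions):
    """Study-style cohort with planted effects, scores and vocabulary."""
    cfg = pc.study_config(paper_regions, seed=7)
    data = pc.simulate_connectomes(cfg, paper_regions)
    scores = pc.simulate_scores(cfg, data)
    vocab = pc.simulate_vocabulary(cfg, scores)
    return cfg, data, scores, vocab


def random_cohort(regions, n_participants, timepoints, seed, scale=1.0):
    """Ad-hoc random symmetric nonnegative cohort (no generative structure)."""
    rng = np.random.default_rng(seed)
    n = regions.n_regions
    mats = {}
    for k in range(n_participants):
        for tp in timepoints:
            m = rng.random((n, n)) * scale
            m = np.triu(m, 1)
            m = m + m.T
            mats[(f"S{k:02d}", tp)] = m
    return pc.LongitudinalConnectomes(regions, mats)
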