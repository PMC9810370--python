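import numpy as np
import pytest

import graphbold as gb


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_graph():
    """Connected weighted graph on 10 nodes (simulation ground truth)."""
    return gb.make_graph(10, 0.4, seed=7)


@pytest.fixture(scope="session")
def path3():
    """3-node path graph 1-2-3 with unit weights."""
    w = np.zeros((3, 3))
    w[0, 1] = w[1, 0] = 1.0
    w[1, 2] = w[2, 1] = 1.0
    return gb.WeightedAdjacency(w, kind="synthetic")


@pytest.fixture(scope="session")
def tiny_session():
    """Short synthetic session on the default benchmark graph."""
    cfg = gb.SyntheticConfig(n_regions=8, n_timepoints=300, n_sessions=1,
                             seed=11)
    sessions, graph, coupling = gb.make_benchmark(cfg)
    return sessions[0], graph, coupling


@pytest.fixture(scope="session")
def trained_splits():
    """Small standardized benchmark splits shared by training-level tests."""
    cfg = gb.SyntheticConfig(n_regions=8, n_timepoints=300, n_sessions=1,
                             seed=5)
    sessions, graph, coupling = gb.make_benchmark(cfg)
    scaled, _ = gb.scale(sessions, "zscore")
    pairs = [gb.make_windows(ts, 10, 5) for ts in scaled]
    train, val, test = gb.split_windows(pairs)
    return (train, val, test), graph, coupling
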