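import numpy as np
import pandas as pd
import pytest

from dendropart.network import StreamNetwork, build_network
from dendropart.simulate import SimulationScenario, simulate_dataset


def make_network(nodes, segments) -> StreamNetwork:
    """Build a network from terse (id, x, y, z) and (up, down, length) rows."""
    node_df = pd.DataFrame(nodes, columns=["node_id", "x", "y", "elevation"])
    node_df["is_site"] = True
    seg_df = pd.DataFrame(segments, columns=["up_node", "down_node", "length"])
    seg_df.insert(0, "segment_id", [f"s{i}" for i in range(len(seg_df))])
    return build_network(node_df, seg_df)


@pytest.fixture
def chain3():
    """Three sites in a line: a -> b -> c (downstream), 100 m and 250 m."""
    return make_network(
        [("a", 0, 0, 4800), ("b", 100, 0, 4400), ("c", 350, 0, 4000)],
        [("a", "b", 100.0), ("b", "c", 250.0)],
    )


@pytest.fixture
def y_network():
    """Two sibling headwaters joining at a confluence site.

    a (4200 m) and b (4200 m) drain into c (4000 m), then to outlet d.
    """
    return make_network(
        [
            ("a", -150, 200, 4200.0),
            ("b", 150, 250, 4200.0),
            ("c", 0, 0, 4000.0),
            ("d", 0, -300, 3900.0),
        ],
        [("a", "c", 200.0), ("b", "c", 300.0), ("c", "d", 300.0)],
    )


def random_tree_network(seed: int, n: int = 20) -> StreamNetwork:
    """Random dendritic tree with random planar positions and elevations."""
    rng = np.random.default_rng(seed)
    parents = [None] + [int(rng.integers(0, i)) for i in range(1, n)]
    # reject parents that already have 2 upstream children
    counts = {}
    for i in range(1, n):
        p = parents[i]
        while counts.get(p, 0) >= 2:
            p = int(rng.integers(0, i))
        parents[i] = p
        counts[p] = counts.get(p, 0) + 1
    depth = [0] * n
    for i in range(1, n):
        depth[i] = depth[parents[i]] + 1
    nodes = [
        (i, float(rng.uniform(0, 1000)), float(rng.uniform(0, 1000)),
         4000.0 + 100.0 * depth[i] + float(rng.uniform(0, 30)))
        for i in range(n)
    ]
    segments = [
        (i, parents[i], float(rng.uniform(50, 500))) for i in range(1, n)
    ]
    return make_network(nodes, segments)


@pytest.fixture(scope="session")
def default_dataset():
    """One default synthetic dataset, shared across tests (read-only)."""
    return simulate_dataset(SimulationScenario(seed=42))


@pytest.fixture(scope="session")
def default_scenario():
    return SimulationScenario(seed=42)
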