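import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracles helper module

from cdlink.fixtures import make_ba, make_er, make_struct_equiv, make_toy, make_ws


@pytest.fixture(scope="session")
def toy_graphs():
    """Deterministic canonical graphs keyed by a short name."""
    return {
        "path3": make_toy("path", 3),
        "path4": make_toy("path", 4),
        "path5": make_toy("path", 5),
        "cycle5": make_toy("cycle", 5),
        "star5": make_toy("star", 5),
        "k4": make_toy("complete", 4),
        "k5": make_toy("complete", 5),
        "k6": make_toy("complete", 6),
    }


@pytest.fixture(scope="session")
def small_random_graphs():
    """Connected random graphs with n <= 12 for brute-force comparisons."""
    gs = [make_er(10, 0.35, seed=s, connected=True) for s in range(4)]
    gs.append(make_ba(12, 2, seed=7))
    gs.append(make_ws(12, 4, 0.2, seed=3))
    gs.append(make_struct_equiv(make_er(9, 0.4, seed=11, connected=True), 2))
    return gs


@pytest.fixture(scope="session")
def oracle_suite_graphs(toy_graphs, small_random_graphs):
    """Everything the brute-force oracle suites run on."""
    return list(toy_graphs.values()) + small_random_graphs
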