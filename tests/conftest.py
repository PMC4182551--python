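import networkx as nx
import numpy as np
import pytest

import ewrank
from ewrank.fixtures import FixtureParams, generate_fixture


@pytest.fixture(scope="session")
def bundle():
    """Default synthetic bundle: 30-protein planted core, 120 periphery."""
    return generate_fixture(FixtureParams())


@pytest.fixture(scope="session")
def measure_table(bundle):
    """GE/PCC/NTE table for the default bundle (shared, read-only)."""
    return ewrank.build_measure_table(
        bundle.net, expr=bundle.expr, annots=bundle.annots
    )


@pytest.fixture(scope="session")
def full_measure_table(bundle):
    """All four measures (incl. the alignment-based distance) on the bundle."""
    return ewrank.build_measure_table(
        bundle.net, expr=bundle.expr, annots=bundle.annots, seqs=bundle.seqs,
        enabled=("GE", "PCC", "NTE", "PP"),
    )


@pytest.fixture(scope="session")
def ranked(measure_table):
    return ewrank.rank_edges(measure_table)


@pytest.fixture(scope="session")
def fixture_dir(bundle, tmp_path_factory):
    d = tmp_path_factory.mktemp("bundle")
    ewrank.write_fixture(bundle, d)
    return d


def random_graph(rng: np.random.Generator, n: int, p: float) -> nx.Graph:
    """Erdős–Rényi graph with string node labels (seeded)."""
    g = nx.gnp_random_graph(n, p, seed=int(rng.integers(2**31)))
    return nx.relabel_nodes(g, {i: f"n{i:03d}" for i in g.nodes})
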