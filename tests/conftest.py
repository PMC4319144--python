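import networkx as nx
import pytest

from mhealthscape import AppRecord, GeneratorConfig, TagAssignment


def make_assignment(app_id: str, tags) -> TagAssignment:
    tags = frozenset(tags)
    return TagAssignment(
        app_id=app_id, tags=tags, matched_strings=frozenset(), included=len(tags) >= 4
    )


def make_record(app_id="a0", description="", store="ios", **kw) -> AppRecord:
    return AppRecord(
        app_id=app_id,
        store=store,
        category="medical",
        description=description,
        **kw,
    )


@pytest.fixture
def two_triangles() -> nx.Graph:
    g = nx.Graph()
    g.add_edges_from(
        [("a", "b"), ("b", "c"), ("a", "c"), ("d", "e"), ("e", "f"), ("d", "f")],
        weight=1,
    )
    return g


@pytest.fixture
def small_config() -> GeneratorConfig:
    return GeneratorConfig(n_apps=300, seed=42)


def random_weighted_graph(seed: int, n: int = 20, p: float = 0.2) -> nx.Graph:
    import numpy as np

    rng = np.random.default_rng(seed)
    g = nx.gnp_random_graph(n, p, seed=int(rng.integers(2**31)))
    out = nx.Graph()
    out.add_nodes_from(f"v{i:02d}" for i in range(n))
    for u, v in g.edges:
        out.add_edge(f"v{u:02d}", f"v{v:02d}", weight=int(rng.integers(1, 4)))
    return out
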