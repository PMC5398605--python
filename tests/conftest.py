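import numpy as np
import pytest

import fragnet as fn


@pytest.fixture
def two_site_graph():
    """2 sites x 3 pupils, 2 intra-site edges each: 6 nodes, 4 edges,
    2 components."""
    nodes = []
    for s, (x, y) in enumerate([(0.0, 0.0), (1000.0, 0.0)]):
        for p in range(3):
            nodes.append({"id": f"s{s}p{p}", "site_id": f"site{s}",
                          "district_id": f"d{s}", "x": x, "y": y,
                          "activities": ["sports"] if p == 0 else []})
    edges = [("s0p0", "s0p1"), ("s0p1", "s0p2"),
             ("s1p0", "s1p1"), ("s1p1", "s1p2")]
    return fn.AttributedGraph.from_records(nodes, edges)


@pytest.fixture(scope="session")
def small_city():
    """Default 20-school x 30-pupil city: (truth, observed, hidden)."""
    truth = fn.generate_truth(fn.CityConfig(seed=42))
    observed, hidden = fn.apply_boundary_specification(truth)
    return truth, observed, hidden


def random_attributed_graph(rng: np.random.Generator, n_max: int = 20):
    """A random site-annotated graph for metric cross-checks."""
    n = int(rng.integers(4, n_max + 1))
    n_sites = int(rng.integers(2, 5))
    site_xy = {f"s{k}": (float(rng.uniform(0, 5000)),
                         float(rng.uniform(0, 5000))) for k in range(n_sites)}
    nodes = []
    for i in range(n):
        s = f"s{int(rng.integers(0, n_sites))}"
        nodes.append({"id": f"n{i}", "site_id": s, "district_id": "d0",
                      "x": site_xy[s][0], "y": site_xy[s][1]})
    edges = []
    for i in range(n):
        for j in range(i + 1, n):
            if rng.random() < 0.3:
                edges.append((f"n{i}", f"n{j}"))
    return fn.AttributedGraph.from_records(nodes, edges)
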