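import itertools
import math

import numpy as np
import pytest
from scipy import integrate, stats

import fragnet as fn
from fragnet.evaluation import (EmpiricalCcdf, ObjectiveBands,
                                check_objectives, fit_ccdf, fit_family,
                                folded_cauchy_pdf, folded_cauchy_sf,
                                log_binned)

from conftest import random_attributed_graph


# ---------------------------------------------------------------------------
# independent brute-force metric oracles


def brute_metrics(graph):
    g = graph.g
    nodes = list(g.nodes)
    n = len(nodes)
    e = g.number_of_edges()
    deg = {v: g.degree(v) for v in nodes}
    triangles = sum(1 for a, b, c in itertools.combinations(nodes, 3)
                    if g.has_edge(a, b) and g.has_edge(b, c)
                    and g.has_edge(a, c))
    triplets = sum(d * (d - 1) // 2 for d in deg.values())
    # degree assortativity: Pearson r over both orientations of each edge
    xs, ys = [], []
    for u, v in g.edges:
        xs += [deg[u], deg[v]]
        ys += [deg[v], deg[u]]
    if len(set(xs)) > 1:
        assort = float(np.corrcoef(xs, ys)[0, 1])
    else:
        assort = float("nan")
    # Floyd-Warshall over reachable ordered pairs
    INF = float("inf")
    dist = {u: {v: (0 if u == v else (1 if g.has_edge(u, v) else INF))
                for v in nodes} for u in nodes}
    for k in nodes:
        for i in nodes:
            dik = dist[i][k]
            if dik == INF:
                continue
            for j in nodes:
                alt = dik + dist[k][j]
                if alt < dist[i][j]:
                    dist[i][j] = alt
    finite = [dist[i][j] for i in nodes for j in nodes
              if i != j and dist[i][j] < INF]
    asp = sum(finite) / len(finite) if finite else float("nan")
    out = sum(1 for u, v in g.edges
              if graph.site_of(u) != graph.site_of(v)) * 2 / n
    return {
        "average_degree": 2 * e / n,
        "density": e / (n * (n - 1) / 2),
        "clustering": (3 * triangles / triplets) if triplets else 0.0,
        "assortativity": assort,
        "average_shortest_path": asp,
        "mean_out_links": out,
    }


class TestNetworkMetrics:
    def _graph(self, n, edges, sites=None):
        sites = sites or {}
        nodes = [{"id": i, "site_id": sites.get(i, "s"), "district_id": "d",
                  "x": 0.0, "y": 0.0} for i in n]
        return fn.AttributedGraph.from_records(nodes, edges)

    def test_triangle(self):
        g = self._graph("abc", [("a", "b"), ("b", "c"), ("a", "c")])
        m = fn.network_metrics(g)
        assert m.density == 1.0
        assert m.clustering == 1.0
        assert m.average_shortest_path == 1.0

    def test_path_of_four(self):
        g = self._graph("abcd", [("a", "b"), ("b", "c"), ("c", "d")])
        m = fn.network_metrics(g)
        assert m.clustering == 0.0
        assert m.average_degree == pytest.approx(1.5)
        assert m.average_shortest_path == pytest.approx(5 / 3)

    def test_star_assortativity(self):
        g = self._graph("abcd", [("a", "b"), ("a", "c"), ("a", "d")])
        m = fn.network_metrics(g)
        assert m.assortativity == pytest.approx(-1.0)

    def test_too_small_graph(self):
        g = self._graph("a", [])
        with pytest.raises(ValueError):
            fn.network_metrics(g)

    @pytest.mark.parametrize("seed", range(10))
    def test_against_brute_force_on_random_graphs(self, seed):
        rng = np.random.default_rng(seed)
        g = random_attributed_graph(rng)
        m = fn.network_metrics(g)
        ref = brute_metrics(g)
        for key, want in ref.items():
            got = getattr(m, key)
            if math.isnan(want):
                assert math.isnan(got)
            else:
                assert got == pytest.approx(want, abs=1e-9), key

    def test_percentages_relative_to_original(self, small_city):
        _, observed, _ = small_city
        out = fn.impute_social_circles(observed,
                                       fn.SocialCirclesConfig(c=2000, seed=0))
        m = fn.network_metrics(out, observed)
        assert m.pct_components_of_original <= 100.0
        assert m.n_components <= fn.components(observed).n_components


class TestCcdfs:
    def test_regular_degree_step(self):
        nodes = [{"id": i, "site_id": "s", "district_id": "d", "x": 0, "y": 0}
                 for i in "abcd"]
        # 4-cycle: every degree 2
        g = fn.AttributedGraph.from_records(
            nodes, [("a", "b"), ("b", "c"), ("c", "d"), ("d", "a")])
        c = fn.degree_ccdf(g)
        assert c.at(0) == 1.0 and c.at(2) == 1.0 and c.at(3) == 0.0

    def test_degree_hand_count(self):
        nodes = [{"id": i, "site_id": "s", "district_id": "d", "x": 0, "y": 0}
                 for i in "abc"]
        g = fn.AttributedGraph.from_records(nodes, [("a", "c"), ("b", "c")])
        c = fn.degree_ccdf(g)  # degrees {1, 1, 2}
        assert c.at(1) == pytest.approx(1.0)
        assert c.at(2) == pytest.approx(1 / 3)

    def test_edgeless_degree_ccdf(self):
        nodes = [{"id": i, "site_id": "s", "district_id": "d", "x": 0, "y": 0}
                 for i in "ab"]
        g = fn.AttributedGraph.from_records(nodes, [])
        c = fn.degree_ccdf(g)
        assert c.at(0) == 1.0 and c.at(1) == 0.0

    def test_distance_ccdf_hand_count(self):
        nodes = []
        for k, x in enumerate([0.0, 1.0, 10.0, 100.0]):
            nodes.append({"id": f"n{k}", "site_id": f"s{k}",
                          "district_id": "d", "x": x, "y": 0.0})
        g = fn.AttributedGraph.from_records(
            nodes, [("n0", "n1"), ("n0", "n2"), ("n0", "n3")])
        c = fn.distance_link_ccdf(g)  # distances {1, 10, 100}
        assert c.at(10) == pytest.approx(2 / 3)
        assert c.at(0.5) == 1.0

    def test_distance_ccdf_needs_edges(self):
        nodes = [{"id": "a", "site_id": "s", "district_id": "d", "x": 0, "y": 0},
                 {"id": "b", "site_id": "t", "district_id": "d", "x": 1, "y": 0}]
        g = fn.AttributedGraph.from_records(nodes, [])
        with pytest.raises(ValueError):
            fn.distance_link_ccdf(g)

    def test_monotone_and_bounded(self, small_city):
        _, observed, _ = small_city
        for c in (fn.degree_ccdf(observed),):
            assert np.all(np.diff(c.sf) <= 0)
            assert c.sf[0] == 1.0
            assert np.all((c.sf >= 0) & (c.sf <= 1))

    def test_log_binning_preserves_monotonicity(self):
        c = EmpiricalCcdf.from_samples(np.geomspace(1, 1000, 200))
        lb = log_binned(c, 30)
        assert np.all(np.diff(lb.sf) <= 1e-12)


class TestFoldedCauchy:
    def test_at_origin(self):
        assert folded_cauchy_pdf(0.0, 0.0) == pytest.approx(2 / math.pi,
                                                            abs=1e-9)

    def test_closed_form_a1(self):
        want = 1 / math.pi + 1 / (5 * math.pi)
        assert folded_cauchy_pdf(1.0, 1.0) == pytest.approx(want, abs=1e-9)

    def test_vanishes_at_infinity(self):
        assert folded_cauchy_pdf(1e9, 1.0) < 1e-15

    def test_negative_x_rejected(self):
        with pytest.raises(ValueError):
            folded_cauchy_pdf(-0.1, 1.0)

    @pytest.mark.parametrize("a", [0.0, 0.5, 1.854])
    def test_integrates_to_one(self, a):
        # piecewise panels: a sharp peak near the fold plus a heavy tail
        breaks = [0.0, 10.0, 1e3, 1e6]
        val = sum(integrate.quad(lambda x: folded_cauchy_pdf(x, a), lo, hi,
                                 limit=200)[0]
                  for lo, hi in zip(breaks, breaks[1:]))
        assert val == pytest.approx(1.0, abs=1e-4)

    def test_matches_scipy_reference(self):
        xs = np.linspace(0, 20, 50)
        for a in (0.3, 1.2):
            assert np.allclose(folded_cauchy_pdf(xs, a),
                               stats.foldcauchy.pdf(xs, a), atol=1e-12)
            assert np.allclose(folded_cauchy_sf(xs, a),
                               stats.foldcauchy.sf(xs, a), atol=1e-12)


class TestFitCcdf:
    def test_folded_cauchy_recovery(self):
        s = stats.foldcauchy.rvs(0.5, size=10_000, random_state=1)
        best = fit_ccdf(EmpiricalCcdf.from_samples(s))
        assert best.family == "folded_cauchy"
        assert best.params["a"] == pytest.approx(0.5, abs=0.1)

    def test_bounded_power_law_selected(self):
        rng = np.random.default_rng(2)
        b, xmin, xmax = 1 - 0.7, 1.0, 1000.0
        u = rng.random(10_000)
        x = ((1 - u) * (xmin ** b - xmax ** b) + xmax ** b) ** (1 / b)
        best = fit_ccdf(EmpiricalCcdf.from_samples(x))
        assert best.family == "power_law"

    def test_self_fit_is_perfect(self):
        xs = np.linspace(0.01, 30, 100)
        curve = EmpiricalCcdf(xs, np.exp(-xs / 3.0), n=100)
        fit = fit_family(curve, "exponential")
        assert fit.params["scale"] == pytest.approx(3.0, rel=1e-4)
        assert fit.pearson_r == pytest.approx(1.0, abs=1e-9)

    def test_degenerate_curve_rejected(self):
        with pytest.raises(ValueError):
            fit_ccdf(EmpiricalCcdf(np.array([5.0]), np.array([1.0]), 50))

    def test_too_few_points_rejected(self):
        c = EmpiricalCcdf.from_samples([1, 2, 3, 4])
        with pytest.raises(ValueError):
            fit_ccdf(c)


class TestObjectives:
    def _report(self, **kw):
        base = dict(average_degree=7.0, density=0.01, clustering=0.2,
                    assortativity=0.1, average_shortest_path=6.0,
                    mean_out_links=1.5, n_isolates=0, n_components=1,
                    pct_components_of_original=1.0,
                    pct_isolates_of_original=0.0)
        base.update(kw)
        return fn.MetricsReport(**base)

    def test_endpoints_pass(self):
        rows = check_objectives(self._report(average_degree=5.0,
                                             average_shortest_path=7.0,
                                             clustering=0.252,
                                             density=0.014,
                                             mean_out_links=2.0))
        assert rows["overall"] is True

    def test_density_excess_fails(self):
        rows = check_objectives(self._report(density=0.02))
        assert rows["density"]["passed"] is False
        assert rows["overall"] is False

    def test_negative_assortativity_fails(self):
        rows = check_objectives(self._report(assortativity=-0.01))
        assert rows["assortativity"]["passed"] is False

    def test_zero_assortativity_fails_strictly(self):
        rows = check_objectives(self._report(assortativity=0.0))
        assert rows["assortativity"]["passed"] is False

    def test_custom_bands(self):
        bands = ObjectiveBands(density=(0.0, 0.5))
        rows = check_objectives(self._report(density=0.02), bands)
        assert rows["density"]["passed"] is True
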