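"""Attributed fragmented-network data model and I/O.

The central object is :class:`AttributedGraph`, an undirected simple graph
whose nodes carry a survey site (school), an administrative district, planar
site coordinates in meters, and a set of binary activity memberships.  Edges
carry a provenance flag distinguishing links recorded by the survey
(``observed``) from links inserted by an imputation method (``imputed``).

Coordinates are site-level: every node of one site shares the site's (x, y).
This mirrors surveys that geocode institutions, not respondents.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx
import numpy as np
import pandas as pd

OBSERVED = "observed"
IMPUTED = "imputed"

_RESERVED_COLS = ("id", "site_id", "district_id", "x", "y")


@dataclass
class AttributedGraph:
    """Undirected simple graph with per-node site/district/coordinate/activity
    attributes and per-edge provenance.

    Wraps a :class:`networkx.Graph`; node attributes are ``site_id``,
    ``district_id``, ``x``, ``y`` (projected meters) and ``activities``
    (frozenset of labels).  Edge attribute ``provenance`` is ``"observed"``
    or ``"imputed"``.
    """

    g: nx.Graph = field(default_factory=nx.Graph)

    # -- construction -----------------------------------------------------

    @classmethod
    def from_records(
        cls,
        nodes: Iterable[Mapping],
        edges: Iterable[tuple],
        provenance: str = OBSERVED,
    ) -> "AttributedGraph":
        """Build and validate a graph from node records and an edge list.

        Each node record must supply ``id``, ``site_id``, ``district_id``,
        ``x``, ``y`` and optionally ``activities`` (iterable of labels).
        Duplicate undirected edges are collapsed; self-loops are rejected.
        """
        g = nx.Graph()
        for rec in nodes:
            x, y = float(rec["x"]), float(rec["y"])
            if not (math.isfinite(x) and math.isfinite(y)):
                raise ValueError(f"non-finite coordinate for node {rec['id']!r}")
            g.add_node(
                rec["id"],
                site_id=rec["site_id"],
                district_id=rec["district_id"],
                x=x,
                y=y,
                activities=frozenset(rec.get("activities", ())),
            )
        for u, v in edges:
            if u == v:
                raise ValueError(f"self-loop on node {u!r}")
            for n in (u, v):
                if n not in g:
                    raise KeyError(f"edge references unknown node {n!r}")
            g.add_edge(u, v, provenance=provenance)
        out = cls(g)
        out._check_site_coherence()
        return out

    def _check_site_coherence(self) -> None:
        seen: dict = {}
        for n, d in self.g.nodes(data=True):
            key = d["site_id"]
            xy = (d["x"], d["y"])
            if key in seen and seen[key] != xy:
                raise ValueError(
                    f"site {key!r} has inconsistent coordinates {seen[key]} vs {xy}"
                )
            seen.setdefault(key, xy)

    # -- basic accessors --------------------------------------------------

    @property
    def n_nodes(self) -> int:
        return self.g.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.g.number_of_edges()

    def node_attr(self, n, key):
        return self.g.nodes[n][key]

    def site_of(self, n):
        return self.g.nodes[n]["site_id"]

    def sites(self) -> dict:
        """Map site_id -> (x, y) site coordinates."""
        out = {}
        for _, d in self.g.nodes(data=True):
            out.setdefault(d["site_id"], (d["x"], d["y"]))
        return out

    def site_members(self) -> dict:
        """Map site_id -> list of member node ids."""
        out: dict = {}
        for n, d in self.g.nodes(data=True):
            out.setdefault(d["site_id"], []).append(n)
        return out

    def observed_edges(self) -> list:
        return [
            (u, v)
            for u, v, p in self.g.edges(data="provenance")
            if p == OBSERVED
        ]

    def imputed_edges(self) -> list:
        return [
            (u, v) for u, v, p in self.g.edges(data="provenance") if p == IMPUTED
        ]

    def copy(self) -> "AttributedGraph":
        return AttributedGraph(self.g.copy())

    def add_imputed_edge(self, u, v) -> None:
        if u == v:
            raise ValueError("self-loop")
        if not self.g.has_edge(u, v):
            self.g.add_edge(u, v, provenance=IMPUTED)

    # -- I/O ---------------------------------------------------------------

    def to_files(self, edge_path, nodes_path, sep: str = ",") -> None:
        """Write the node table and edge list as delimited text (headers)."""
        acts = sorted({a for _, d in self.g.nodes(data=True) for a in d["activities"]})
        rows = []
        for n, d in sorted(self.g.nodes(data=True), key=lambda t: str(t[0])):
            row = {
                "id": n,
                "site_id": d["site_id"],
                "district_id": d["district_id"],
                "x": d["x"],
                "y": d["y"],
            }
            for a in acts:
                row[a] = int(a in d["activities"])
            rows.append(row)
        pd.DataFrame(rows).to_csv(nodes_path, sep=sep, index=False)
        erows = [
            {"source": u, "target": v, "provenance": p}
            for u, v, p in sorted(
                ((min(str(u), str(v)), max(str(u), str(v)), p)
                 for u, v, p in self.g.edges(data="provenance"))
            )
        ]
        pd.DataFrame(erows, columns=["source", "target", "provenance"]).to_csv(
            edge_path, sep=sep, index=False
        )

    def to_graphml(self, path) -> None:
        g = self.g.copy()
        for _, d in g.nodes(data=True):
            d["activities"] = ",".join(sorted(d["activities"]))
        nx.write_graphml(g, path)


def load_network(edge_path, nodes_path, sep: str = ",") -> AttributedGraph:
    """Load an attributed network from a node table and a 2-column edge list.

    The node table needs columns ``id, site_id, district_id, x, y``; any
    extra 0/1 column is read as an activity membership.  Edges are undirected
    and collapsed; every edge endpoint must appear in the node table.  All
    loaded edges are marked observed (a ``provenance`` column, if present,
    is honored instead).
    """
    ndf = pd.read_csv(nodes_path, sep=sep)
    missing = [c for c in _RESERVED_COLS if c not in ndf.columns]
    if missing:
        raise ValueError(f"node table missing column(s) {missing} in {nodes_path}")
    act_cols = [c for c in ndf.columns if c not in _RESERVED_COLS and c != "provenance"]
    records = []
    for i, row in ndf.iterrows():
        for c in ("x", "y"):
            try:
                float(row[c])
            except (TypeError, ValueError):
                raise ValueError(
                    f"non-numeric coordinate {row[c]!r} in column {c}, row {i + 2} of {nodes_path}"
                ) from None
        records.append(
            {
                "id": row["id"],
                "site_id": row["site_id"],
                "district_id": row["district_id"],
                "x": row["x"],
                "y": row["y"],
                "activities": [c for c in act_cols if int(row[c]) == 1],
            }
        )
    edf = pd.read_csv(edge_path, sep=sep)
    if edf.shape[1] < 2:
        raise ValueError(f"edge file {edge_path} needs two id columns")
    have_prov = "provenance" in edf.columns
    g = AttributedGraph.from_records(records, [])
    for _, row in edf.iterrows():
        u, v = row.iloc[0], row.iloc[1]
        if u == v:
            raise ValueError(f"self-loop on node {u!r} in {edge_path}")
        for n in (u, v):
            if n not in g.g:
                raise KeyError(f"edge references unknown node {n!r} in {edge_path}")
        prov = row["provenance"] if have_prov else OBSERVED
        g.g.add_edge(u, v, provenance=prov)
    return g


def load_network_lonlat(edge_path, nodes_path, sep: str = ",") -> AttributedGraph:
    """Load a network whose node coordinates are (lon, lat) in degrees.

    Applies an equirectangular projection about the centroid, yielding
    planar meters compatible with the distance-decay models.
    """
    g = load_network(edge_path, nodes_path, sep=sep)
    lat = np.array([d["y"] for _, d in g.g.nodes(data=True)], dtype=float)
    lon = np.array([d["x"] for _, d in g.g.nodes(data=True)], dtype=float)
    lat0, lon0 = lat.mean(), lon.mean()
    r_earth = 6_371_000.0
    for n, d in g.g.nodes(data=True):
        d["x"] = math.radians(d["x"] - lon0) * r_earth * math.cos(math.radians(lat0))
        d["y"] = math.radians(d["y"] - lat0) * r_earth
    return g


@dataclass(frozen=True)
class ComponentSummary:
    """Connected components of size >= 2, and degree-0 isolates.

    A "component" is a set of at least two mutually reachable nodes; a node
    with no edges at all is counted separately as an isolate.
    """

    components: tuple
    isolates: frozenset

    @property
    def n_components(self) -> int:
        return len(self.components)

    @property
    def n_isolates(self) -> int:
        return len(self.isolates)


def components(graph: AttributedGraph) -> ComponentSummary:
    """Split the graph into size->=2 connected components and isolates."""
    comps = []
    isolates = set()
    for cc in nx.connected_components(graph.g):
        if len(cc) >= 2:
            comps.append(frozenset(cc))
        else:
            isolates.update(cc)
    return ComponentSummary(tuple(comps), frozenset(isolates))


def geo_distance(graph: AttributedGraph, u, v) -> float:
    """Euclidean distance in meters between two nodes' site coordinates."""
    for n in (u, v):
        if n not in graph.g:
            raise KeyError(f"unknown node {n!r}")
    du, dv = graph.g.nodes[u], graph.g.nodes[v]
    return math.hypot(du["x"] - dv["x"], du["y"] - dv["y"])


def site_distance_matrix(graph: AttributedGraph):
    """(site_ids, dense site-to-site distance matrix in meters)."""
    sites = graph.sites()
    ids = sorted(sites, key=str)
    xy = np.array([sites[s] for s in ids], dtype=float)
    diff = xy[:, None, :] - xy[None, :, :]
    return ids, np.sqrt((diff ** 2).sum(axis=2))


def filter_outlier_sites(graph: AttributedGraph, quantile: float) -> AttributedGraph:
    """Drop sites that are geographic outliers.

    For each site, the median distance to the other sites is computed; sites
    whose median exceeds the given quantile of the distribution of those
    medians are removed (with all their nodes).  ``quantile=1.0`` removes
    nothing.  Used before distance-driven imputation, where a far-flung site
    would dominate the distance scale.
    """
    if not 0.0 < quantile <= 1.0:
        raise ValueError(f"quantile must be in (0, 1], got {quantile}")
    ids, dm = site_distance_matrix(graph)
    if len(ids) < 2:
        return graph.copy()
    medians = np.array(
        [np.median(np.delete(dm[i], i)) for i in range(len(ids))]
    )
    cut = np.quantile(medians, quantile)
    keep_sites = {s for s, m in zip(ids, medians) if m <= cut}
    keep_nodes = [n for n, d in graph.g.nodes(data=True) if d["site_id"] in keep_sites]
    return AttributedGraph(graph.g.subgraph(keep_nodes).copy())
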