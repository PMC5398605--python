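"""Two-phase cold-start link prediction over attribute groups.

With zero observed edges between survey components, graph-based predictors
have nothing to work with.  The bootstrap proceeds in two phases:

Phase I assigns each candidate pair a prior from the co-occurrence groups
it shares (e.g. "same district and both practice sports").  Each concrete
group gamma carries a link share l/e estimated from the observed network —
internal links over links incident to the group — and a pair sharing
several groups links if *at least one* of them produces the tie:

    P1(u, v) = 1 - prod_gamma (1 - p_gamma)

(the closed form of the sum over all 2^k - 1 non-null outcomes).

Phase II reinforces the priors with a probabilistic Common-Neighbors
score, P2(u, v) = sum_y P1(u, y) * P1(v, y), scores are summed and mapped
back to [0, 1] with a log normalization, and a deterministic threshold r
turns high-probability pairs into imputed edges.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

from .graph import AttributedGraph


@dataclass(frozen=True)
class GroupDefinition:
    """A co-occurrence group template.

    ``scope`` is the partitioning node attribute (default the district):
    one concrete group arises per scope value.  A node belongs to a
    concrete group if it carries the scope value and *all* required
    activities; the induced pair predicate (same scope value, both with
    the activities) is symmetric, and concrete groups of one definition
    are disjoint across scope values.
    """

    name: str
    activities: frozenset = field(default_factory=frozenset)
    scope: str = "district_id"

    def __post_init__(self):
        object.__setattr__(self, "activities", frozenset(self.activities))


def default_groups() -> list[GroupDefinition]:
    """District-scoped activity groups: sports, church, shared transport."""
    return [
        GroupDefinition("sports", {"sports"}),
        GroupDefinition("church", {"church"}),
        GroupDefinition("transport", {"transport"}),
    ]


def concrete_groups(graph: AttributedGraph, gd: GroupDefinition) -> dict:
    """Materialize ``gd`` into {scope value: member node set}."""
    sample = next(iter(graph.g.nodes(data=True)), None)
    if sample is not None and gd.scope not in sample[1]:
        raise KeyError(f"unknown scope attribute {gd.scope!r}")
    universe = {a for _, d in graph.g.nodes(data=True) for a in d["activities"]}
    unknown = gd.activities - universe
    if unknown:
        raise KeyError(f"unknown activity attribute(s) {sorted(unknown)}")
    out: dict = {}
    for n, d in graph.g.nodes(data=True):
        if gd.activities <= d["activities"]:
            out.setdefault(d[gd.scope], set()).add(n)
    return out


class ProbabilisticGraph:
    """Sparse map from unordered node pairs to link probabilities.

    Pairs absent from the map have probability 0.  Phase-II
    Common-Neighbors output is a *score* map and may exceed 1; range
    checking is controlled by ``check_range``.
    """

    def __init__(self, universe, pairs=None, check_range: bool = True):
        self.universe = frozenset(universe)
        self._p: dict = {}
        if pairs:
            for (u, v), p in pairs.items():
                self.set(u, v, p, check_range=check_range)

    @staticmethod
    def key(u, v):
        return (u, v) if str(u) <= str(v) else (v, u)

    def set(self, u, v, p, check_range: bool = True):
        if u == v:
            raise ValueError("self-pair")
        if check_range and not 0.0 <= p <= 1.0:
            raise ValueError(f"probability {p} outside [0, 1]")
        if p < 0.0:
            raise ValueError(f"negative value {p}")
        self._p[self.key(u, v)] = float(p)

    def get(self, u, v) -> float:
        return self._p.get(self.key(u, v), 0.0)

    def items(self):
        return self._p.items()

    def __len__(self):
        return len(self._p)

    def to_table(self, path, sep: str = ",") -> None:
        """Write as 3-column delimited text (u, v, p), sorted by pair."""
        import pandas as pd

        rows = [{"u": u, "v": v, "p": p}
                for (u, v), p in sorted(self._p.items(),
                                        key=lambda t: (str(t[0][0]), str(t[0][1])))]
        pd.DataFrame(rows, columns=["u", "v", "p"]).to_csv(path, sep=sep,
                                                           index=False)


def group_link_share(graph: AttributedGraph, members) -> float:
    """Share of a group's incident observed links that are internal.

    l = observed edges with both endpoints in ``members``; e = observed
    edges with at least one endpoint in ``members`` (each edge counted
    once).  Returns l/e, or 0 when the group has no incident edge.
    """
    members = set(members)
    unknown = members - set(graph.g.nodes)
    if unknown:
        raise KeyError(f"unknown node(s) {sorted(map(str, unknown))[:3]}")
    l = e = 0
    for u, v in graph.observed_edges():
        iu, iv = u in members, v in members
        if iu or iv:
            e += 1
            if iu and iv:
                l += 1
    return l / e if e else 0.0


def phase1_probability(group_probs) -> float:
    """Probability that at least one shared group produces the link.

    Closed form 1 - prod(1 - p) of the inclusion-exclusion sum over the
    2^k - 1 non-null group outcomes; 0 for an empty list.
    """
    acc = 1.0
    for p in group_probs:
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"probability {p} outside [0, 1]")
        acc *= 1.0 - p
    return 1.0 - acc if group_probs else 0.0


def build_phase1(graph: AttributedGraph, defs) -> ProbabilisticGraph:
    """Phase-I probabilistic graph from group co-membership.

    Every unordered non-edge pair sharing at least one concrete group gets
    the at-least-one-group probability of its shared groups' link shares;
    observed edges enter at probability 1 so phase II can exploit the known
    structure.
    """
    out = ProbabilisticGraph(graph.g.nodes)
    # accumulate 1 - prod(1 - share) incrementally, group by group
    surv: dict = {}
    for gd in defs:
        for members in concrete_groups(graph, gd).values():
            share = group_link_share(graph, members)
            if share == 0.0:
                continue
            ms = sorted(members, key=str)
            for i, u in enumerate(ms):
                for v in ms[i + 1:]:
                    if graph.g.has_edge(u, v):
                        continue
                    k = ProbabilisticGraph.key(u, v)
                    surv[k] = surv.get(k, 1.0) * (1.0 - share)
    for (u, v), s in surv.items():
        out.set(u, v, 1.0 - s)
    for u, v in graph.observed_edges():
        out.set(u, v, 1.0)
    return out


def _to_matrix(p: ProbabilisticGraph):
    ids = sorted(p.universe, key=str)
    idx = {n: i for i, n in enumerate(ids)}
    n = len(ids)
    rows, cols, vals = [], [], []
    for (u, v), pr in p.items():
        i, j = idx[u], idx[v]
        rows += [i, j]
        cols += [j, i]
        vals += [pr, pr]
    m = sp.csr_array((vals, (rows, cols)), shape=(n, n))
    return ids, m


def phase2_common_neighbors(p1: ProbabilisticGraph) -> ProbabilisticGraph:
    """Probabilistic Common-Neighbors reinforcement.

    P2(u, v) = sum over y not in {u, v} of P1(u, y) * P1(v, y).  Values are
    scores (may exceed 1).  Computed as a symmetric matrix square; the
    diagonal of P1 is zero so the y in {u, v} terms vanish.  A dense product
    is used when P1 is dense enough for BLAS to win.
    """
    ids, m = _to_matrix(p1)
    n = len(ids)
    if n == 0:
        return ProbabilisticGraph(p1.universe, check_range=False)
    if m.nnz > 0.05 * n * n:
        sq = np.asarray(m.todense() @ m.todense())
        iu, ju = np.nonzero(np.triu(sq, k=1))
        vals = sq[iu, ju]
    else:
        sq = (m @ m).tocoo()
        mask = sq.row < sq.col
        iu, ju, vals = sq.row[mask], sq.col[mask], sq.data[mask]
    out = ProbabilisticGraph(p1.universe, check_range=False)
    for i, j, v in zip(iu, ju, vals):
        if v > 0.0:
            out._p[ProbabilisticGraph.key(ids[i], ids[j])] = float(v)
    return out


def finalize_scores(p1: ProbabilisticGraph, p2: ProbabilisticGraph,
                    observed_pairs=None) -> ProbabilisticGraph:
    """Sum the two phases and log-normalize back to [0, 1].

    score(u, v) = P1 + P2, then P_link = log(score + 1) / log(max + 1)
    where max is taken over the candidate (non-observed) pairs, so the
    arg-max candidate maps to exactly 1 and the score order is preserved.
    Observed pairs pass through at probability 1.
    """
    if p1.universe != p2.universe:
        raise ValueError("phase I and phase II universes differ")
    observed = {ProbabilisticGraph.key(u, v) for u, v in (observed_pairs or ())}
    keys = ({k for k, _ in p1.items()} | {k for k, _ in p2.items()}) - observed
    scores = {k: p1.get(*k) + p2.get(*k) for k in keys}
    out = ProbabilisticGraph(p1.universe)
    max_score = max(scores.values(), default=0.0)
    if max_score == 0.0:
        if scores:
            warnings.warn("all pair scores are zero; log normalizer undefined, "
                          "emitting zeros", stacklevel=2)
        for (u, v) in keys:
            out.set(u, v, 0.0)
    else:
        norm = math.log1p(max_score)
        for (u, v), s in scores.items():
            out.set(u, v, min(1.0, math.log1p(s) / norm))
    for (u, v) in observed:
        out.set(u, v, 1.0)
    return out


def threshold_links(p: ProbabilisticGraph, r: float,
                    graph: AttributedGraph) -> AttributedGraph:
    """Add every non-observed pair with P_link >= r as an imputed edge.

    Deterministic; the imputed-edge count is a non-increasing step
    function of r.
    """
    if not 0.0 <= r <= 1.0:
        raise ValueError(f"threshold r must be in [0, 1], got {r}")
    out = graph.copy()
    for (u, v), prob in p.items():
        if prob >= r and not out.g.has_edge(u, v):
            out.add_imputed_edge(u, v)
    return out


def impute_bootstrap(graph: AttributedGraph, r: float,
                     defs=None) -> AttributedGraph:
    """Full two-phase pipeline: phase I, Common-Neighbors, log scores,
    threshold.  Deterministic (no RNG involved)."""
    defs = list(defs) if defs is not None else default_groups()
    p1 = build_phase1(graph, defs)
    p2 = phase2_common_neighbors(p1)
    final = finalize_scores(p1, p2, observed_pairs=graph.observed_edges())
    return threshold_links(final, r, graph)
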