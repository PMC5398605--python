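"""Hybrid imputation: geo-social distance decay as a probabilistic phase I,
then the bootstrap's Common-Neighbors reinforcement and log scoring.

Phase I replaces the hard accept/reject of the social-circles method with
stored probabilities

    P(u, v) = exp(-(d(u, v) / c) * 1 / (k + 1))

where d is a geo-social distance (Euclidean geography augmented with a
third, social coordinate) and k the *expected* degree of both endpoints:
observed edges count 1 each and previously stored probabilities count at
their value.  Note the damping direction: a higher expected degree brings
the exponent closer to 0 and so *raises* the probability — the opposite of
the social-circles rule — as the formula is printed; the
``inverse_degree_damping`` switch flips it.

The social coordinate s of a node is drawn uniformly on
[0, alpha / 2^n_activities]: the interval halves per activity, so socially
active nodes concentrate near 0 and two active nodes are socially close.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

from . import _traversal
from .bootstrap import (ProbabilisticGraph, finalize_scores,
                        phase2_common_neighbors)
from .graph import AttributedGraph, site_distance_matrix


@dataclass(frozen=True)
class SocialPosition:
    """A node's position on the social axis (same length unit as geography)."""

    s: float
    n_activities: int
    alpha: float

    def __post_init__(self):
        if not 0.0 <= self.s <= self.alpha / 2 ** self.n_activities + 1e-12:
            raise ValueError("social coordinate outside its interval")


def social_position(n_activities: int, alpha: float, seed: int) -> SocialPosition:
    """Draw s uniformly on [0, alpha / 2^n_activities]."""
    if alpha <= 0:
        raise ValueError(f"alpha must be positive, got {alpha}")
    if n_activities < 0:
        raise ValueError("n_activities must be >= 0")
    rng = np.random.default_rng(seed)
    hi = alpha / 2 ** n_activities
    return SocialPosition(float(rng.uniform(0.0, hi)), n_activities, alpha)


def assign_social_positions(graph: AttributedGraph, alpha: float,
                            rng: np.random.Generator) -> dict:
    """Draw one social coordinate per node (sorted-id order, reproducible)."""
    if alpha < 0:
        raise ValueError("alpha must be >= 0")
    out = {}
    for n in sorted(graph.g.nodes, key=str):
        k = len(graph.g.nodes[n]["activities"])
        hi = alpha / 2 ** k
        out[n] = float(rng.uniform(0.0, hi)) if hi > 0 else 0.0
    return out


def geo_social_distance(graph: AttributedGraph, u, v, s: dict) -> float:
    """sqrt(dx^2 + dy^2 + ds^2); reduces to geography when s_u == s_v."""
    for n in (u, v):
        if n not in s:
            raise KeyError(f"missing social position for node {n!r}")
    du, dv = graph.g.nodes[u], graph.g.nodes[v]
    return math.sqrt((du["x"] - dv["x"]) ** 2 + (du["y"] - dv["y"]) ** 2
                     + (s[u] - s[v]) ** 2)


def link_probability_combined(d: float, k_exp: float, c: float) -> float:
    """exp(-(d/c) * 1/(k_exp + 1)); the +1 keeps the exponent finite at 0."""
    if c <= 0:
        raise ValueError(f"c must be positive, got {c}")
    if d < 0 or k_exp < 0:
        raise ValueError("d and k_exp must be non-negative")
    return math.exp(-(d / c) / (k_exp + 1.0))


def median_intersite_distance(graph: AttributedGraph) -> float:
    """Median of the off-diagonal site-to-site distances (the default alpha)."""
    _, dm = site_distance_matrix(graph)
    n = dm.shape[0]
    if n < 2:
        return 0.0
    iu = np.triu_indices(n, k=1)
    return float(np.median(dm[iu]))


def combined_phase1(graph: AttributedGraph, c: float, alpha=None,
                    seed=0,
                    candidate_policy: str = _traversal.CROSS_SITE_ONLY,
                    inverse_degree_damping: bool = False):
    """Phase I of the hybrid method: stored geo-social decay probabilities.

    Returns ``(p1, pair_order)`` — the probabilistic graph (with observed
    edges at 1) and the candidate pairs in traversal order.  ``seed`` may
    be an integer or an existing :class:`numpy.random.Generator`.
    """
    if c <= 0:
        raise ValueError(f"c must be positive, got {c}")
    rng = np.random.default_rng(seed)
    if alpha is None:
        alpha = median_intersite_distance(graph)
    s = assign_social_positions(graph, alpha, rng)

    nodes = sorted(graph.g.nodes, key=str)
    idx = {n: i for i, n in enumerate(nodes)}
    k_exp = np.array([graph.g.degree(n) for n in nodes], dtype=float)
    sv = np.array([s[n] for n in nodes], dtype=float)

    p1 = ProbabilisticGraph(graph.g.nodes)
    pair_order = []  # traversal order, reused for the acceptance draws
    for u, cands, dists in _traversal.candidate_blocks(graph, rng,
                                                       candidate_policy):
        if not cands:
            continue
        ui = idx[u]
        cidx = np.fromiter((idx[v] for v in cands), dtype=np.intp,
                           count=len(cands))
        dgs = np.sqrt(dists ** 2 + (sv[ui] - sv[cidx]) ** 2)
        ku = k_exp[ui]
        kv = k_exp[cidx]  # fixed within the block: v occurs once per block
        for i in range(len(cands)):
            k = ku + kv[i]
            e = (dgs[i] / c) * (k + 1.0) if inverse_degree_damping \
                else (dgs[i] / c) / (k + 1.0)
            p = math.exp(-e)
            v = cands[i]
            p1._p[ProbabilisticGraph.key(u, v)] = p
            pair_order.append((u, v))
            ku += p
            k_exp[cidx[i]] += p
        k_exp[ui] = ku

    for u, v in graph.observed_edges():
        p1.set(u, v, 1.0)
    return p1, pair_order


def impute_combined(graph: AttributedGraph, c: float, alpha=None,
                    seed: int = 0,
                    candidate_policy: str = _traversal.CROSS_SITE_ONLY,
                    inverse_degree_damping: bool = False) -> AttributedGraph:
    """Hybrid imputation run.

    Assigns social positions, stores phase-I probabilities for every
    eligible pair in the semi-random order with k = running expected degree
    of both endpoints, applies Common-Neighbors and the log normalization,
    then accepts each candidate pair iff its final probability exceeds an
    independent uniform threshold.

    alpha=None uses the median inter-site distance, making the social axis
    commensurate with geography; alpha=0 reduces phase I to pure geography.
    """
    rng = np.random.default_rng(seed)
    p1, pair_order = combined_phase1(graph, c, alpha, rng, candidate_policy,
                                     inverse_degree_damping)
    if not pair_order:
        warnings.warn("candidate policy produced an empty candidate set; "
                      "returning the input unchanged", stacklevel=2)
        return graph.copy()

    observed = graph.observed_edges()
    p2 = phase2_common_neighbors(p1)
    final = finalize_scores(p1, p2, observed_pairs=observed)

    out = graph.copy()
    t = rng.random(len(pair_order))
    for i, (u, v) in enumerate(pair_order):
        if final.get(u, v) > t[i]:
            out.add_imputed_edge(u, v)
    return out
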