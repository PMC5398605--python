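"""Distance-decay ("social circles" / Waxman-style) link imputation.

Links between the disconnected survey components are inserted
stochastically with probability

    P_link(u, v) = exp(-d(u, v) * k / c)

where ``d`` is the distance in meters between the two nodes' sites, ``k``
the accumulated degree of both endpoints at evaluation time, and ``c`` an
adjustable decay divisor.  The degree damping deliberately favors nodes
that are sparsely connected in the survey: under boundary-specification
missingness, a low observed degree signals censored nominations rather
than true social isolation.  Because ``k`` evolves as edges are accepted,
the evaluation order matters; pairs are visited in the semi-random
nearest-site-first order (see :mod:`fragnet._traversal`).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

from . import _traversal
from .graph import AttributedGraph


@dataclass(frozen=True)
class SocialCirclesConfig:
    """Parameters of the distance-decay imputation.

    c: decay divisor in meters; larger c means slower decay, more links.
    seed: RNG seed (traversal order, partner shuffles, acceptance draws).
    candidate_policy: which pairs are eligible — ``cross_site_only``
        (default; same-site pairs sit at distance 0 and would clique-ify
        sites) or ``cross_component_only``.
    """

    c: float
    seed: int
    candidate_policy: str = _traversal.CROSS_SITE_ONLY

    def __post_init__(self):
        if self.c <= 0:
            raise ValueError(f"c must be positive, got {self.c}")


def link_probability_sc(d: float, k: float, c: float) -> float:
    """exp(-d*k/c): decay in distance d (meters) and accumulated degree k."""
    if c <= 0:
        raise ValueError(f"c must be positive, got {c}")
    if d < 0 or k < 0:
        raise ValueError("d and k must be non-negative")
    return math.exp(-d * k / c)


def impute_social_circles(graph: AttributedGraph,
                          config: SocialCirclesConfig) -> AttributedGraph:
    """Impute cross-component links by the degree-damped distance decay.

    Every eligible unordered pair is evaluated exactly once in the
    semi-random order; the edge is accepted iff P_link exceeds an
    independent uniform threshold.  Accepted edges are marked imputed and
    raise the accumulated degree used for later pairs.  Deterministic for
    fixed (graph, config).
    """
    rng = np.random.default_rng(config.seed)
    out = graph.copy()
    nodes = sorted(out.g.nodes, key=str)
    idx = {n: i for i, n in enumerate(nodes)}
    deg = np.array([out.g.degree(n) for n in nodes], dtype=float)
    c = float(config.c)

    n_eval = 0
    for u, cands, dists in _traversal.candidate_blocks(
            graph, rng, config.candidate_policy):
        if not cands:
            continue
        n_eval += len(cands)
        ui = idx[u]
        cidx = np.fromiter((idx[v] for v in cands), dtype=np.intp,
                           count=len(cands))
        degv = deg[cidx]  # fixed during u's block: v occurs once per block
        u01 = rng.random(len(cands))
        with np.errstate(divide="ignore"):
            thresh = -c * np.log(u01)  # accept iff d*k < -c*ln(r)
        ku = deg[ui]
        for i in range(len(cands)):
            if dists[i] * (ku + degv[i]) < thresh[i]:
                vi = cidx[i]
                out.g.add_edge(u, cands[i], provenance="imputed")
                ku += 1.0
                deg[vi] += 1.0
        deg[ui] = ku
    if n_eval == 0:
        warnings.warn("candidate policy produced an empty candidate set; "
                      "returning the input unchanged", stacklevel=2)
    return out
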