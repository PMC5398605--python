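"""Semi-random candidate-pair traversal.

Both distance-decay imputation methods evaluate every eligible unordered
node pair exactly once, in an order that favors geographically close pairs:
centers u are drawn as a random permutation; for each center, the other
sites are visited in increasing distance from u's site, taking one random
not-yet-paired member per site per pass and cycling until u's candidates
are exhausted.  Because each pair is evaluated when the *first* of its
endpoints becomes the center, a pair is never revisited.
"""

from __future__ import annotations

import numpy as np

from .graph import AttributedGraph, components, site_distance_matrix

CROSS_SITE_ONLY = "cross_site_only"
CROSS_COMPONENT_ONLY = "cross_component_only"


def candidate_blocks(graph: AttributedGraph, rng: np.random.Generator,
                     policy: str = CROSS_SITE_ONLY):
    """Yield ``(u, candidates, distances)`` blocks in semi-random order.

    ``candidates`` is the ordered list of partners for center ``u`` (nearest
    site first, one random member per site per pass), ``distances`` the
    matching site-to-site distances in meters.  Site-distance ties are broken
    by site id.  Each unordered pair appears in exactly one block.
    """
    if policy not in (CROSS_SITE_ONLY, CROSS_COMPONENT_ONLY):
        raise ValueError(f"unknown candidate_policy {policy!r}")
    site_ids, dm = site_distance_matrix(graph)
    site_index = {s: i for i, s in enumerate(site_ids)}
    members = {s: sorted(m, key=str) for s, m in graph.site_members().items()}

    comp_of = {}
    if policy == CROSS_COMPONENT_ONLY:
        summary = components(graph)
        for ci, comp in enumerate(summary.components):
            for n in comp:
                comp_of[n] = ci
        for iso in summary.isolates:
            comp_of[iso] = ("iso", iso)

    nodes = sorted(graph.g.nodes, key=str)
    order = rng.permutation(len(nodes))
    done = set()

    for oi in order:
        u = nodes[oi]
        si = site_index[graph.site_of(u)]
        # sites by increasing distance from u's site, ties by site id
        site_order = sorted(range(len(site_ids)),
                            key=lambda j: (dm[si, j], str(site_ids[j])))
        lists, dists = [], []
        for j in site_order:
            s = site_ids[j]
            if policy == CROSS_SITE_ONLY:
                if j == si:
                    continue
                elig = [v for v in members[s] if v not in done]
            else:
                cu = comp_of[u]
                elig = [v for v in members[s]
                        if v not in done and v != u and comp_of[v] != cu]
            if elig:
                elig = list(elig)
                rng.shuffle(elig)
                lists.append(elig)
                dists.append(dm[si, j])
        cands, cd = [], []
        if lists:
            longest = max(len(l) for l in lists)
            for p in range(longest):
                for li, l in enumerate(lists):
                    if p < len(l):
                        cands.append(l[p])
                        cd.append(dists[li])
        done.add(u)
        yield u, cands, np.asarray(cd, dtype=float)
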