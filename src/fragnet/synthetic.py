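"""Ground-truth synthetic city networks and boundary-specification censoring.

The generator emulates a fragmented school survey: districts on a planar
grid with population weights, schools apportioned to districts by weight,
fixed-choice friendship nominations inside each class (capped at five
names), and cross-school friendships whose probability decays
exponentially with the distance between schools and is boosted by shared
district/activity groups.  The cross-school rate is calibrated so the
expected number of out-of-school ties per pupil lands on a target inside
the 1–2 band reported for comparable adolescent friendship surveys.

Censoring the truth with :func:`apply_boundary_specification` removes
exactly the cross-school edges — reproducing the survey design in which a
nomination is only traced inside the respondent's own class — and returns
them as the hidden ground truth an imputation method is scored against.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
from scipy.stats import rankdata

from .bootstrap import ProbabilisticGraph
from .graph import AttributedGraph


@dataclass(frozen=True)
class CityConfig:
    """Layout and sampling parameters of the synthetic city.

    district_spacing: grid pitch between district centers, meters.
    district_weights: relative population weights (cycled 1,2,3 by default);
        heavier districts receive proportionally more schools.
    in_class_nomination_rate: probability that one of a pupil's best-friend
        nominations falls on a classmate (and is therefore traceable); the
        remainder name people outside the surveyed class and are lost,
        which is what leaves some pupils sparsely connected or isolated.
    cross_link_scale: exponential decay length of cross-school friendship
        probability, meters.
    group_boost: multiplicative boost per shared co-occurrence group.
    out_link_target: desired expected out-of-school ties per pupil.
    """

    n_districts: int = 12
    district_spacing: float = 1500.0
    district_weights: tuple | None = None
    n_schools: int = 20
    pupils_per_school: int = 30
    classes_per_school: int = 1
    activity_rates: Mapping = field(
        default_factory=lambda: {"sports": 0.3, "church": 0.3, "transport": 0.2})
    nomination_limit: int = 5
    in_class_nomination_rate: float = 0.5
    cross_link_scale: float = 2000.0
    group_boost: float = 3.0
    out_link_target: float = 1.5
    seed: int = 0

    def __post_init__(self):
        for name in ("n_districts", "n_schools", "pupils_per_school",
                     "classes_per_school", "nomination_limit"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.cross_link_scale <= 0:
            raise ValueError("cross_link_scale must be positive")
        if self.group_boost < 1:
            raise ValueError("group_boost must be >= 1")
        if not 0.0 <= self.in_class_nomination_rate <= 1.0:
            raise ValueError("in_class_nomination_rate outside [0, 1]")
        for a, r in self.activity_rates.items():
            if not 0.0 <= r <= 1.0:
                raise ValueError(f"activity rate for {a!r} outside [0, 1]")

    def weights(self) -> np.ndarray:
        if self.district_weights is not None:
            w = np.asarray(self.district_weights, dtype=float)
            if len(w) != self.n_districts or np.any(w <= 0):
                raise ValueError("district_weights must be positive, one per district")
            return w
        return np.array([1.0 + (i % 3) for i in range(self.n_districts)])


def _apportion(weights: np.ndarray, total: int) -> np.ndarray:
    """Largest-remainder apportionment of ``total`` schools by weight."""
    quota = weights / weights.sum() * total
    base = np.floor(quota).astype(int)
    rem = total - base.sum()
    order = np.argsort(-(quota - base))
    base[order[:rem]] += 1
    return base


def generate_truth(config: CityConfig) -> AttributedGraph:
    """Sample a complete ground-truth friendship network.

    Intra-class edges are the undirected union of fixed-choice nominations
    (each pupil names up to ``nomination_limit`` classmates).  Cross-school
    edges are sampled independently with probability
    min(1, beta * exp(-d / lambda) * boost^shared_groups), with beta found
    by bisection so the expected out-links per pupil equal the target.
    Bit-identical under the same seed.
    """
    rng = np.random.default_rng(config.seed)
    weights = config.weights()
    ncols = math.ceil(math.sqrt(config.n_districts))
    dpos = np.array([(i % ncols, i // ncols) for i in range(config.n_districts)],
                    dtype=float) * config.district_spacing
    per_district = _apportion(weights, config.n_schools)

    acts = sorted(config.activity_rates)
    records, school_xy, school_of, district_of = [], [], [], []
    si = 0
    for di in range(config.n_districts):
        for _ in range(per_district[di]):
            sx = dpos[di, 0] + rng.uniform(-0.4, 0.4) * config.district_spacing
            sy = dpos[di, 1] + rng.uniform(-0.4, 0.4) * config.district_spacing
            for pi in range(config.pupils_per_school):
                node_acts = [a for a in acts
                             if rng.random() < config.activity_rates[a]]
                records.append({
                    "id": f"s{si:03d}p{pi:03d}",
                    "site_id": f"school{si:03d}",
                    "district_id": f"district{di:02d}",
                    "x": sx, "y": sy,
                    "activities": node_acts,
                })
                school_of.append(si)
                district_of.append(di)
            school_xy.append((sx, sy))
            si += 1

    n = len(records)
    ids = [r["id"] for r in records]
    edges = set()

    # fixed-choice nominations within each class
    class_size = config.pupils_per_school // config.classes_per_school
    if class_size < 2:
        raise ValueError("classes_per_school leaves classes of size < 2")
    for s in range(config.n_schools):
        base = s * config.pupils_per_school
        pupils = list(range(base, base + config.pupils_per_school))
        classes = [pupils[k::config.classes_per_school]
                   for k in range(config.classes_per_school)]
        for cls in classes:
            for p in cls:
                others = [q for q in cls if q != p]
                # each of the (up to) nomination_limit named best friends is
                # a classmate with probability in_class_nomination_rate; the
                # rest fall outside the class boundary and leave no trace
                k_in = int(rng.binomial(config.nomination_limit,
                                        config.in_class_nomination_rate))
                k = min(k_in, len(others))
                if k == 0:
                    continue
                picks = rng.choice(len(others), size=k, replace=False)
                for j in picks:
                    q = others[j]
                    edges.add((min(p, q), max(p, q)))

    # cross-school edges: distance decay x group boost, calibrated rate
    if config.n_schools > 1:
        sxy = np.asarray(school_xy)
        sdiff = sxy[:, None, :] - sxy[None, :, :]
        sdm = np.sqrt((sdiff ** 2).sum(axis=2))
        school_arr = np.asarray(school_of)
        district_arr = np.asarray(district_of)
        amat = np.array([[a in r["activities"] for a in acts] for r in records],
                        dtype=float)
        shared = amat @ amat.T
        same_d = district_arr[:, None] == district_arr[None, :]
        shared = np.where(same_d, shared, 0.0)
        iu, ju = np.triu_indices(n, k=1)
        cross = school_arr[iu] != school_arr[ju]
        iu, ju = iu[cross], ju[cross]
        d = sdm[school_arr[iu], school_arr[ju]]
        w = np.exp(-d / config.cross_link_scale) \
            * config.group_boost ** shared[iu, ju]
        target = config.out_link_target * n / 2.0
        if len(w) < target:
            raise ValueError(
                "infeasible out-link calibration: expected edge target "
                f"{target:.0f} exceeds the {len(w)} cross-school pairs")
        beta = _calibrate_beta(w, target)
        p = np.minimum(1.0, beta * w)
        hits = rng.random(len(p)) < p
        for a, b in zip(iu[hits], ju[hits]):
            edges.add((min(a, b), max(a, b)))

    return AttributedGraph.from_records(
        records, [(ids[a], ids[b]) for a, b in sorted(edges)])


def _calibrate_beta(w: np.ndarray, target: float) -> float:
    """Bisect the global rescaling beta so sum(min(1, beta*w)) == target."""
    f = lambda b: float(np.minimum(1.0, b * w).sum())
    lo, hi = 0.0, 1.0
    while f(hi) < target:
        hi *= 2.0
        if hi > 1e18:
            raise ValueError("infeasible out-link calibration: decay weights "
                             "too small to reach the target edge count")
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if f(mid) < target:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def apply_boundary_specification(truth: AttributedGraph):
    """Censor the truth to what the survey records.

    Returns ``(observed, hidden)``: ``observed`` is the truth minus every
    cross-site edge; ``hidden`` is exactly the removed edge set.
    Idempotent — the observed graph has zero cross-site edges.
    """
    observed = truth.copy()
    hidden = set()
    for u, v in list(observed.g.edges):
        if observed.site_of(u) != observed.site_of(v):
            observed.g.remove_edge(u, v)
            hidden.add(ProbabilisticGraph.key(u, v))
    return observed, frozenset(hidden)


@dataclass(frozen=True)
class RecoveryReport:
    """Precision/recall of imputed edges and ranking AUC vs. hidden truth.

    Fields are None when undefined (no imputed edges; no probabilities)."""

    precision: float | None
    recall: float | None
    auc: float | None


def recovery_scores(hidden, candidates, graph: AttributedGraph | None = None,
                    seed: int = 0, n_negatives: int | None = None
                    ) -> RecoveryReport:
    """Score an imputation against the hidden cross-site edges.

    ``candidates`` is either an imputed edge set (-> precision/recall) or a
    :class:`ProbabilisticGraph` (-> ranking AUC of hidden pairs against
    cross-site non-link pairs sampled from ``graph``).  Ties in the
    probabilities contribute 1/2, so a constant scorer sits at AUC 0.5.
    """
    hidden = {ProbabilisticGraph.key(u, v) for u, v in hidden}
    if isinstance(candidates, ProbabilisticGraph):
        if not hidden:
            raise ValueError("AUC needs a non-empty hidden edge set")
        if graph is None:
            raise ValueError("AUC needs the observed graph to sample negatives")
        rng = np.random.default_rng(seed)
        nodes = sorted(graph.g.nodes, key=str)
        n_neg = n_negatives or min(10 * len(hidden), 50_000)
        negatives, tries = set(), 0
        while len(negatives) < n_neg and tries < 50 * n_neg:
            u, v = (nodes[i] for i in rng.integers(0, len(nodes), 2))
            tries += 1
            if u == v or graph.site_of(u) == graph.site_of(v):
                continue
            k = ProbabilisticGraph.key(u, v)
            if k not in hidden:
                negatives.add(k)
        pos = np.array([candidates.get(*k) for k in sorted(hidden)])
        neg = np.array([candidates.get(*k) for k in sorted(negatives)])
        ranks = rankdata(np.concatenate([pos, neg]))
        auc = (ranks[:len(pos)].sum() - len(pos) * (len(pos) + 1) / 2.0) \
            / (len(pos) * len(neg))
        return RecoveryReport(None, None, float(auc))
    imputed = {ProbabilisticGraph.key(u, v) for u, v in candidates}
    if not imputed:
        return RecoveryReport(None, 0.0 if hidden else None, None)
    tp = len(imputed & hidden)
    return RecoveryReport(tp / len(imputed),
                          tp / len(hidden) if hidden else None, None)
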