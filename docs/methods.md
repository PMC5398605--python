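# Methods

## Problem setting and data model

The package operates on undirected simple graphs whose nodes carry a site
(school), a district, planar site coordinates in meters, and a set of
binary activity memberships.  Coordinates are site-level: all pupils of a
school share the school's location, because surveys of this kind geocode
institutions, not respondents.  Consequently the within-site distance is
exactly 0, and the imputation methods exclude same-site pairs by default —
with site-level granularity a distance-decay rule would otherwise connect
every same-site pair with probability 1 and turn each school into a
clique.  An optional loader accepts lon/lat degrees and applies an
equirectangular projection about the centroid; all internal distances are
Euclidean meters.

"Components" are connected vertex sets of size ≥ 2; degree-0 nodes are
counted separately as isolates.  Both counts are reported, since imputation
at weak settings can *pair up* former isolates and temporarily raise the
component count above its starting value.

## Distance-decay imputation

P_link(u,v) = exp(−d·k/c) with d the site distance (m), k the accumulated
degree of both endpoints at evaluation time, c > 0 a decay divisor in
meters.  Properties: P = 1 when d = 0 or k = 0; strictly decreasing in d
and k otherwise; pointwise increasing in c (so the mean imputed-edge count
rises with c).  The degree damping encodes the censoring hypothesis: nodes
with few observed ties are the ones whose nominations were lost, so they
deserve new links first.

Because k evolves, the evaluation order matters.  The traversal draws
centers u as a random permutation; for each center the other sites are
visited nearest-first (ties broken by site id), taking one randomly chosen
not-yet-evaluated member per site per pass and cycling until the center's
candidates are exhausted.  Each unordered pair is evaluated exactly once —
when the first of its endpoints becomes the center.  Acceptance is strict:
the edge is created iff P_link > r for an independent uniform r.  The whole
run is a deterministic function of (graph, c, policy, seed).

## Cold-start bootstrap

Phase I. A group definition is a scope attribute (default: district) plus a
set of required activities; each scope value yields one concrete group.
The group link share is p_γ = l_γ / e_γ over *observed* edges, where l_γ
counts edges internal to the group and e_γ counts edges with at least one
endpoint in the group, each edge once.  This convention guarantees
l_γ ≤ e_γ and hence a valid probability (a degree-sum convention would
double-count internal edges).  A pair sharing k groups links if at least
one group produces the tie: summing the 2^k − 1 non-null outcomes gives
1 − Π(1 − p_γ), which is what the code evaluates (the enumeration is kept
as a test oracle).  Observed edges enter the probabilistic graph at
probability 1 so that phase II can exploit the known structure.

Phase II. P2(u,v) = Σ_y P1(u,y)·P1(v,y), computed as a symmetric matrix
square (dense when the matrix is ≥ 5% full, sparse otherwise; the zero
diagonal makes the y ∈ {u,v} exclusion automatic).  P2 is a score and may
exceed 1.

Scores score = P1 + P2 are mapped to probabilities by
log(score+1)/log(max+1), with the max taken over candidate (non-observed)
pairs only, so the best candidate maps to exactly 1 and observed
probability-1 entries do not pin the scale.  If every score is zero the
normalizer is undefined; the code warns and emits zeros.  Thresholding at
P ≥ r is deterministic and the imputed count is a non-increasing step
function of r.  A single phase-II pass is applied.

## Combined method

Phase I stores (rather than accepts) probabilities
exp(−(d/c)·1/(k+1)) along the same semi-random traversal, with d a
geo-social distance √(Δx²+Δy²+Δs²) and k the running expected degree:
observed edges count 1, previously stored probabilities count at their
value.  The social coordinate s is drawn once per run, uniformly on
[0, α/2^n] for a node with n activities, so active nodes concentrate near
0 and are mutually close on the social axis.  α defaults to the median
inter-site distance, making the social leg commensurate with geography;
α = 0 reduces phase I to pure geography (tested equivalence).

Note the damping direction: a higher expected degree *raises* the
probability (the +1-guarded reciprocal), which is the opposite of the
distance-decay method.  The formula is implemented exactly as stated, and a
documented `inverse_degree_damping` switch exposes the penalizing variant.
A consequence visible in the synthetic experiments is that on observed
networks with moderate degrees the stored probabilities are high nearly
everywhere and the hybrid floods the graph with edges at all but very small
c; it behaves conservatively only when the observed components are sparse.
Phase II and the log normalization are identical to the bootstrap; each
candidate pair is finally accepted iff P_link > t for an independent
uniform t, drawn in traversal order.

## Evaluation

Reference bands for a plausible urban friendship network: average degree in
[5, 10]; density ≤ 0.014; mean shortest path in [5, 7]; transitivity
≤ 0.252; degree assortativity strictly positive; mean out-of-site links per
node in [1, 2]; component and isolate counts to be minimized (no hard
band).  Interval endpoints pass.

Transitivity uses the standard 3·triangles/connected-triplets form.  The
mean shortest path averages over all reachable *ordered* pairs (equivalent
to unordered for the mean), i.e. it is component-size weighted; an
unweighted per-component mean is available as an option because the
averaging convention is genuinely ambiguous in the field.  Out-links count,
for each node, its edges whose other endpoint has a different site id.

CCDF machinery: empirical survival curves over node degrees or over the
distances spanned by existing edges.  Site-level coordinates put every
same-site edge at distance exactly 0 — a point mass no continuous family
can follow — so fits are run on the positive-distance part
(`positive_only=True`).  Candidate families: folded Cauchy
f(x;a) = 1/(π(1+(x−a)²)) + 1/(π(1+(x+a)²)) with a free scale; bounded
power law x^(−α) on [x_min, x_max] (α < 1 is admissible thanks to the
upper cutoff, and the survival curve then bends down near x_max on log-log
axes); lognormal; exponential.  Each family is fitted by least squares on
the survival function; selection is by highest KS p-value, ties by lowest
KS statistic; the Pearson correlation between empirical and fitted curves
is reported.  KS p-values use the asymptotic distribution with the small-n
Stephens correction and are computed against the *fitted* distribution
without a refit penalty — they are approximate and serve model selection,
not formal hypothesis testing.

Outlier sites (whose median distance to the other sites exceeds a chosen
quantile of the median-distance distribution) can be removed before
distance-driven imputation; a far-flung site would otherwise dominate the
distance scale.

## Synthetic city generator

Defaults: 12 districts on a 1500 m grid with population weights cycling
1,2,3; 20 schools apportioned to districts by weight (largest remainder);
30 pupils per school in one class; activities sports/church/transport with
rates 0.30/0.30/0.20; nomination limit 5 with in-class rate 0.5;
cross-school decay length λ = 2000 m; group boost 3; out-link target 1.5
per pupil; everything driven by one seed (regeneration is bit-identical).

Intra-class edges are the undirected union of fixed-choice nominations:
each pupil names up to five best friends, of which each lands on a
classmate with probability 0.5 — the rest name people outside the class
boundary and leave no trace.  This censoring is what produces the sparse
and occasionally isolated respondents that characterize real fixed-choice
survey data; the observed mean degree comes out near 4 and the full truth
near 6, inside the [5, 10] band real close-friendship networks occupy.
Cross-school ties are sampled independently with probability
min(1, β·exp(−d/λ)·boost^(shared groups)), with β found by bisection so the
expected out-links per pupil hit the target; an unreachable target raises
an error naming the binding constraint.  The exponential decay (rather
than a power law) keeps this calibration analytic; the distribution
fitters are exercised on both families via direct samplers in the tests.

What the generator does *not* emulate: demographic homophily (age, gender),
multi-class schools' internal structure beyond equal splits, per-pupil
geocoding, degree heterogeneity beyond the nomination mechanism, and any
calibration to a particular real survey.  Tests passing on this synthetic
city therefore show that the methods behave as designed under controlled
conditions — recovery above chance, monotone parameter response, bands
reachable — not that they are accurate on any specific real data set.

Censoring removes exactly the cross-school edges; the removed set is the
hidden ground truth.  Recovery is scored by precision/recall of imputed
edges and by the rank AUC of predicted probabilities for hidden pairs
against sampled cross-school non-links (ties count 1/2, so a constant
predictor scores 0.5).

## Numerical choices and problem sizes

- Acceptance of a stochastic edge uses the log-transformed comparison
  d·k < −c·ln(r), avoiding an exp per pair.
- The phase-II matrix square switches to dense BLAS above 5% fill.
- The traversal keeps per-run state in numpy arrays; all randomness flows
  from one `numpy.random.Generator` per run, so identical (input, config,
  seed) reproduce byte-identical edge lists.
- Test and acceptance runs use the default 20-school × 30-pupil city
  (600 nodes, ~170k candidate pairs) with 20 method seeds for the
  Monte-Carlo sweeps, which keeps every check well-resolved at desk scale.
- Degenerate inputs: empty candidate sets warn and return the input copy;
  graphs below 2 nodes are rejected by the metrics; a single-site graph
  passes through the outlier filter unchanged; an all-zero score map warns
  and emits zeros.

## Known limitations

- The bootstrap's groups are district-scoped; pupils living near district
  borders are never candidates, which caps achievable recall — a
  granularity limit inherent to the method, visible in the synthetic
  experiments as a residual component count at high thresholds.
- The combined method's degree direction (rewarding expected degree) makes
  it aggressive on dense observed components; use the
  `inverse_degree_damping` switch for the conservative variant.
- KS p-values are approximate (no refit penalty) and should be read as a
  ranking criterion.
- All distances assume a planar projection; city-scale extents only.
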