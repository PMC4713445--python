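# Methods

## Model

cdlink treats link prediction as similarity ranking on an unweighted,
undirected simple graph *G* = (*V*, *E*): every unordered node pair gets a
real score; pairs absent from the observed graph are ranked by descending
score, and the top of the list is the prediction. The package's own
contribution is the CD family, which embeds nodes in *n*-dimensional space
using shortest-path distances:

1. **Distances.** `bfs_apsp` runs a frontier-expansion breadth-first
   search from every source against the adjacency structure: the nodes at
   distance *k* are located, the union of their not-yet-stamped neighbours
   is stamped *k* + 1, and the sweep ends when the frontier empties.
   Per-source BFS costs O(n + m), so the full matrix costs O(n(n + m));
   correctness is pinned by entrywise equality with an independent
   Floyd–Warshall on every fixture, including ∞ placement on disconnected
   graphs. (The frontier step is a *union* of neighbour sets: any reading
   that intersects the frontier members' neighbourhoods would not compute
   BFS distances, and the oracle-equivalence suite is the arbiter.)
2. **Thresholding.** `k_distance_matrix` keeps entries ≤ *k* and maps the
   rest to ∞. *k* controls how far structural information travels:
   *k* = d_max (the default) keeps the whole metric, small *k* localises
   the coordinates. Requests with *k* > d_max clamp to d_max (identical
   result by construction).
3. **Coordinates.** `coordinate_matrix` inverts entrywise,
   c_ij = 1/l_ij with 1/∞ := 0, and sets the diagonal to 1. The unit
   diagonal is essential: with c_ii = 0 a coordinate shared by the two
   rows can drop out of the cosine entirely (the worked 3-vector example
   in the test suite shows the score inflating from 0.4822 to 0.8305),
   and the unit diagonal also keeps every row nonzero so the cosine is
   always defined. At *k* = 1 the matrix is exactly A + I.
4. **Scores.** CD is the cosine of two coordinate rows; CD-LD sums CD
   over unordered distinct pairs of common neighbours; CD\*LD multiplies
   the two; CDI multiplies CD by the degree product k_i·k_j of the
   training graph.

Structurally equivalent nodes (identical neighbour sets) have identical
distance profiles and hence identical CD scores against all third nodes;
this is enforced as a property test at 1e-12 tolerance via twin fixtures.

## Handling disconnection

The CD construction presumes a connected graph, but removing a random 10%
of edges can disconnect even a connected input. Unreachable pairs get
coordinate 0, the continuity limit of 1/l; the training-graph diameter is
recomputed per split for diameter-threshold variants; no split is ever
re-sampled for connectivity, so evaluation conditions stay unconditional.
The ∞ sentinel is `numpy.inf` throughout — it compares above any finite
distance and inverts to exactly 0, never overflowing.

## Baselines

The fourteen comparison indices use their standard literature formulas
(see `cdlink.baselines`). Conventions that the literature leaves open:

- **LP3 / LP4**: damping ε = 0.01 on the A³ and A⁴ terms; ε = 0 reduces
  LP3 to CN, a tested limit.
- **LRW**: 3 walk steps; the walker starts as a point mass at the source,
  moves by the row-normalised adjacency matrix, and each direction is
  weighted by the source's stationary mass q_i = k_i/2m.
- **CPA** external degree: e_x = k_x − |CN| − a_xy.
- **CAA** uses log₂; any fixed base only rescales scores and leaves
  rankings unchanged.
- Salton/Sorensen/LHN score 0 when an endpoint has degree 0.
- **RANDOM** assigns i.i.d. uniform(0,1) scores to all pairs under a
  stated seed — equivalent in distribution to inserting a random
  permutation of the probe links into the candidate ranking.

All of these are locked by brute-force loop oracles on every fixture with
n ≤ 12.

## Evaluation protocol

`split_edges` samples round-half-up(fraction·m) edges (minimum 1,
default fraction 0.1) uniformly without replacement into the probe set;
the training graph keeps the full node set. `precision_at_L` ranks all
non-training pairs; candidates are shuffled with a per-iteration seed
before a stable descending sort, so ties resolve uniformly at random —
indices like CD-LD and the CAR family put mass at exactly 0, and any
deterministic tie order would bias precision. `evaluate_index` repeats
split → rescore → precision with seeds base_seed + i and reports all
per-iteration values, their mean, and any iteration-level scoring errors
(surfaced, never silently skipped). Relative precision (method / random
predictor) returns NaN when the random baseline is exactly 0.

AUC is deliberately not implemented; precision@L is the protocol's
metric of record.

## Topology descriptors

`topology_summary` reports efficiency e = 2/(n(n−1)) Σ_{i<j} 1/d_ij
(unreachable pairs contribute 0), average local clustering
(Watts–Strogatz; the global transitivity ratio is available behind a
flag), Newman's degree-assortativity coefficient r (NaN on
degree-regular graphs, where it is undefined), heterogeneity
h = ⟨k²⟩/⟨k⟩², and the diameter. These are the quantities that predict
which index family will work: CD favours r > 0, CDI targets r < 0.

## Synthetic data

Test and example graphs come from `cdlink.fixtures`: deterministic toys
(path, cycle, star, complete), Erdős–Rényi G(n, p) (optionally
rejection-sampled to connectivity when an oracle suite needs a connected
instance), Barabási–Albert preferential attachment, connected
Watts–Strogatz rings, and a twin construction that adds a structurally
equivalent copy of a node. These reproduce the *mechanisms* the indices
respond to — degree heterogeneity, disassortative hubs, clustering — but
not the community structure, degree-correlation profiles or noise of
real interaction networks, so a passing suite certifies the arithmetic
and the protocol, not field performance on any particular real network.
Default study sizes: oracle suites use n ≤ 12 (exhaustive enumeration is
the point), distance oracles n ≤ 40 over 25 seeds, calibration of the
random predictor 2000 splits of a 30-node graph, and the end-to-end
protocol run a 200-node BA graph with 100 splits — large enough for the
informative-beats-random ordering to be stable at the chosen seeds,
small enough that the whole suite runs in seconds.

## Numerical choices

- Scores and equality assertions use absolute tolerance 1e-12; cosine
  values are clipped to [0, 1] to absorb floating-point overshoot on
  parallel rows.
- The LD sum is over unordered *distinct* pairs {p, q} of common
  neighbours (it measures similarity density *between* community
  members). The alternative reading that adds the diagonal terms —
  contributing |CN| for a cosine-type base — is available via
  `include_self=True` but off by default, and no adjacency restriction
  is imposed on {p, q}.
- Score tables are computed eagerly for all pairs as dense symmetric
  matrices; at the package's intended scales (10²–10³ nodes) this is
  simpler and faster than lazy per-pair evaluation, and value-identical.

## Known limitations

- Dense n×n matrices bound practical use to ~10⁴ nodes.
- Weighted, directed, bipartite and temporal graphs are out of scope, as
  is the LD construction over base indices other than CD.
- No theory is offered for choosing the threshold *k*; small integers
  (2–6) versus the diameter are exposed and compared empirically.
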