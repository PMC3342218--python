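# Methods

## Scope and model

`mllayout` lays out simple undirected interaction networks (opaque string
node ids, no edge weights or directions) and scores 2-D layouts against Gene
Ontology Biological Process annotations.  Disconnected inputs are not laid
out as a whole; callers extract the largest connected component first (the
package provides the extraction, with a deterministic lexicographic
tie-break between equal-sized components).

### Coarsening

The hierarchy G₀ … G_L is built by greedy randomized maximal matching:
nodes are visited in an order shuffled by the level's RNG; an unmatched node
is paired with the unmatched neighbour u minimizing a score — w(u) in the
original weighting, w(u)·(1 + deg u) in the degree-modified weighting — with
ties broken by smallest node id.  Matched pairs contract into metanodes
(weight = sum of members, name = lexicographically smallest member, so the
hierarchy is reproducible), unmatched nodes carry over as singletons, and
projected parallel edges collapse.  Coarsening stops at ≤ 2 nodes, so a
connected input always terminates in two nodes joined by one edge; a
zero-pair round additionally terminates the loop, although it cannot occur
on a connected graph.  Finding a truly optimal matching is NP-hard; the
greedy maximal matching is a deliberate trade of optimality for speed.

The multiplicative form of the degree-modified score is this package's own
choice: any function increasing in both weight and degree discourages hub
absorption, and the multiplicative form keeps the two factors on one scale.
It is a configuration choice (`weighting=`) so alternative penalties can be
substituted.

### Force model and refinement

Classic Fruchterman–Reingold forces with a node-weight factor on repulsion:
repulsion C·w·k²/d from a node of weight w at distance d, attraction d²/k
along edges, natural spring length k (default 100 layout units), repulsion
multiplier C (default 0.2).  The defaults for C, the convergence tolerance
(0.01), the cooling factor (0.95) and the per-level iteration budget (300)
were calibrated once on the synthetic suite so that an isolated edge reaches
its closed-form equilibrium distance k·C^⅓ within a few percent and
400-node benchmarks converge in well under a minute; all are exposed in
`ForceParams`.

A refinement sweep computes all node displacements simultaneously from the
current positions (Jacobi style, which is what makes a sweep reproducible
and directly comparable to a reference implementation), caps each move by
the current temperature, then cools geometrically.  The initial temperature
is 0.1 × the bounding-box diagonal of the starting layout, floored at k:
a freshly expanded level starts with members co-placed on their metanode,
and a temperature tied to that tiny extent would freeze refinement.
Iteration stops when the largest move falls below tolerance·k; hitting the
iteration budget logs a warning and returns the current positions rather
than failing.  Exactly coincident nodes are separated at sweep zero by a
seeded jitter of 10⁻⁴·k, and any residual zero distance is clamped at
10⁻¹²·k, so no division by zero can occur.

The per-level iteration budget is constant across levels.  Scaling the
budget with level depth is a known alternative; a constant budget keeps run
times predictable and was adopted deliberately.

### Clustering modulation

Local clustering coefficients are computed once on G₀ and propagated to
metanodes as the weight-weighted mean of their members' values.  With the
clustering option on (the default), edge attraction is scaled by
1 + α·(CC_u + CC_v)/2 and the repulsion between *non-adjacent* pairs by
1 + β·max(CC_u, CC_v), defaults α = β = 1.  The multiplicative 1 + gain·CC
form is this package's design: it is identity at CC = 0, bounded, and
reduces exactly to the plain engine at zero gains (`clustering=False`).

### Spatial index

The repulsion sum for a node of weight w is truncated at radius 3·k·√w and
the nodes inside the ball are fetched from an exact index.  Three backends
share one contract — the exact closed-ball membership set: an M-tree (pivot
and covering-radius pruning, works from distances alone), a uniform bucket
grid, and a vectorized exhaustive scan.  The brute backend applies no cutoff
and is the oracle the others are tested against; backends are rebuilt each
sweep, which at the target network sizes is far cheaper than the force
computation itself.  The cutoff factor 3 balances truncation error (the
neglected far-field repulsion decays as 1/d) against query cost and is
configurable.

### Uncoarsening

The coarsest graph is placed uniformly at random in a square canvas of side
10·k centred at the origin (only relative geometry matters downstream), and
is itself refined before expansion — harmless for two nodes and uniform
with the other levels.  Members of a metanode start at its final position;
pass-through nodes inherit their own.  After each level's refinement the
layout is auto-downscaled if its bounding box exceeds `width_limit`
(default 10⁶): coordinates and k shrink together (a similarity transform),
with k floored at 10⁻³ to guard against inter-node distances underflowing
the floating-point scale.  A single-level run from a random start
(`single_level_layout`) is the plain force-directed baseline.

One root seed drives everything — hierarchy randomization, canvas
placement, per-level jitter — through a `numpy` `default_rng` chain, so a
fixed seed gives bit-identical layouts across invocations.

## Evaluation procedure

Term information content is IC(t) = −ln p(t) with p(t) the fraction of
annotated genes assigned to t or any descendant; the root has IC 0 and
unannotated subtrees have undefined IC and are excluded from ancestor
searches.  Gene similarity is the best-match average of Lin term similarity
2·IC(MICA)/(IC(t₁)+IC(t₂)), bounded in [0, 1] — a boundedness the area
normalization of the score implicitly needs.  Identical terms score 1 even
at IC 0, where the Lin ratio degenerates to 0/0.  Resnik similarity is
available for exploration but is unbounded and not used by the score.
Only is_a edges are traversed and only the Biological Process namespace is
read from OBO/GAF inputs.

The trace sorts evaluable edges (both endpoints annotated; others are
excluded from all three traces symmetrically and counted) by Euclidean
layout distance, ties broken by edge insertion order, and reports the mean
similarity of the first ⌈f·E⌉ edges on a 1 % fraction grid.  The optimal
trace sorts by similarity itself; the random level is the overall mean, and
every trace ends exactly there at f = 1.  The score is the trapezoidal area
of (algorithm − random) over the grid divided by the area of
(optimal − random); an all-equal similarity distribution makes the
denominator zero and the score is then defined as 0.  Replicate layouts are
summarized by mean and SEM = sd/√n, and algorithms are compared with a
two-tailed paired t-test (zero-variance differences report p = 1 with a
degeneracy flag).

## Synthetic benchmark

The generator emulates the regime of published yeast interaction networks:
a planted-partition graph (intra-module edge probability p_in, inter-module
p_out, largest component kept) and a tree-shaped Biological Process
ontology with one branch of `depth` levels per module.  Each gene is
annotated to its module's leaf except, with probability `noise`, to a
uniformly random leaf.  The default benchmark — four modules of 100 nodes,
p_in = 0.2, p_out = 0.005, depth 3, noise 0.1 — has density and mean
clustering coefficient inside the ranges spanned by the published yeast
networks the method targets (D ≈ 0.002–0.065, MCC ≈ 0.04–0.65), and is
small enough that ten replicate layouts run in a few minutes on one CPU.

What the generator does *not* emulate: scale-free degree tails, overlapping
modules, multi-term gene annotations, and DAG-shaped ontologies with
multiple parentage (a small multi-parent DAG fixture exists in the tests
for parser and IC correctness only).  With a single leaf per module branch,
gene similarity is effectively binary (same leaf vs different branches), so
passing benchmarks demonstrates that the score separates module-respecting
layouts from random ones — not that absolute score values transfer to real
GO corpora, whose graded similarities and annotation depth are richer.

## Numerical choices and degenerate inputs

- Lexicographic tie-breaks everywhere (component choice, matching partner,
  metanode naming, distance-tied edges) keep runs reproducible.
- Self-loops and duplicate edges in input files are dropped with a log
  entry rather than rejected; interaction files routinely contain both.
- Degree-SD in network summaries is the population SD (the sample variant
  is available); the mean clustering coefficient averages over *all* nodes,
  counting degree ≤ 1 nodes as 0.
- A one-layout evaluation reports SEM 0 with a single-run flag rather than
  NaN.
- Empty edge lists, disconnected layout inputs, unknown nodes, cyclic
  ontologies and multi-root ontologies raise typed errors early.

## Known limitations

- Layouts are 2-D only; no Barnes–Hut approximation, so the brute backend
  is quadratic per sweep and the indexed backends remain linear-times-ball
  occupancy.
- The evaluation reads one annotation namespace at a time and ignores
  part_of relations.
- Score values depend on the similarity distribution of the network's
  edges; comparing scores is meaningful within one network and annotation
  corpus, not across corpora.
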