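# mllayout

Multilevel force-directed layout for biological interaction networks, with a
GO-based procedure for scoring how biologically meaningful a layout is.

Large protein–protein and genetic interaction networks drawn with a plain
spring embedder tend to collapse into "hairballs" that hide their modular
organization.  `mllayout` implements a multilevel variant of force-directed
placement aimed at systems-biology users: the network is recursively
coarsened into a hierarchy of metanode graphs G₀, G₁, …, G_L by randomized
weighted edge matching, and the layout is then built top-down, refining each
level with a node-weighted Fruchterman–Reingold engine.  An optional
clustering mode modulates the forces by local clustering coefficients so that
dense modules contract and separate.  Because a pretty layout is not
necessarily an informative one, the package also ships an evaluation
procedure that walks the edges of a layout in order of their drawn length and
traces the cumulative mean Gene Ontology semantic similarity of the connected
gene pairs, normalizing the result into a single score (1 = ideal ordering,
≈ 0 = random).

## The model

Coarsening: visiting nodes in random order, each node is matched to its
unmatched neighbour u minimizing the weight w(u) (or w(u)·(1 + deg u) in the
degree-modified mode, which keeps hubs from swallowing star-like regions);
matched pairs contract into metanodes whose weight is the number of original
nodes they contain.  A connected graph terminates in a two-node, one-edge
coarsest graph.

Refinement at each level uses the spring-embedder force pair

    f_rep(d) = C · w · k² / d        f_attr(d) = d² / k

with natural spring length k, repulsion multiplier C and the weight w of the
repelling node; displacements are capped by a geometrically cooled
temperature.  With the clustering option, attraction along an edge is scaled
by 1 + α·mean(CC) of its endpoints and repulsion between non-adjacent nodes
by 1 + β·max(CC).  Neighbours inside the repulsion cutoff are fetched from an
exact metric index (M-tree, uniform grid, or brute force — all
interchangeable and exact).

Evaluation: with term information content IC(t) = −ln p(t) under the
annotation corpus, gene similarity is the best-match average of Lin term
similarity 2·IC(MICA)/(IC(t₁)+IC(t₂)).  The layout score is the area between
the algorithm's distance-ranked similarity trace and the random level,
normalized by the area under the ideal (similarity-ranked) trace.

## Worked example

```bash
mllayout --seed 5 simulate --modules 2 --size 20 --p-in 0.4 --p-out 0.02 \
    --out net.sif,go.obo,ann.gaf
mllayout --seed 5 layout net.sif --out coords.tsv
mllayout evaluate net.sif coords.tsv --obo go.obo --gaf ann.gaf \
    --out chart.png,scores.tsv
```

which prints

```
wrote net.sif (40 nodes, 155 edges), go.obo, ann.gaf
mean score 0.5908 (SEM 0.0000, n=1)
```

The simulated network has two planted 20-gene modules; the multilevel layout
places each module's genes together, so ranking edges by their drawn length
front-loads the functionally similar pairs and the normalized semantic
similarity score lands well above the random level (0.59 here; a random
placement of the same network scores about 0, a perfect ordering 1).  `chart.png` shows the three traces — algorithm,
optimal and random — as the fraction of evaluated neighbours grows to 100 %.

The same workflow runs from Python:

```python
from mllayout import (build_graph, largest_connected_component, ForceParams,
                      multilevel_layout, evaluation_trace, semantic_similarity_score)
```

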