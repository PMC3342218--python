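"""Biological evaluation of 2-D layouts via Gene Ontology semantic similarity.

A layout is biologically meaningful when nodes drawn close together share
biological process annotations.  The evaluation walks all edges of the
network in ascending order of their Euclidean length in the layout and traces
the cumulative mean semantic similarity of the edges seen so far.  Two
references frame the trace: the *optimal* trace ranks the same edges by
similarity itself (the best any layout could do), and the *random* level is
the mean similarity over all edges (what a random ordering converges to).
The normalized score is the area between the algorithm trace and the random
level divided by the area between the optimal trace and the random level:
1 for an ideal layout, about 0 for a random one.

Gene-level similarity is the best-match average of Lin term similarity,
sim(t1, t2) = 2 IC(MICA) / (IC(t1) + IC(t2)), where IC(t) = -ln p(t) is the
information content of a term under the annotation corpus and MICA the most
informative common ancestor.  Lin similarity is bounded in [0, 1], which the
area normalization implicitly requires; Resnik (IC of the MICA, unbounded)
is available as an alternative for exploratory use.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import NamedTuple

import networkx as nx
import numpy as np
from scipy import stats

from .forcelayout import Layout
from .graph_model import Graph


class OntologyError(ValueError):
    pass


class OntologyDAG:
    """A rooted is_a DAG of ontology terms (one namespace).

    Edges point child -> parent.  The structure must be acyclic with a
    single root reachable from every term.
    """

    def __init__(self, terms, is_a_edges, namespace: str = "biological_process"):
        self.namespace = namespace
        dag = nx.DiGraph()
        dag.add_nodes_from(terms)
        for child, parent in is_a_edges:
            if child not in dag or parent not in dag:
                raise OntologyError(f"is_a edge references unknown term: {child} -> {parent}")
            dag.add_edge(child, parent)
        if not nx.is_directed_acyclic_graph(dag):
            raise OntologyError("is_a graph contains a cycle")
        roots = [t for t in dag.nodes if dag.out_degree(t) == 0]
        if len(roots) != 1:
            raise OntologyError(f"ontology must have exactly one root, found {len(roots)}")
        self.root = roots[0]
        for t in dag.nodes:
            if t != self.root and not nx.has_path(dag, t, self.root):
                raise OntologyError(f"term {t} does not reach the root")
        self._dag = dag
        # ancestor closure incl. the term itself, cached once
        self._ancestors = {t: frozenset(nx.descendants(dag, t)) | {t} for t in dag.nodes}

    @property
    def terms(self) -> set:
        return set(self._dag.nodes)

    def parents(self, term) -> set:
        return set(self._dag.successors(term))

    def ancestors(self, term) -> frozenset:
        """Ancestor closure of ``term``, including the term itself."""
        return self._ancestors[term]

    def descendants(self, term) -> set:
        """All terms below ``term`` (excluding it)."""
        return set(nx.ancestors(self._dag, term))

    def __contains__(self, term) -> bool:
        return term in self._dag

    def __len__(self) -> int:
        return self._dag.number_of_nodes()

    def __eq__(self, other):
        if not isinstance(other, OntologyDAG):
            return NotImplemented
        return self.terms == other.terms and set(self._dag.edges) == set(other._dag.edges)


class AnnotationMap:
    """Direct gene -> GO-term annotations for one namespace."""

    def __init__(self, annotations: dict, onto: OntologyDAG | None = None):
        self._ann = {g: frozenset(ts) for g, ts in annotations.items() if ts}
        if onto is not None:
            unknown = {t for ts in self._ann.values() for t in ts if t not in onto}
            if unknown:
                raise OntologyError(f"annotations reference unknown terms: {sorted(unknown)[:5]}")

    def terms_of(self, gene) -> frozenset:
        return self._ann.get(gene, frozenset())

    @property
    def genes(self) -> set:
        return set(self._ann)

    def __contains__(self, gene) -> bool:
        return gene in self._ann

    def __len__(self) -> int:
        return len(self._ann)

    def __eq__(self, other):
        if not isinstance(other, AnnotationMap):
            return NotImplemented
        return self._ann == other._ann


def information_content(onto: OntologyDAG, ann: AnnotationMap) -> dict:
    """IC(t) = -ln( genes annotated to t or any descendant / total genes ).

    The root scores 0 by construction.  Terms with no annotated gene in
    their subtree have undefined IC and are omitted (and hence excluded
    from MICA searches).
    """
    counts: dict = {}
    for gene in ann.genes:
        covered = set()
        for t in ann.terms_of(gene):
            covered |= onto.ancestors(t)
        for t in covered:
            counts[t] = counts.get(t, 0) + 1
    total = len(ann)
    if total == 0:
        raise OntologyError("annotation map is empty")
    return {t: -math.log(c / total) for t, c in counts.items()}


def term_similarity(t1, t2, onto: OntologyDAG, ic: dict, measure: str = "lin") -> float:
    """Pairwise term similarity via the most informative common ancestor.

    Identical terms score 1 under Lin even when their IC is 0 (a term
    annotating the whole corpus), where the 2 IC/(IC+IC) form is 0/0.
    """
    if measure == "lin" and t1 == t2:
        return 1.0
    common = onto.ancestors(t1) & onto.ancestors(t2)
    mica_ic = max((ic[t] for t in common if t in ic), default=0.0)
    if measure == "resnik":
        return mica_ic
    denom = ic.get(t1, 0.0) + ic.get(t2, 0.0)
    if denom <= 0.0:
        return 0.0
    return 2.0 * mica_ic / denom


def gene_similarity(
    g1,
    g2,
    onto: OntologyDAG,
    ann: AnnotationMap,
    ic: dict | None = None,
    measure: str = "lin",
) -> float:
    """Best-match-average similarity between two annotated genes."""
    if g1 not in ann or g2 not in ann:
        raise OntologyError(f"gene without annotation: {g1 if g1 not in ann else g2!r}")
    if ic is None:
        ic = information_content(onto, ann)
    ts1, ts2 = sorted(ann.terms_of(g1)), sorted(ann.terms_of(g2))
    sim = np.array([[term_similarity(a, b, onto, ic, measure) for b in ts2] for a in ts1])
    return float(0.5 * (sim.max(axis=1).mean() + sim.max(axis=0).mean()))


@dataclass
class EvaluationTrace:
    """Cumulative similarity traces over distance-ranked edge prefixes."""

    ranked_fractions: np.ndarray
    algorithm_trace: np.ndarray
    optimal_trace: np.ndarray
    random_level: float
    n_edges_evaluated: int
    n_edges_excluded: int = 0


def _prefix_means(sims: np.ndarray, fractions: np.ndarray) -> np.ndarray:
    cum = np.cumsum(sims)
    m = len(sims)
    counts = np.ceil(fractions * m - 1e-9).astype(int)
    counts = np.clip(counts, 1, m)
    return cum[counts - 1] / counts


def evaluation_trace(
    g: Graph,
    layout: Layout,
    onto: OntologyDAG,
    ann: AnnotationMap,
    grid_step: float = 0.01,
    ic: dict | None = None,
    measure: str = "lin",
) -> EvaluationTrace:
    """Trace mean similarity over edges ranked by layout distance.

    Edges with an unannotated endpoint are excluded from all three traces
    symmetrically (their count is reported).  Distance ties are broken by
    edge insertion order so runs are reproducible.
    """
    if ic is None:
        ic = information_content(onto, ann)
    edges = g.edges
    sims, dists, excluded = [], [], 0
    for eidx, (u, v) in enumerate(edges):
        if u not in ann or v not in ann:
            excluded += 1
            continue
        pu = np.asarray(layout.positions[u])
        pv = np.asarray(layout.positions[v])
        dists.append((float(np.sqrt(np.sum((pu - pv) ** 2))), eidx))
        sims.append(gene_similarity(u, v, onto, ann, ic=ic, measure=measure))
    if not sims:
        raise OntologyError("no evaluable edges: every edge has an unannotated endpoint")
    sims = np.asarray(sims)
    order = np.lexsort((np.array([e for _, e in dists]), np.array([d for d, _ in dists])))
    n_grid = round(1.0 / grid_step)
    fractions = np.linspace(grid_step, 1.0, n_grid)
    return EvaluationTrace(
        ranked_fractions=fractions,
        algorithm_trace=_prefix_means(sims[order], fractions),
        optimal_trace=_prefix_means(np.sort(sims)[::-1], fractions),
        random_level=float(sims.mean()),
        n_edges_evaluated=len(sims),
        n_edges_excluded=excluded,
    )


def semantic_similarity_score(tr: EvaluationTrace) -> float:
    """Area-normalized layout quality: 1 ideal, about 0 for random orderings.

    Trapezoidal area between the algorithm trace and the random level,
    divided by the area between the optimal trace and the random level.
    When all similarities are equal the optimal area is zero and the score
    is defined as 0.
    """
    f = tr.ranked_fractions
    a_alg = float(np.trapezoid(tr.algorithm_trace - tr.random_level, f))
    a_opt = float(np.trapezoid(tr.optimal_trace - tr.random_level, f))
    if a_opt <= 1e-15:
        return 0.0
    return a_alg / a_opt


@dataclass
class ScoreSummary:
    scores: list[float] = field(default_factory=list)
    mean: float = 0.0
    sem: float = 0.0
    single_run: bool = False


def evaluate_algorithm(
    g: Graph,
    layouts: list[Layout],
    onto: OntologyDAG,
    ann: AnnotationMap,
    grid_step: float = 0.01,
    measure: str = "lin",
) -> ScoreSummary:
    """Score each replicate layout; report the mean and SEM = sd / sqrt(n)."""
    if not layouts:
        raise ValueError("need at least one layout")
    ic = information_content(onto, ann)
    scores = [
        semantic_similarity_score(
            evaluation_trace(g, lay, onto, ann, grid_step=grid_step, ic=ic, measure=measure)
        )
        for lay in layouts
    ]
    n = len(scores)
    sem = float(np.std(scores, ddof=1) / np.sqrt(n)) if n > 1 else 0.0
    return ScoreSummary(scores=scores, mean=float(np.mean(scores)), sem=sem, single_run=(n == 1))


class PairedTestResult(NamedTuple):
    t: float
    p: float
    degenerate: bool


def compare_scores(scores_a, scores_b) -> PairedTestResult:
    """Two-tailed paired t-test on replicate score lists.

    Zero-variance differences (identical lists, or a constant shift) make
    the t statistic undefined; those cases report p = 1 with a degeneracy
    flag instead of failing.
    """
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired score lists must have equal length")
    if len(a) < 2:
        raise ValueError("paired t-test needs at least 2 pairs")
    diff = a - b
    if np.std(diff, ddof=1) == 0.0:
        return PairedTestResult(t=float("nan"), p=1.0, degenerate=True)
    t, p = stats.ttest_rel(a, b)
    return PairedTestResult(t=float(t), p=float(p), degenerate=False)
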