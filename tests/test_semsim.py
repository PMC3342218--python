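"""Semantic-similarity machinery: information content, Lin/best-match-average
gene similarity, distance-ranked traces and the normalized layout score."""

import math

import numpy as np
import pytest
from scipy import stats

from mllayout.forcelayout import Layout
from mllayout.graph_model import build_graph
from mllayout.semsim_eval import (
    AnnotationMap,
    EvaluationTrace,
    OntologyDAG,
    OntologyError,
    _prefix_means,
    compare_scores,
    evaluate_algorithm,
    evaluation_trace,
    gene_similarity,
    information_content,
    semantic_similarity_score,
)

LN2, LN4 = math.log(2), math.log(4)


class TestOntologyDAG:
    def test_cycle_rejected(self):
        with pytest.raises(OntologyError, match="cycle"):
            OntologyDAG(["a", "b"], [("a", "b"), ("b", "a")])

    def test_two_roots_rejected(self):
        with pytest.raises(OntologyError, match="root"):
            OntologyDAG(["r1", "r2", "c"], [("c", "r1")])

    def test_ancestors_include_self(self, toy_ontology):
        assert toy_ontology.ancestors("t3") == {"t3", "t1", "b1", "root"}
        assert toy_ontology.ancestors("t2") == {"t2", "b1", "b2", "root"}


class TestInformationContent:
    def test_root_ic_zero(self, toy_ontology, toy_annotations):
        ic = information_content(toy_ontology, toy_annotations)
        assert ic["root"] == 0.0

    def test_one_of_eight_genes(self):
        onto = OntologyDAG(["root", "leaf"], [("leaf", "root")])
        ann = AnnotationMap(
            {"g1": {"leaf"}, **{f"g{i}": {"root"} for i in range(2, 9)}}, onto
        )
        ic = information_content(onto, ann)
        assert ic["leaf"] == pytest.approx(-math.log(1 / 8))

    def test_hand_counted_toy_values(self, toy_ontology, toy_annotations):
        ic = information_content(toy_ontology, toy_annotations)
        assert ic["t3"] == pytest.approx(LN4)
        assert ic["t1"] == pytest.approx(LN2)
        assert ic["t2"] == pytest.approx(LN4)
        assert ic["b1"] == pytest.approx(math.log(4 / 3))
        assert ic["b2"] == pytest.approx(LN2)

    def test_antitone_along_is_a(self, toy_ontology, toy_annotations):
        ic = information_content(toy_ontology, toy_annotations)
        for child in toy_ontology.terms:
            for parent in toy_ontology.parents(child):
                if child in ic and parent in ic:
                    assert ic[child] >= ic[parent]

    def test_unannotated_subtree_excluded(self, toy_ontology):
        ann = AnnotationMap({"g1": {"t1"}, "g2": {"t1"}}, toy_ontology)
        ic = information_content(toy_ontology, ann)
        assert "t2" not in ic and "b2" not in ic


class TestGeneSimilarity:
    def test_self_similarity_is_one(self, toy_ontology, toy_annotations):
        assert gene_similarity("gene1", "gene1", toy_ontology, toy_annotations) == 1.0

    def test_root_only_common_ancestor_is_zero(self, toy_ontology, toy_annotations):
        # gene1 (t1, branch b1) vs gene4 (b2): only shared ancestor is the root
        assert gene_similarity("gene1", "gene4", toy_ontology, toy_annotations) == 0.0

    def test_hand_enumerated_pairs(self, toy_ontology, toy_annotations):
        # gene1 {t1} vs gene3 {t3}: MICA t1, Lin = 2 ln2 / (ln2 + ln4)
        assert gene_similarity("gene1", "gene3", toy_ontology, toy_annotations) == pytest.approx(
            2 * LN2 / (LN2 + LN4)
        )
        # gene1 {t1} vs gene2 {t2}: MICA b1
        assert gene_similarity("gene1", "gene2", toy_ontology, toy_annotations) == pytest.approx(
            2 * math.log(4 / 3) / (LN2 + LN4)
        )
        # gene2 {t2} vs gene4 {b2}: MICA b2
        assert gene_similarity("gene2", "gene4", toy_ontology, toy_annotations) == pytest.approx(
            2 * LN2 / (LN4 + LN2)
        )

    def test_similarity_bounded(self, toy_ontology, toy_annotations):
        genes = sorted(toy_annotations.genes)
        for g1 in genes:
            for g2 in genes:
                s = gene_similarity(g1, g2, toy_ontology, toy_annotations)
                assert 0.0 <= s <= 1.0 + 1e-12

    def test_unannotated_gene_flagged(self, toy_ontology, toy_annotations):
        with pytest.raises(OntologyError, match="annotation"):
            gene_similarity("gene1", "ghost", toy_ontology, toy_annotations)


def two_leaf_fixture():
    """Two process leaves under the root; similarity is 1 within a leaf's
    gene set and 0 across (the MICA collapses to the root)."""
    onto = OntologyDAG(["root", "A", "B"], [("A", "root"), ("B", "root")])
    ann = AnnotationMap(
        {g: {"A"} for g in ("a1", "a2", "a3")} | {g: {"B"} for g in ("b1", "b2", "b3")},
        onto,
    )
    return onto, ann


class TestEvaluationTrace:
    def test_hand_computed_cumulative_means(self):
        onto, ann = two_leaf_fixture()
        edges = [("a1", "a2"), ("a2", "a3"), ("a1", "b1"), ("b1", "b2"), ("a3", "b3")]
        g = build_graph(edges)
        # distances by construction: (a1,b1)=1 < (a1,a2)=2 < (a3,b3)=3 < (a2,a3)=4 < (b1,b2)=5
        pos = {
            "a1": (0.0, 0.0), "b1": (1.0, 0.0), "a2": (-2.0, 0.0),
            "a3": (-2.0, 4.0), "b3": (1.0, 4.0), "b2": (1.0, 5.0),
        }
        lay = Layout(pos, 100.0)
        tr = evaluation_trace(g, lay, onto, ann, grid_step=0.2)
        # similarity by distance order: 0, 1, 0, 1, 1 -> prefix means
        np.testing.assert_allclose(tr.algorithm_trace, [0, 1 / 2, 1 / 3, 2 / 4, 3 / 5])
        # optimal: 1, 1, 1, 0, 0
        np.testing.assert_allclose(tr.optimal_trace, [1, 1, 1, 3 / 4, 3 / 5])
        assert tr.random_level == pytest.approx(3 / 5)
        assert tr.n_edges_evaluated == 5

    def test_constant_similarities_give_flat_traces(self):
        onto, ann = two_leaf_fixture()
        g = build_graph([("a1", "a2"), ("a2", "a3"), ("a1", "a3")])
        lay = Layout({"a1": (0, 0), "a2": (3, 0), "a3": (0, 7)}, 100.0)
        tr = evaluation_trace(g, lay, onto, ann, grid_step=0.25)
        assert np.all(tr.algorithm_trace == 1.0)
        assert np.all(tr.optimal_trace == 1.0)
        assert tr.random_level == 1.0

    def test_unannotated_endpoints_excluded_symmetrically(self):
        onto, ann = two_leaf_fixture()
        g = build_graph([("a1", "a2"), ("a1", "zz")])
        lay = Layout({"a1": (0, 0), "a2": (1, 0), "zz": (2, 0)}, 100.0)
        tr = evaluation_trace(g, lay, onto, ann)
        assert tr.n_edges_evaluated == 1
        assert tr.n_edges_excluded == 1

    def test_no_evaluable_edges_is_an_error(self):
        onto, ann = two_leaf_fixture()
        g = build_graph([("x", "y")])
        lay = Layout({"x": (0, 0), "y": (1, 0)}, 100.0)
        with pytest.raises(OntologyError):
            evaluation_trace(g, lay, onto, ann)

    def test_trace_at_full_fraction_equals_random_level(self):
        onto, ann = two_leaf_fixture()
        g = build_graph([("a1", "a2"), ("a1", "b1"), ("a2", "b2"), ("b1", "b2")])
        rng = np.random.default_rng(0)
        lay = Layout({v: tuple(rng.uniform(0, 10, 2)) for v in g.nodes}, 100.0)
        tr = evaluation_trace(g, lay, onto, ann)
        assert tr.algorithm_trace[-1] == pytest.approx(tr.random_level)
        assert tr.optimal_trace[-1] == pytest.approx(tr.random_level)


def trace_for_ordering(sims, order, grid_step=0.02):
    """Trace object for an explicit edge ordering of given similarities."""
    sims = np.asarray(sims, float)
    n_grid = round(1.0 / grid_step)
    fr = np.linspace(grid_step, 1.0, n_grid)
    return EvaluationTrace(
        ranked_fractions=fr,
        algorithm_trace=_prefix_means(sims[order], fr),
        optimal_trace=_prefix_means(np.sort(sims)[::-1], fr),
        random_level=float(sims.mean()),
        n_edges_evaluated=len(sims),
    )


class TestSemanticSimilarityScore:
    def test_optimal_ordering_scores_one(self):
        rng = np.random.default_rng(1)
        sims = rng.uniform(0, 1, 40)
        order = np.argsort(-sims)
        assert semantic_similarity_score(trace_for_ordering(sims, order)) == pytest.approx(1.0)

    def test_constant_similarities_score_zero(self):
        sims = np.full(30, 0.7)
        order = np.arange(30)
        assert semantic_similarity_score(trace_for_ordering(sims, order)) == 0.0

    def test_any_ordering_bounded_by_optimal(self):
        rng = np.random.default_rng(2)
        sims = rng.uniform(0, 1, 30)
        for _ in range(50):
            order = rng.permutation(30)
            assert semantic_similarity_score(trace_for_ordering(sims, order)) <= 1.0 + 1e-12

    def test_random_orderings_average_near_zero(self):
        rng = np.random.default_rng(3)
        sims = rng.uniform(0, 1, 50)
        scores = [
            semantic_similarity_score(trace_for_ordering(sims, rng.permutation(50)))
            for _ in range(1000)
        ]
        assert abs(np.mean(scores)) < 0.02

    def test_invariant_under_similarity_transforms(self):
        onto, ann = two_leaf_fixture()
        g = build_graph([("a1", "a2"), ("a1", "b1"), ("a2", "b2"), ("b1", "b2"), ("a3", "a1")])
        rng = np.random.default_rng(5)
        base = {v: rng.uniform(0, 10, 2) for v in g.nodes}
        lay = Layout({v: tuple(p) for v, p in base.items()}, 100.0)
        ref = semantic_similarity_score(evaluation_trace(g, lay, onto, ann))
        theta = 1.1
        rot = np.array([[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]])
        transforms = {
            "translate": {v: p + np.array([100.0, -40.0]) for v, p in base.items()},
            "rotate": {v: rot @ p for v, p in base.items()},
            "reflect": {v: np.array([-p[0], p[1]]) for v, p in base.items()},
            "scale": {v: 7.3 * p for v, p in base.items()},
        }
        for name, pts in transforms.items():
            lay_t = Layout({v: tuple(p) for v, p in pts.items()}, 100.0)
            got = semantic_similarity_score(evaluation_trace(g, lay_t, onto, ann))
            assert got == pytest.approx(ref), name


class TestEvaluateAlgorithm:
    def test_single_layout_flagged(self):
        onto, ann = two_leaf_fixture()
        g = build_graph([("a1", "a2"), ("a1", "b1")])
        lay = Layout({"a1": (0, 0), "a2": (1, 0), "b1": (5, 0)}, 100.0)
        summary = evaluate_algorithm(g, [lay], onto, ann)
        assert summary.single_run and summary.sem == 0.0

    def test_identical_layouts_zero_sem(self):
        onto, ann = two_leaf_fixture()
        g = build_graph([("a1", "a2"), ("a1", "b1"), ("b1", "b2")])
        lay = Layout({"a1": (0, 0), "a2": (1, 0), "b1": (5, 0), "b2": (5, 1)}, 100.0)
        summary = evaluate_algorithm(g, [lay, lay.copy(), lay.copy()], onto, ann)
        assert summary.sem == 0.0

    def test_mean_and_sem_match_recomputation(self):
        onto, ann = two_leaf_fixture()
        g = build_graph([("a1", "a2"), ("a1", "b1"), ("b1", "b2"), ("a2", "b2")])
        rng = np.random.default_rng(9)
        layouts = [
            Layout({v: tuple(rng.uniform(0, 10, 2)) for v in g.nodes}, 100.0) for _ in range(6)
        ]
        summary = evaluate_algorithm(g, layouts, onto, ann)
        scores = [
            semantic_similarity_score(evaluation_trace(g, lay, onto, ann)) for lay in layouts
        ]
        assert summary.mean == pytest.approx(np.mean(scores))
        assert summary.sem == pytest.approx(np.std(scores, ddof=1) / np.sqrt(len(scores)))


class TestCompareScores:
    def test_identical_lists_give_p_one(self):
        res = compare_scores([0.1, 0.2, 0.3], [0.1, 0.2, 0.3])
        assert res.p == 1.0 and res.degenerate

    def test_constant_shift_degenerate(self):
        a = [0.5, 0.6, 0.7]
        res = compare_scores([x + 1 for x in a], a)
        assert res.p == 1.0 and res.degenerate

    def test_matches_closed_form_t(self):
        rng = np.random.default_rng(12)
        a, b = rng.uniform(0, 1, 10), rng.uniform(0, 1, 10)
        res = compare_scores(a, b)
        d = a - b
        t_manual = d.mean() / (d.std(ddof=1) / np.sqrt(len(d)))
        p_manual = 2 * stats.t.sf(abs(t_manual), df=len(d) - 1)
        assert res.t == pytest.approx(t_manual, abs=1e-6)
        assert res.p == pytest.approx(p_manual, abs=1e-6)
        assert not res.degenerate

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            compare_scores([1, 2], [1, 2, 3])
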