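"""Synthetic modular networks and module-correlated ontology annotations.

Real interaction networks of budding yeast combine a hierarchically modular
wiring (dense functional modules, sparse cross-talk) with GO annotations
that track module membership imperfectly.  The generators here emulate both
features so the layout engine and the evaluation procedure can be exercised
end to end without any downloads: a planted-partition graph supplies the
modular topology, and a small tree-shaped process ontology annotates each
gene to its module's branch, with a tunable fraction of annotations
re-assigned at random to mimic annotation noise.
"""

from __future__ import annotations

import json
import pathlib

import numpy as np

from .graph_model import Graph, GraphModelError, build_graph, largest_connected_component
from .semsim_eval import AnnotationMap, OntologyDAG


def generate_modular_graph(
    module_sizes: list[int],
    p_in: float,
    p_out: float,
    rng_seed: int = 0,
) -> tuple[Graph, dict[str, int]]:
    """Planted-partition graph with the given module sizes.

    Every intra-module node pair is joined with probability ``p_in`` and
    every inter-module pair with ``p_out`` (< p_in).  The largest connected
    component is returned together with the module label of each surviving
    node.  Node ids are strings ``g0000``, ``g0001``, ...
    """
    if not (p_out < p_in <= 1.0):
        raise ValueError("need p_out < p_in <= 1")
    rng = np.random.default_rng(rng_seed)
    labels: list[int] = []
    for m, size in enumerate(module_sizes):
        labels.extend([m] * size)
    n = len(labels)
    ids = [f"g{i:04d}" for i in range(n)]
    lab = np.asarray(labels)
    iu, ju = np.triu_indices(n, k=1)
    same = lab[iu] == lab[ju]
    prob = np.where(same, p_in, p_out)
    keep = rng.random(len(iu)) < prob
    pairs = [(ids[iu[k]], ids[ju[k]]) for k in np.flatnonzero(keep)]
    if not pairs:
        raise GraphModelError("generator parameters produced an empty graph")
    g = largest_connected_component(build_graph(pairs))
    modules = {ids[i]: int(lab[i]) for i in range(n) if ids[i] in g}
    return g, modules


def generate_annotations(
    modules: dict[str, int],
    depth: int = 3,
    noise: float = 0.1,
    rng_seed: int = 0,
) -> tuple[OntologyDAG, AnnotationMap]:
    """Tree ontology with one branch per module, plus noisy annotations.

    The ontology is a rooted tree with ``depth`` levels: the root, then a
    chain of increasingly specific terms per module ending in that module's
    leaf term.  Each gene is annotated to its own module's leaf, except that
    with probability ``noise`` it is annotated to a uniformly random leaf
    instead; every gene ends up annotated.  With noise 0 the within-module
    gene similarity is maximal (shared leaf) and the between-module
    similarity collapses to the root.
    """
    if depth < 2:
        raise ValueError("depth must be >= 2")
    if not 0.0 <= noise < 1.0:
        raise ValueError("noise must be in [0, 1)")
    rng = np.random.default_rng(rng_seed)
    module_ids = sorted(set(modules.values()))
    root = "GO:0000000"
    terms = [root]
    edges = []
    leaves: dict[int, str] = {}
    for m in module_ids:
        parent = root
        for lvl in range(1, depth):
            term = f"GO:{m + 1:03d}{lvl:04d}"
            terms.append(term)
            edges.append((term, parent))
            parent = term
        leaves[m] = parent
    onto = OntologyDAG(terms, edges, namespace="biological_process")
    leaf_list = [leaves[m] for m in module_ids]
    ann = {}
    for gene in sorted(modules):
        if rng.random() < noise:
            leaf = leaf_list[int(rng.integers(0, len(leaf_list)))]
        else:
            leaf = leaves[modules[gene]]
        ann[gene] = {leaf}
    return onto, AnnotationMap(ann, onto)


def write_provenance(path, **params) -> None:
    """Record generator parameters next to emitted files."""
    pathlib.Path(path).write_text(json.dumps(params, indent=2, sort_keys=True) + "\n")
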