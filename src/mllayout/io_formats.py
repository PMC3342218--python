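"""Readers and writers for the interchange formats the toolkit touches.

Networks come in as Cytoscape SIF files or plain two-column edge lists,
layouts travel as TSV node/x/y tables, ontologies as OBO 1.2 and annotations
as GAF 2.x.  Everything normalizes through :func:`~mllayout.graph_model.build_graph`,
so duplicate edges and self-loops in interaction files are tolerated.
"""

from __future__ import annotations

import logging
import pathlib

import obonet
import pandas as pd

from .forcelayout import Layout
from .graph_model import Graph, GraphModelError, build_graph
from .semsim_eval import AnnotationMap, OntologyDAG

logger = logging.getLogger(__name__)


class FormatError(ValueError):
    pass


# ---------------------------------------------------------------------------
# networks
# ---------------------------------------------------------------------------

def read_network(path, format: str | None = None) -> Graph:
    """Read a SIF or edge-list file into a level-0 graph.

    SIF rows are ``source interaction target [target ...]`` and fan out to
    one edge per target; the interaction type is parsed but discarded (the
    layout is type-blind).  Edge lists take the two leading columns of each
    row; ``#`` comments and blank lines are skipped in both formats.
    """
    path = pathlib.Path(path)
    if format is None:
        format = "sif" if path.suffix.lower() == ".sif" else "edgelist"
    if format not in ("sif", "edgelist"):
        raise FormatError(f"unknown network format {format!r}")
    pairs = []
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        tokens = line.split()
        if format == "sif":
            if len(tokens) < 3:
                raise FormatError(f"{path}:{lineno}: SIF row needs source, interaction, target")
            source = tokens[0]
            for target in tokens[2:]:
                pairs.append((source, target))
        else:
            if len(tokens) < 2:
                raise FormatError(f"{path}:{lineno}: edge-list row needs two columns")
            pairs.append((tokens[0], tokens[1]))
    if not pairs:
        raise GraphModelError(f"{path}: no edges found")
    return build_graph(pairs)


def write_network(g: Graph, path, format: str = "sif", interaction: str = "pp") -> None:
    """Write the edge set as SIF (``u pp v`` rows) or a two-column edge list."""
    lines = []
    for u, v in sorted(g.edges):
        if format == "sif":
            lines.append(f"{u}\t{interaction}\t{v}")
        else:
            lines.append(f"{u}\t{v}")
    pathlib.Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# layouts
# ---------------------------------------------------------------------------

def write_layout(layout: Layout, path) -> None:
    """TSV ``node_id  x  y`` with a header; 6 significant digits, C locale."""
    lines = ["node_id\tx\ty"]
    for node in sorted(layout.positions):
        x, y = layout.positions[node]
        lines.append(f"{node}\t{x:.6g}\t{y:.6g}")
    pathlib.Path(path).write_text("\n".join(lines) + "\n")


def read_layout(path, graph: Graph | None = None, spring_length: float = 100.0) -> Layout:
    """Read a node/x/y TSV back into a :class:`Layout`.

    If ``graph`` is given and its node set does not match the file, a
    warning is logged (the layout is returned regardless).
    """
    df = pd.read_csv(path, sep="\t", dtype={"node_id": str})
    positions = {
        str(row.node_id): (float(row.x), float(row.y)) for row in df.itertuples(index=False)
    }
    if graph is not None and set(positions) != set(graph.nodes):
        logger.warning(
            "layout file %s covers %d nodes but the graph has %d",
            path,
            len(positions),
            graph.n_nodes,
        )
    return Layout(positions, spring_length, {"source": str(path)})


# ---------------------------------------------------------------------------
# ontology and annotations
# ---------------------------------------------------------------------------

def read_obo(path, namespace: str = "biological_process") -> OntologyDAG:
    """Parse an OBO 1.2 file into a rooted is_a DAG for one namespace.

    Obsolete terms are skipped and only is_a edges are traversed; terms of
    other namespaces are dropped.
    """
    g = obonet.read_obo(path)  # skips obsolete terms
    keep = {
        t
        for t, data in g.nodes(data=True)
        if data.get("namespace", namespace) == namespace
    }
    edges = [
        (child, parent)
        for child, parent, key in g.edges(keys=True)
        if key == "is_a" and child in keep and parent in keep
    ]
    return OntologyDAG(keep, edges, namespace=namespace)


def write_obo(onto: OntologyDAG, path) -> None:
    """Serialize a DAG as minimal OBO 1.2 (id, name, namespace, is_a)."""
    blocks = ["format-version: 1.2"]
    for term in sorted(onto.terms):
        lines = [f"[Term]", f"id: {term}", f"name: {term}", f"namespace: {onto.namespace}"]
        for parent in sorted(onto.parents(term)):
            lines.append(f"is_a: {parent} ! {parent}")
        blocks.append("\n".join(lines))
    pathlib.Path(path).write_text("\n\n".join(blocks) + "\n")


def read_gaf(path, onto: OntologyDAG | None = None, aspect: str = "P") -> AnnotationMap:
    """Parse GAF 2.x annotations, keeping one aspect (default ``P``).

    Column 2 is the gene id, column 5 the GO term, column 9 the aspect.
    Annotations to terms missing from the ontology are dropped with a
    logged count.
    """
    ann: dict[str, set] = {}
    dropped = 0
    for line in pathlib.Path(path).read_text().splitlines():
        if not line or line.startswith("!"):
            continue
        cols = line.split("\t")
        if len(cols) < 9:
            raise FormatError(f"GAF row with fewer than 9 columns: {line[:60]!r}")
        gene, term, asp = cols[1], cols[4], cols[8]
        if asp != aspect:
            continue
        if onto is not None and term not in onto:
            dropped += 1
            continue
        ann.setdefault(gene, set()).add(term)
    if dropped:
        logger.info("dropped %d annotation(s) to terms missing from the ontology", dropped)
    return AnnotationMap(ann, onto)


def write_gaf(ann: AnnotationMap, path, db: str = "SYNTH", aspect: str = "P") -> None:
    """Serialize annotations as minimal GAF 2.1 rows."""
    lines = ["!gaf-version: 2.1"]
    for gene in sorted(ann.genes):
        for term in sorted(ann.terms_of(gene)):
            cols = [
                db, gene, gene, "", term, "SYNTH:0001", "IEA", "", aspect,
                gene, "", "gene", "taxon:4932", "20120326", db, "", "",
            ]
            lines.append("\t".join(cols))
    pathlib.Path(path).write_text("\n".join(lines) + "\n")
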