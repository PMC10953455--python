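"""Ontology-aware term enrichment on transferred annotations.

Reads an OBO ontology (is_a edges, optionally part_of) and GAF 2.x
annotations, propagates annotations to ancestors (true-path rule), and
tests term overrepresentation with one-sided Fisher's exact tests,
either per-term ("classic") or with the elim decorrelation scheme that
removes the significant genes of a significant child term from its
ancestors before they are tested.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import obonet
import pandas as pd
from scipy import stats

__all__ = [
    "EnrichmentResult",
    "OntologyDAG",
    "classic_fisher_term",
    "elim_enrichment",
    "propagate_annotations",
    "read_gaf",
]

NAMESPACES = ("biological_process", "cellular_component", "molecular_function")


class OntologyDAG:
    """Directed acyclic is_a graph of ontology terms.

    Edges run child -> parent.  Terms carry a namespace; obsolete terms
    are excluded at load time.
    """

    def __init__(self, graph: nx.DiGraph):
        if not nx.is_directed_acyclic_graph(graph):
            raise ValueError("ontology graph contains a cycle")
        self.graph = graph

    @classmethod
    def from_obo(cls, path, include_part_of: bool = False) -> "OntologyDAG":
        multi = obonet.read_obo(path)
        g = nx.DiGraph()
        for node, data in multi.nodes(data=True):
            if data.get("is_obsolete") in ("true", True):
                continue
            g.add_node(node, namespace=data.get("namespace", "biological_process"))
        for child, parent, key in multi.edges(keys=True):
            if child not in g or parent not in g:
                continue
            if key == "is_a" or (include_part_of and key == "part_of"):
                g.add_edge(child, parent)
        return cls(g)

    @classmethod
    def from_edges(cls, parents: dict, namespace: dict | None = None) -> "OntologyDAG":
        """Build from {term: parent set}; convenient for toy ontologies."""
        g = nx.DiGraph()
        for term, ps in parents.items():
            ns = (namespace or {}).get(term, "biological_process")
            g.add_node(term, namespace=ns)
            for p in ps:
                g.add_edge(term, p)
        for node in g.nodes:
            g.nodes[node].setdefault("namespace", "biological_process")
        return cls(g)

    def namespace(self, term: str) -> str:
        return self.graph.nodes[term]["namespace"]

    def ancestors(self, term: str) -> set:
        """All is_a ancestors of a term (excluding the term itself)."""
        return nx.descendants(self.graph, term)  # edges point child -> parent

    def terms(self, namespace: str | None = None) -> list:
        if namespace is None:
            return list(self.graph.nodes)
        return [t for t in self.graph.nodes if self.namespace(t) == namespace]

    def bottom_up_order(self, terms=None) -> list:
        """Terms ordered children before parents (topological order on
        the child -> parent graph)."""
        order = list(nx.topological_sort(self.graph))
        if terms is None:
            return order
        keep = set(terms)
        return [t for t in order if t in keep]


def read_gaf(path, key: str = "DB_Object_Symbol") -> dict:
    """Gene -> direct GO term set from a GAF 2.x file.

    ``key`` selects the gene identifier column (symbol by default).
    NOT-qualified annotations are skipped.
    """
    from Bio.UniProt import GOA

    annotations: dict = {}
    with open(path) as fh:
        for rec in GOA.gafiterator(fh):
            if any(q.startswith("NOT") for q in rec.get("Qualifier", []) if q):
                continue
            annotations.setdefault(rec[key], set()).add(rec["GO_ID"])
    return annotations


def propagate_annotations(dag: OntologyDAG, direct: dict) -> dict:
    """True-path closure: each gene is annotated to every ancestor of
    its direct terms.  Terms absent from the DAG are kept as-is."""
    closure_cache: dict = {}

    def closed(term: str) -> set:
        if term not in closure_cache:
            if term in dag.graph:
                closure_cache[term] = {term} | dag.ancestors(term)
            else:
                closure_cache[term] = {term}
        return closure_cache[term]

    out = {}
    for gene, terms in direct.items():
        full: set = set()
        for t in terms:
            full |= closed(t)
        out[gene] = full
    return out


def _term_to_genes(closed_annotations: dict, universe: set) -> dict:
    t2g: dict = {}
    for gene, terms in closed_annotations.items():
        if gene not in universe:
            continue
        for t in terms:
            t2g.setdefault(t, set()).add(gene)
    return t2g


def classic_fisher_term(term: str, sig_genes, universe, closed_annotations: dict) -> float:
    """One-sided Fisher p for overrepresentation of ``term``'s genes in
    the significant set.  Terms annotating no universe gene are skipped
    (ValueError)."""
    universe = set(universe)
    sig = set(sig_genes)
    if sig - universe:
        raise ValueError("significant genes must be a subset of the universe")
    in_term = {g for g, ts in closed_annotations.items() if term in ts and g in universe}
    if not in_term:
        raise ValueError(f"term {term} annotates no gene in the universe")
    a = len(in_term & sig)
    table = [[a, len(in_term) - a], [len(sig) - a, len(universe) - len(in_term) - len(sig) + a]]
    return float(stats.fisher_exact(table, alternative="greater")[1])


@dataclass
class EnrichmentResult:
    term: str
    namespace: str
    annotated: int
    significant: int
    expected: float
    p: float
    algorithm: str


def _run_enrichment(dag, closed_annotations, sig_genes, universe, alpha,
                    namespace, algorithm) -> list[EnrichmentResult]:
    universe = set(universe)
    sig = set(sig_genes) & universe
    t2g = _term_to_genes(closed_annotations, universe)
    testable = [t for t in t2g if t in dag.graph and dag.namespace(t) == namespace]
    removed: dict = {t: set() for t in testable}
    results = []
    if not sig:
        return results
    sig_frac = len(sig) / len(universe)
    for term in dag.bottom_up_order(testable):
        genes = t2g[term] - removed[term]
        n_sig = len(genes & sig)
        if not genes:
            continue
        a = n_sig
        table = [[a, len(genes) - a],
                 [len(sig) - a, len(universe) - len(genes) - len(sig) + a]]
        p = float(stats.fisher_exact(table, alternative="greater")[1])
        if p < alpha:
            results.append(EnrichmentResult(
                term=term, namespace=namespace, annotated=len(genes),
                significant=n_sig, expected=len(genes) * sig_frac, p=p,
                algorithm=algorithm,
            ))
            if algorithm == "elim":
                eliminated = genes & sig
                for anc in dag.ancestors(term):
                    if anc in removed:
                        removed[anc] |= eliminated
    return results


def elim_enrichment(dag: OntologyDAG, closed_annotations: dict, sig_genes, universe,
                    alpha: float = 0.01, namespace: str = "biological_process",
                    algorithm: str = "elim") -> list[EnrichmentResult]:
    """Bottom-up enrichment with child-term decorrelation.

    Terms are processed children-first; when a term tests significant
    (p < ``alpha``) its significant annotated genes are removed from all
    of its ancestors before they are tested.  ``algorithm='classic'``
    disables the elimination and tests every term independently.
    Results are the terms with final p < alpha.
    """
    if algorithm not in ("elim", "classic"):
        raise ValueError("algorithm must be 'elim' or 'classic'")
    return _run_enrichment(dag, closed_annotations, sig_genes, universe,
                           alpha, namespace, algorithm)


def enrichment_table(results: list[EnrichmentResult]) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in results],
                        columns=["term", "namespace", "annotated", "significant",
                                 "expected", "p", "algorithm"])
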