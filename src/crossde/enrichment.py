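"""GO biological-process, gene-set, and network-neighbour enrichment.

GO terms are tested one-sidedly with the hypergeometric distribution on
annotations propagated up the is_a DAG, adjusted by Benjamini–Yekutieli
(valid under the arbitrary dependence induced by nested terms).  Because
an ancestor term can reach significance purely through one significant
offspring, a local redundancy step re-tests each significant ancestor
after removing the genes of its significant offspring from both the
query and the term: the ancestor is kept only if residual signal remains.

Gene-set enrichment (e.g. against a known cancer-gene catalogue) and
direct-interaction-neighbour enrichment on a protein-protein interaction
graph are thin applications of the same hypergeometric tail.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import networkx as nx

from .stats import TailTestResult, by_adjust, hypergeom_tail

logger = logging.getLogger(__name__)

__all__ = [
    "GODag",
    "EnrichmentRecord",
    "go_enrich",
    "resolve_redundancy",
    "geneset_enrich",
    "ppi_neighbor_enrich",
    "load_ppi_network",
]


class GODag:
    """is_a DAG of GO terms with gene annotations propagated to ancestors.

    ``edges`` are (child, parent) pairs; ``annotations`` maps gene →
    directly annotated terms.  On construction every gene is propagated to
    all ancestors of its direct terms, so ``term_genes[t]`` is the full
    annotation of ``t``.
    """

    def __init__(
        self,
        edges: list[tuple[str, str]],
        annotations: dict[str, set[str]],
        names: dict[str, str] | None = None,
    ) -> None:
        g = nx.DiGraph()
        g.add_edges_from(edges)  # child -> parent
        for gene, terms in annotations.items():
            for t in terms:
                if t not in g:
                    g.add_node(t)
        if not nx.is_directed_acyclic_graph(g):
            raise ValueError("GO is_a relation must be acyclic")
        self.graph = g
        self.names = dict(names or {})
        self.term_genes: dict[str, set[str]] = {t: set() for t in g.nodes}
        for gene, terms in annotations.items():
            covered: set[str] = set()
            for t in terms:
                covered.add(t)
                covered |= nx.descendants(g, t)  # ancestors along child->parent
            for t in covered:
                self.term_genes[t].add(gene)

    @property
    def terms(self) -> set[str]:
        return set(self.graph.nodes)

    def ancestors(self, term: str) -> set[str]:
        return nx.descendants(self.graph, term)

    def offspring(self, term: str) -> set[str]:
        return nx.ancestors(self.graph, term)

    def name_of(self, term: str) -> str:
        return self.names.get(term, term)


@dataclass(frozen=True)
class EnrichmentRecord:
    """One tested term: counts, raw p, BY-adjusted q, and selection flags."""

    term: str
    name: str
    k: int  # query genes in term
    K: int  # term size in universe
    n: int  # query size
    N: int  # universe size
    p_value: float
    log10_p: float
    q_value: float
    significant: bool
    selected: bool


def go_enrich(
    query: set[str],
    universe: set[str],
    dag: GODag,
    fdr: float = 0.05,
    min_term_size: int = 5,
    max_term_size: int = 2000,
    resolve: bool = True,
    retest_p: float = 0.05,
) -> list[EnrichmentRecord]:
    """Hypergeometric GO enrichment with BY adjustment and redundancy step.

    Terms whose universe-restricted annotation size falls outside
    [min_term_size, max_term_size] are excluded from testing (and from the
    adjustment).  Significant terms (q ≤ fdr) are passed through
    :func:`resolve_redundancy` unless ``resolve=False``; non-significant
    terms are never selected.  Records are returned sorted by raw p.
    """
    outside = query - universe
    if outside:
        raise ValueError(f"query not a subset of universe: {sorted(outside)[:10]}")
    if not query:
        return []
    tested: list[tuple[str, set[str]]] = []
    for term, genes in dag.term_genes.items():
        tg = genes & universe
        if min_term_size <= len(tg) <= max_term_size:
            tested.append((term, tg))
    if not tested:
        return []
    results = [
        hypergeom_tail(len(query & tg), len(tg), len(query), len(universe))
        for _, tg in tested
    ]
    qvals = by_adjust([r.p_value for r in results])
    records = [
        EnrichmentRecord(
            term=term,
            name=dag.name_of(term),
            k=len(query & tg),
            K=len(tg),
            n=len(query),
            N=len(universe),
            p_value=r.p_value,
            log10_p=r.log10_p,
            q_value=float(q),
            significant=bool(q <= fdr),
            selected=bool(q <= fdr),
        )
        for (term, tg), r, q in zip(tested, results, qvals)
    ]
    records.sort(key=lambda rec: (rec.p_value, rec.term))
    if resolve:
        significant = [rec for rec in records if rec.significant]
        kept = {
            rec.term: rec.selected
            for rec in resolve_redundancy(
                significant, dag, query, universe, retest_p=retest_p
            )
        }
        records = [
            replace(rec, selected=kept.get(rec.term, False)) for rec in records
        ]
    return records


def resolve_redundancy(
    records: list[EnrichmentRecord],
    dag: GODag,
    query: set[str],
    universe: set[str],
    retest_p: float = 0.05,
) -> list[EnrichmentRecord]:
    """Resolve ancestor/offspring redundancy among significant terms.

    Working bottom-up (offspring before ancestors in topological order),
    each significant term with at least one significant offspring is
    re-tested after removing the genes annotated to its significant
    offspring from both the query and the term's annotation; the ancestor
    is kept only if the residual raw p is ≤ ``retest_p``.  Terms without
    significant offspring are kept as-is.
    """
    sig_terms = {rec.term for rec in records}
    selected: dict[str, bool] = {}
    order = [t for t in nx.topological_sort(dag.graph) if t in sig_terms]
    for term in order:
        sig_offspring = dag.offspring(term) & sig_terms
        if not sig_offspring:
            selected[term] = True
            continue
        removed: set[str] = set()
        for off in sig_offspring:
            removed |= dag.term_genes[off] & universe
        reduced_query = query - removed
        reduced_term = (dag.term_genes[term] & universe) - removed
        k = len(reduced_query & reduced_term)
        res = hypergeom_tail(k, len(reduced_term), len(reduced_query), len(universe))
        selected[term] = res.p_value <= retest_p
        if not selected[term]:
            logger.info(
                "resolve_redundancy: dropping %s (residual p=%.3g after "
                "removing %d offspring genes)", term, res.p_value, len(removed),
            )
    return [replace(rec, selected=selected[rec.term]) for rec in records]


def geneset_enrich(
    query: set[str], reference: set[str], universe: set[str]
) -> TailTestResult:
    """Hypergeometric tail for the overlap of a query with a reference set."""
    for name, s in (("query", query), ("reference", reference)):
        outside = s - universe
        if outside:
            raise ValueError(f"{name} not a subset of universe: {sorted(outside)[:10]}")
    return hypergeom_tail(
        len(query & reference), len(reference), len(query), len(universe)
    )


def ppi_neighbor_enrich(
    query: set[str], seeds: set[str], net: nx.Graph, universe: set[str]
) -> TailTestResult:
    """Enrichment of a query in the direct interaction neighbours of seeds.

    The reference set is the union of the seeds' direct neighbours in the
    interaction graph, minus the seeds themselves, intersected with the
    universe.  The query must not overlap the seeds (remove known seed
    members first); seeds absent from the network are skipped with a
    warning.
    """
    if query & seeds:
        raise ValueError("query and seeds must be disjoint; remove seed members first")
    present = seeds & set(net.nodes)
    absent = seeds - present
    if absent:
        logger.warning(
            "ppi_neighbor_enrich: %d seeds absent from network (skipped)", len(absent)
        )
    neighbors: set[str] = set()
    for s in present:
        neighbors.update(net.neighbors(s))
    neighbors -= seeds
    return geneset_enrich(query, neighbors & universe, universe)


def load_ppi_network(edges: list[tuple[str, str]]) -> nx.Graph:
    """Build a simple undirected interaction graph, dropping self-loops."""
    g = nx.Graph()
    n_self = 0
    for u, v in edges:
        if u == v:
            n_self += 1
            continue
        g.add_edge(str(u), str(v))
    if n_self:
        logger.info("load_ppi_network: dropped %d self-loops", n_self)
    return g
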