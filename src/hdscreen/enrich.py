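"""Gene-set statistics on hit sets.

Covers the over-representation machinery of the screen analysis: the plain
one-sided hypergeometric test, the DAG-aware conditional enrichment (terms
are tested leaves-first; genes of a significantly enriched child are
excluded from its ancestors' annotations before those are tested, so the
most specific enriched terms win), the enrichment-map graph whose edges
join term pairs with Jaccard coefficient strictly above 0.25, the
chi-square test of independence for 2 x k contingency tables, and the
GWAS-homolog overlap test with its two filtering rules (case-control study
design and association p < 1e-5).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

GWAS_P_THRESHOLD = 1e-5


@dataclass
class OntologyDAG:
    """A rooted term DAG with per-term gene annotations.

    ``graph`` holds child -> parent edges. Annotations are propagated to
    ancestors with :meth:`propagate`, after which every child's gene set is
    a subset of each parent's.
    """

    graph: nx.DiGraph
    annotations: dict = field(default_factory=dict)

    @classmethod
    def from_edges(cls, edges, annotations=None, terms=None) -> "OntologyDAG":
        g = nx.DiGraph()
        if terms is not None:
            g.add_nodes_from(terms)
        g.add_edges_from(edges)
        if not nx.is_directed_acyclic_graph(g):
            raise ValueError("ontology edges contain a cycle")
        ann = {t: set(annotations.get(t, set())) for t in g.nodes} if annotations else {
            t: set() for t in g.nodes
        }
        return cls(graph=g, annotations=ann)

    @classmethod
    def from_tables(cls, edge_df: pd.DataFrame, annot_df: pd.DataFrame) -> "OntologyDAG":
        """Build from a (child_id, parent_id) edge table and a
        (term_id, gene_id) annotation table."""
        edges = list(zip(edge_df["child_id"], edge_df["parent_id"]))
        ann: dict = {}
        for t, g in zip(annot_df["term_id"], annot_df["gene_id"]):
            ann.setdefault(t, set()).add(g)
        terms = set(ann) | {t for e in edges for t in e}
        return cls.from_edges(edges, ann, terms=sorted(terms))

    @property
    def terms(self) -> list:
        return sorted(self.graph.nodes)

    def parents(self, term) -> list:
        return sorted(self.graph.successors(term))

    def children(self, term) -> list:
        return sorted(self.graph.predecessors(term))

    def ancestors(self, term) -> set:
        return nx.descendants(self.graph, term)  # child -> parent edges

    def propagate(self) -> None:
        """Push every term's genes up to all its ancestors (in place)."""
        for term in nx.topological_sort(self.graph):  # children before parents
            genes = self.annotations.setdefault(term, set())
            for parent in self.graph.successors(term):
                self.annotations.setdefault(parent, set()).update(genes)

    def is_propagated(self) -> bool:
        return all(
            self.annotations.get(c, set()) <= self.annotations.get(p, set())
            for c, p in self.graph.edges
        )

    def bottom_up_order(self) -> list:
        """Reverse-topological (leaves-first) order; sibling ties broken
        lexicographically by term ID."""
        return list(nx.lexicographical_topological_sort(self.graph))


@dataclass
class EnrichmentTerm:
    term_id: str
    term_size: int  # tested gene count after conditioning
    overlap: int
    p: float
    enriched: bool
    genes: set = field(default_factory=set)


def hypergeom_overrep(hits: set, target: set, universe: set) -> float:
    """One-sided P(X >= |hits & target|) under the hypergeometric null."""
    hits, target, universe = set(hits), set(target), set(universe)
    if not hits <= universe or not target <= universe:
        raise ValueError("hits and target must be contained in the universe")
    k = len(hits & target)
    if k == 0:
        return 1.0
    return float(stats.hypergeom.sf(k - 1, len(universe), len(target), len(hits)))


def conditional_enrichment(
    hits: set,
    universe: set,
    dag: OntologyDAG,
    alpha: float = 0.05,
    keep_all: bool = False,
) -> list[EnrichmentTerm]:
    """DAG-aware conditional over-representation test.

    Terms are tested leaves-first. When a term comes out significant
    (p < ``alpha``), its annotated genes are excluded from the annotations
    of all its ancestors before those are tested; the universe itself is
    left untouched. Returns the significant terms (all tested terms when
    ``keep_all``), with the conditioned counts used for each test.
    """
    hits = set(hits)
    universe = set(universe)
    if not hits <= universe:
        raise ValueError("hits must be contained in the universe")
    if not dag.is_propagated():
        raise ValueError("annotations must be propagated before testing")

    removed: dict = {t: set() for t in dag.graph.nodes}
    results = []
    for term in dag.bottom_up_order():
        genes = (dag.annotations.get(term, set()) - removed[term]) & universe
        k = len(genes & hits)
        p = hypergeom_overrep(hits, genes, universe) if genes else 1.0
        enriched = p < alpha
        results.append(
            EnrichmentTerm(
                term_id=term,
                term_size=len(genes),
                overlap=k,
                p=p,
                enriched=enriched,
                genes=genes,
            )
        )
        if enriched:
            for anc in dag.ancestors(term):
                removed[anc] |= dag.annotations.get(term, set())
    if keep_all:
        return results
    return [r for r in results if r.enriched]


def enrichment_map(
    terms: list[EnrichmentTerm],
    threshold: float = 0.25,
) -> pd.DataFrame:
    """Jaccard edges between enriched terms (strictly above ``threshold``).

    Terms with empty gene sets are excluded with a warning. Returns an
    edge table ``term_a, term_b, jaccard`` ordered by term IDs.
    """
    usable = []
    for t in terms:
        if not t.genes:
            warnings.warn(f"term {t.term_id} has an empty gene set; excluded")
            continue
        usable.append(t)
    usable.sort(key=lambda t: t.term_id)
    rows = []
    for i, a in enumerate(usable):
        for b in usable[i + 1:]:
            j = len(a.genes & b.genes) / len(a.genes | b.genes)
            if j > threshold:
                rows.append({"term_a": a.term_id, "term_b": b.term_id, "jaccard": j})
    return pd.DataFrame(rows, columns=["term_a", "term_b", "jaccard"])


def enrichment_map_graph(terms: list[EnrichmentTerm], threshold: float = 0.25) -> nx.Graph:
    """The enrichment map as a weighted graph (for GraphML export)."""
    edges = enrichment_map(terms, threshold)
    g = nx.Graph()
    for t in terms:
        if t.genes:
            g.add_node(t.term_id, p=float(t.p), size=int(t.term_size),
                       overlap=int(t.overlap))
    for _, row in edges.iterrows():
        g.add_edge(row["term_a"], row["term_b"], jaccard=float(row["jaccard"]),
                   weight=float(row["jaccard"]))
    return g


def chi_square_independence(table) -> tuple[float, float]:
    """Pearson chi-square test of independence on a 2 x k count table."""
    arr = np.asarray(table, dtype=float)
    if arr.ndim != 2:
        raise ValueError("contingency table must be 2-dimensional")
    if (arr < 0).any():
        raise ValueError("counts must be non-negative")
    if (arr.sum(axis=0) == 0).any() or (arr.sum(axis=1) == 0).any():
        raise ValueError("zero marginal in contingency table")
    statistic, p, _, _ = stats.chi2_contingency(arr, correction=False)
    return float(statistic), float(p)


def filter_gwas_records(records: pd.DataFrame) -> pd.DataFrame:
    """Apply the two GWAS filters: case-control design, association p < 1e-5."""
    need = {"disease", "study_design", "assoc_p", "yeast_homolog"}
    missing = need - set(records.columns)
    if missing:
        raise ValueError(f"GWAS records missing columns {sorted(missing)}")
    design = records["study_design"].astype(str).str.lower().str.replace("_", "-")
    keep = design.str.contains("case-control") & (records["assoc_p"] < GWAS_P_THRESHOLD)
    return records[keep]


def gwas_overlap(
    hits: set,
    records: pd.DataFrame,
    universe: set,
) -> pd.DataFrame:
    """Per-disease hypergeometric overlap of GWAS homolog sets with hits.

    Records are filtered by the study-design and association-p rules, then
    collapsed to per-disease yeast gene sets (restricted to the universe)
    and tested with :func:`hypergeom_overrep`.
    """
    filtered = filter_gwas_records(records)
    rows = []
    for disease, g in filtered.groupby("disease"):
        genes = set(g["yeast_homolog"].dropna()) & set(universe)
        p = hypergeom_overrep(set(hits), genes, set(universe)) if genes else 1.0
        rows.append(
            {
                "disease": disease,
                "n_genes": len(genes),
                "overlap": len(genes & set(hits)),
                "p": p,
            }
        )
    return pd.DataFrame(rows, columns=["disease", "n_genes", "overlap", "p"])
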