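"""Gene-set over-representation with the enrichment ratio statistic.

Supports GO-like ontologies (a rooted DAG with true-path annotation
propagation) as well as flat pathway collections. Each tested term gets a
one-sided Fisher exact p-value, a Pearson chi-square p-value from the same
2x2 table, a BH-FDR across tested terms, and the enrichment ratio

    Re = (n_f / n) / (N_f / N)

where ``n_f`` is the number of significant genes in the term, ``n`` the
number of universe genes in the term, ``N_f`` the total number of
significant genes, and ``N`` the universe size.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .deg import DegRecord, bh_fdr

__all__ = [
    "OntologyDag",
    "EnrichmentResult",
    "propagate_annotations",
    "fisher_enrichment",
    "enrichment_ratio",
    "chi_square_2x2",
    "filter_enriched",
    "build_go_tree",
    "enrichment_frame",
]


@dataclass
class OntologyDag:
    """Rooted term DAG with direct term->gene annotations.

    ``parents`` maps each term to its (possibly empty) set of parent terms;
    ``annotations`` holds the *direct* gene sets — run
    :func:`propagate_annotations` to close them under the ancestor relation.
    """

    parents: dict[str, set[str]]
    names: dict[str, str] = field(default_factory=dict)
    annotations: dict[str, set[str]] = field(default_factory=dict)

    @property
    def terms(self) -> list[str]:
        return list(self.parents)

    def children_map(self) -> dict[str, set[str]]:
        children: dict[str, set[str]] = {t: set() for t in self.parents}
        for child, parent_set in self.parents.items():
            for parent in parent_set:
                children.setdefault(parent, set()).add(child)
        return children

    def roots(self) -> list[str]:
        return [t for t, ps in self.parents.items() if not ps]

    def topological_order(self) -> list[str]:
        """Parents before children; raises on cycles naming one cycle edge."""
        graph = self.to_networkx()
        try:
            return list(nx.topological_sort(graph))
        except nx.NetworkXUnfeasible:
            cycle = nx.find_cycle(graph)
            u, v = cycle[0][0], cycle[0][1]
            raise ValueError(f"ontology contains a cycle through edge {u} -> {v}")

    def to_networkx(self) -> nx.DiGraph:
        """Directed graph with parent -> child edges."""
        graph = nx.DiGraph()
        graph.add_nodes_from(self.parents)
        for child, parent_set in self.parents.items():
            for parent in parent_set:
                graph.add_edge(parent, child)
        return graph

    def ancestors(self, term: str) -> set[str]:
        seen: set[str] = set()
        stack = list(self.parents.get(term, ()))
        while stack:
            cur = stack.pop()
            if cur not in seen:
                seen.add(cur)
                stack.extend(self.parents.get(cur, ()))
        return seen


@dataclass(frozen=True)
class EnrichmentResult:
    term: str
    name: str
    n_f: int  # significant genes in the term
    n: int  # universe genes in the term
    N_f: int  # total significant genes
    N: int  # universe size
    re: float  # enrichment ratio, NaN when undefined
    fisher_p: float
    chisq_p: float
    fdr: float
    genes: tuple[str, ...]  # significant genes in the term, sorted


def propagate_annotations(dag: OntologyDag) -> OntologyDag:
    """Close annotations under the true-path rule.

    Each term's gene set becomes the union of its direct set and every
    descendant's direct set, with set semantics (a gene reachable through
    two paths is counted once).
    """
    order = dag.topological_order()  # raises on cycles
    closed: dict[str, set[str]] = {
        t: set(dag.annotations.get(t, set())) for t in dag.parents
    }
    children = dag.children_map()
    for term in reversed(order):  # children before parents
        for child in children.get(term, ()):
            closed[term] |= closed[child]
    return OntologyDag(
        parents={t: set(ps) for t, ps in dag.parents.items()},
        names=dict(dag.names),
        annotations=closed,
    )


def enrichment_ratio(n_f: int, n: int, N_f: int, N: int) -> float:
    """``(n_f/n) / (N_f/N)``; NaN when ``n`` or ``N_f`` is zero."""
    if N <= 0:
        raise ValueError("universe size N must be positive")
    if n == 0 or N_f == 0:
        return float("nan")
    return (n_f / n) / (N_f / N)


def chi_square_2x2(table: Sequence[Sequence[int]]) -> float:
    """Upper-tail p of the Pearson chi-square statistic, df=1, no continuity
    correction. A zero row/column marginal yields ``p = 1`` with a warning."""
    obs = np.asarray(table, dtype=float)
    if obs.shape != (2, 2) or (obs < 0).any():
        raise ValueError("expected a non-negative 2x2 table")
    if (obs.sum(axis=0) == 0).any() or (obs.sum(axis=1) == 0).any():
        warnings.warn("zero marginal in 2x2 table; chi-square p set to 1")
        return 1.0
    statistic, p, _, _ = stats.chi2_contingency(obs, correction=False)
    return float(p)


def _fisher_one_sided(n_f: int, n: int, N_f: int, N: int) -> float:
    """Over-representation tail ``P(X >= n_f)`` for X ~ Hypergeom(N, N_f, n)."""
    return float(stats.hypergeom.sf(n_f - 1, N, N_f, n))


def fisher_enrichment(
    deg_set: Iterable[str],
    universe: Iterable[str],
    term_sets: Mapping[str, Iterable[str]],
    term_names: Mapping[str, str] | None = None,
    alternative: str = "greater",
) -> list[EnrichmentResult]:
    """Per-term over-representation of ``deg_set`` within ``universe``.

    The 2x2 table for each term is ``[[n_f, n - n_f], [N_f - n_f,
    N - n - N_f + n_f]]``. Fisher is one-sided (over-representation) by
    default; ``alternative="two-sided"`` switches to the exact two-sided
    test. BH-FDR is computed across all tested terms on the Fisher p.
    """
    universe = set(universe)
    deg_set = set(deg_set)
    if not deg_set <= universe:
        raise ValueError("deg_set must be a subset of the universe")
    N = len(universe)
    N_f = len(deg_set)
    if N_f == 0:
        warnings.warn("empty significant-gene set: all Fisher p = 1, Re undefined")
    names = term_names or {}

    rows: list[tuple] = []
    for term in term_sets:
        members = set(term_sets[term]) & universe
        n = len(members)
        hits = sorted(members & deg_set)
        n_f = len(hits)
        if N_f == 0:
            fisher_p = 1.0
        elif alternative == "greater":
            fisher_p = _fisher_one_sided(n_f, n, N_f, N)
        else:
            table = [[n_f, n - n_f], [N_f - n_f, N - n - N_f + n_f]]
            fisher_p = float(stats.fisher_exact(table, alternative="two-sided")[1])
        chisq_p = chi_square_2x2(
            [[n_f, n - n_f], [N_f - n_f, N - n - N_f + n_f]]
        )
        re = enrichment_ratio(n_f, n, N_f, N)
        rows.append((term, n_f, n, fisher_p, chisq_p, re, tuple(hits)))

    fdrs = bh_fdr([r[3] for r in rows])
    return [
        EnrichmentResult(
            term=term,
            name=names.get(term, term),
            n_f=n_f,
            n=n,
            N_f=N_f,
            N=N,
            re=re,
            fisher_p=fisher_p,
            chisq_p=chisq_p,
            fdr=float(q),
            genes=hits,
        )
        for (term, n_f, n, fisher_p, chisq_p, re, hits), q in zip(rows, fdrs)
    ]


def filter_enriched(
    results: Iterable[EnrichmentResult],
    p_max: float = 0.05,
    fdr_max: float = 0.05,
) -> list[EnrichmentResult]:
    """Keep terms with ``fisher_p < p_max`` and ``fdr < fdr_max``, sorted
    ascending by Fisher p (ties by term id)."""
    kept = [r for r in results if r.fisher_p < p_max and r.fdr < fdr_max]
    return sorted(kept, key=lambda r: (r.fisher_p, r.term))


def build_go_tree(
    enriched_terms: Iterable[str],
    dag: OntologyDag,
    deg_records: Iterable[DegRecord],
    majority_rule: bool = False,
) -> nx.DiGraph:
    """Induced ancestor-closed subgraph over enriched terms with regulation labels.

    Nodes are the enriched terms plus all of their ancestors; edges follow
    the parent -> child direction of the ontology. Each node carries a
    ``regulation`` attribute: ``up`` if every DEG annotated to the term
    (after closure) is up-regulated, ``down`` if every one is
    down-regulated, else ``ambiguous``. With ``majority_rule=True`` the
    label follows the strict majority instead, falling back to
    ``ambiguous`` on ties. Terms with no annotated DEG are ``ambiguous``.
    """
    enriched = list(enriched_terms)
    missing = [t for t in enriched if t not in dag.parents]
    if missing:
        raise KeyError(f"term(s) absent from ontology: {missing}")
    closed = propagate_annotations(dag)

    calls = {r.gene: r.call for r in deg_records if r.call in ("up", "down")}
    keep: set[str] = set(enriched)
    for term in enriched:
        keep |= dag.ancestors(term)

    tree = nx.DiGraph()
    for term in sorted(keep):
        members = closed.annotations.get(term, set())
        n_up = sum(1 for g in members if calls.get(g) == "up")
        n_down = sum(1 for g in members if calls.get(g) == "down")
        if majority_rule:
            if n_up > n_down:
                label = "up"
            elif n_down > n_up:
                label = "down"
            else:
                label = "ambiguous"
        else:
            if n_up and not n_down:
                label = "up"
            elif n_down and not n_up:
                label = "down"
            else:
                label = "ambiguous"
        tree.add_node(
            term,
            regulation=label,
            name=dag.names.get(term, term),
            enriched=term in set(enriched),
        )
    for child in sorted(keep):
        for parent in dag.parents.get(child, ()):
            if parent in keep:
                tree.add_edge(parent, child)
    return tree


def enrichment_frame(results: Iterable[EnrichmentResult]) -> pd.DataFrame:
    """Tabular enrichment report; ``significant_nf`` always equals the
    length of the semicolon-joined gene list."""
    rows = []
    for r in results:
        rows.append(
            (
                r.term,
                r.name,
                r.n,
                len(r.genes),
                r.re,
                r.fisher_p,
                r.chisq_p,
                r.fdr,
                ";".join(r.genes),
            )
        )
    return pd.DataFrame(
        rows,
        columns=[
            "term_id",
            "term_name",
            "total_n",
            "significant_nf",
            "Re",
            "fisher_p",
            "chisq_p",
            "fdr",
            "genes",
        ],
    )
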