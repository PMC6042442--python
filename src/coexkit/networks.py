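"""Gene-act, pathway-act and per-condition co-expression networks.

Co-expression networks link gene pairs whose Pearson correlation across the
samples of one condition passes both an absolute-correlation and a
significance threshold. "Key regulatory" genes are ranked by the degree and
core-number differences between the treated and control networks.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "EdgeRule",
    "ConditionNetwork",
    "DiffTopologyRecord",
    "correlation_with_pvalue",
    "build_coexpression_network",
    "node_degree",
    "core_number",
    "differential_topology",
    "rank_topology_differences",
    "gene_act_network",
    "pathway_act_network",
    "topology_frame",
]


@dataclass(frozen=True)
class EdgeRule:
    """Edge selection rule: keep (g, h) iff |r| >= min_abs_r and p < alpha."""

    min_abs_r: float = 0.8
    alpha: float = 0.05


@dataclass
class ConditionNetwork:
    """Undirected co-expression graph for one condition.

    Edges carry the Pearson ``r`` (signed) as the ``r`` attribute; topology
    metrics ignore the sign. The selection rule is recorded in ``rule``.
    """

    condition: str
    graph: nx.Graph
    rule: EdgeRule = field(default_factory=EdgeRule)
    n_samples: int = 0


@dataclass(frozen=True)
class DiffTopologyRecord:
    gene: str
    degree_control: int
    degree_treated: int
    kcore_control: int
    kcore_treated: int
    rank: int

    @property
    def dif_degree(self) -> int:
        return self.degree_treated - self.degree_control

    @property
    def dif_kcore(self) -> int:
        return self.kcore_treated - self.kcore_control


def correlation_with_pvalue(x, y) -> tuple[float, float]:
    """Pearson r and its two-sided p-value.

    The p-value comes from ``t = r * sqrt((n-2) / (1-r^2))`` on ``n - 2``
    degrees of freedom; ``r = +/-1`` maps to ``p = 0``. Zero variance in
    either vector makes the correlation undefined: ``(nan, nan)``.
    """
    from scipy import stats

    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 3:
        raise ValueError("x and y must be equal-length 1-D vectors of length >= 3")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("inputs must be finite")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return (float("nan"), float("nan"))
    n = x.size
    r = float(np.corrcoef(x, y)[0, 1])
    r = max(-1.0, min(1.0, r))
    if abs(r) == 1.0:
        return (r, 0.0)
    t = r * np.sqrt((n - 2) / (1.0 - r * r))
    p = 2.0 * float(stats.t.sf(abs(t), df=n - 2))
    return (r, min(p, 1.0))


def build_coexpression_network(
    expr: pd.DataFrame,
    condition: str,
    rule: EdgeRule = EdgeRule(),
) -> ConditionNetwork:
    """Build the co-expression graph for one condition.

    Parameters
    ----------
    expr:
        Genes-by-samples expression matrix restricted to the samples of
        ``condition`` (typically RPKM restricted to the DEGs).
    condition:
        Label recorded on the network.
    rule:
        Edge selection thresholds.

    Every gene is a node; constant genes stay isolated. Pearson p-values
    have little power below ~5 samples, so a warning (not an error) is
    emitted for small designs.
    """
    from scipy import stats

    n_samples = expr.shape[1]
    if n_samples < 3:
        raise ValueError(
            f"need >=3 samples to correlate, condition {condition!r} has {n_samples}"
        )
    if n_samples < 5:
        warnings.warn(
            f"condition {condition!r} has only {n_samples} samples; "
            "correlation p-values are nearly powerless"
        )

    genes = list(expr.index)
    graph = nx.Graph()
    graph.add_nodes_from(genes)

    values = expr.to_numpy(dtype=float)
    sd = values.std(axis=1)
    ok = sd > 0
    idx = np.flatnonzero(ok)
    if idx.size >= 2:
        with np.errstate(invalid="ignore"):
            corr = np.corrcoef(values[idx])
        corr = np.clip(corr, -1.0, 1.0)
        n = n_samples
        with np.errstate(divide="ignore", invalid="ignore"):
            t = corr * np.sqrt((n - 2) / (1.0 - corr * corr))
        pmat = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
        pmat[np.abs(corr) == 1.0] = 0.0
        for a in range(idx.size):
            for b in range(a + 1, idx.size):
                r = float(corr[a, b])
                p = float(pmat[a, b])
                if abs(r) >= rule.min_abs_r and p < rule.alpha:
                    graph.add_edge(genes[idx[a]], genes[idx[b]], r=r)
    return ConditionNetwork(
        condition=condition, graph=graph, rule=rule, n_samples=n_samples
    )


def node_degree(net: ConditionNetwork | nx.Graph) -> dict[str, int]:
    graph = net.graph if isinstance(net, ConditionNetwork) else net
    return {node: int(d) for node, d in graph.degree()}


def core_number(net: ConditionNetwork | nx.Graph) -> dict[str, int]:
    """Core number of every node by iterative minimum-degree peeling.

    The core number of ``v`` is the largest ``k`` such that ``v`` belongs
    to a subgraph of minimum degree >= k. Peeling removes a minimum-degree
    node at each step; the core number is the running maximum of the
    minimum degree seen when the node is removed.
    """
    graph = net.graph if isinstance(net, ConditionNetwork) else net
    if any(u == v for u, v in graph.edges()):
        raise ValueError("core_number requires a simple graph (no self-loops)")
    degrees = {v: int(d) for v, d in graph.degree()}
    adjacency = {v: set(graph.neighbors(v)) for v in graph.nodes()}
    core: dict[str, int] = {}
    current_k = 0
    remaining = set(degrees)
    while remaining:
        v = min(remaining, key=lambda u: (degrees[u], str(u)))
        current_k = max(current_k, degrees[v])
        core[v] = current_k
        remaining.remove(v)
        for u in adjacency[v]:
            if u in remaining:
                degrees[u] -= 1
        for u in adjacency[v]:
            adjacency[u].discard(v)
    return core


def rank_topology_differences(
    control_stats: Mapping[str, tuple[int, int]],
    treated_stats: Mapping[str, tuple[int, int]],
) -> list[DiffTopologyRecord]:
    """Build ranked records from per-condition ``gene -> (degree, kcore)`` maps.

    Genes missing from one condition contribute degree 0 and core 0 there.
    Ranking: |dif_degree| descending, ties by |dif_kcore| descending, then
    gene id; ranks start at 1.
    """
    genes = sorted(set(control_stats) | set(treated_stats))
    rows = []
    for gene in genes:
        dc, kc = control_stats.get(gene, (0, 0))
        dt, kt = treated_stats.get(gene, (0, 0))
        rows.append((gene, int(dc), int(dt), int(kc), int(kt)))
    rows.sort(key=lambda r: (-abs(r[2] - r[1]), -abs(r[4] - r[3]), r[0]))
    return [
        DiffTopologyRecord(
            gene=gene,
            degree_control=dc,
            degree_treated=dt,
            kcore_control=kc,
            kcore_treated=kt,
            rank=i + 1,
        )
        for i, (gene, dc, dt, kc, kt) in enumerate(rows)
    ]


def differential_topology(
    net_control: ConditionNetwork,
    net_treated: ConditionNetwork,
) -> list[DiffTopologyRecord]:
    """Ranked degree/core differences between the two condition networks."""
    deg_c = node_degree(net_control)
    deg_t = node_degree(net_treated)
    core_c = core_number(net_control)
    core_t = core_number(net_treated)
    control_stats = {g: (deg_c[g], core_c[g]) for g in deg_c}
    treated_stats = {g: (deg_t[g], core_t[g]) for g in deg_t}
    return rank_topology_differences(control_stats, treated_stats)


def gene_act_network(
    deg_list: Iterable[str],
    relations: nx.Graph,
) -> tuple[nx.Graph, list[set[str]]]:
    """Induced subgraph of the background relation graph on the DEGs.

    Returns the subgraph and its connected components of size >= 2,
    largest first (ties by sorted member list for determinism).
    """
    degs = set(deg_list)
    sub = nx.Graph()
    sub.add_nodes_from(sorted(degs))
    for u, v in relations.edges():
        if u in degs and v in degs and u != v:
            sub.add_edge(u, v)
    modules = [set(c) for c in nx.connected_components(sub) if len(c) >= 2]
    modules.sort(key=lambda c: (-len(c), sorted(c)))
    return sub, modules


def pathway_act_network(
    enriched_pathways: Iterable[str],
    pathway_sets: Mapping[str, Iterable[str]],
    min_shared: int = 1,
) -> tuple[nx.Graph, list[tuple[str, int]]]:
    """Pathway graph linking pathways that share >= ``min_shared`` genes.

    Returns the graph (edges annotated with ``shared``) and the hub ranking:
    pathways sorted by degree descending, ties by id.
    """
    pathways = list(dict.fromkeys(enriched_pathways))
    missing = [p for p in pathways if p not in pathway_sets]
    if missing:
        raise KeyError(f"enriched pathway(s) without gene sets: {missing}")
    sets = {p: set(pathway_sets[p]) for p in pathways}
    graph = nx.Graph()
    graph.add_nodes_from(pathways)
    for i, p in enumerate(pathways):
        for q in pathways[i + 1 :]:
            shared = len(sets[p] & sets[q])
            if shared >= min_shared:
                graph.add_edge(p, q, shared=shared)
    hubs = sorted(graph.degree(), key=lambda kv: (-kv[1], kv[0]))
    return graph, [(p, int(d)) for p, d in hubs]


def topology_frame(records: Iterable[DiffTopologyRecord]) -> pd.DataFrame:
    rows = [
        (
            r.gene,
            r.degree_control,
            r.degree_treated,
            r.kcore_control,
            r.kcore_treated,
            r.dif_degree,
            r.dif_kcore,
            r.rank,
        )
        for r in records
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "gene",
            "degree_control",
            "degree_treated",
            "kcore_control",
            "kcore_treated",
            "dif_degree",
            "dif_kcore",
            "rank",
        ],
    )
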