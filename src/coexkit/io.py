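"""Readers and writers for the plain-text interchange formats.

Formats: counts/design TSV, GMT gene sets, OBO-lite TSV ontology edges,
SIF relation graphs, Ct TSV, dose-response TSV, GraphML (via networkx),
and JSON ground truth. All writers go through an atomic replace so a
crashed run never leaves a truncated artifact behind.
"""

from __future__ import annotations

import json
import os
import tempfile
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx
import pandas as pd

from .assays import CtTable
from .deg import CountMatrix
from .enrich import OntologyDag
from .simulate import GroundTruth

__all__ = [
    "atomic_write_text",
    "write_counts",
    "read_counts",
    "write_gmt",
    "read_gmt",
    "write_obo_lite",
    "read_obo_lite",
    "write_sif",
    "read_sif",
    "write_ct_table",
    "read_ct_table",
    "write_dose_response",
    "read_dose_response",
    "write_graphml",
    "write_ground_truth",
    "read_ground_truth",
    "write_tsv",
]


def atomic_write_text(path: str | Path, text: str) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fd, tmp = tempfile.mkstemp(dir=path.parent, prefix=f".{path.name}.")
    try:
        with os.fdopen(fd, "w") as handle:
            handle.write(text)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


def write_tsv(df: pd.DataFrame, path: str | Path, index: bool = False) -> None:
    atomic_write_text(path, df.to_csv(sep="\t", index=index))


def write_counts(matrix: CountMatrix, counts_path, design_path) -> None:
    """Counts TSV (gene_id, length_bp, one column per sample) + design TSV."""
    table = matrix.counts.copy()
    table.insert(0, "length_bp", matrix.lengths)
    table.insert(0, "gene_id", matrix.counts.index)
    write_tsv(table, counts_path)
    design = pd.DataFrame(
        {"sample_id": matrix.design.index, "condition": matrix.design.values}
    )
    design = design[design["sample_id"].isin(matrix.counts.columns)]
    write_tsv(design, design_path)


def read_counts(counts_path, design_path) -> CountMatrix:
    table = pd.read_csv(counts_path, sep="\t")
    for col in ("gene_id", "length_bp"):
        if col not in table.columns:
            raise ValueError(f"{counts_path}: missing required column {col!r}")
    table = table.set_index("gene_id")
    lengths = table.pop("length_bp").astype(int)
    design_df = pd.read_csv(design_path, sep="\t")
    if not {"sample_id", "condition"} <= set(design_df.columns):
        raise ValueError(f"{design_path}: need columns sample_id, condition")
    design = pd.Series(
        design_df["condition"].values, index=design_df["sample_id"].values
    )
    return CountMatrix(counts=table.astype(int), lengths=lengths, design=design)


def write_gmt(
    term_sets: Mapping[str, Iterable[str]],
    path,
    names: Mapping[str, str] | None = None,
) -> None:
    names = names or {}
    lines = []
    for term in term_sets:
        members = sorted(set(term_sets[term]))
        lines.append("\t".join([term, names.get(term, term)] + members))
    atomic_write_text(path, "\n".join(lines) + "\n")


def read_gmt(path) -> tuple[dict[str, set[str]], dict[str, str]]:
    """Returns ``(term -> gene set, term -> name)``."""
    sets: dict[str, set[str]] = {}
    names: dict[str, str] = {}
    with open(path) as handle:
        for lineno, raw in enumerate(handle, 1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise ValueError(f"{path}:{lineno}: GMT line needs id and name")
            term, name = fields[0], fields[1]
            sets[term] = {g for g in fields[2:] if g}
            names[term] = name
    return sets, names


def write_obo_lite(dag: OntologyDag, path) -> None:
    """One row per child->parent edge; roots get an empty parent field."""
    lines = ["child_id\tparent_id\tterm_name"]
    for term in dag.parents:
        parent_set = sorted(dag.parents[term])
        name = dag.names.get(term, term)
        if not parent_set:
            lines.append(f"{term}\t\t{name}")
        for parent in parent_set:
            lines.append(f"{term}\t{parent}\t{name}")
    atomic_write_text(path, "\n".join(lines) + "\n")


def read_obo_lite(path, annotations: Mapping[str, Iterable[str]] | None = None) -> OntologyDag:
    table = pd.read_csv(path, sep="\t", keep_default_na=False)
    if not {"child_id", "parent_id", "term_name"} <= set(table.columns):
        raise ValueError(f"{path}: need columns child_id, parent_id, term_name")
    parents: dict[str, set[str]] = {}
    names: dict[str, str] = {}
    for row in table.itertuples(index=False):
        child = str(row.child_id)
        parents.setdefault(child, set())
        names[child] = str(row.term_name)
        parent = str(row.parent_id)
        if parent:
            parents[child].add(parent)
            parents.setdefault(parent, set())
    anno = {t: set(annotations.get(t, ())) for t in parents} if annotations else {}
    return OntologyDag(parents=parents, names=names, annotations=anno)


def write_sif(graph: nx.Graph, path, relation: str = "pp") -> None:
    lines = []
    isolated = [n for n in graph.nodes() if graph.degree(n) == 0]
    for u, v in sorted((sorted((str(a), str(b))) for a, b in graph.edges())):
        lines.append(f"{u}\t{relation}\t{v}")
    for node in sorted(str(n) for n in isolated):
        lines.append(str(node))
    atomic_write_text(path, "\n".join(lines) + "\n")


def read_sif(path) -> nx.Graph:
    graph = nx.Graph()
    with open(path) as handle:
        for lineno, raw in enumerate(handle, 1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) == 1:
                graph.add_node(fields[0])
            elif len(fields) >= 3:
                source = fields[0]
                for target in fields[2:]:
                    if source != target:
                        graph.add_edge(source, target)
            else:
                raise ValueError(f"{path}:{lineno}: malformed SIF line")
    return graph


def write_ct_table(ct: CtTable, path) -> None:
    header = (
        f"# reference={ct.reference}\tcontrol_condition={ct.control_condition}\n"
    )
    atomic_write_text(path, header + ct.data.to_csv(sep="\t", index=False))


def read_ct_table(path) -> CtTable:
    with open(path) as handle:
        first = handle.readline()
    if not first.startswith("# reference="):
        raise ValueError(f"{path}:1: missing '# reference=...' header line")
    meta = dict(
        item.split("=", 1) for item in first[2:].strip().split("\t") if "=" in item
    )
    data = pd.read_csv(path, sep="\t", comment="#")
    return CtTable(
        data=data,
        reference=meta["reference"],
        control_condition=meta["control_condition"],
    )


def write_dose_response(table: pd.DataFrame, path) -> None:
    write_tsv(table[["dose", "response"]], path)


def read_dose_response(path) -> pd.DataFrame:
    table = pd.read_csv(path, sep="\t")
    if not {"dose", "response"} <= set(table.columns):
        raise ValueError(f"{path}: need columns dose, response")
    return table


def write_graphml(graph: nx.Graph, path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fd, tmp = tempfile.mkstemp(dir=path.parent, prefix=f".{path.name}.")
    os.close(fd)
    try:
        nx.write_graphml(graph, tmp)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


def write_ground_truth(truth: GroundTruth, path) -> None:
    payload = {
        "de_genes_up": sorted(truth.de_genes_up),
        "de_genes_down": sorted(truth.de_genes_down),
        "modules": [
            {"members": sorted(members), "active_condition": cond}
            for members, cond in truth.module_members
        ],
        "true_lfc": {g: truth.true_lfc[g] for g in sorted(truth.true_lfc)},
    }
    atomic_write_text(path, json.dumps(payload, indent=2) + "\n")


def read_ground_truth(path) -> GroundTruth:
    with open(path) as handle:
        payload = json.load(handle)
    return GroundTruth(
        de_genes_up=frozenset(payload["de_genes_up"]),
        de_genes_down=frozenset(payload["de_genes_down"]),
        module_members=tuple(
            (frozenset(m["members"]), m["active_condition"])
            for m in payload["modules"]
        ),
        true_lfc={g: float(v) for g, v in payload["true_lfc"].items()},
    )
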