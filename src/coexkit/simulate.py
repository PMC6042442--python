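"""Seeded synthetic inputs for every stage of the pipeline.

The generator emulates the statistical structure the analysis assumes: a
two-condition negative-binomial count matrix with a minority of planted
differentially expressed genes, gene modules whose co-expression exists
only in one condition, a rooted annotation DAG, a background relation
graph, a qPCR Ct table consistent with the planted log2 fold changes, and
a four-parameter-logistic dose-response table.

Negative-binomial counts use the mean/dispersion parameterization
``var = mu + phi * mu**2``. Determinism: a single seed drives everything;
per-gene sub-streams are spawned from it so a change in one gene's
parameters does not perturb the counts of another.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .assays import CtTable, four_pl
from .deg import CountMatrix
from .enrich import OntologyDag

__all__ = [
    "SimulationParams",
    "GroundTruth",
    "generate_counts",
    "generate_ontology",
    "generate_relation_graph",
    "generate_qpcr",
    "generate_dose_response",
    "CONTROL",
    "TREATED",
    "GENE_LENGTH_RANGE",
    "MODULE_FACTOR_LOADING",
]

CONTROL = "control"
TREATED = "treated"

#: gene lengths are drawn uniform on this closed range (bp)
GENE_LENGTH_RANGE = (500, 5000)

#: loading of the shared standard-normal latent factor on the log2 scale
MODULE_FACTOR_LOADING = 0.9


@dataclass(frozen=True)
class SimulationParams:
    n_genes: int = 2000
    n_per_group: int = 3
    baseline_mean: float = 100.0
    dispersion: float = 0.1  # phi in var = mu + phi * mu^2
    frac_up: float = 0.02
    frac_down: float = 0.04
    lfc_magnitude: float = 1.5  # |log2 fold change| planted on DE genes
    module_sizes: tuple[int, ...] = ()
    module_condition: tuple[str, ...] = ()
    #: where module members come from: "background" picks non-DE genes,
    #: "up" carves them out of the up-regulated block so that planted
    #: modules are themselves DEGs (condition-specific connectivity among
    #: screened genes)
    modules_from: str = "background"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes <= 0:
            raise ValueError("n_genes: must be a positive count")
        if self.n_per_group < 3:
            raise ValueError("n_per_group: need at least 3 replicates per condition")
        if self.baseline_mean <= 0:
            raise ValueError("baseline_mean: must be positive")
        if self.dispersion < 0:
            raise ValueError("dispersion: must be >= 0")
        for name in ("frac_up", "frac_down"):
            value = getattr(self, name)
            if not 0 <= value < 1:
                raise ValueError(f"{name}: must lie in [0, 1)")
        if self.frac_up + self.frac_down >= 1:
            raise ValueError("frac_up, frac_down: fractions must sum to < 1")
        if self.lfc_magnitude <= 0.585:
            raise ValueError(
                "lfc_magnitude: must exceed 0.585 (log2 of the 1.5x threshold)"
            )
        if len(self.module_sizes) != len(self.module_condition):
            raise ValueError("module_sizes: one active condition per module required")
        for size in self.module_sizes:
            if not 3 <= size <= self.n_genes:
                raise ValueError(f"module_sizes: size {size} outside [3, n_genes]")
        for cond in self.module_condition:
            if cond not in (CONTROL, TREATED):
                raise ValueError(
                    f"module_condition: {cond!r} is not {CONTROL!r}/{TREATED!r}"
                )
        if sum(self.module_sizes) > self.n_genes:
            raise ValueError("module_sizes: modules exceed the gene universe")
        if self.modules_from not in ("background", "up"):
            raise ValueError('modules_from: must be "background" or "up"')


@dataclass(frozen=True)
class GroundTruth:
    """What was planted: DE gene sets, module membership, true log2 fold changes."""

    de_genes_up: frozenset[str]
    de_genes_down: frozenset[str]
    module_members: tuple[tuple[frozenset[str], str], ...]
    true_lfc: Mapping[str, float]

    def __post_init__(self) -> None:
        if self.de_genes_up & self.de_genes_down:
            raise ValueError("up and down DE sets must be disjoint")


def _gene_ids(n: int) -> list[str]:
    width = max(4, len(str(n)))
    return [f"G{i:0{width}d}" for i in range(1, n + 1)]


def generate_counts(params: SimulationParams) -> tuple[CountMatrix, GroundTruth]:
    """Draw a two-condition NB count matrix with planted DE genes and modules.

    Planted up/down genes have their treated-group mean multiplied by
    ``2 ** (+/- lfc_magnitude)``. Genes inside a planted module share a
    per-sample standard-normal latent factor (loading 0.9) added to their
    log2 mean only in the module's active condition, which induces high
    pairwise correlation there and ~0 elsewhere. ``dispersion == 0``
    degenerates to Poisson sampling.
    """
    genes = _gene_ids(params.n_genes)
    samples = [f"{CONTROL}_{i + 1}" for i in range(params.n_per_group)] + [
        f"{TREATED}_{i + 1}" for i in range(params.n_per_group)
    ]
    design = pd.Series(
        [CONTROL] * params.n_per_group + [TREATED] * params.n_per_group,
        index=samples,
        name="condition",
    )

    n_up = int(round(params.frac_up * params.n_genes))
    n_down = int(round(params.frac_down * params.n_genes))
    up_genes = genes[:n_up]
    down_genes = genes[n_up : n_up + n_down]
    true_lfc = {g: 0.0 for g in genes}
    for g in up_genes:
        true_lfc[g] = params.lfc_magnitude
    for g in down_genes:
        true_lfc[g] = -params.lfc_magnitude

    # modules claim a contiguous block of genes: from the non-DE tail by
    # default (module membership independent of DE status), or from the
    # up-regulated block so modules are DEGs themselves
    modules: list[tuple[frozenset[str], str]] = []
    cursor = n_up + n_down if params.modules_from == "background" else 0
    limit = params.n_genes if params.modules_from == "background" else n_up
    for size, cond in zip(params.module_sizes, params.module_condition):
        if cursor + size > limit:
            raise ValueError(
                f"module_sizes: not enough {params.modules_from} genes for all modules"
            )
        modules.append((frozenset(genes[cursor : cursor + size]), cond))
        cursor += size

    root = np.random.SeedSequence(params.seed)
    length_seq, factor_seq, *gene_seqs = root.spawn(params.n_genes + 2)

    lengths = pd.Series(
        np.random.default_rng(length_seq).integers(
            GENE_LENGTH_RANGE[0], GENE_LENGTH_RANGE[1] + 1, size=params.n_genes
        ),
        index=genes,
        name="length_bp",
    )

    # one latent factor value per module per sample (shared by module members)
    factor_rng = np.random.default_rng(factor_seq)
    factors = factor_rng.standard_normal((len(modules), len(samples)))
    module_of = {}
    for m, (members, cond) in enumerate(modules):
        for g in members:
            module_of[g] = (m, cond)

    counts = np.zeros((params.n_genes, len(samples)), dtype=np.int64)
    treated_mask = np.array([design[s] == TREATED for s in samples])
    for i, gene in enumerate(genes):
        rng = np.random.default_rng(gene_seqs[i])
        log2_mu = np.full(len(samples), np.log2(params.baseline_mean))
        log2_mu[treated_mask] += true_lfc[gene]
        if gene in module_of:
            m, cond = module_of[gene]
            active = treated_mask if cond == TREATED else ~treated_mask
            log2_mu[active] += MODULE_FACTOR_LOADING * factors[m, active]
        mu = np.exp2(log2_mu)
        if params.dispersion == 0:
            counts[i] = rng.poisson(mu)
        else:
            n_param = 1.0 / params.dispersion
            p_param = n_param / (n_param + mu)
            counts[i] = rng.negative_binomial(n_param, p_param)

    matrix = CountMatrix(
        counts=pd.DataFrame(counts, index=pd.Index(genes, name="gene_id"), columns=samples),
        lengths=lengths,
        design=design,
    )
    truth = GroundTruth(
        de_genes_up=frozenset(up_genes),
        de_genes_down=frozenset(down_genes),
        module_members=tuple(modules),
        true_lfc=true_lfc,
    )
    return matrix, truth


def generate_ontology(
    n_terms: int,
    max_parents: int,
    annotation_rate: float,
    seed: int,
    gene_universe: Sequence[str] | None = None,
) -> tuple[OntologyDag, dict[str, set[str]]]:
    """Random rooted DAG with direct annotations on its leaf terms.

    Term ``T0001`` is the single root; every later term draws 1 to
    ``max_parents`` parents among the earlier terms, which guarantees
    acyclicity and a single root. Each gene of the universe is attached to
    each leaf independently with probability ``annotation_rate``; the
    returned annotation sets are *direct* (not ancestor-closed).
    """
    if n_terms < 2:
        raise ValueError("n_terms must be >= 2")
    if max_parents < 1:
        raise ValueError("max_parents must be >= 1")
    if not 0 < annotation_rate <= 1:
        raise ValueError("annotation_rate must lie in (0, 1]")
    if gene_universe is None:
        gene_universe = _gene_ids(100)
    genes = list(gene_universe)

    rng = np.random.default_rng(np.random.SeedSequence(seed))
    width = max(4, len(str(n_terms)))
    terms = [f"T{i:0{width}d}" for i in range(1, n_terms + 1)]
    parents: dict[str, set[str]] = {terms[0]: set()}
    for i in range(1, n_terms):
        k = int(rng.integers(1, min(max_parents, i) + 1))
        chosen = rng.choice(i, size=k, replace=False)
        parents[terms[i]] = {terms[j] for j in chosen}

    has_children = {p for ps in parents.values() for p in ps}
    leaves = [t for t in terms if t not in has_children]
    annotations: dict[str, set[str]] = {t: set() for t in terms}
    for leaf in leaves:
        mask = rng.random(len(genes)) < annotation_rate
        annotations[leaf] = {g for g, hit in zip(genes, mask) if hit}

    names = {t: f"synthetic term {t}" for t in terms}
    dag = OntologyDag(parents=parents, names=names, annotations=annotations)
    return dag, {t: set(s) for t, s in annotations.items()}


def generate_relation_graph(
    gene_universe: Sequence[str],
    edge_density: float,
    seed: int,
) -> nx.Graph:
    """Erdos-Renyi G(n, p) background relation graph over the gene universe."""
    if not 0 < edge_density < 1:
        raise ValueError("edge_density must lie in (0, 1)")
    genes = list(gene_universe)
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    graph = nx.Graph()
    graph.add_nodes_from(genes)
    n = len(genes)
    for i in range(n):
        hits = rng.random(n - i - 1) < edge_density
        for offset in np.flatnonzero(hits):
            graph.add_edge(genes[i], genes[i + 1 + int(offset)])
    return graph


def generate_qpcr(
    truth: GroundTruth,
    ref_gene: str = "REFG",
    ct_noise_sd: float = 0.0,
    seed: int = 0,
    genes: Sequence[str] | None = None,
    n_replicates: int = 3,
    base_ct: float = 25.0,
    ref_ct: float = 20.0,
) -> CtTable:
    """Ct table whose expected delta-delta-Ct equals minus the planted log2FC.

    The treated-condition Ct of gene ``g`` is shifted by ``-true_lfc(g)``
    cycles relative to control (more template, earlier threshold), so
    ``E[ddCt] = -true_lfc(g)`` and ``2**-ddCt`` recovers the planted fold
    change. The reference gene must not be a planted DE gene.
    """
    if ref_gene in truth.de_genes_up or ref_gene in truth.de_genes_down:
        raise ValueError(f"ref_gene: {ref_gene!r} is a planted DE gene")
    if genes is None:
        genes = sorted(truth.de_genes_up | truth.de_genes_down)
    rng = np.random.default_rng(np.random.SeedSequence(seed))

    rows = []
    for cond in (CONTROL, TREATED):
        for rep in range(1, n_replicates + 1):
            sample = f"{cond}_q{rep}"
            for gene in list(genes) + [ref_gene]:
                if gene == ref_gene:
                    ct = ref_ct
                else:
                    ct = base_ct
                    if cond == TREATED:
                        ct -= truth.true_lfc.get(gene, 0.0)
                ct += rng.normal(0.0, ct_noise_sd) if ct_noise_sd > 0 else 0.0
                rows.append((gene, sample, cond, ct))
    data = pd.DataFrame(rows, columns=["gene", "sample", "condition", "ct"])
    return CtTable(data=data, reference=ref_gene, control_condition=CONTROL)


def generate_dose_response(
    top: float,
    bottom: float,
    ic50: float,
    hill: float,
    doses: Sequence[float],
    noise_sd: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Viability table from a 4PL curve plus Gaussian noise.

    Returns a DataFrame with columns ``dose`` and ``response``.
    """
    if top <= bottom:
        raise ValueError("top must exceed bottom")
    if ic50 <= 0:
        raise ValueError("ic50 must be positive")
    doses = np.asarray(list(doses), dtype=float)
    if len(np.unique(doses)) < 4:
        raise ValueError("need at least 4 distinct doses")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    response = four_pl(doses, top, bottom, ic50, hill)
    if noise_sd > 0:
        response = response + rng.normal(0.0, noise_sd, size=doses.shape)
    return pd.DataFrame({"dose": doses, "response": response})
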