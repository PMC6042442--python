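"""End-to-end orchestration: DEG screen -> enrichment -> networks -> assays.

A single flat config drives every stage; stages whose inputs are absent
are skipped and logged. All artifacts are plain text and written
atomically; identical config + seed reproduces identical artifacts.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import sys
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from . import assays as assays_mod
from . import deg as deg_mod
from . import enrich as enrich_mod
from . import io as io_mod
from . import networks as net_mod
from . import simulate as sim_mod

__all__ = ["PipelineConfig", "run_pipeline", "demo", "write_synthetic_bundle"]

logger = logging.getLogger("coexkit")


@dataclass
class PipelineConfig:
    """Flat key-value pipeline configuration.

    Every analysis threshold is a named key with its default from the
    screening/enrichment/network conventions this pipeline implements:
    fold-change cut-offs 1.50 / 0.67 with DEG FDR < 0.05, enrichment
    p < 0.05 and FDR < 0.05, co-expression edges at |r| >= 0.8 and
    p < 0.05.
    """

    counts: str | None = None
    design: str | None = None
    go_gmt: str | None = None
    ontology: str | None = None
    pathway_gmt: str | None = None
    relations: str | None = None
    ct_table: str | None = None
    dose_response: str | None = None
    control_condition: str = sim_mod.CONTROL
    treated_condition: str = sim_mod.TREATED
    fc_up: float = 1.50
    fc_down: float = 0.67
    deg_fdr: float = 0.05
    enrich_p: float = 0.05
    enrich_fdr: float = 0.05
    min_abs_r: float = 0.8
    corr_alpha: float = 0.05
    min_shared: int = 1
    seed: int = 0
    outdir: str = "coexkit_out"
    force: bool = True

    def __post_init__(self) -> None:
        if not (self.fc_up > 1 > self.fc_down > 0):
            raise ValueError("need fc_up > 1 > fc_down > 0")
        for name in ("deg_fdr", "enrich_p", "enrich_fdr", "corr_alpha"):
            value = getattr(self, name)
            if not 0 < value < 1:
                raise ValueError(f"{name} must lie in (0, 1)")

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as handle:
            payload = yaml.safe_load(handle) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(payload) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**payload)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _stage(report: dict, name: str) -> dict:
    entry = {"status": "skipped", "outputs": [], "counts": {}}
    report["stages"][name] = entry
    return entry


def _log_event(events: list[dict], stage: str, message: str) -> None:
    logger.info("[%s] %s", stage, message)
    events.append({"stage": stage, "message": message})


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every stage whose inputs are configured; return the report.

    The report (also written to ``<outdir>/report.json``) carries per-stage
    summary counts, a config echo, the package version and per-stage wall
    time. With ``force=False`` a stage whose artifacts already exist is
    reloaded instead of recomputed.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    events: list[dict] = []
    report: dict = {
        "version": __version__,
        "config": config.to_dict(),
        "stages": {},
    }

    if not config.counts or not config.design:
        raise ValueError("counts and design inputs are required")

    # ---- DEG screening -------------------------------------------------
    stage = _stage(report, "deg")
    t0 = time.perf_counter()
    deg_path = outdir / "degs.tsv"
    matrix = io_mod.read_counts(config.counts, config.design)
    rpkm = deg_mod.compute_rpkm(matrix)
    if not config.force and deg_path.exists():
        deg_table = pd.read_csv(deg_path, sep="\t")
        _log_event(events, "deg", f"reused existing {deg_path}")
    else:
        fc = deg_mod.fold_change(
            rpkm, matrix.design, config.control_condition, config.treated_condition
        )
        pvals = deg_mod.differential_test(
            rpkm, matrix.design, config.control_condition, config.treated_condition
        )
        fdr = deg_mod.bh_fdr(pvals)
        fc["pvalue"] = pvals
        records, summary = deg_mod.screen_degs(
            fc, fdr, config.fc_up, config.fc_down, config.deg_fdr
        )
        deg_table = deg_mod.deg_frame(records)
        io_mod.write_tsv(deg_table, deg_path)
        _log_event(
            events,
            "deg",
            f"{summary.n_up} up, {summary.n_down} down of {len(records)} genes",
        )
    n_up = int((deg_table["call"] == "up").sum())
    n_down = int((deg_table["call"] == "down").sum())
    stage.update(status="complete", outputs=[deg_path.name])
    stage["counts"] = {"n_up": n_up, "n_down": n_down, "n_total": n_up + n_down}
    stage["wall_time_s"] = time.perf_counter() - t0

    deg_genes = list(deg_table.loc[deg_table["call"] != "ns", "gene_id"])
    deg_records = [
        deg_mod.DegRecord(
            gene=str(r.gene_id),
            log2fc=float(r.log2fc),
            fold_change=float(r.fold_change),
            pvalue=float(r.pvalue),
            fdr=float(r.fdr),
            call=str(r.call),
        )
        for r in deg_table.itertuples(index=False)
    ]

    # ---- GO enrichment + GO tree --------------------------------------
    stage = _stage(report, "go_enrichment")
    if config.go_gmt and config.ontology:
        t0 = time.perf_counter()
        sets, names = io_mod.read_gmt(config.go_gmt)
        dag = io_mod.read_obo_lite(config.ontology, annotations=sets)
        closed = enrich_mod.propagate_annotations(dag)
        annotated = set().union(*closed.annotations.values()) if closed.annotations else set()
        universe = annotated & set(matrix.genes)
        results = enrich_mod.fisher_enrichment(
            set(deg_genes) & universe,
            universe,
            {t: s & universe for t, s in closed.annotations.items()},
            term_names=closed.names,
        )
        kept = enrich_mod.filter_enriched(results, config.enrich_p, config.enrich_fdr)
        table = enrich_mod.enrichment_frame(kept)
        go_path = outdir / "go_enrichment.tsv"
        io_mod.write_tsv(table, go_path)
        tree = enrich_mod.build_go_tree([r.term for r in kept], dag, deg_records)
        tree_path = outdir / "go_tree.graphml"
        io_mod.write_graphml(tree, tree_path)
        stage.update(status="complete", outputs=[go_path.name, tree_path.name])
        stage["counts"] = {
            "enriched_terms": len(kept),
            "tree_nodes": tree.number_of_nodes(),
        }
        stage["wall_time_s"] = time.perf_counter() - t0
        _log_event(events, "go_enrichment", f"{len(kept)} enriched terms")
    else:
        _log_event(events, "go_enrichment", "skipped (no GO inputs)")

    # ---- pathway enrichment + pathway act network ----------------------
    stage = _stage(report, "pathways")
    if config.pathway_gmt:
        t0 = time.perf_counter()
        psets, pnames = io_mod.read_gmt(config.pathway_gmt)
        universe = set(matrix.genes)
        results = enrich_mod.fisher_enrichment(
            set(deg_genes) & universe,
            universe,
            {t: set(s) & universe for t, s in psets.items()},
            term_names=pnames,
        )
        kept = enrich_mod.filter_enriched(results, config.enrich_p, config.enrich_fdr)
        table = enrich_mod.enrichment_frame(kept)
        pw_path = outdir / "pathway_enrichment.tsv"
        io_mod.write_tsv(table, pw_path)
        pgraph, hubs = net_mod.pathway_act_network(
            [r.term for r in kept], psets, config.min_shared
        )
        pact_path = outdir / "pathway_act.graphml"
        io_mod.write_graphml(pgraph, pact_path)
        stage.update(status="complete", outputs=[pw_path.name, pact_path.name])
        stage["counts"] = {
            "enriched_pathways": len(kept),
            "act_edges": pgraph.number_of_edges(),
        }
        stage["wall_time_s"] = time.perf_counter() - t0
        _log_event(events, "pathways", f"{len(kept)} enriched pathways")
    else:
        _log_event(events, "pathways", "skipped (no pathway GMT)")

    # ---- networks ------------------------------------------------------
    stage = _stage(report, "networks")
    t0 = time.perf_counter()
    outputs = []
    counts: dict = {}
    if config.relations:
        relations = io_mod.read_sif(config.relations)
        act, modules = net_mod.gene_act_network(deg_genes, relations)
        act_path = outdir / "gene_act.graphml"
        io_mod.write_graphml(act, act_path)
        outputs.append(act_path.name)
        counts["gene_act_modules"] = len(modules)
    if deg_genes:
        rule = net_mod.EdgeRule(min_abs_r=config.min_abs_r, alpha=config.corr_alpha)
        expr = rpkm.values.loc[deg_genes]
        nets = {}
        for cond in (config.control_condition, config.treated_condition):
            samples = [s for s in expr.columns if matrix.design[s] == cond]
            nets[cond] = net_mod.build_coexpression_network(
                expr[samples], cond, rule
            )
            path = outdir / f"coexpression_{cond}.graphml"
            io_mod.write_graphml(nets[cond].graph, path)
            outputs.append(path.name)
        records = net_mod.differential_topology(
            nets[config.control_condition], nets[config.treated_condition]
        )
        topo = net_mod.topology_frame(records)
        topo_path = outdir / "key_genes.tsv"
        io_mod.write_tsv(topo, topo_path)
        outputs.append(topo_path.name)
        counts["key_gene_records"] = len(records)
        counts["top_genes"] = list(topo.head(10)["gene"])
        stage.update(status="complete", outputs=outputs, counts=counts)
        stage["wall_time_s"] = time.perf_counter() - t0
        _log_event(events, "networks", f"{len(records)} genes ranked")
    else:
        stage["counts"] = counts
        _log_event(events, "networks", "skipped (no DEGs)")

    # ---- assays --------------------------------------------------------
    stage = _stage(report, "assays")
    outputs = []
    counts = {}
    ran = False
    t0 = time.perf_counter()
    if config.ct_table:
        ct = io_mod.read_ct_table(config.ct_table)
        genes = sorted(set(ct.data["gene"]) - {ct.reference})
        rows = []
        for gene in genes:
            ddct, rel, log2_ratio = assays_mod.delta_delta_ct(
                ct, gene, treated_condition=None
            )
            rows.append((gene, ddct, rel, log2_ratio))
        qtable = pd.DataFrame(
            rows, columns=["gene", "ddct", "relative_expression", "log2_ratio"]
        )
        q_path = outdir / "qpcr_relative_expression.tsv"
        io_mod.write_tsv(qtable, q_path)
        outputs.append(q_path.name)
        counts["qpcr_genes"] = len(qtable)
        rnaseq = {
            r.gene: r.log2fc for r in deg_records if r.gene in set(qtable["gene"])
        }
        if len(rnaseq) >= 3:
            qpcr = dict(zip(qtable["gene"], qtable["log2_ratio"]))
            slope, intercept, r = assays_mod.concordance(rnaseq, qpcr)
            counts["concordance_r"] = r
            counts["concordance_slope"] = slope
        ran = True
    if config.dose_response:
        dr = io_mod.read_dose_response(config.dose_response)
        fit = assays_mod.fit_4pl(dr["dose"], dr["response"])
        fit_path = outdir / "dose_response_fit.json"
        io_mod.atomic_write_text(
            fit_path,
            json.dumps(
                {
                    "top": fit.top,
                    "bottom": fit.bottom,
                    "ic50": fit.ic50,
                    "hill": fit.hill,
                    "rss": fit.rss,
                },
                indent=2,
            )
            + "\n",
        )
        outputs.append(fit_path.name)
        counts["ic50"] = fit.ic50
        ran = True
    if ran:
        stage.update(status="complete", outputs=outputs, counts=counts)
        stage["wall_time_s"] = time.perf_counter() - t0
        _log_event(events, "assays", "complete")
    else:
        _log_event(events, "assays", "skipped (no assay inputs)")

    io_mod.atomic_write_text(
        outdir / "events.jsonl",
        "\n".join(json.dumps(e) for e in events) + "\n",
    )
    io_mod.atomic_write_text(
        outdir / "report.json", json.dumps(report, indent=2, default=str) + "\n"
    )
    return report


def write_synthetic_bundle(
    outdir: str | Path,
    seed: int = 42,
    params: sim_mod.SimulationParams | None = None,
) -> PipelineConfig:
    """Generate a full synthetic input bundle and a matching config.

    The bundle exercises every stage: counts + design with planted DEGs and
    a treated-only co-expression module, a GO-like DAG with GMT
    annotations, a pathway GMT, a background relation SIF, a Ct table and
    a dose-response table (planted IC50 of 120 on the 8-dose grid
    25..3200).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if params is None:
        params = sim_mod.SimulationParams(
            n_genes=600,
            n_per_group=10,
            baseline_mean=150.0,
            dispersion=0.05,
            frac_up=0.05,
            frac_down=0.08,
            lfc_magnitude=2.0,
            module_sizes=(10,),
            module_condition=(sim_mod.TREATED,),
            modules_from="up",
            seed=seed,
        )
    matrix, truth = sim_mod.generate_counts(params)
    io_mod.write_counts(matrix, outdir / "counts.tsv", outdir / "design.tsv")
    io_mod.write_ground_truth(truth, outdir / "ground_truth.json")

    genes = list(matrix.genes)
    dag, annotations = sim_mod.generate_ontology(
        n_terms=40, max_parents=2, annotation_rate=0.03, seed=seed + 1,
        gene_universe=genes,
    )
    io_mod.write_obo_lite(dag, outdir / "ontology.tsv")
    io_mod.write_gmt(
        {t: s for t, s in annotations.items() if s},
        outdir / "go_sets.gmt",
        names=dag.names,
    )

    rng_sets, _ = sim_mod.generate_ontology(
        n_terms=15, max_parents=1, annotation_rate=0.05, seed=seed + 2,
        gene_universe=genes,
    )
    pathway_sets = {
        f"PW{idx:03d}": members
        for idx, (term, members) in enumerate(sorted(rng_sets.annotations.items()), 1)
        if members
    }
    io_mod.write_gmt(pathway_sets, outdir / "pathways.gmt")

    relations = sim_mod.generate_relation_graph(genes, edge_density=0.01, seed=seed + 3)
    io_mod.write_sif(relations, outdir / "relations.sif")

    ct = sim_mod.generate_qpcr(truth, ct_noise_sd=0.05, seed=seed + 4)
    io_mod.write_ct_table(ct, outdir / "qpcr_ct.tsv")

    doses = [25, 50, 100, 200, 400, 800, 1600, 3200]
    dr = sim_mod.generate_dose_response(
        top=100.0, bottom=0.0, ic50=120.0, hill=1.0, doses=doses,
        noise_sd=1.0, seed=seed + 5,
    )
    io_mod.write_dose_response(dr, outdir / "dose_response.tsv")

    return PipelineConfig(
        counts=str(outdir / "counts.tsv"),
        design=str(outdir / "design.tsv"),
        go_gmt=str(outdir / "go_sets.gmt"),
        ontology=str(outdir / "ontology.tsv"),
        pathway_gmt=str(outdir / "pathways.gmt"),
        relations=str(outdir / "relations.sif"),
        ct_table=str(outdir / "qpcr_ct.tsv"),
        dose_response=str(outdir / "dose_response.tsv"),
        seed=seed,
        outdir=str(outdir / "results"),
    )


def demo(seed: int = 7, outdir: str | Path | None = None) -> int:
    """Generate a synthetic bundle, run the full pipeline, print the
    top-10 key-gene table. Returns a process exit status."""
    import tempfile

    try:
        if outdir is None:
            workdir = Path(tempfile.mkdtemp(prefix="coexkit_demo_"))
        else:
            workdir = Path(outdir)
        config = write_synthetic_bundle(workdir / "inputs", seed=seed)
        config.outdir = str(workdir / "results")
        run_pipeline(config)
        topo = pd.read_csv(Path(config.outdir) / "key_genes.tsv", sep="\t")
        print(topo.head(10).to_string(index=False))
        return 0
    except Exception as exc:  # pragma: no cover - defensive
        print(f"demo failed: {exc}", file=sys.stderr)
        return 1
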