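# coexkit

Toolkit for a transcriptome screening and network-topology workflow:

- **`coexkit.simulate`** — seeded synthetic data: negative-binomial
  two-condition count matrices with planted differentially expressed genes
  and condition-specific co-expression modules, random rooted ontology
  DAGs, background relation graphs, qPCR Ct tables and 4PL dose–response
  tables.
- **`coexkit.deg`** — RPKM normalization, fold changes, a Welch stand-in
  differential test on `log2(RPKM+1)`, Benjamini–Hochberg FDR, and DEG
  screening (`FC > 1.50` or `FC < 0.67`, `FDR < 0.05`).
- **`coexkit.enrich`** — over-representation of a gene list in GO-like
  ontologies (with true-path annotation propagation) or flat pathway sets:
  one-sided Fisher exact test, Pearson χ², BH-FDR, the enrichment ratio
  `Re = (n_f/n)/(N_f/N)`, and ancestor-closed "GO tree" construction with
  up/down/ambiguous regulation labels.
- **`coexkit.networks`** — per-condition Pearson co-expression networks
  (edges at `|r| ≥ 0.8` and `p < 0.05` by default), degree and k-core
  (minimum-degree peeling), ranking of key regulatory genes by the
  treated-minus-control degree/k-core differences, gene-act networks on a
  background relation graph, and pathway-act networks by shared-gene
  overlap.
- **`coexkit.assays`** — 2^−ΔΔCt qPCR relative quantification,
  RNA-seq/qPCR concordance regression, and four-parameter-logistic IC50
  fitting.
- **`coexkit.pipeline` / `coexkit.cli`** — an end-to-end orchestrator with
  a flat YAML config, atomic plain-text artifacts, a JSON report, and
  seeded reproducibility.

## CLI

```sh
coexkit demo --seed 7                 # synthesize, run everything, print top key genes
coexkit simulate --outdir bundle --seed 42
coexkit run --config bundle/config.yaml
coexkit deg --counts bundle/counts.tsv --design bundle/design.tsv --out degs.tsv
coexkit enrich --degs degs.tsv --gmt bundle/go_sets.gmt --ontology bundle/ontology.tsv --out go.tsv
coexkit network --counts bundle/counts.tsv --design bundle/design.tsv --degs degs.tsv --out key_genes.tsv
coexkit assays --dose-response bundle/dose_response.tsv --out fit.json
```

Exit codes: 0 ok, 1 input error, 2 internal error.

All interchange formats are plain text: counts/design TSV, GMT gene sets,
an OBO-lite TSV for ontology edges (`child_id`, `parent_id`, `term_name`),
SIF relation graphs, GraphML networks, and JSON reports.

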