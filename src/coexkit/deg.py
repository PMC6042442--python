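"""Differential-expression screening on RPKM-normalized count matrices.

The screening stage normalizes raw read counts to RPKM, computes per-gene
fold changes between two conditions, attaches a per-gene two-sided p-value
from a Welch test on ``log2(RPKM + 1)``, adjusts with Benjamini-Hochberg,
and calls genes up/down/ns under the thresholds ``FC > 1.50`` /
``FC < 0.67`` with ``FDR < 0.05``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CountMatrix",
    "RpkmMatrix",
    "DegRecord",
    "DegSummary",
    "compute_rpkm",
    "fold_change",
    "differential_test",
    "bh_fdr",
    "screen_degs",
    "FC_UP_DEFAULT",
    "FC_DOWN_DEFAULT",
    "DEG_FDR_DEFAULT",
    "FOLD_CHANGE_EPSILON",
]

#: screening thresholds (strict inequalities)
FC_UP_DEFAULT = 1.50
FC_DOWN_DEFAULT = 0.67
DEG_FDR_DEFAULT = 0.05

#: pseudo-RPKM added to both group means before forming the ratio, so that
#: genes absent from one condition yield a finite fold change.
FOLD_CHANGE_EPSILON = 1.0


@dataclass(frozen=True)
class CountMatrix:
    """Integer gene-by-sample read counts plus lengths and a two-group design.

    Attributes
    ----------
    counts:
        DataFrame indexed by gene id with one integer column per sample.
    lengths:
        Series of per-gene transcript lengths in base pairs (index aligned
        with ``counts``).
    design:
        Series mapping sample id -> condition label; exactly two distinct
        conditions.
    """

    counts: pd.DataFrame
    lengths: pd.Series
    design: pd.Series

    def __post_init__(self) -> None:
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("counts must be non-negative")
        if (self.lengths.to_numpy() <= 0).any():
            raise ValueError("gene lengths must be positive")
        if not self.counts.index.equals(self.lengths.index):
            raise ValueError("counts and lengths must share the same gene index")
        missing = [s for s in self.counts.columns if s not in self.design.index]
        if missing:
            raise ValueError(f"samples missing from design: {missing}")
        conditions = self.conditions
        if len(conditions) != 2:
            raise ValueError(
                f"design must contain exactly two conditions, found {conditions}"
            )
        for cond in conditions:
            if len(self.samples_for(cond)) < 2:
                raise ValueError(f"condition {cond!r} has fewer than 2 samples")

    @property
    def genes(self) -> pd.Index:
        return self.counts.index

    @property
    def conditions(self) -> list[str]:
        seen: list[str] = []
        for sample in self.counts.columns:
            cond = self.design[sample]
            if cond not in seen:
                seen.append(cond)
        return seen

    def samples_for(self, condition: str) -> list[str]:
        return [s for s in self.counts.columns if self.design[s] == condition]


@dataclass(frozen=True)
class RpkmMatrix:
    """Real-valued gene-by-sample RPKM matrix with its per-sample denominators."""

    values: pd.DataFrame
    total_reads: pd.Series

    def __post_init__(self) -> None:
        if (self.values.to_numpy() < 0).any():
            raise ValueError("RPKM values must be non-negative")


@dataclass(frozen=True)
class DegRecord:
    gene: str
    log2fc: float
    fold_change: float
    pvalue: float
    fdr: float
    call: str  # "up" | "down" | "ns"


@dataclass(frozen=True)
class DegSummary:
    n_up: int
    n_down: int

    @property
    def n_total(self) -> int:
        return self.n_up + self.n_down


def compute_rpkm(counts: CountMatrix) -> RpkmMatrix:
    """Reads per kilobase of transcript per million mapped reads.

    ``RPKM(g, s) = 1e9 * c(g, s) / (T(s) * L(g))`` where ``T(s)`` is the
    column sum of sample ``s`` and ``L(g)`` the gene length in bp.

    Raises
    ------
    ValueError
        If any sample has zero total reads (the sample is named).
    """
    totals = counts.counts.sum(axis=0).astype(float)
    zero = totals[totals == 0]
    if len(zero) > 0:
        raise ValueError(
            f"sample(s) with zero total mapped reads: {list(zero.index)}"
        )
    values = (
        counts.counts.to_numpy(dtype=float)
        * 1e9
        / np.outer(counts.lengths.to_numpy(dtype=float), totals.to_numpy())
    )
    df = pd.DataFrame(values, index=counts.genes, columns=counts.counts.columns)
    return RpkmMatrix(values=df, total_reads=totals)


def fold_change(
    rpkm: RpkmMatrix,
    design: pd.Series,
    control: str,
    treated: str,
    epsilon: float = FOLD_CHANGE_EPSILON,
) -> pd.DataFrame:
    """Per-gene fold change ``(mean treated + eps) / (mean control + eps)``.

    Returns a DataFrame with columns ``fold_change`` and ``log2fc`` indexed
    by gene. The epsilon guard keeps zero-expression genes finite.
    """
    control_samples = [s for s in rpkm.values.columns if design[s] == control]
    treated_samples = [s for s in rpkm.values.columns if design[s] == treated]
    if not control_samples or not treated_samples:
        raise ValueError(
            f"both conditions must be present (control={control!r}, treated={treated!r})"
        )
    mean_c = rpkm.values[control_samples].mean(axis=1)
    mean_t = rpkm.values[treated_samples].mean(axis=1)
    fc = (mean_t + epsilon) / (mean_c + epsilon)
    return pd.DataFrame({"fold_change": fc, "log2fc": np.log2(fc)})


def differential_test(
    rpkm: RpkmMatrix,
    design: pd.Series,
    control: str,
    treated: str,
) -> pd.Series:
    """Two-sided per-gene p-value from a Welch test on ``log2(RPKM + 1)``.

    This is a documented stand-in for an empirical-Bayes DE engine: the
    screening criteria, not the posterior model, are what downstream stages
    consume. Genes constant across all samples get ``p = 1`` by convention;
    genes with zero variance in both groups but different means get ``p = 0``.
    """
    control_samples = [s for s in rpkm.values.columns if design[s] == control]
    treated_samples = [s for s in rpkm.values.columns if design[s] == treated]
    if len(control_samples) < 2 or len(treated_samples) < 2:
        raise ValueError("differential_test requires >=2 replicates per condition")

    log_expr = np.log2(rpkm.values.to_numpy(dtype=float) + 1.0)
    cols = list(rpkm.values.columns)
    xc = log_expr[:, [cols.index(s) for s in control_samples]]
    xt = log_expr[:, [cols.index(s) for s in treated_samples]]

    with np.errstate(divide="ignore", invalid="ignore"):
        res = stats.ttest_ind(xt, xc, axis=1, equal_var=False)
    pvals = np.asarray(res.pvalue, dtype=float)

    var_c = xc.var(axis=1)
    var_t = xt.var(axis=1)
    degenerate = (var_c == 0) & (var_t == 0)
    equal_means = np.isclose(xc.mean(axis=1), xt.mean(axis=1))
    pvals[degenerate & equal_means] = 1.0
    pvals[degenerate & ~equal_means] = 0.0
    pvals = np.clip(np.nan_to_num(pvals, nan=1.0), 0.0, 1.0)
    return pd.Series(pvals, index=rpkm.values.index, name="pvalue")


def bh_fdr(pvalues: Sequence[float] | pd.Series) -> np.ndarray | pd.Series:
    """Benjamini-Hochberg step-up adjusted p-values.

    ``q(i) = min_{j >= i} m * p(j) / j`` over the ascending ordering, capped
    at 1. Ties are broken by a stable sort so the output is deterministic.
    Output preserves input order; a Series input returns a Series.
    """
    is_series = isinstance(pvalues, pd.Series)
    p = np.asarray(pvalues, dtype=float)
    if p.size and (np.isnan(p).any() or p.min() < 0 or p.max() > 1):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    if m == 0:
        q = p.copy()
    else:
        order = np.argsort(p, kind="stable")
        ranked = p[order] * m / np.arange(1, m + 1)
        q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
        q = np.empty(m, dtype=float)
        q[order] = np.minimum(q_sorted, 1.0)
    if is_series:
        return pd.Series(q, index=pvalues.index, name="fdr")
    return q


def screen_degs(
    fc_table: pd.DataFrame,
    fdr: pd.Series | Mapping[str, float],
    fc_up: float = FC_UP_DEFAULT,
    fc_down: float = FC_DOWN_DEFAULT,
    max_fdr: float = DEG_FDR_DEFAULT,
) -> tuple[list[DegRecord], DegSummary]:
    """Call genes up/down/ns under strict fold-change and FDR thresholds.

    ``call = up`` iff ``FC > fc_up`` and ``FDR < max_fdr``; ``call = down``
    iff ``FC < fc_down`` and ``FDR < max_fdr``; otherwise ``ns``.
    """
    fdr = pd.Series(fdr)
    if not set(fc_table.index) == set(fdr.index):
        raise ValueError("fold-change table and FDR table must share a gene universe")
    pvalues = (
        fc_table["pvalue"] if "pvalue" in fc_table.columns
        else pd.Series(np.nan, index=fc_table.index)
    )
    records: list[DegRecord] = []
    n_up = n_down = 0
    for gene in fc_table.index:
        fc = float(fc_table.at[gene, "fold_change"])
        q = float(fdr[gene])
        if fc > fc_up and q < max_fdr:
            call = "up"
            n_up += 1
        elif fc < fc_down and q < max_fdr:
            call = "down"
            n_down += 1
        else:
            call = "ns"
        records.append(
            DegRecord(
                gene=str(gene),
                log2fc=float(fc_table.at[gene, "log2fc"]),
                fold_change=fc,
                pvalue=float(pvalues[gene]),
                fdr=q,
                call=call,
            )
        )
    return records, DegSummary(n_up=n_up, n_down=n_down)


def deg_frame(records: Iterable[DegRecord]) -> pd.DataFrame:
    """Tabular view of DEG records with the canonical column names."""
    rows = [
        (r.gene, r.log2fc, r.fold_change, r.pvalue, r.fdr, r.call) for r in records
    ]
    return pd.DataFrame(
        rows, columns=["gene_id", "log2fc", "fold_change", "pvalue", "fdr", "call"]
    )
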