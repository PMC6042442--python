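"""qPCR relative quantification, RNA-seq concordance, and 4PL IC50 fitting."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "CtTable",
    "DoseResponseFit",
    "FitError",
    "delta_delta_ct",
    "concordance",
    "fit_4pl",
    "four_pl",
]


@dataclass(frozen=True)
class CtTable:
    """Long-format qPCR cycle-threshold table.

    ``data`` has columns ``gene``, ``sample``, ``condition``, ``ct``.
    ``reference`` is the endogenous reference gene; ``control_condition``
    names the baseline condition for the delta-delta-Ct contrast.
    """

    data: pd.DataFrame
    reference: str
    control_condition: str

    def __post_init__(self) -> None:
        required = {"gene", "sample", "condition", "ct"}
        if not required <= set(self.data.columns):
            raise ValueError(f"Ct table must have columns {sorted(required)}")
        conditions = set(self.data["condition"])
        if self.control_condition not in conditions:
            raise ValueError(
                f"control condition {self.control_condition!r} absent from Ct table"
            )
        for cond in conditions:
            sub = self.data[self.data["condition"] == cond]
            if self.reference not in set(sub["gene"]):
                raise ValueError(
                    f"reference gene {self.reference!r} missing in condition {cond!r}"
                )

    @property
    def conditions(self) -> list[str]:
        return sorted(set(self.data["condition"]))


@dataclass(frozen=True)
class DoseResponseFit:
    top: float
    bottom: float
    ic50: float
    hill: float
    rss: float
    fitted: pd.DataFrame  # columns dose, response, fitted
    converged: bool = True


class FitError(RuntimeError):
    """Raised on non-convergence; carries the best-so-far parameters."""

    def __init__(self, message: str, best: DoseResponseFit | None = None):
        super().__init__(message)
        self.best = best


def delta_delta_ct(
    ct: CtTable,
    gene: str,
    treated_condition: str | None = None,
) -> tuple[float, float, float]:
    """Relative expression of ``gene`` by the 2^-ddCt method.

    ``dCt(cond) = mean Ct(gene, cond) - mean Ct(reference, cond)`` and
    ``ddCt = dCt(treated) - dCt(control)``. Returns
    ``(ddct, 2 ** -ddct, -ddct)`` — the last element is the log2 expression
    ratio of treated over control. Replicate wells are averaged
    arithmetically on the Ct scale before differencing.
    """
    data = ct.data
    conditions = [c for c in ct.conditions if c != ct.control_condition]
    if treated_condition is None:
        if len(conditions) != 1:
            raise ValueError(
                "treated_condition must be given when more than two conditions exist"
            )
        treated_condition = conditions[0]

    def mean_ct(g: str, cond: str) -> float:
        sub = data[(data["gene"] == g) & (data["condition"] == cond)]
        if sub.empty:
            raise ValueError(f"no Ct wells for gene {g!r} in condition {cond!r}")
        return float(sub["ct"].mean())

    dct = {}
    for cond in (ct.control_condition, treated_condition):
        dct[cond] = mean_ct(gene, cond) - mean_ct(ct.reference, cond)
    ddct = dct[treated_condition] - dct[ct.control_condition]
    return (ddct, float(2.0 ** (-ddct)), -ddct)


def concordance(
    rnaseq_lfc: Mapping[str, float],
    qpcr_lfc: Mapping[str, float],
) -> tuple[float, float, float]:
    """OLS of qPCR log2 ratios on RNA-seq log2FC over the shared genes.

    Returns ``(slope, intercept, pearson_r)``; requires >= 3 shared genes.
    """
    shared = sorted(set(rnaseq_lfc) & set(qpcr_lfc))
    if len(shared) < 3:
        raise ValueError(f"need >=3 shared genes, got {len(shared)}")
    x = np.array([rnaseq_lfc[g] for g in shared], dtype=float)
    y = np.array([qpcr_lfc[g] for g in shared], dtype=float)
    res = stats.linregress(x, y)
    return (float(res.slope), float(res.intercept), float(res.rvalue))


def four_pl(dose, top: float, bottom: float, ic50: float, hill: float):
    """Four-parameter logistic: ``bottom + (top-bottom) / (1 + (d/ic50)^hill)``."""
    dose = np.asarray(dose, dtype=float)
    return bottom + (top - bottom) / (1.0 + (dose / ic50) ** hill)


def fit_4pl(doses, responses) -> DoseResponseFit:
    """Least-squares 4PL fit; reports IC50 and diagnostics.

    Initialization: top/bottom from the response extremes, IC50 at the
    geometric-mean dose, hill = 1. The optimizer is bounded so IC50 stays
    positive. Non-convergence raises :class:`FitError` carrying the
    best-so-far parameters.
    """
    doses = np.asarray(doses, dtype=float)
    responses = np.asarray(responses, dtype=float)
    if doses.shape != responses.shape or doses.ndim != 1:
        raise ValueError("doses and responses must be equal-length 1-D arrays")
    if len(np.unique(doses)) < 4:
        raise ValueError("need >=4 distinct doses for a 4PL fit")
    if (doses <= 0).any():
        raise ValueError("doses must be positive")

    top0 = float(responses.max())
    bottom0 = float(responses.min())
    ic50_0 = float(np.exp(np.mean(np.log(doses))))
    p0 = [top0, bottom0, ic50_0, 1.0]
    bounds = (
        [-np.inf, -np.inf, 1e-12, -50.0],
        [np.inf, np.inf, np.inf, 50.0],
    )
    try:
        popt, _ = optimize.curve_fit(
            four_pl, doses, responses, p0=p0, bounds=bounds, maxfev=20000
        )
    except RuntimeError as exc:
        fitted = four_pl(doses, *p0)
        best = DoseResponseFit(
            top=p0[0],
            bottom=p0[1],
            ic50=p0[2],
            hill=p0[3],
            rss=float(((responses - fitted) ** 2).sum()),
            fitted=pd.DataFrame(
                {"dose": doses, "response": responses, "fitted": fitted}
            ),
            converged=False,
        )
        raise FitError(f"4PL fit did not converge: {exc}", best=best) from exc

    fitted = four_pl(doses, *popt)
    return DoseResponseFit(
        top=float(popt[0]),
        bottom=float(popt[1]),
        ic50=float(popt[2]),
        hill=float(popt[3]),
        rss=float(((responses - fitted) ** 2).sum()),
        fitted=pd.DataFrame({"dose": doses, "response": responses, "fitted": fitted}),
    )
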