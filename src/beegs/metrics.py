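"""Evaluation of breeding-value estimates: accuracy, bias, rescaling.

Accuracy is the Pearson correlation between (simulated) true breeding
values and their estimates within a cohort; bias is measured by the
ordinary-least-squares regression coefficient of TBV on EBV (``b1 = 1``
means unbiased dispersion).  Colony (worker-group) accuracies and queen
accuracies are not directly comparable because selection acts on
different genetic variances; the worker-group accuracy is rescaled to a
*replacement-queen* accuracy

    rho_pR = (sigma_pW / sigma_pQ) * rho_pW,

the correlation that the EBV of a phenotyped colony would have with the
TBV of a daughter queen reared from it.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from typing import TYPE_CHECKING

import numpy as np
import pandas as pd

if TYPE_CHECKING:  # pragma: no cover
    from .breeding import PopulationHistory

__all__ = [
    "AccuracyReport",
    "accuracy_by_cohort",
    "bias_regression",
    "rescale_accuracy",
    "evaluate_analysis",
]

CRITERIA = {"direct": ("tbv_a", "ebv_direct"),
            "maternal": ("tbv_m", "ebv_maternal"),
            "sum": (None, "ebv_sum")}


class DegenerateCohortError(ValueError):
    pass


def _tbv_ebv(
    ebv: pd.DataFrame,
    history: "PopulationHistory",
    cohort: list[str],
    criterion: str,
) -> tuple[np.ndarray, np.ndarray]:
    if len(cohort) == 0:
        raise DegenerateCohortError("empty cohort")
    if criterion not in CRITERIA:
        raise ValueError(f"criterion must be one of {sorted(CRITERIA)}")
    tbv2 = history.tbv_of(cohort)
    tbv = {
        "direct": tbv2[:, 0],
        "maternal": tbv2[:, 1],
        "sum": tbv2.sum(axis=1),
    }[criterion]
    est = ebv.set_index("id").loc[cohort, CRITERIA[criterion][1]].to_numpy(float)
    return tbv, est


def accuracy_by_cohort(
    ebv: pd.DataFrame,
    history: "PopulationHistory",
    cohort: list[str],
    criterion: str = "sum",
) -> float:
    """Pearson correlation between TBV and EBV over the cohort."""
    tbv, est = _tbv_ebv(ebv, history, cohort, criterion)
    if np.std(tbv) == 0 or np.std(est) == 0:
        raise DegenerateCohortError("zero variance in TBV or EBV")
    return float(np.corrcoef(tbv, est)[0, 1])


def bias_regression(
    ebv: pd.DataFrame,
    history: "PopulationHistory",
    cohort: list[str],
    criterion: str = "sum",
) -> float:
    """OLS slope of TBV on EBV (1 = no dispersion bias)."""
    tbv, est = _tbv_ebv(ebv, history, cohort, criterion)
    if len(cohort) < 3:
        raise DegenerateCohortError("need at least 3 cohort members")
    var = np.var(est)
    if var == 0:
        raise DegenerateCohortError("zero EBV variance")
    return float(np.cov(tbv, est, ddof=0)[0, 1] / var)


def rescale_accuracy(rho_pW: float, sigma_pW: float, sigma_pQ: float) -> float:
    """Rescale a colony accuracy to a replacement-queen accuracy."""
    if sigma_pQ <= 0:
        raise ZeroDivisionError("sigma_pQ must be positive")
    return (sigma_pW / sigma_pQ) * rho_pW


@dataclass(frozen=True)
class AccuracyReport:
    """Cohort accuracies and TBV dispersions of one analysis.

    Cohorts follow the reference design: *unfertilized queens* are the
    final-year BQ (phenotype not yet recorded), *phenotyped colonies*
    the worker groups of the year before, ``sigma_pQ`` the TBV spread of
    the queens heading those colonies.
    """

    analysis: str
    criterion: str
    rho_uQ: float
    rho_pW: float
    rho_pR: float
    sigma_uQ: float
    sigma_pQ: float
    sigma_pW: float
    b1_uQ: float
    b1_pW: float
    n_uQ: int
    n_pW: int

    def as_dict(self) -> dict:
        return asdict(self)


def evaluate_analysis(
    ebv: pd.DataFrame,
    history: "PopulationHistory",
    criterion: str = "sum",
    genotyped_bq: list[str] | None = None,
    uq_year: int | None = None,
) -> AccuracyReport:
    """Standard accuracy/bias report for one EBV table.

    With ``genotyped_bq`` given, queen cohorts are restricted to their
    genotyped members (the convention for single-step analyses); worker
    groups of non-genotyped queens remain included in ``rho_pW`` so the
    colony accuracy can feed the deterministic gain model.
    """
    last = history.config.years - 1 if uq_year is None else uq_year
    uq = history.queen_ids(last, "BQ")
    pq = history.queen_ids(last - 1, "BQ")
    pw = history.wg_ids(last - 1)
    if genotyped_bq is not None:
        keep = set(genotyped_bq)
        uq_r = [i for i in uq if i in keep] or uq
    else:
        uq_r = uq
    tbv_sum = lambda ids: history.tbv_of(ids).sum(axis=1)
    sigma_uQ = float(np.std(tbv_sum(uq), ddof=1))
    sigma_pQ = float(np.std(tbv_sum(pq), ddof=1))
    sigma_pW = float(np.std(tbv_sum(pw), ddof=1))
    rho_uQ = accuracy_by_cohort(ebv, history, uq_r, criterion)
    rho_pW = accuracy_by_cohort(ebv, history, pw, criterion)
    return AccuracyReport(
        analysis=str(ebv.analysis.iloc[0]) if "analysis" in ebv else "",
        criterion=criterion,
        rho_uQ=rho_uQ,
        rho_pW=rho_pW,
        rho_pR=rescale_accuracy(rho_pW, sigma_pW, sigma_pQ),
        sigma_uQ=sigma_uQ,
        sigma_pQ=sigma_pQ,
        sigma_pW=sigma_pW,
        b1_uQ=bias_regression(ebv, history, uq_r, criterion),
        b1_pW=bias_regression(ebv, history, pw, criterion),
        n_uQ=len(uq_r),
        n_pW=len(pw),
    )
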