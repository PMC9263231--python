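"""Disproportionality statistics: ROR with Woolf CI, shrinkage IC with IC025.

The reporting odds ratio (ROR) of a 2x2 table is ad/bc with a 95%
confidence interval from the log-odds normal approximation
exp(ln ROR +/- z * sqrt(1/a + 1/b + 1/c + 1/d)).  When any cell is zero,
0.5 is added to all four cells (Haldane-Anscombe) and the result is
flagged as corrected.

The information component (IC) compares the observed count of exposed
case reports with its expectation under in-sample independence,
E = (a+b)(a+c)/N, on a log2 scale with shrinkage:

    IC    = log2((a + 1/2) / (E + 1/2))
    IC025 = log2(q)   with q the 2.5% quantile of Gamma(shape a + 1/2,
                      rate E + 1/2)

This is the shrinkage observed-to-expected formulation with a gamma
credibility interval currently used for database-wide screening; the
legacy Bayesian confidence propagation neural network (BCPNN) normal
approximation is available via ``method="legacy_bcpnn"``.  The classical
screening threshold keeps pairs with IC025 > 0 and at least 30 reports;
this is a screening rule, not an inferential procedure — no
multiple-testing adjustment is applied, mirroring routine practice.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Literal, Optional

import pandas as pd
from scipy import stats

from .contingency import ContingencyTable
from .report_store import DrugDictionary, ReportSet

ICMethod = Literal["gamma", "legacy_bcpnn"]


@dataclass(frozen=True)
class RorEstimate:
    """ROR point estimate with CI; ``estimable`` is False when the drug is
    absent from, or universal in, the database (a+b or c+d zero)."""

    ror: float
    low: float
    high: float
    corrected: bool = False
    estimable: bool = True

    NOT_ESTIMABLE: "RorEstimate" = None  # set below


RorEstimate.NOT_ESTIMABLE = RorEstimate(math.nan, math.nan, math.nan, False, False)


def expected_count(t: ContingencyTable) -> float:
    """Expected exposed-case count under in-sample independence:
    (a+b)(a+c)/N."""
    if t.n == 0:
        raise ValueError("empty table")
    return (t.a + t.b) * (t.a + t.c) / t.n


def ror_with_ci(t: ContingencyTable, alpha: float = 0.05) -> RorEstimate:
    """Reporting odds ratio with a (1-alpha) Woolf confidence interval."""
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must be in (0,1)")
    if t.a + t.b == 0 or t.c + t.d == 0:
        return RorEstimate.NOT_ESTIMABLE
    a, b, c, d = (float(x) for x in t.as_tuple())
    corrected = min(a, b, c, d) == 0.0
    if corrected:  # Haldane-Anscombe: 0.5 to all four cells
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    ror = (a * d) / (b * c)
    z = stats.norm.ppf(1 - alpha / 2)
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    return RorEstimate(
        ror=ror,
        low=ror * math.exp(-z * se),
        high=ror * math.exp(z * se),
        corrected=corrected,
    )


def information_component(
    t: ContingencyTable, method: ICMethod = "gamma", credibility: float = 0.95
) -> tuple[float, float]:
    """(IC, IC025) for one table.  Shrinkage makes every table estimable."""
    if method == "gamma":
        return _ic_gamma(t.a, expected_count(t), credibility)
    if method == "legacy_bcpnn":
        return _ic_legacy_bcpnn(t, credibility)
    raise ValueError(f"unknown IC method {method!r}")


def _ic_gamma(a: int, e: float, credibility: float = 0.95) -> tuple[float, float]:
    o, ex = a + 0.5, e + 0.5
    ic = math.log2(o / ex)
    q = stats.gamma.ppf((1 - credibility) / 2, a=o, scale=1.0 / ex)
    return ic, math.log2(q)


def _ic_legacy_bcpnn(t: ContingencyTable, credibility: float = 0.95) -> tuple[float, float]:
    # Closed-form posterior moments of the BCPNN IC (beta-binomial model
    # with uniform-style priors), expressed through digamma/trigamma; the
    # credibility bound is the normal approximation on those moments.
    from scipy.special import polygamma

    digamma = lambda x: polygamma(0, x)
    trigamma = lambda x: polygamma(1, x)
    n11, n1_, n_1, n = float(t.a), float(t.a + t.b), float(t.a + t.c), float(t.n)
    p1, p2 = 1 + n1_, 1 + n - n1_
    q1, q2 = 1 + n_1, 1 + n - n_1
    r1 = 1 + n11
    r2b = n - n11 - 1 + (2 + n) ** 2 / (q1 * p1)
    ln2 = math.log(2)
    ic = (
        digamma(r1) - digamma(r1 + r2b)
        - (digamma(p1) - digamma(p1 + p2) + digamma(q1) - digamma(q1 + q2))
    ) / ln2
    var = (
        trigamma(r1) - trigamma(r1 + r2b)
        + trigamma(p1) - trigamma(p1 + p2)
        + trigamma(q1) - trigamma(q1 + q2)
    ) / ln2**2
    z = stats.norm.ppf(1 - (1 - credibility) / 2)
    return float(ic), float(ic - z * math.sqrt(var))


# ---------------------------------------------------------------------------
# results, screening criteria, ranking

@dataclass
class DisproResult:
    """Disproportionality summary for one drug or class."""

    label: str
    n: int  # exposed case reports (cell a)
    ror: float
    ror_low: float
    ror_high: float
    ic: float
    ic025: float
    ror_corrected: bool = False
    ror_estimable: bool = True
    is_signal: bool = False


def result_from_table(
    t: ContingencyTable, alpha: float = 0.05, ic_method: ICMethod = "gamma"
) -> DisproResult:
    r = ror_with_ci(t, alpha=alpha)
    ic, ic025 = information_component(t, method=ic_method)
    return DisproResult(
        label=t.label,
        n=t.a,
        ror=r.ror,
        ror_low=r.low,
        ror_high=r.high,
        ic=ic,
        ic025=ic025,
        ror_corrected=r.corrected,
        ror_estimable=r.estimable,
    )


def apply_signal_criteria(
    results: Iterable[DisproResult],
    min_reports: int = 30,
    ic_threshold: float = 0.0,
) -> list[DisproResult]:
    """Classical screening rule: keep IC025 > threshold and n >= min_reports.

    ``is_signal`` is set on every input result; the kept subset is returned
    in input order.
    """
    kept = []
    for res in results:
        res.is_signal = res.ic025 > ic_threshold and res.n >= min_reports
        if res.is_signal:
            kept.append(res)
    return kept


def rank_results(
    results: Iterable[DisproResult], by: Literal["n_reports", "ror"] = "n_reports"
) -> list[DisproResult]:
    """Stable descending sort by the chosen key; ties alphabetical by label.

    Non-estimable RORs sort last under ``by="ror"``.
    """
    if by == "n_reports":
        key = lambda r: (-r.n, r.label)
    elif by == "ror":
        key = lambda r: (-(r.ror if r.ror_estimable else -math.inf), r.label)
    else:
        raise ValueError(f"unknown ranking key {by!r}")
    return sorted(results, key=key)


def results_to_frame(results: Iterable[DisproResult], n_cases: int) -> pd.DataFrame:
    """Machine-readable results table; pct_of_cases = 100*n/n_cases at one
    decimal (half away from zero)."""
    from .descriptives import pct  # local import: avoids a module cycle

    return pd.DataFrame(
        [
            {
                "label": r.label,
                "n": r.n,
                "pct_of_cases": pct(r.n, n_cases),
                "ror": r.ror,
                "ror_low": r.ror_low,
                "ror_high": r.ror_high,
                "ic": r.ic,
                "ic025": r.ic025,
                "is_signal": r.is_signal,
            }
            for r in results
        ]
    )


def disproportionality(
    db: ReportSet,
    case_terms: Iterable[str],
    dictionary: Optional[DrugDictionary] = None,
    class_level: Optional[int] = None,
    min_reports: int = 30,
    ic_threshold: float = 0.0,
    rank_by: Literal["n_reports", "ror"] = "n_reports",
    ic_method: ICMethod = "gamma",
    signals_only: bool = True,
) -> list[DisproResult]:
    """End-to-end screen: tables for every substance (and optional ATC
    class), ROR + IC, screening criteria, ranking."""
    from .contingency import build_all_tables

    tables = build_all_tables(db, case_terms, dictionary=dictionary, class_level=class_level)
    results = [result_from_table(t, ic_method=ic_method) for t in tables]
    kept = apply_signal_criteria(results, min_reports=min_reports, ic_threshold=ic_threshold)
    return rank_results(kept if signals_only else results, by=rank_by)
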