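"""Case-cohort characterization: demographics, seriousness, fatality,
co-reported terms, outcomes, time to onset, and drug report shares.

Denominator policy (recorded explicitly on every field): demographic
breakdowns with an appreciable unknown fraction — age bands and outcomes —
use the known-value denominator; seriousness, fatality, country, reporter,
co-reported-term and drug shares use all case reports.  Percentages are
rounded to one decimal, half away from zero, so each printed percentage
re-derives exactly from its count and declared denominator.
"""
from __future__ import annotations

import json
import math
from collections import Counter
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Iterable, Optional

import numpy as np
import pandas as pd

from .report_store import AGE_GROUPS, OUTCOMES, REPORTERS, UNKNOWN, DrugDictionary, ReportSet


def pct(count: int, denominator: int) -> float:
    """100*count/denominator at one decimal, rounding half away from zero."""
    if denominator == 0:
        return math.nan
    exact = Decimal(100) * Decimal(count) / Decimal(denominator)
    return float(exact.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


@dataclass
class FieldBreakdown:
    """Counts and percentages for one characteristic, with its denominator."""

    counts: dict[str, int]
    denominator: int
    denominator_kind: str  # "all_reports" or "known_values"

    def pcts(self) -> dict[str, float]:
        return {k: pct(v, self.denominator) for k, v in self.counts.items()}


@dataclass
class CohortSummary:
    """Descriptive characterization of a case cohort."""

    n_total: int
    age: FieldBreakdown
    n_age_unknown: int
    sex: FieldBreakdown
    country: FieldBreakdown  # top-k only
    reporter: FieldBreakdown  # includes the explicit unknown row
    n_serious: int
    pct_serious: float
    n_fatal: int
    pct_fatal: float
    tto_median_days: Optional[float]
    tto_iqr_days: Optional[tuple[float, float]]
    n_tto_known: int
    coreported_terms: FieldBreakdown  # top-k, index case terms excluded
    outcome: FieldBreakdown
    n_outcome_known: int

    def to_dict(self) -> dict:
        def fb(f: FieldBreakdown) -> dict:
            return {
                "counts": f.counts,
                "pcts": f.pcts(),
                "denominator": f.denominator,
                "denominator_kind": f.denominator_kind,
            }

        return {
            "n_total": self.n_total,
            "age": fb(self.age),
            "n_age_unknown": self.n_age_unknown,
            "sex": fb(self.sex),
            "country": fb(self.country),
            "reporter": fb(self.reporter),
            "serious": {"count": self.n_serious, "pct": self.pct_serious, "denominator": self.n_total},
            "fatal": {"count": self.n_fatal, "pct": self.pct_fatal, "denominator": self.n_total},
            "time_to_onset_days": {
                "median": self.tto_median_days,
                "iqr": list(self.tto_iqr_days) if self.tto_iqr_days else None,
                "n_known": self.n_tto_known,
            },
            "coreported_terms": fb(self.coreported_terms),
            "outcome": fb(self.outcome),
            "n_outcome_known": self.n_outcome_known,
        }

    def to_json(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    def to_rows(self) -> list[tuple[str, str]]:
        """Two-column (characteristic, "count (pct)") rows."""
        rows: list[tuple[str, str]] = [("Number of reports", str(self.n_total))]

        def emit(title: str, f: FieldBreakdown) -> None:
            rows.append((title, ""))
            for k, v in f.counts.items():
                rows.append((f"  {k}", f"{v} ({pct(v, f.denominator)})"))

        emit("Age", self.age)
        emit("Sex", self.sex)
        emit("Country", self.country)
        emit("Reporter qualification", self.reporter)
        rows.append(("Serious", f"{self.n_serious} ({self.pct_serious})"))
        rows.append(("Fatal", f"{self.n_fatal} ({self.pct_fatal})"))
        if self.tto_median_days is not None:
            q1, q3 = self.tto_iqr_days
            rows.append(
                ("Time to onset, days (median [IQR])", f"{self.tto_median_days} [{q1}-{q3}]")
            )
        emit("Co-reported terms", self.coreported_terms)
        emit("Outcome", self.outcome)
        return rows

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame(self.to_rows(), columns=["characteristic", "count (pct)"]).to_csv(
            path, index=False
        )


def time_to_onset_summary(cases: ReportSet) -> tuple[Optional[float], Optional[float], Optional[float], int]:
    """(median, q1, q3, n_known) over reports with a recorded time to onset.

    Quantiles use linear interpolation.  With no known values the three
    quantiles are returned as None.
    """
    values = [r.time_to_onset_days for r in cases if r.time_to_onset_days is not None]
    if not values:
        return None, None, None, 0
    q1, med, q3 = np.percentile(values, [25, 50, 75])
    return float(med), float(q1), float(q3), len(values)


def summarize_cohort(
    cases: ReportSet,
    case_terms: Iterable[str],
    top_k_countries: int = 10,
    top_k_terms: int = 10,
) -> CohortSummary:
    """Report-level descriptive summary of a case cohort.

    ``case_terms`` identifies the index reaction term(s), excluded from the
    co-reported term ranking.  Top-k rankings break count ties
    alphabetically for reproducibility.
    """
    if len(cases) == 0:
        raise ValueError("cannot summarize an empty cohort")
    terms = frozenset(case_terms)
    n = len(cases)

    age_counts = Counter(r.age_group for r in cases)
    n_age_unknown = age_counts.pop(UNKNOWN, 0)
    n_age_known = n - n_age_unknown
    age = FieldBreakdown(
        {band: age_counts.get(band, 0) for band in AGE_GROUPS[:-1] if band in age_counts},
        denominator=n_age_known,
        denominator_kind="known_values",
    )

    sex_counts = Counter(r.sex for r in cases)
    n_sex_unknown = sex_counts.pop(UNKNOWN, 0)
    sex = FieldBreakdown(
        dict(sex_counts), denominator=n - n_sex_unknown, denominator_kind="known_values"
    )

    country_counts = Counter(r.country for r in cases if r.country != UNKNOWN)
    top_countries = sorted(country_counts.items(), key=lambda kv: (-kv[1], kv[0]))[:top_k_countries]
    country = FieldBreakdown(dict(top_countries), denominator=n, denominator_kind="all_reports")

    reporter_counts = Counter(r.reporter for r in cases)
    reporter = FieldBreakdown(
        {rep: reporter_counts[rep] for rep in REPORTERS if rep in reporter_counts},
        denominator=n,
        denominator_kind="all_reports",
    )

    n_serious = sum(1 for r in cases if r.serious is True)
    n_fatal = sum(1 for r in cases if r.fatal is True)

    term_counts: Counter[str] = Counter()
    for r in cases:
        term_counts.update(r.reaction_terms - terms)
    top_terms = sorted(term_counts.items(), key=lambda kv: (-kv[1], kv[0]))[:top_k_terms]
    coreported = FieldBreakdown(dict(top_terms), denominator=n, denominator_kind="all_reports")

    outcome_counts = Counter(r.outcome for r in cases)
    outcome_counts.pop(UNKNOWN, 0)
    n_outcome_known = sum(outcome_counts.values())
    outcome = FieldBreakdown(
        {o: outcome_counts[o] for o in OUTCOMES[:-1] if o in outcome_counts},
        denominator=n_outcome_known,
        denominator_kind="known_values",
    )

    med, q1, q3, n_tto = time_to_onset_summary(cases)
    return CohortSummary(
        n_total=n,
        age=age,
        n_age_unknown=n_age_unknown,
        sex=sex,
        country=country,
        reporter=reporter,
        n_serious=n_serious,
        pct_serious=pct(n_serious, n),
        n_fatal=n_fatal,
        pct_fatal=pct(n_fatal, n),
        tto_median_days=med,
        tto_iqr_days=(q1, q3) if med is not None else None,
        n_tto_known=n_tto,
        coreported_terms=coreported,
        outcome=outcome,
        n_outcome_known=n_outcome_known,
    )


def drug_report_shares(
    cases: ReportSet,
    dictionary: Optional[DrugDictionary] = None,
    level: Optional[int] = None,
) -> pd.DataFrame:
    """Report-level drug (or ATC-class) counts with percentage of all cases.

    At class level a report exposed to two members of the same class counts
    once.  Returns columns label/count/pct sorted by count descending, ties
    alphabetical.  Codes absent from the dictionary are skipped at class
    level (no class is known for them) but reported at substance level.
    """
    if len(cases) == 0:
        raise ValueError("cannot tabulate shares for an empty cohort")
    n = len(cases)
    counts: Counter[str] = Counter()
    if level is None:
        for r in cases:
            for code in r.drug_codes:
                counts[dictionary.display_name(code) if dictionary else code] += 1
    else:
        if dictionary is None:
            raise ValueError("class-level shares require a drug dictionary")
        for r in cases:
            classes = {
                cls
                for code in r.drug_codes
                if (cls := dictionary.class_at_level(code, level)) is not None
            }
            for cls in classes:
                counts[cls] += 1
    rows = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    return pd.DataFrame(
        [{"label": lab, "count": cnt, "pct": pct(cnt, n)} for lab, cnt in rows],
        columns=["label", "count", "pct"],
    )
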