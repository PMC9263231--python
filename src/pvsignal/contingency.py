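"""2x2 contingency tables for drug-case and drug-class-case pairs.

Counting is always at report level: a report mentioning any code of the
drug (or class) counts once as exposed, and a report carrying any case
term counts once as a case.  The comparator is the rest of the whole
database (all non-case reports), the standard database-wide
disproportionality setup.  Class tables pool member exposure report-ID
sets by union, never by cell-wise summation, so a report exposed to two
class members still contributes one.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional

import pandas as pd

from .report_store import DrugDictionary, ReportSet


@dataclass(frozen=True)
class ContingencyTable:
    """Counts for one drug-or-class x one case definition.

    a: case reports mentioning the drug/class; b: non-case reports
    mentioning it; c: case reports not mentioning it; d: the rest.
    """

    a: int
    b: int
    c: int
    d: int
    label: str = ""

    def __post_init__(self) -> None:
        for name in "abcd":
            v = getattr(self, name)
            if not isinstance(v, int) or v < 0:
                raise ValueError(f"cell {name} must be a non-negative integer, got {v!r}")

    @property
    def n(self) -> int:
        """Total number of reports in the database."""
        return self.a + self.b + self.c + self.d

    @property
    def n_cases(self) -> int:
        return self.a + self.c

    @property
    def n_exposed(self) -> int:
        return self.a + self.b

    def as_tuple(self) -> tuple[int, int, int, int]:
        return (self.a, self.b, self.c, self.d)


def build_table(
    db: ReportSet,
    case_terms: Iterable[str],
    drug_codes: Iterable[str],
    label: Optional[str] = None,
    dictionary: Optional[DrugDictionary] = None,
) -> ContingencyTable:
    """Cross-classify a de-duplicated database by drug mention and case status.

    ``drug_codes`` is a singleton for a substance or a set for a pooled
    class.  If a ``dictionary`` is supplied, codes absent from it raise a
    warning but are still counted by literal code match.
    """
    if len(db) == 0:
        raise ValueError("empty database: contingency table undefined")
    codes = frozenset(drug_codes)
    if not codes:
        raise ValueError("drug_codes must be non-empty")
    terms = frozenset(case_terms)
    if not terms:
        raise ValueError("case_terms must be non-empty")
    if dictionary is not None:
        unknown = sorted(c for c in codes if c not in dictionary)
        if unknown:
            warnings.warn(
                f"drug code(s) not in dictionary, counted by literal match: {unknown}",
                stacklevel=2,
            )
    a = b = c = d = 0
    for r in db:
        exposed = bool(r.drug_codes & codes)
        case = bool(r.reaction_terms & terms)
        if exposed and case:
            a += 1
        elif exposed:
            b += 1
        elif case:
            c += 1
        else:
            d += 1
    return ContingencyTable(a, b, c, d, label=label or "/".join(sorted(codes)))


def build_all_tables(
    db: ReportSet,
    case_terms: Iterable[str],
    dictionary: Optional[DrugDictionary] = None,
    class_level: Optional[int] = None,
) -> list[ContingencyTable]:
    """One table per substance appearing in >=1 report, plus optional
    class-level tables.

    With ``class_level`` given (1-based ATC level) one additional table is
    built per class at that level, pooling the member codes found in the
    dictionary.  Substance tables are labelled by display name when a
    dictionary is available.
    """
    if len(db) == 0:
        raise ValueError("empty database: contingency tables undefined")
    terms = frozenset(case_terms)
    if not terms:
        raise ValueError("case_terms must be non-empty")

    # single pass: exposure report index per substance + case flags
    case_flags: list[bool] = []
    exposed_idx: dict[str, set[int]] = {}
    for i, r in enumerate(db):
        case_flags.append(bool(r.reaction_terms & terms))
        for code in r.drug_codes:
            exposed_idx.setdefault(code, set()).add(i)
    n_total = len(db)
    n_cases = sum(case_flags)

    def table_from_index(idx: set[int], label: str) -> ContingencyTable:
        a = sum(1 for i in idx if case_flags[i])
        b = len(idx) - a
        c = n_cases - a
        d = n_total - a - b - c
        return ContingencyTable(a, b, c, d, label=label)

    tables = [
        table_from_index(
            idx, dictionary.display_name(code) if dictionary else code
        )
        for code, idx in sorted(exposed_idx.items())
    ]
    if class_level is not None:
        if dictionary is None:
            raise ValueError("class_level requires a drug dictionary")
        for cls, members in sorted(dictionary.classes_at_level(class_level).items()):
            idx: set[int] = set()
            for code in members:
                idx |= exposed_idx.get(code, set())
            if idx:
                tables.append(table_from_index(idx, label=cls))
    return tables


def tables_to_frame(tables: Iterable[ContingencyTable]) -> pd.DataFrame:
    return pd.DataFrame(
        [{"label": t.label, "a": t.a, "b": t.b, "c": t.c, "d": t.d} for t in tables]
    )


def export_tables(tables: Iterable[ContingencyTable], path: str | Path) -> None:
    """Write tables as a delimited file: label, a, b, c, d."""
    tables_to_frame(tables).to_csv(path, index=False)
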