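"""Data model and line-listing I/O for individual case safety reports (ICSRs).

A spontaneous report carries one or more drugs and one or more reaction
terms, plus demographics, seriousness flags, an outcome and a time to
onset.  Reports are the counting unit throughout the package: a report
mentioning a drug twice still counts once, matching how spontaneous-report
databases present "number of reports".

The canonical on-disk format is a UTF-8 comma-delimited line listing with
a header row; multi-valued cells (drug codes, reaction terms) use a
semicolon intra-cell separator so commas stay reserved for field
separation.  "unknown" is an explicit category rather than an absence, so
denominators over known values remain computable and auditable.
"""
from __future__ import annotations

import csv
import logging

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Optional

logger = logging.getLogger("pvsignal")

UNKNOWN = "unknown"
INTRA_CELL_SEP = ";"

AGE_GROUPS = ("<=23mo", "2-11y", "12-17y", "18-44y", "45-64y", "65-74y", ">=75y", UNKNOWN)
SEXES = ("male", "female", UNKNOWN)
REPORTERS = ("physician", "pharmacist", "other_health", "lawyer", "consumer", UNKNOWN)
OUTCOMES = ("recovered", "recovering_or_sequelae", "not_recovered", UNKNOWN)

#: Canonical line-listing header, in order.
COLUMNS = (
    "report_id",
    "drug_codes",
    "reaction_terms",
    "age_group",
    "sex",
    "country",
    "reporter",
    "serious",
    "fatal",
    "outcome",
    "time_to_onset_days",
)


class LineListingFormatError(ValueError):
    """Raised when a line listing lacks a mandatory column."""


def _check_token(value: str, what: str) -> str:
    if not value:
        raise ValueError(f"{what} must be a non-empty string")
    if INTRA_CELL_SEP in value or "\n" in value or "\r" in value:
        raise ValueError(f"{what} {value!r} may not contain {INTRA_CELL_SEP!r} or newlines")
    return value


@dataclass(frozen=True)
class Report:
    """One individual case safety report.

    ``serious`` and ``fatal`` are tri-state: ``True``/``False``/``None``
    (None = unknown).  A fatal report is necessarily serious.
    """

    report_id: str
    drug_codes: frozenset[str]
    reaction_terms: frozenset[str]
    age_group: str = UNKNOWN
    sex: str = UNKNOWN
    country: str = UNKNOWN
    reporter: str = UNKNOWN
    serious: Optional[bool] = None
    fatal: Optional[bool] = None
    outcome: str = UNKNOWN
    time_to_onset_days: Optional[int] = None

    def __post_init__(self) -> None:
        _check_token(self.report_id, "report_id")
        object.__setattr__(self, "drug_codes", frozenset(self.drug_codes))
        object.__setattr__(self, "reaction_terms", frozenset(self.reaction_terms))
        if not self.drug_codes:
            raise ValueError(f"report {self.report_id}: at least one drug code required")
        if not self.reaction_terms:
            raise ValueError(f"report {self.report_id}: at least one reaction term required")
        for code in self.drug_codes:
            _check_token(code, "drug code")
        for term in self.reaction_terms:
            _check_token(term, "reaction term")
        if self.age_group not in AGE_GROUPS:
            raise ValueError(f"report {self.report_id}: bad age_group {self.age_group!r}")
        if self.sex not in SEXES:
            raise ValueError(f"report {self.report_id}: bad sex {self.sex!r}")
        if self.reporter not in REPORTERS:
            raise ValueError(f"report {self.report_id}: bad reporter {self.reporter!r}")
        if self.outcome not in OUTCOMES:
            raise ValueError(f"report {self.report_id}: bad outcome {self.outcome!r}")
        _check_token(self.country, "country")
        if self.fatal is True and self.serious is not True:
            raise ValueError(f"report {self.report_id}: fatal report must be serious")
        if self.time_to_onset_days is not None and self.time_to_onset_days < 0:
            raise ValueError(f"report {self.report_id}: negative time to onset")

    def n_unknown_fields(self) -> int:
        """How many of the optional fields are unknown/missing (dedup tie-break)."""
        n = 0
        n += self.age_group == UNKNOWN
        n += self.sex == UNKNOWN
        n += self.country == UNKNOWN
        n += self.reporter == UNKNOWN
        n += self.serious is None
        n += self.fatal is None
        n += self.outcome == UNKNOWN
        n += self.time_to_onset_days is None
        return n


@dataclass
class ReportSet:
    """An ordered collection of reports with free-text provenance.

    Uniqueness of ``report_id`` is only guaranteed after :func:`deduplicate`;
    a freshly parsed line listing may legitimately contain duplicates.
    """

    reports: list[Report] = field(default_factory=list)
    provenance: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.reports)

    def __iter__(self) -> Iterator[Report]:
        return iter(self.reports)

    def __getitem__(self, i):
        return self.reports[i]

    def report_ids(self) -> list[str]:
        return [r.report_id for r in self.reports]

    def all_drug_codes(self) -> set[str]:
        out: set[str] = set()
        for r in self.reports:
            out |= r.drug_codes
        return out

    def all_reaction_terms(self) -> set[str]:
        out: set[str] = set()
        for r in self.reports:
            out |= r.reaction_terms
        return out


# ---------------------------------------------------------------------------
# drug dictionary

@dataclass(frozen=True)
class DrugDictionaryEntry:
    """Maps a drug code to a display name and an ATC-style class path.

    ``atc_path`` runs from the anatomical main group (level 1) down to the
    substance, e.g. ``("alimentary tract and metabolism",
    "drugs for acid related disorders", "proton pump inhibitors",
    "omeprazole")``.
    """

    drug_code: str
    display_name: str
    atc_path: tuple[str, ...]

    def __post_init__(self) -> None:
        _check_token(self.drug_code, "drug_code")
        if not self.atc_path:
            raise ValueError(f"{self.drug_code}: atc_path must be non-empty")


class DrugDictionary:
    """Lookup of :class:`DrugDictionaryEntry` by code, with class pooling."""

    def __init__(self, entries: Iterable[DrugDictionaryEntry]):
        self._entries: dict[str, DrugDictionaryEntry] = {}
        for e in entries:
            if e.drug_code in self._entries:
                raise ValueError(f"duplicate drug_code {e.drug_code!r} in dictionary")
            self._entries[e.drug_code] = e

    def __contains__(self, code: str) -> bool:
        return code in self._entries

    def __len__(self) -> int:
        return len(self._entries)

    def __getitem__(self, code: str) -> DrugDictionaryEntry:
        return self._entries[code]

    def get(self, code: str) -> Optional[DrugDictionaryEntry]:
        return self._entries.get(code)

    def display_name(self, code: str) -> str:
        e = self._entries.get(code)
        return e.display_name if e else code

    def class_at_level(self, code: str, level: int) -> Optional[str]:
        """ATC class label at 1-based ``level``; None if the code is
        unknown or its path is shallower than ``level``."""
        e = self._entries.get(code)
        if e is None or len(e.atc_path) < level:
            return None
        return e.atc_path[level - 1]

    def classes_at_level(self, level: int) -> dict[str, set[str]]:
        """Mapping class label -> member drug codes at 1-based ``level``."""
        out: dict[str, set[str]] = {}
        for code, e in self._entries.items():
            if len(e.atc_path) >= level:
                out.setdefault(e.atc_path[level - 1], set()).add(code)
        return out

    @classmethod
    def from_csv(cls, path: str | Path) -> "DrugDictionary":
        with open(path, newline="", encoding="utf-8") as fh:
            reader = csv.DictReader(fh)
            required = {"drug_code", "display_name", "atc_path"}
            missing = required - set(reader.fieldnames or ())
            if missing:
                raise LineListingFormatError(
                    f"drug dictionary missing column(s): {', '.join(sorted(missing))}"
                )
            entries = [
                DrugDictionaryEntry(
                    drug_code=row["drug_code"],
                    display_name=row["display_name"],
                    atc_path=tuple(p for p in row["atc_path"].split("|") if p),
                )
                for row in reader
            ]
        return cls(entries)

    def to_csv(self, path: str | Path) -> None:
        with open(path, "w", newline="", encoding="utf-8") as fh:
            writer = csv.writer(fh)
            writer.writerow(["drug_code", "display_name", "atc_path"])
            for e in self._entries.values():
                writer.writerow([e.drug_code, e.display_name, "|".join(e.atc_path)])


# ---------------------------------------------------------------------------
# line-listing I/O

_TRISTATE_OUT = {True: "true", False: "false", None: UNKNOWN}


def _parse_tristate(cell: str, row_no: int) -> Optional[bool]:
    cell = cell.strip().lower()
    if cell in ("", UNKNOWN):
        return None
    if cell == "true":
        return True
    if cell == "false":
        return False
    raise ValueError(f"row {row_no}: boolean cell must be true/false/unknown, got {cell!r}")


def read_line_listing(path: str | Path, intra_sep: str = INTRA_CELL_SEP) -> ReportSet:
    """Parse a canonical comma-delimited line listing into a :class:`ReportSet`.

    Unknown/empty cells map to the explicit unknown/missing values.  Rows
    lacking any drug code or any reaction term (or otherwise invalid) are
    rejected and logged with their row number; valid rows are preserved in
    file order, duplicates included.

    Raises
    ------
    LineListingFormatError
        If a mandatory column is absent from the header.
    """
    reports: list[Report] = []
    n_rejected = 0
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        missing = set(COLUMNS) - set(reader.fieldnames or ())
        if missing:
            raise LineListingFormatError(
                f"line listing missing mandatory column(s): {', '.join(sorted(missing))}"
            )
        for row_no, row in enumerate(reader, start=2):  # header is row 1
            try:
                reports.append(_row_to_report(row, row_no, intra_sep))
            except ValueError as exc:
                n_rejected += 1
                logger.warning("rejected line-listing row %d: %s", row_no, exc)
    return ReportSet(
        reports,
        provenance={"source": str(path), "n_rows_rejected": n_rejected},
    )


def _row_to_report(row: dict, row_no: int, intra_sep: str) -> Report:
    def cell(name: str) -> str:
        v = row.get(name)
        return "" if v is None else v

    def cat(name: str) -> str:
        v = cell(name).strip()
        return v if v else UNKNOWN

    drugs = frozenset(c for c in cell("drug_codes").split(intra_sep) if c)
    terms = frozenset(t for t in cell("reaction_terms").split(intra_sep) if t)
    tto_cell = cell("time_to_onset_days").strip()
    tto = None if tto_cell in ("", UNKNOWN) else int(tto_cell)
    return Report(
        report_id=cell("report_id"),
        drug_codes=drugs,
        reaction_terms=terms,
        age_group=cat("age_group"),
        sex=cat("sex"),
        country=cat("country"),
        reporter=cat("reporter"),
        serious=_parse_tristate(cell("serious"), row_no),
        fatal=_parse_tristate(cell("fatal"), row_no),
        outcome=cat("outcome"),
        time_to_onset_days=tto,
    )


def write_line_listing(rs: ReportSet, path: str | Path, intra_sep: str = INTRA_CELL_SEP) -> None:
    """Write ``rs`` in the canonical schema; read-back equality holds.

    Multi-valued cells are emitted in sorted order so output is a pure
    function of the report contents.
    """
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(COLUMNS)
        for r in rs:
            writer.writerow(
                [
                    r.report_id,
                    intra_sep.join(sorted(r.drug_codes)),
                    intra_sep.join(sorted(r.reaction_terms)),
                    r.age_group,
                    r.sex,
                    r.country,
                    r.reporter,
                    _TRISTATE_OUT[r.serious],
                    _TRISTATE_OUT[r.fatal],
                    r.outcome,
                    "" if r.time_to_onset_days is None else r.time_to_onset_days,
                ]
            )


# ---------------------------------------------------------------------------
# de-duplication and case selection

def deduplicate(rs: ReportSet) -> tuple[ReportSet, int]:
    """Collapse reports sharing a ``report_id`` to a single report.

    Among duplicates the row with the fewest unknown fields wins; ties are
    broken by first occurrence.  Returns the de-duplicated set (in order of
    each id's first occurrence) and the number of removed rows.
    """
    best: dict[str, tuple[int, int, Report]] = {}  # id -> (n_unknown, first_pos, report)
    order: list[str] = []
    for pos, r in enumerate(rs):
        key = r.report_id
        cand = (r.n_unknown_fields(), pos, r)
        if key not in best:
            best[key] = cand
            order.append(key)
        elif cand[0] < best[key][0]:  # strictly fewer unknowns; ties keep first
            best[key] = (cand[0], best[key][1], r)
    kept = [best[k][2] for k in order]
    n_removed = len(rs) - len(kept)
    prov = dict(rs.provenance)
    prov["n_duplicates_removed"] = prov.get("n_duplicates_removed", 0) + n_removed
    return ReportSet(kept, provenance=prov), n_removed


def select_cases(rs: ReportSet, case_terms: Iterable[str]) -> ReportSet:
    """Return the reports whose reaction terms intersect ``case_terms``.

    The input set is unmodified; the returned set preserves report order.
    """
    terms = frozenset(case_terms)
    if not terms:
        raise ValueError("case_terms must be non-empty")
    kept = [r for r in rs if r.reaction_terms & terms]
    prov = dict(rs.provenance)
    prov["case_terms"] = sorted(terms)
    return ReportSet(kept, provenance=prov)
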