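"""Cohort characterization: counts, declared denominators, exact rounding."""
from __future__ import annotations

from collections import Counter

import numpy as np
import pytest

from pvsignal import (
    AGE_GROUPS,
    DrugDictionary,
    DrugDictionaryEntry,
    ReportSet,
    drug_report_shares,
    pct,
    summarize_cohort,
    time_to_onset_summary,
)

from conftest import make_report

CASE_TERM = "tubulointerstitial nephritis"


def cohort_from_age_counts(counts_by_band: dict[str, int], n_unknown: int = 0) -> ReportSet:
    reports, i = [], 0
    for band, cnt in counts_by_band.items():
        for _ in range(cnt):
            reports.append(make_report(f"r{i}", terms=(CASE_TERM,), age_group=band))
            i += 1
    for _ in range(n_unknown):
        reports.append(make_report(f"r{i}", terms=(CASE_TERM,)))
        i += 1
    return ReportSet(reports)


class TestPct:
    @pytest.mark.parametrize(
        "count, denom, expected",
        [
            (1, 16, 6.3),     # 6.25 rounds half away from zero, not to even
            (1, 8, 12.5),
            (1, 3, 33.3),
            (2, 3, 66.7),
            (0, 10, 0.0),
            (10, 10, 100.0),
        ],
    )
    def test_one_decimal_half_away_from_zero(self, count, denom, expected):
        assert pct(count, denom) == expected

    def test_zero_denominator_is_nan(self):
        assert np.isnan(pct(1, 0))


class TestSummarizeCohort:
    def test_age_band_percentages_use_known_age_denominator(self):
        # the seven-band cohort: unknown ages are excluded from the
        # percentage denominator, so the modal band is 4075/11548 = 35.3%
        bands = dict(zip(AGE_GROUPS[:-1], (52, 235, 554, 2143, 4075, 2459, 2030)))
        cohort = cohort_from_age_counts(bands, n_unknown=4148)
        s = summarize_cohort(cohort, {CASE_TERM})
        assert s.age.denominator == 11548
        assert s.age.pcts()["45-64y"] == 35.3
        assert s.age.pcts()["18-44y"] == 18.6
        assert s.n_age_unknown == 4148

    def test_fully_serious_fatal_cohort(self):
        cohort = ReportSet(
            [
                make_report(f"r{i}", terms=(CASE_TERM,), serious=True, fatal=True)
                for i in range(7)
            ]
        )
        s = summarize_cohort(cohort, {CASE_TERM})
        assert s.pct_serious == 100.0 and s.pct_fatal == 100.0

    def test_index_terms_excluded_from_coreported_ranking(self):
        cohort = ReportSet(
            [
                make_report("r1", terms=(CASE_TERM, "acute kidney injury")),
                make_report("r2", terms=(CASE_TERM, "rash")),
                make_report("r3", terms=(CASE_TERM, "acute kidney injury")),
            ]
        )
        s = summarize_cohort(cohort, {CASE_TERM})
        assert CASE_TERM not in s.coreported_terms.counts
        assert list(s.coreported_terms.counts) == ["acute kidney injury", "rash"]
        assert s.coreported_terms.counts["acute kidney injury"] == 2

    def test_matches_brute_force_tallies(self, rng):
        reports = []
        for i in range(1000):
            reports.append(
                make_report(
                    f"r{i}",
                    terms=(CASE_TERM, rng.choice(["aki", "rash", "fever"])),
                    age_group=rng.choice(AGE_GROUPS),
                    sex=rng.choice(["male", "female", "unknown"]),
                    country=rng.choice(["US", "FR", "JP", "unknown"]),
                    reporter=rng.choice(["physician", "consumer", "unknown"]),
                    serious=rng.choice([True, False, None]),
                    outcome=rng.choice(["recovered", "not_recovered", "unknown"]),
                    time_to_onset_days=rng.choice([None, rng.randrange(0, 200)]),
                )
            )
        cohort = ReportSet(reports)
        s = summarize_cohort(cohort, {CASE_TERM}, top_k_countries=5, top_k_terms=5)
        # independent linear tallies
        assert s.n_serious == sum(1 for r in reports if r.serious is True)
        assert s.n_fatal == sum(1 for r in reports if r.fatal is True)
        ages = Counter(r.age_group for r in reports)
        assert s.n_age_unknown == ages["unknown"]
        for band, cnt in s.age.counts.items():
            assert cnt == ages[band]
        countries = Counter(r.country for r in reports if r.country != "unknown")
        assert s.country.counts == dict(countries.most_common(5))
        terms = Counter(
            t for r in reports for t in r.reaction_terms if t != CASE_TERM
        )
        assert sum(s.coreported_terms.counts.values()) == sum(
            v for _, v in terms.most_common(5)
        )
        outcomes = Counter(r.outcome for r in reports if r.outcome != "unknown")
        assert s.outcome.counts == dict(outcomes)
        assert s.n_outcome_known == sum(outcomes.values())

    def test_invariant_to_report_order(self, rng):
        reports = [
            make_report(
                f"r{i}",
                terms=(CASE_TERM, rng.choice(["aki", "rash"])),
                age_group=rng.choice(AGE_GROUPS),
                time_to_onset_days=rng.randrange(100),
            )
            for i in range(200)
        ]
        shuffled = reports[:]
        rng.shuffle(shuffled)
        s1 = summarize_cohort(ReportSet(reports), {CASE_TERM})
        s2 = summarize_cohort(ReportSet(shuffled), {CASE_TERM})
        assert s1.to_dict() == s2.to_dict()

    def test_percentages_over_known_values_sum_to_100(self, rng):
        reports = [
            make_report(
                f"r{i}",
                terms=(CASE_TERM,),
                age_group=rng.choice(AGE_GROUPS),
                outcome=rng.choice(["recovered", "recovering_or_sequelae", "not_recovered", "unknown"]),
            )
            for i in range(500)
        ]
        s = summarize_cohort(ReportSet(reports), {CASE_TERM})
        assert sum(s.age.pcts().values()) == pytest.approx(100, abs=0.2)
        assert sum(s.outcome.pcts().values()) == pytest.approx(100, abs=0.2)


class TestTimeToOnset:
    def test_single_value(self):
        rs = ReportSet([make_report("r1", time_to_onset_days=10)])
        assert time_to_onset_summary(rs) == (10.0, 10.0, 10.0, 1)

    def test_odd_length_closed_form(self):
        rs = ReportSet(
            [make_report(f"r{i}", time_to_onset_days=v) for i, v in enumerate([1, 2, 3, 4, 5])]
        )
        assert time_to_onset_summary(rs) == (3.0, 2.0, 4.0, 5)

    def test_no_known_values_not_estimable(self):
        rs = ReportSet([make_report("r1")])
        assert time_to_onset_summary(rs) == (None, None, None, 0)

    def test_agrees_with_reference_quantile_routine(self, rng):
        values = [int(rng.lognormvariate(3, 1.2)) for _ in range(400)]
        rs = ReportSet(
            [make_report(f"r{i}", time_to_onset_days=v) for i, v in enumerate(values)]
        )
        med, q1, q3, n = time_to_onset_summary(rs)
        ref = np.percentile(values, [25, 50, 75], method="linear")
        assert (q1, med, q3) == pytest.approx(tuple(ref), abs=1e-9)
        assert n == 400


class TestDrugReportShares:
    @pytest.fixture
    def dictionary(self):
        return DrugDictionary(
            [
                DrugDictionaryEntry("ome", "Omeprazole", ("alimentary", "acid", "ppi", "ome")),
                DrugDictionaryEntry("lan", "Lansoprazole", ("alimentary", "acid", "ppi", "lan")),
                DrugDictionaryEntry("cip", "Ciprofloxacin", ("antiinfectives", "abx", "fq", "cip")),
            ]
        )

    def test_substance_counts_and_shares(self, dictionary):
        cohort = ReportSet(
            [
                make_report("r1", drugs=("ome",), terms=(CASE_TERM,)),
                make_report("r2", drugs=("ome", "cip"), terms=(CASE_TERM,)),
                make_report("r3", drugs=("lan",), terms=(CASE_TERM,)),
                make_report("r4", drugs=("cip",), terms=(CASE_TERM,)),
            ]
        )
        table = drug_report_shares(cohort, dictionary)
        assert list(table.label) == ["Ciprofloxacin", "Omeprazole", "Lansoprazole"]
        assert list(table["count"]) == [2, 2, 1]
        assert list(table.pct) == [50.0, 50.0, 25.0]

    def test_class_level_counts_union_not_sum(self, dictionary):
        cohort = ReportSet(
            [
                make_report("r1", drugs=("ome", "lan"), terms=(CASE_TERM,)),
                make_report("r2", drugs=("cip",), terms=(CASE_TERM,)),
            ]
        )
        table = drug_report_shares(cohort, dictionary, level=3)
        row = table[table.label == "ppi"].iloc[0]
        assert row["count"] == 1 and row["pct"] == 50.0

    def test_class_share_bounds(self, rng):
        dictionary = DrugDictionary(
            [DrugDictionaryEntry(f"d{i}", f"d{i}", ("grp", f"d{i}")) for i in range(4)]
        )
        cohort = ReportSet(
            [
                make_report(
                    f"r{i}",
                    drugs=rng.sample([f"d{j}" for j in range(4)], rng.randrange(1, 4)),
                    terms=(CASE_TERM,),
                )
                for i in range(120)
            ]
        )
        substances = drug_report_shares(cohort, dictionary)
        classes = drug_report_shares(cohort, dictionary, level=1)
        class_count = classes.iloc[0]["count"]
        assert class_count >= substances["count"].max()
        assert class_count <= substances["count"].sum()

    def test_matches_union_count_oracle(self, rng):
        dictionary = DrugDictionary(
            [
                DrugDictionaryEntry(f"d{i}", f"d{i}", (f"grp{i % 3}", f"d{i}"))
                for i in range(9)
            ]
        )
        cohort = ReportSet(
            [
                make_report(
                    f"r{i}",
                    drugs=rng.sample([f"d{j}" for j in range(9)], rng.randrange(1, 5)),
                    terms=(CASE_TERM,),
                )
                for i in range(300)
            ]
        )
        classes = drug_report_shares(cohort, dictionary, level=1)
        for grp in ("grp0", "grp1", "grp2"):
            members = {f"d{i}" for i in range(9) if i % 3 == int(grp[-1])}
            union = {r.report_id for r in cohort if set(r.drug_codes) & members}
            assert classes.set_index("label").loc[grp, "count"] == len(union)
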