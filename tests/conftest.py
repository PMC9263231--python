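from __future__ import annotations

import random
import string

import pytest
from hypothesis import strategies as st

from pvsignal import (
    AGE_GROUPS,
    OUTCOMES,
    REPORTERS,
    SEXES,
    UNKNOWN,
    Report,
    ReportSet,
)

# token alphabet avoids the intra-cell separator and newlines, which the
# data model itself forbids; commas and quotes are allowed (CSV handles them)
_TOKEN_ALPHABET = string.ascii_letters + string.digits + " _-.,/()'"


def token_strategy(min_size: int = 1, max_size: int = 20):
    return st.text(alphabet=_TOKEN_ALPHABET, min_size=min_size, max_size=max_size).filter(
        lambda s: s.strip() == s and s != ""
    )


@st.composite
def reports(draw, report_id=None):
    tri = st.sampled_from([True, False, None])
    serious = draw(tri)
    fatal = draw(st.sampled_from([False, None])) if serious is not True else draw(tri)
    return Report(
        report_id=report_id if report_id is not None else draw(token_strategy(1, 12)),
        drug_codes=frozenset(draw(st.sets(token_strategy(), min_size=1, max_size=4))),
        reaction_terms=frozenset(draw(st.sets(token_strategy(), min_size=1, max_size=4))),
        age_group=draw(st.sampled_from(AGE_GROUPS)),
        sex=draw(st.sampled_from(SEXES)),
        country=draw(st.one_of(st.just(UNKNOWN), token_strategy(2, 3))),
        reporter=draw(st.sampled_from(REPORTERS)),
        serious=serious,
        fatal=fatal,
        outcome=draw(st.sampled_from(OUTCOMES)),
        time_to_onset_days=draw(st.one_of(st.none(), st.integers(0, 10_000))),
    )


@st.composite
def report_sets(draw, min_size: int = 0, max_size: int = 20):
    n = draw(st.integers(min_size, max_size))
    rs = [draw(reports(report_id=f"id{i:04d}")) for i in range(n)]
    return ReportSet(rs)


def make_report(rid: str, drugs=("D1",), terms=("E1",), **kw) -> Report:
    return Report(
        report_id=rid,
        drug_codes=frozenset(drugs),
        reaction_terms=frozenset(terms),
        **kw,
    )


@pytest.fixture
def rng():
    return random.Random(20_260_928)
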