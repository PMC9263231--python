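"""Seeded generator of synthetic spontaneous-reporting databases.

The generator emulates the statistical structure a database-wide
disproportionality analysis assumes: many reports, each exposed to one or
more drugs (independent Bernoulli draws per drug) and carrying one or more
reaction terms, where a configured (drug, event) "signal" multiplies the
event's baseline reporting probability by a relative reporting rate.
Demographics, seriousness, outcome and a log-normal time to onset are
drawn independently per report.  Ground truth (which pairs are associated
and at what rate, and which signals fired on each report) is returned
alongside, enabling parameter-recovery tests of the estimators.

Modelling notes
---------------
* Drug co-prescription is independent Bernoulli per drug; exposure
  correlation is out of scope — it changes margins, not the estimators
  under test here.
* For a report exposed to several signal drugs for the same event, the
  maximum configured rate applies ("strongest association dominates").
* The >=1 drug / >=1 event guarantee is enforced by capped resampling.
  This conditions marginals upward by a factor of about
  1/(1 - P(zero draws)); keep the configured probability of an empty draw
  small (the generator warns above 1%) so empirical marginals track the
  configured ones.
* Fatality is drawn only among serious reports, so fatal implies serious
  by construction.
"""
from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from .report_store import (
    AGE_GROUPS,
    OUTCOMES,
    REPORTERS,
    SEXES,
    UNKNOWN,
    Report,
    ReportSet,
)

_RESAMPLE_CAP = 1000


@dataclass
class CategoricalField:
    """A categorical demographic distribution with explicit missingness.

    ``dist`` is over known categories and must sum to 1; with probability
    ``missing_prob`` the field is recorded as unknown instead.
    """

    dist: dict[str, float]
    missing_prob: float = 0.0

    def validate(self, name: str, allowed: Optional[Sequence[str]] = None) -> None:
        if not 0.0 <= self.missing_prob <= 1.0:
            raise ValueError(f"{name}: missing_prob outside [0,1]")
        if not self.dist:
            raise ValueError(f"{name}: empty distribution")
        total = sum(self.dist.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"{name}: distribution sums to {total}, not 1")
        for cat, p in self.dist.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name}: probability for {cat!r} outside [0,1]")
            if allowed is not None and cat not in allowed:
                raise ValueError(f"{name}: category {cat!r} not in {allowed}")


@dataclass
class SimConfig:
    """Full parameterization of a synthetic spontaneous-reporting system.

    ``drugs`` maps drug code -> marginal exposure probability; ``events``
    maps reaction term -> baseline reporting probability; ``signals`` is a
    list of (drug, event, relative reporting rate) triples, rate 1 meaning
    "no association".  One global ``seed`` drives a single reproducible
    stream: identical configs produce byte-identical line listings.
    """

    n_reports: int
    drugs: dict[str, float]
    events: dict[str, float]
    signals: list[tuple[str, str, float]] = field(default_factory=list)
    age_group: CategoricalField = field(
        default_factory=lambda: CategoricalField({"18-44y": 0.3, "45-64y": 0.4, ">=75y": 0.3})
    )
    sex: CategoricalField = field(
        default_factory=lambda: CategoricalField({"male": 0.5, "female": 0.5})
    )
    country: CategoricalField = field(default_factory=lambda: CategoricalField({"US": 1.0}))
    reporter: CategoricalField = field(
        default_factory=lambda: CategoricalField({"physician": 1.0})
    )
    seriousness_prob: float = 0.5
    fatality_prob_given_serious: float = 0.05
    outcome_dist: dict[str, float] = field(
        default_factory=lambda: {
            "recovered": 0.3,
            "recovering_or_sequelae": 0.2,
            "not_recovered": 0.2,
            UNKNOWN: 0.3,
        }
    )
    tto_log_mean: float = math.log(20.0)
    tto_log_sd: float = 2.45
    tto_missing_prob: float = 0.3
    seed: int = 0

    # -- validation ---------------------------------------------------------
    def validate(self) -> None:
        if self.n_reports <= 0:
            raise ValueError("n_reports must be positive")
        if not self.drugs or not self.events:
            raise ValueError("at least one drug and one event required")
        for code, p in self.drugs.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"drug {code!r}: exposure probability outside [0,1]")
        for term, p in self.events.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"event {term!r}: baseline probability outside [0,1]")
        for d, e, r in self.signals:
            if d not in self.drugs:
                raise ValueError(f"signal references undeclared drug {d!r}")
            if e not in self.events:
                raise ValueError(f"signal references undeclared event {e!r}")
            if r < 0:
                raise ValueError(f"signal ({d},{e}): rate must be >= 0")
        self.age_group.validate("age_group", AGE_GROUPS)
        self.sex.validate("sex", SEXES)
        self.country.validate("country")
        self.reporter.validate("reporter", REPORTERS)
        for name, p in (
            ("seriousness_prob", self.seriousness_prob),
            ("fatality_prob_given_serious", self.fatality_prob_given_serious),
            ("tto_missing_prob", self.tto_missing_prob),
        ):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} outside [0,1]")
        total = sum(self.outcome_dist.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"outcome_dist sums to {total}, not 1")
        for cat in self.outcome_dist:
            if cat not in OUTCOMES:
                raise ValueError(f"outcome_dist: bad category {cat!r}")
        if self.tto_log_sd < 0:
            raise ValueError("tto_log_sd must be >= 0")
        for name, probs in (("drug", self.drugs.values()), ("event", self.events.values())):
            p_empty = float(np.exp(np.sum(np.log1p(-np.minimum(list(probs), 1 - 1e-12)))))
            if p_empty > 0.01:
                warnings.warn(
                    f"P(report with zero {name}s) = {p_empty:.3f} > 1%; the >=1 "
                    f"resampling guarantee will noticeably inflate {name} marginals",
                    stacklevel=2,
                )

    # -- (de)serialisation --------------------------------------------------
    def to_dict(self) -> dict:
        d = asdict(self)
        d["signals"] = [list(s) for s in self.signals]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        d = dict(d)
        for f in ("age_group", "sex", "country", "reporter"):
            if f in d and isinstance(d[f], dict):
                d[f] = CategoricalField(**d[f])
        d["signals"] = [tuple(s) for s in d.get("signals", [])]
        return cls(**d)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimConfig":
        with open(path, encoding="utf-8") as fh:
            return cls.from_dict(yaml.safe_load(fh))


@dataclass
class GroundTruth:
    """Configured pairwise rates plus the signals that fired per report."""

    rates: dict[tuple[str, str], float]  # every (drug, event) pair
    fired: dict[str, list[tuple[str, str]]]  # report_id -> signal pairs present

    def rate(self, drug: str, event: str) -> float:
        return self.rates.get((drug, event), 1.0)


def summarize_truth(gt: GroundTruth) -> pd.DataFrame:
    """One row per (drug, event) pair with its configured relative rate."""
    rows = [
        {"drug_code": d, "reaction_term": e, "relative_rate": r}
        for (d, e), r in sorted(gt.rates.items())
    ]
    return pd.DataFrame(rows, columns=["drug_code", "reaction_term", "relative_rate"])


def truth_to_csv(gt: GroundTruth, path: str | Path) -> None:
    summarize_truth(gt).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# generation

def _resample_until_nonempty(
    rng: np.random.Generator, draw, mask_empty, what: str
) -> np.ndarray:
    """Redraw rows of a boolean matrix until every row has >=1 True."""
    x = draw(None)
    for _ in range(_RESAMPLE_CAP):
        empty = mask_empty(x)
        if not empty.any():
            return x
        x[empty] = draw(empty)
    raise RuntimeError(
        f"could not draw >=1 {what} per report within {_RESAMPLE_CAP} resampling "
        f"rounds; the configured probabilities are degenerate"
    )


def _draw_categorical(
    rng: np.random.Generator, fld: CategoricalField, n: int
) -> np.ndarray:
    cats = np.array(list(fld.dist.keys()), dtype=object)
    probs = np.array(list(fld.dist.values()), dtype=float)
    probs = probs / probs.sum()  # guard residual float error
    out = rng.choice(cats, size=n, p=probs)
    if fld.missing_prob > 0:
        out = np.where(rng.random(n) < fld.missing_prob, UNKNOWN, out)
    return out


def generate_reports(cfg: SimConfig) -> tuple[ReportSet, GroundTruth]:
    """Draw a synthetic report database and its ground truth.

    Exactly ``cfg.n_reports`` reports are produced.  P(event e | exposure
    to drug d alone) equals ``baseline(e) * rate(d, e)`` capped at 1; with
    several signal drugs on the report the maximum rate applies.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_reports
    drug_names = list(cfg.drugs)
    event_names = list(cfg.events)
    p_drug = np.array([cfg.drugs[d] for d in drug_names])
    base = np.array([cfg.events[e] for e in event_names])
    d_idx = {d: i for i, d in enumerate(drug_names)}
    e_idx = {e: i for i, e in enumerate(event_names)}

    # drug exposures
    def draw_drugs(empty):
        rows = n if empty is None else int(empty.sum())
        return rng.random((rows, len(drug_names))) < p_drug

    X = _resample_until_nonempty(rng, draw_drugs, lambda x: ~x.any(axis=1), "drug")

    # per-report event probabilities: baseline times max rate among exposed signal drugs
    factor = np.ones((n, len(event_names)))
    has_sig = np.zeros((n, len(event_names)), dtype=bool)
    for d, e, r in cfg.signals:
        exposed = X[:, d_idx[d]]
        j = e_idx[e]
        sel = exposed & has_sig[:, j]
        factor[sel, j] = np.maximum(factor[sel, j], r)
        fresh = exposed & ~has_sig[:, j]
        factor[fresh, j] = r
        has_sig[exposed, j] = True
    p_event = np.minimum(base * factor, 1.0)

    def draw_events(empty):
        if empty is None:
            return rng.random((n, len(event_names))) < p_event
        return rng.random((int(empty.sum()), len(event_names))) < p_event[empty]

    Y = _resample_until_nonempty(rng, draw_events, lambda y: ~y.any(axis=1), "event")

    # demographics and clinical fields
    age = _draw_categorical(rng, cfg.age_group, n)
    sex = _draw_categorical(rng, cfg.sex, n)
    country = _draw_categorical(rng, cfg.country, n)
    reporter = _draw_categorical(rng, cfg.reporter, n)
    serious = rng.random(n) < cfg.seriousness_prob
    fatal = serious & (rng.random(n) < cfg.fatality_prob_given_serious)
    out_cats = np.array(list(cfg.outcome_dist.keys()), dtype=object)
    out_probs = np.array(list(cfg.outcome_dist.values()), dtype=float)
    outcome = rng.choice(out_cats, size=n, p=out_probs / out_probs.sum())
    tto = np.rint(rng.lognormal(cfg.tto_log_mean, cfg.tto_log_sd, n)).astype(np.int64)
    tto_missing = rng.random(n) < cfg.tto_missing_prob

    width = max(6, len(str(n)))
    drug_arr = np.array(drug_names, dtype=object)
    event_arr = np.array(event_names, dtype=object)
    reports: list[Report] = []
    fired: dict[str, list[tuple[str, str]]] = {}
    signal_pairs = [(d, e, r) for d, e, r in cfg.signals if r != 1.0]
    for i in range(n):
        rid = f"R{i:0{width}d}"
        codes = frozenset(drug_arr[X[i]])
        terms = frozenset(event_arr[Y[i]])
        reports.append(
            Report(
                report_id=rid,
                drug_codes=codes,
                reaction_terms=terms,
                age_group=age[i],
                sex=sex[i],
                country=country[i],
                reporter=reporter[i],
                serious=bool(serious[i]),
                fatal=bool(fatal[i]),
                outcome=outcome[i],
                time_to_onset_days=None if tto_missing[i] else int(tto[i]),
            )
        )
        hits = [(d, e) for d, e, _ in signal_pairs if d in codes and e in terms]
        if hits:
            fired[rid] = hits

    rates = {(d, e): 1.0 for d in drug_names for e in event_names}
    for d, e, r in cfg.signals:
        rates[(d, e)] = float(r)
    rs = ReportSet(reports, provenance={"source": "pvsignal.simulate", "seed": cfg.seed})
    return rs, GroundTruth(rates=rates, fired=fired)


# ---------------------------------------------------------------------------
# study-shaped default configuration

#: Reaction term used as the index case definition in the default config.
INDEX_EVENT = "tubulointerstitial nephritis"


def default_study_config(seed: int = 0, n_reports: int = 50_000) -> SimConfig:
    """A default reporting system shaped like a drug-induced nephritis study.

    Demographics, seriousness, fatality, outcome mix and the time-to-onset
    distribution mirror a large renal-safety case series (about 80% serious,
    6% fatal, median onset 20 days with a wide right-skewed spread, roughly
    a quarter of reports missing age, half the outcomes unknown).  The drug
    panel carries acid-suppressant, antibiotic, NSAID and checkpoint-
    inhibitor exposures with injected nephritis signals of graded strength
    over a backbone of common drugs and common reaction terms.  The common
    backbone keeps the probability of an empty drug or event draw below
    0.5%, so the >=1 resampling guarantee leaves marginals essentially
    uninflated (reports average ~5 drugs and ~5 terms; real spontaneous
    reports are sparser, which does not affect the pairwise estimators).
    """
    background_drugs = {
        f"bg_drug_{i:02d}": p
        for i, p in enumerate(
            [0.40, 0.38, 0.35, 0.35, 0.33, 0.32, 0.30, 0.30, 0.28, 0.28,
             0.26, 0.25, 0.25, 0.22, 0.20, 0.20]
        )
    }
    panel_drugs = {
        "omeprazole": 0.040,
        "lansoprazole": 0.020,
        "esomeprazole": 0.020,
        "pantoprazole": 0.015,
        "ciprofloxacin": 0.030,
        "vancomycin": 0.010,
        "ibuprofen": 0.060,
        "diclofenac": 0.030,
        "mesalazine": 0.005,
        "nivolumab": 0.004,
        "amoxicillin": 0.050,
        "flucloxacillin": 0.003,
    }
    background_events = {
        f"bg_event_{i:02d}": p
        for i, p in enumerate(
            [0.38, 0.36, 0.34, 0.34, 0.32, 0.32, 0.30, 0.30, 0.28, 0.28,
             0.26, 0.26, 0.24, 0.24, 0.22, 0.20]
        )
    }
    specific_events = {
        INDEX_EVENT: 0.002,
        "acute kidney injury": 0.020,
        "chronic kidney disease": 0.010,
        "eosinophilia": 0.004,
    }
    signals = [
        ("omeprazole", INDEX_EVENT, 60.0),
        ("lansoprazole", INDEX_EVENT, 100.0),
        ("esomeprazole", INDEX_EVENT, 60.0),
        ("pantoprazole", INDEX_EVENT, 75.0),
        ("ciprofloxacin", INDEX_EVENT, 8.0),
        ("vancomycin", INDEX_EVENT, 10.0),
        ("ibuprofen", INDEX_EVENT, 5.0),
        ("diclofenac", INDEX_EVENT, 3.5),
        ("mesalazine", INDEX_EVENT, 35.0),
        ("nivolumab", INDEX_EVENT, 10.0),
        ("flucloxacillin", INDEX_EVENT, 30.0),
        ("amoxicillin", INDEX_EVENT, 2.0),
        ("ibuprofen", "acute kidney injury", 5.0),
        ("vancomycin", "acute kidney injury", 4.0),
    ]
    # age bands among known ages, with about a quarter of ages missing
    age = CategoricalField(
        dist={
            "<=23mo": 52 / 11548,
            "2-11y": 235 / 11548,
            "12-17y": 554 / 11548,
            "18-44y": 2143 / 11548,
            "45-64y": 4075 / 11548,
            "65-74y": 2459 / 11548,
            ">=75y": 2030 / 11548,
        },
        missing_prob=4148 / 15696,
    )
    sex = CategoricalField(dist={"male": 0.531, "female": 0.469}, missing_prob=0.174)
    country = CategoricalField(
        dist={
            "US": 0.507, "JP": 0.080, "GB": 0.063, "FR": 0.062, "AU": 0.045,
            "ES": 0.033, "DE": 0.031, "CA": 0.028, "SE": 0.016, "CH": 0.015,
            "other": 0.120,
        }
    )
    reporter = CategoricalField(
        dist={
            "physician": 6062 / 12393,
            "pharmacist": 1487 / 12393,
            "other_health": 2118 / 12393,
            "lawyer": 1175 / 12393,
            "consumer": 1551 / 12393,
        },
        missing_prob=3671 / 15696,
    )
    return SimConfig(
        n_reports=n_reports,
        drugs={**background_drugs, **panel_drugs},
        events={**background_events, **specific_events},
        signals=signals,
        age_group=age,
        sex=sex,
        country=country,
        reporter=reporter,
        seriousness_prob=12481 / 15696,
        fatality_prob_given_serious=977 / 12481,
        outcome_dist={
            "recovered": 3019 / 15696,
            "recovering_or_sequelae": 2526 / 15696,
            "not_recovered": 2676 / 15696,
            UNKNOWN: 7475 / 15696,
        },
        tto_log_mean=math.log(20.0),
        tto_log_sd=2.45,
        tto_missing_prob=0.35,
        seed=seed,
    )


def default_drug_dictionary():
    """Dictionary with ATC-style paths for the default study drug panel."""
    from .report_store import DrugDictionary, DrugDictionaryEntry

    A = "alimentary tract and metabolism"
    J = "antiinfectives for systemic use"
    M = "musculo-skeletal system"
    L = "antineoplastic and immunomodulating agents"
    PPI = (A, "drugs for acid related disorders", "proton pump inhibitors")
    entries = [
        DrugDictionaryEntry("omeprazole", "Omeprazole", PPI + ("omeprazole",)),
        DrugDictionaryEntry("lansoprazole", "Lansoprazole", PPI + ("lansoprazole",)),
        DrugDictionaryEntry("esomeprazole", "Esomeprazole", PPI + ("esomeprazole",)),
        DrugDictionaryEntry("pantoprazole", "Pantoprazole", PPI + ("pantoprazole",)),
        DrugDictionaryEntry("mesalazine", "Mesalazine", (A, "antiinflammatory intestinal agents", "aminosalicylic acid and similar agents", "mesalazine")),
        DrugDictionaryEntry("ciprofloxacin", "Ciprofloxacin", (J, "antibacterials for systemic use", "fluoroquinolones", "ciprofloxacin")),
        DrugDictionaryEntry("amoxicillin", "Amoxicillin", (J, "antibacterials for systemic use", "beta-lactam antibacterials, penicillins", "amoxicillin")),
        DrugDictionaryEntry("flucloxacillin", "Flucloxacillin", (J, "antibacterials for systemic use", "beta-lactam antibacterials, penicillins", "flucloxacillin")),
        DrugDictionaryEntry("vancomycin", "Vancomycin", (J, "antibacterials for systemic use", "glycopeptide antibacterials", "vancomycin")),
        DrugDictionaryEntry("ibuprofen", "Ibuprofen", (M, "antiinflammatory and antirheumatic products", "propionic acid derivatives", "ibuprofen")),
        DrugDictionaryEntry("diclofenac", "Diclofenac", (M, "antiinflammatory and antirheumatic products", "acetic acid derivatives", "diclofenac")),
        DrugDictionaryEntry("nivolumab", "Nivolumab", (L, "antineoplastic agents", "PD-1/PDL-1 inhibitors", "nivolumab")),
    ]
    for i in range(16):
        entries.append(
            DrugDictionaryEntry(
                f"bg_drug_{i:02d}", f"Background drug {i:02d}",
                ("various", "background", f"bg_drug_{i:02d}"),
            )
        )
    return DrugDictionary(entries)
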