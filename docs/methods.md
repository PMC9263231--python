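# Methods

## Data model and counting conventions

An individual case safety report (ICSR) carries a unique report id, one
or more drug codes, one or more reaction terms, demographics (age band,
sex, country, reporter qualification), seriousness and fatality flags, an
outcome, and a time to onset in days. Reports are the counting unit
everywhere: a report mentioning a drug twice, or two members of the same
ATC class, contributes one exposed report. "Unknown" is an explicit
category rather than an absence, so each percentage can declare its
denominator (all reports vs. known values) and be re-derived exactly.

Age is modelled as seven ordinal bands (≤23 mo, 2–11 y, 12–17 y, 18–44 y,
45–64 y, 65–74 y, ≥75 y) because case-series tables report bands, not a
continuous age. `fatal = true` implies `serious = true`; the generator
enforces this by drawing fatality only among serious reports, and the
data model rejects violations on construction.

The canonical line listing is UTF-8 CSV with a header row; multi-valued
cells use a semicolon intra-cell separator (commas stay reserved for
field separation, avoiding quoting ambiguity in drug names); booleans are
the literals `true`/`false`/`unknown`, and a missing time to onset is an
empty cell. Tokens (ids, codes, terms) may not contain the intra-cell
separator — this is validated, which is what makes the write→read round
trip lossless for arbitrary valid report sets.

De-duplication keeps, per report id, the row with the fewest
unknown/missing fields, ties broken by first occurrence, and reports the
number of rows removed. The procedure used by the original database
operator is not public; fewest-unknowns is this package's own rule, is
idempotent, and biases retention toward the most informative record.

## Disproportionality statistics

For a case definition and a drug (or pooled class), the 2×2 table
(a, b, c, d) partitions the de-duplicated database; by construction
a+c equals the case-cohort size and a+b+c+d the database size, asserted
on every output. The comparator is always the rest of the whole
database; restricted comparators and stratified tables are out of scope.

**ROR.** ad/bc with the Woolf (log-odds normal) CI,
exp(ln ROR ± z₁₋α/₂·√(1/a+1/b+1/c+1/d)), α = 0.05 by default. A zero
cell triggers the Haldane–Anscombe correction (+0.5 to all four cells)
and an explicit `corrected` flag. A drug absent from (a+b = 0) or
universal in (c+d = 0) the database yields a not-estimable marker rather
than a number. Multiplying all cells by k leaves the ROR unchanged and
narrows the CI — a property test.

**IC.** The default is the shrinkage observed-to-expected formulation:
with E = (a+b)(a+c)/N, IC = log₂((a+½)/(E+½)) and IC025 = log₂ q₀.₀₂₅ of
Gamma(shape a+½, rate E+½). The +½ shrinkage keeps every table estimable
(including a = 0) and bounds IC below the unshrunk log₂(a/E) whenever
a > E; as a → ∞ at fixed a/E the credibility gap vanishes. The gamma
quantile is validated against an independent Monte-Carlo oracle (10⁶
gamma draws, empirical 2.5% quantile) to within 0.02 bits over a 16-point
grid of (a, E). The legacy BCPNN normal approximation (digamma/trigamma
posterior moments of the beta-binomial model) is available via
`method="legacy_bcpnn"`; the two agree closely for large counts. Which
formulation a given published case series used is generally not stated,
so its drug-level IC025 values should not be treated as reproducible —
only the screening behaviour is.

**Screening and ranking.** `is_signal ⇔ IC025 > 0 and n ≥ 30` (both
thresholds configurable); ranking is a stable descending sort by report
count or ROR with alphabetical tie-break, so output order is
deterministic. Expected counts use in-sample margins only — no external
reference rates. No multiple-testing adjustment is applied, deliberately:
the rule is a screen whose operating characteristics (coverage, recovery)
are what the tests measure, not a family-wise error guarantee.

One limitation: the line-listing schema has no drug-role field
(suspected/concomitant), so all drug mentions count as exposure and no
role-restricted sensitivity analysis is possible on this schema.

## Synthetic reporting-system generator

Each of n reports draws: drug exposures as independent Bernoulli per
drug; reaction terms as independent Bernoulli per event with
P(event e) = baseline(e) × rate(d, e) capped at 1, where rate comes from
the configured signal list (rate 1 = no association); demographics from
categorical distributions with explicit missingness probabilities;
seriousness ~ Bernoulli, fatality ~ Bernoulli among serious only;
outcome from a four-category distribution including unknown; time to
onset as a rounded log-normal with a missingness probability. One global
seed drives a single numpy Generator stream, so identical configurations
produce byte-identical line listings.

Choices made where the mechanism was open:

* **Several signal drugs on one report**: the maximum configured rate
  among exposed drugs applies — the strongest association dominates; the
  effects do not stack multiplicatively.
* **≥1 drug / ≥1 event** is guaranteed by capped resampling (1000
  rounds, then a hard error for degenerate configurations). Conditioning
  on a non-empty draw inflates marginals by ≈ 1/(1 − P(empty draw)); all
  shipped configurations keep P(empty draw) ≲ 0.5% via a backbone of
  common background drugs and events, so configured and empirical
  marginals agree within 3 binomial standard errors at n = 50,000, and
  `SimConfig.validate` warns when a configuration exceeds 1%. The
  backbone makes simulated reports drug- and term-richer (≈5 each) than
  typical real reports; this affects sparsity, not the pairwise 2×2
  estimators under test.
* **No exposure correlation, no syndrome correlation, no reporting
  dynamics**: drugs are independent given the margins and events are
  independent given drugs, because the statistics under test treat each
  drug–event pair marginally. Consequently passing tests say nothing
  about masking by correlated co-medication, duplicate submission waves,
  or secular reporting trends in real data — only about estimator
  correctness under the stated mechanism.

The default study-shaped configuration mirrors a large renal-safety case
series: age bands (modal band 45–64 y ≈ 35% of known ages, ≈26% of ages
missing), sex ≈53% male among known, country mix dominated by one large
contributor (≈51%), ≈79.5% serious with ≈7.8% fatality among serious,
half of outcomes unknown and roughly even thirds among known, and a
log-normal time to onset with median 20 days. The log-sd 2.45 was set so
the theoretical quartiles (≈3.9, ≈104 days) bracket a 5–103-day
interquartile range; the simulated median at n ≥ 10,000 falls in
[15, 26]. The injected signal panel spans rates 2–100 on a
rare index event (baseline 0.002), emulating associations from weak
(NSAIDs) to very strong (acid suppressants).

**Calibration oracle.** baseline × rate is the exact conditional event
probability only given exposure to the drug *without* co-exposure to
another drug carrying a signal on the same event; co-exposure to a
rate-10 drug legitimately inflates the raw conditional frequency
(confounding the generator reproduces by design). Calibration tests
therefore condition on the clean-exposure set. With ~300 pairs checked
at 3 SE, ≈0.8 chance excursions are expected even under perfect
calibration; the tests require every signal pair to pass individually
and allow at most three null-pair excursions — an allowance fixed in the
test design, not tuned.

## Validation design and problem sizes

The original drug-level RORs are functions of the full restricted
database margins and are not reproducible at desk scale, so validation
rests on properties computed at these sizes (chosen to keep the full
suite in the low minutes on one CPU while leaving the Monte-Carlo noise
floor well below each tolerance):

* IC025 vs. Monte-Carlo gamma quantile: 16-point grid, 10⁶ draws,
  tolerance 0.02 bits.
* Null-pair CI coverage: 4–6 databases of 50,000 reports, ~20 rate-1
  events × 20 drugs each (≈1,300–2,400 pairs); coverage within 3 binomial
  SE of 95%.
* Signal recovery: 8 rate-10 signals per database on a baseline-0.005
  event (expected exposed-case count ≈125 ≫ 30); required recovery ≥95%.
* ROR parameter recovery: 5 databases of 200,000 reports, single rate-10
  signal, baseline 0.005; geometric-mean ROR within 10% of the configured
  rate (the odds-vs-risk gap at this baseline is ≈5%).
* Contingency cells vs. a brute-force double loop on 500-report
  databases for 20 random drugs; exact equality.
* Cohort percentages: a 15,696-report cohort rebuilt from published
  marginal counts; every percentage must re-derive exactly at one-decimal
  rounding, half away from zero, against its declared denominator
  (known-value denominators for age and outcome, all-reports for
  seriousness, fatality, country, reporter, co-reported terms and drug
  shares). Quantiles use linear interpolation throughout.

## Known limitations

* Reaction terms and drug codes are opaque strings; no MedDRA/WHODrug
  ingestion, no E2B/XML parsing, and combination products are distinct
  substances unless a dictionary maps them.
* Crude (unstratified) disproportionality only; no PRR/EBGM estimators;
  no time-scan or sequential detection.
* The generator's independence assumptions exclude masking and
  co-medication structure; see above for what passing tests do and do
  not establish about real databases.
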