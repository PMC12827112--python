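# Methods

This note documents the models, estimators, defaults and design choices
behind `faerskit`, and what the synthetic-data generators do and do not
emulate.

## Report cleaning and the unit of analysis

The spontaneous-report model is case-centric. A *case* is one deduplicated
report; duplicated CASEIDs are collapsed to the maximum of the lexicographic
key (caseversion, receipt date, input order) — version first, following the
convention of versioned spontaneous-report streams where a higher version is
by construction the more recent revision. Deduplication is idempotent and its
output is ordered by caseid for determinism.

Demographic normalization maps age codes to years (DEC×10, YR×1, MON×1/12,
WK×7/365.25, DY×1/365.25, HR×1/8766), weight codes to kilograms (LBS×0.453592,
GMS×0.001) and any sex code outside {F, M} to Unknown. Unparseable values
degrade to missing/Unknown and are never fatal; dropped or degraded rows are
counted in a cleaning log. Age bins are left-closed — [0,18), [18,45),
[45,65), [65,∞) — because interval labels such as "18~45 / 45~65" leave
boundary membership ambiguous; a left-closed rule makes bin membership
deterministic. Partial dates (YYYYMM, YYYY) are imputed to mid-span (day 15,
July 1), flagged approximate, and used only for onset arithmetic.

**Exposure** is defined as having at least one drug record with role code PS
(primary suspect) whose trimmed, case-folded name appears in a user-supplied
synonym list. Reports that carry the study drug in a non-suspect role (SS/C/I)
remain in the comparator population: the exposure definition is deliberately
the narrow primary-suspect one, and diluting the comparator slightly is the
conservative direction for disproportionality.

**Onset days** = event date − earliest therapy start linked to a
primary-suspect study-drug record. Negative onsets (therapy starting after
the event) usually indicate data errors and are treated as missing rather
than clamped. Onset bins are left-closed: [0,7), [7,28), [28,60), [60,∞),
with missing mapped to Unknown.

## Disproportionality estimators

ROR = (a·d)/(b·c) and PRR = [a/(a+b)]/[c/(c+d)] with Wald-type 95% intervals
on the log scale (z = 1.96 fixed; the confidence level is not configurable
because the signal criterion is defined at 95%). A case contributes at most
once per term at either hierarchy level (preferred term, or organ class via
the supplied PT→SOC dictionary), so the SOC-level "n" counts reports, not PT
records. Estimability is explicit: ROR requires all four cells positive, PRR
requires a > 0, c > 0 and non-empty margins. No continuity correction is
applied to zero cells — corrected estimates would silently change the
criterion semantics; inestimable rows are reported but never flagged.

The dual signal criterion — a ≥ 3, ROR CI lower limit > 1 and PRR CI lower
limit > 1, all strict — is encoded in `SignalCriteria` and applied verbatim.
Result rows are sorted by ROR point estimate descending, inestimable rows
last, ties broken by term label, so runs are reproducible byte for byte.

Stratification covers gender only (All/F/M). Unknown-gender cases are
excluded from the F and M strata but retained in the overall run, so
per-term event counts satisfy a_F + a_M ≤ a_All with the difference equal to
Unknown-gender events.

Demographic summaries report per-category counts with percentages at two
decimals. The denominator is the case count for the year, gender, age,
reporter, country and route blocks, and the number of recorded entries for
the outcome and onset blocks (a case may carry several outcomes, or none).
Weight is summarized as median and quartiles with linear interpolation
(the numpy default), which reproduces published-style quartile arithmetic
exactly.

## Network track

Gene symbols are compared case-folded throughout. Relevance filtering keeps
scores strictly greater than the threshold (default 10, the GeneCards-style
cut). Venn accounting is exact set algebra; the three output sets are
disjoint by construction.

Interaction graphs are built from (node_a, node_b, combined_score) triples:
scores on a 0–1000 scale are auto-detected (any score > 1) and divided by
1000; edges are kept when the score is strictly greater than the confidence
threshold (default 0.4, the usual "medium confidence" cut); A–B/B–A
duplicates collapse to the maximum score; self-loops are dropped. Isolated
nodes are removed before metric computation.

Node metrics follow the Cytoscape NetworkAnalyzer definitions, since those
are the de facto reporting convention for this kind of screen: closeness is
the reciprocal mean shortest-path length to reachable nodes (computed within
components; cross-component pairs contribute nothing), betweenness is
normalized by 2/((N−1)(N−2)), and the topological coefficient of node n
averages J(n,m)/degree(n) over all nodes m sharing at least one neighbor
with n, where J adds one when n–m is itself an edge (0 when no node shares
a neighbor). Closeness and betweenness are delegated to networkx; the
topological coefficient is implemented here. All four are validated against
an independent brute-force oracle (BFS distances plus the
σ_sv·σ_vt shortest-path-count identity) in the test suite.

Core targets are nodes with degree strictly greater than twice the median
degree (even-sized medians are the mean of the middle two). Hub ranking is
by degree, ties by closeness then symbol, for determinism.

## Enrichment

Over-representation uses the one-sided hypergeometric upper tail
P(X ≥ k) computed by exact big-integer summation of binomial coefficients
(machine-precision accurate at any practical universe size; cross-checked
against scipy's survival function in tests). Benjamini–Hochberg adjustment
runs within each annotation category (GO-BP/GO-CC/GO-MF/KEGG separately),
matching the per-subclass top-10 / top-30 reporting convention; adjusted
values are order-invariant and capped at 1. A term is significant under the
dual threshold raw p < 0.05 and FDR < 0.05. The gene-ratio denominator is
the number of query symbols mappable into the universe; the universe
defaults to all symbols in the GMT collection but is configurable, since
annotation-space choices legitimately differ between analyses.

## What the generators emulate — and what they do not

`simulate_reports` draws exposure per report as Bernoulli(p_exposed) and
each vocabulary term independently per report with probability q (unexposed)
or q·λ (exposed). This independence makes the population reporting odds
ratio available in closed form, `true_odds_ratio(q, λ)`, which is the
estimand all recovery tests target. Two deliberate departures from real
spontaneous-report streams follow from this design:

* **zero-event reports are retained** (a real stream has a reaction in every
  report) — they count in the b/d cells and keep the estimand exact;
* event terms are mutually independent, so there is no co-reporting
  structure, no indication bias and no temporal reporting trend.

Consequently, passing calibration and recovery tests demonstrates that the
estimators and criteria are implemented correctly and behave as advertised
under their own sampling assumptions — not that real reporting data satisfy
those assumptions.

Default demographic marginals emulate a post-marketing cohort: gender mix
63/29/8 (F/M/Unknown), age normal(58, 17) with 30% missing, weight
log-normal with median 80 kg and log-sd 0.30 (quartiles ≈ 65.4–97.9 kg,
45% missing), reporter mix dominated by consumers (54%), country mix
dominated by one region (56%), oral route 63%, single outcome draw per case
with 24% of cases carrying none, therapy-to-event offset log-normal with
median 21 days and 55% missing. Exposure probability defaults to 0.05 —
large enough that exposed margins are informative at desk scale.

Duplicate injection adds round-half-up(rate·n) obsolete DEMO rows. A planted
obsolete row is strictly smaller in both caseversion and receipt date (the
original's version is raised to at least 2 first), so deduplication keyed on
either field succeeds; duplicates also carry perturbed demographics so that
keeping the wrong row is detectable.

`simulate_network_inputs` plants: an exact drug/disease overlap; hubs wired
to a fixed fraction (default 0.5) of all nodes over an Erdős–Rényi
background (default edge probability 0.05 on 200 nodes, five hubs) — hub
degrees then dominate the degree distribution and the 2×median rule recovers
them; sub-threshold decoy edges that the confidence filter must drop; and
gene-set terms whose overlap with the designated query is the chance level
multiplied by the enrichment factor (default 5). Relevance scores default to
uniform(11, 100), i.e. entirely above the threshold, so the generator's
overlap contract is exact; threshold behaviour is exercised separately with
explicit scored lists.

All generators are deterministic: identical configuration and seed give
byte-identical output files.

## Numerical and interface choices

* Probability tables must sum to 1 within 1e-9; violations raise a
  configuration error naming the field.
* The FAERS dialect is parsed with the standard csv machinery ("$"
  delimiter); ragged lines and missing mandatory columns are format errors
  with the line number or column name. Unknown columns are ignored.
* The PT→SOC dictionary is a two-column TSV supplied by the user (the
  regulatory dictionary is licensed and never bundled); one primary SOC per
  PT, conflicts are errors, unmapped terms map to an `UNMAPPED` sentinel and
  are counted, never fatal.
* CLI exit codes: 0 success, 2 input/configuration error, 3 internal error.
  Each run writes a manifest (config hash, seed, input digests, version).

## Problem sizes used in validation

The test suite and `scripts/acceptance.py` exercise the pipeline at sizes
chosen to make the statistical checks sharp while staying desk-scale:
200,000-report cohorts (200 replicates in the suite, 50 in the script) for
planted-OR recovery; 100,000-report cohorts for null calibration; 1,000
binomial tables for CI coverage; 200-node graphs (100/50 replicates) for hub
recovery; universes of 2,000 genes with 40 terms (100/50 replicates) for
enrichment detection; exhaustive enumeration for the estimator and
hypergeometric oracles (all 1,296 small tables; all populations up to 25).

## Known limitations

* No Bayesian disproportionality (BCPNN/MGPS), time-scan methods or
  dose–response analysis.
* No NLP drug-name standardization — exposure matching is exact after
  trimming and case-folding against the synonym list.
* Single merged reporting period; no per-quarter file stitching beyond
  concatenation.
* One primary SOC per PT; no HLT/HLGT levels or multiaxial secondary
  assignments.
* Enrichment takes annotations as given (no GO-graph propagation, no
  pathway topology).
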