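"""Disproportionality analysis of spontaneous adverse-event reports.

For each event term t (a MedDRA-style preferred term, or its organ class) the
deduplicated reports are cross-classified against drug exposure in a 2x2
contingency table::

                  event present   event absent
    exposed             a              b
    non-exposed         c              d

Two frequentist disproportionality measures are computed on that table:

* reporting odds ratio    ROR = (a*d) / (b*c)
* proportional reporting ratio  PRR = [a/(a+b)] / [c/(c+d)]

with 95% confidence intervals on the log scale,
``exp(ln ROR +/- 1.96*sqrt(1/a + 1/b + 1/c + 1/d))`` and
``exp(ln PRR +/- 1.96*sqrt(1/a - 1/(a+b) + 1/c - 1/(c+d)))``.

A term is flagged as a signal when a >= 3 and both CI lower limits exceed 1.
The unit of counting is the case report: a case contributes at most once per
term regardless of how many of its reactions match.  No continuity correction
is applied; tables with an empty cell are reported as inestimable and never
flagged.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigError
from .faers_io import AGE_BIN_LABELS, CleanDataset
from .meddra import PtSocMap

Z_95 = 1.96  # normal quantile for the fixed 95% confidence level

ONSET_BIN_LABELS = ("<7", "7-28", "28-60", ">=60", "Unknown")
_ONSET_EDGES = (7.0, 28.0, 60.0)  # left-closed: [0,7), [7,28), [28,60), [60,inf)

OUTCOME_ORDER = ("HO", "DE", "LT", "DS", "RI", "CA", "OT")
OUTCOME_LABELS = {
    "HO": "Hospitalization",
    "DE": "Death",
    "LT": "Life threatening",
    "DS": "Disability",
    "RI": "Required intervention",
    "CA": "Congenital anomaly",
    "OT": "Other serious",
}

__all__ = [
    "ContingencyTable",
    "RatioEstimate",
    "SignalCriteria",
    "SignalRow",
    "DemographicSummary",
    "build_contingency",
    "ror_estimate",
    "prr_estimate",
    "evaluate_signal",
    "run_disproportionality",
    "signal_frame",
    "onset_bins",
    "percentage_block",
    "summarize_demographics",
    "Z_95",
    "ONSET_BIN_LABELS",
]


@dataclass(frozen=True)
class ContingencyTable:
    a: int  # exposed cases with the event
    b: int  # exposed cases without the event
    c: int  # non-exposed cases with the event
    d: int  # non-exposed cases without the event

    def __post_init__(self):
        for name in "abcd":
            if getattr(self, name) < 0:
                raise ValueError(f"cell {name} is negative")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d


@dataclass(frozen=True)
class RatioEstimate:
    point: float
    ci_low: float
    ci_high: float
    estimable: bool = True
    confidence_level: float = 0.95

    @classmethod
    def inestimable(cls) -> "RatioEstimate":
        return cls(math.nan, math.nan, math.nan, estimable=False)


@dataclass(frozen=True)
class SignalCriteria:
    """Dual signal criterion: a >= min_a and both CI lower limits > 1."""

    min_a: int = 3
    ror_ci_low_gt: float = 1.0
    prr_ci_low_gt: float = 1.0


@dataclass(frozen=True)
class SignalRow:
    term: str
    level: str  # "PT" or "SOC"
    stratum: str  # "All", "F" or "M"
    table: ContingencyTable
    ror: RatioEstimate
    prr: RatioEstimate
    is_signal: bool


def ror_estimate(t: ContingencyTable) -> RatioEstimate:
    """Reporting odds ratio with 95% CI; inestimable if any cell is zero."""
    if min(t.a, t.b, t.c, t.d) == 0:
        return RatioEstimate.inestimable()
    point = (t.a * t.d) / (t.b * t.c)
    se = math.sqrt(1 / t.a + 1 / t.b + 1 / t.c + 1 / t.d)
    log_point = math.log(point)
    return RatioEstimate(
        point=point,
        ci_low=math.exp(log_point - Z_95 * se),
        ci_high=math.exp(log_point + Z_95 * se),
    )


def prr_estimate(t: ContingencyTable) -> RatioEstimate:
    """Proportional reporting ratio with 95% CI.

    Estimable iff a > 0, c > 0 and both margins are non-empty.
    """
    if t.a == 0 or t.c == 0 or (t.a + t.b) == 0 or (t.c + t.d) == 0:
        return RatioEstimate.inestimable()
    point = (t.a / (t.a + t.b)) / (t.c / (t.c + t.d))
    se_sq = 1 / t.a - 1 / (t.a + t.b) + 1 / t.c - 1 / (t.c + t.d)
    se = math.sqrt(max(se_sq, 0.0))
    log_point = math.log(point)
    return RatioEstimate(
        point=point,
        ci_low=math.exp(log_point - Z_95 * se),
        ci_high=math.exp(log_point + Z_95 * se),
    )


def evaluate_signal(
    table: ContingencyTable,
    ror: RatioEstimate,
    prr: RatioEstimate,
    criteria: SignalCriteria | None = None,
) -> bool:
    """Apply the dual signal criterion (strict inequalities)."""
    crit = criteria or SignalCriteria()
    return bool(
        ror.estimable
        and prr.estimable
        and table.a >= crit.min_a
        and ror.ci_low > crit.ror_ci_low_gt
        and prr.ci_low > crit.prr_ci_low_gt
    )


def _stratum_cases(ds: CleanDataset, stratum: str) -> pd.DataFrame:
    if stratum == "All":
        return ds.cases
    if stratum in ("F", "M"):
        # Unknown-gender cases are dropped from stratified (not overall) runs
        return ds.cases[ds.cases["sex_norm"] == stratum]
    raise ConfigError(f"unknown stratum {stratum!r}; expected All, F or M")


def _event_case_sets(
    ds: CleanDataset, level: str, soc_map: PtSocMap | None
) -> pd.DataFrame:
    """Unique (caseid, term) pairs at the requested hierarchy level."""
    if level == "PT":
        pairs = ds.reactions[["caseid", "pt"]].rename(columns={"pt": "term"})
    elif level == "SOC":
        if soc_map is None:
            raise ConfigError("SOC-level analysis requires a PT->SOC map")
        terms = ds.reactions["pt"].map(soc_map.soc_of)
        pairs = pd.DataFrame({"caseid": ds.reactions["caseid"], "term": terms})
    else:
        raise ConfigError(f"unknown level {level!r}; expected PT or SOC")
    return pairs.drop_duplicates()


def build_contingency(
    ds: CleanDataset,
    term: str,
    level: str = "PT",
    stratum: str = "All",
    soc_map: PtSocMap | None = None,
) -> ContingencyTable:
    """2x2 table for one term; an unknown term yields a=c=0, not an error."""
    cases = _stratum_cases(ds, stratum)
    ids = set(cases["caseid"])
    exposed = ds.exposed & ids
    pairs = _event_case_sets(ds, level, soc_map)
    with_event = set(pairs.loc[pairs["term"] == term, "caseid"]) & ids
    a = len(with_event & exposed)
    c = len(with_event) - a
    b = len(exposed) - a
    d = len(ids) - len(exposed) - c
    return ContingencyTable(a=a, b=b, c=c, d=d)


def run_disproportionality(
    ds: CleanDataset,
    level: str = "PT",
    stratum: str = "All",
    soc_map: PtSocMap | None = None,
    criteria: SignalCriteria | None = None,
) -> list[SignalRow]:
    """One SignalRow per term with a >= 1 in the stratum.

    Rows are sorted by ROR point estimate descending with inestimable rows
    last; ties broken by term label ascending for determinism.
    """
    crit = criteria or SignalCriteria()
    cases = _stratum_cases(ds, stratum)
    ids = set(cases["caseid"])
    exposed = ds.exposed & ids
    n_exp, n_total = len(exposed), len(ids)

    pairs = _event_case_sets(ds, level, soc_map)
    pairs = pairs[pairs["caseid"].isin(ids)]
    if pairs.empty:
        return []
    is_exp = pairs["caseid"].isin(exposed)
    counts = pd.DataFrame(
        {
            "a": pairs[is_exp].groupby("term").size(),
            "with_event": pairs.groupby("term").size(),
        }
    ).fillna(0)

    rows: list[SignalRow] = []
    for term, rec in counts.iterrows():
        a = int(rec["a"])
        if a < 1:
            continue
        c = int(rec["with_event"]) - a
        table = ContingencyTable(a=a, b=n_exp - a, c=c, d=n_total - n_exp - c)
        ror = ror_estimate(table)
        prr = prr_estimate(table)
        rows.append(
            SignalRow(
                term=str(term),
                level=level,
                stratum=stratum,
                table=table,
                ror=ror,
                prr=prr,
                is_signal=evaluate_signal(table, ror, prr, crit),
            )
        )
    rows.sort(
        key=lambda r: (
            not r.ror.estimable,
            -(r.ror.point if r.ror.estimable else 0.0),
            r.term,
        )
    )
    return rows


def signal_frame(rows: list[SignalRow], soc_map: PtSocMap | None = None) -> pd.DataFrame:
    """Tabular view of signal rows suitable for TSV export."""
    records = []
    for r in rows:
        records.append(
            {
                "term": r.term,
                "level": r.level,
                "stratum": r.stratum,
                "soc": soc_map.soc_of(r.term) if (soc_map and r.level == "PT") else "",
                "a": r.table.a,
                "b": r.table.b,
                "c": r.table.c,
                "d": r.table.d,
                "ROR": r.ror.point,
                "ROR_low": r.ror.ci_low,
                "ROR_high": r.ror.ci_high,
                "PRR": r.prr.point,
                "PRR_low": r.prr.ci_low,
                "PRR_high": r.prr.ci_high,
                "signal": r.is_signal,
            }
        )
    cols = [
        "term", "level", "stratum", "soc", "a", "b", "c", "d",
        "ROR", "ROR_low", "ROR_high", "PRR", "PRR_low", "PRR_high", "signal",
    ]
    return pd.DataFrame(records, columns=cols)


def _onset_label(days: float) -> str:
    if days is None or np.isnan(days) or days < 0:
        return "Unknown"
    for edge, label in zip(_ONSET_EDGES, ONSET_BIN_LABELS):
        if days < edge:
            return label
    return ">=60"


def onset_bins(ds: CleanDataset) -> dict[str, int]:
    """Counts of cases per time-to-onset bin (left-closed; missing -> Unknown)."""
    labels = ds.cases["onset_days"].map(_onset_label)
    counts = labels.value_counts()
    return {lab: int(counts.get(lab, 0)) for lab in ONSET_BIN_LABELS}


def percentage_block(counts, denominator: int | None = None):
    """Counts -> (category, count, percentage) rows, percentages at 2 d.p.

    The default denominator is the block's own total; zero-count categories
    are reported as ``0 (0.00)``.  This is the arithmetic behind every block
    of the demographic summary table.
    """
    items = list(counts.items())
    denom = denominator if denominator is not None else sum(c for _, c in items)
    rows = []
    for cat, count in items:
        pct = round(100.0 * count / denom, 2) if denom else 0.0
        rows.append((cat, int(count), pct))
    return rows


@dataclass
class DemographicSummary:
    """Per-category counts/percentages plus the weight median and quartiles."""

    blocks: dict[str, list[tuple[str, int, float]]] = field(default_factory=dict)
    weight_median: float = math.nan
    weight_q1: float = math.nan
    weight_q3: float = math.nan

    def to_frame(self) -> pd.DataFrame:
        records = [
            {"block": name, "category": cat, "count": cnt, "percent": pct}
            for name, rows in self.blocks.items()
            for cat, cnt, pct in rows
        ]
        return pd.DataFrame(records, columns=["block", "category", "count", "percent"])


def summarize_demographics(ds: CleanDataset) -> DemographicSummary:
    """Publication-style summary of a report cohort.

    Year/gender/age/reporter/country/route percentages use the case count as
    denominator; outcome and onset percentages use the number of recorded
    entries in their own block.  Weight quartiles use linear interpolation.
    """
    cases = ds.cases
    n = len(cases)
    blocks: dict[str, list[tuple[str, int, float]]] = {}

    years = cases["year"].dropna().astype(int)
    year_counts = {str(y): int(c) for y, c in years.value_counts().sort_index().items()}
    blocks["year"] = percentage_block(year_counts, denominator=n)

    sex_counts = cases["sex_norm"].value_counts()
    blocks["gender"] = percentage_block(
        {k: int(sex_counts.get(k, 0)) for k in ("F", "M", "Unknown")}, denominator=n
    )

    age_counts = cases["age_bin"].value_counts()
    blocks["age"] = percentage_block(
        {k: int(age_counts.get(k, 0)) for k in AGE_BIN_LABELS}, denominator=n
    )

    for name, col in (("reporter", "reporter"), ("country", "country"), ("route", "route")):
        counts = cases[col].value_counts()
        ordered = dict(
            sorted(counts.items(), key=lambda kv: (-kv[1], str(kv[0])))
        )
        blocks[name] = percentage_block(
            {str(k): int(v) for k, v in ordered.items()}, denominator=n
        )

    out_counts = ds.outcomes["outc_cod"].value_counts() if not ds.outcomes.empty else {}
    outcome_block = {
        OUTCOME_LABELS[code]: int(out_counts.get(code, 0)) for code in OUTCOME_ORDER
    }
    blocks["outcomes"] = percentage_block(outcome_block)  # denominator = entries

    blocks["onset"] = percentage_block(onset_bins(ds))  # denominator = entries

    weights = cases["weight_kg"].dropna().to_numpy()
    if weights.size:
        q1, med, q3 = np.percentile(weights, [25, 50, 75])  # linear interpolation
    else:
        q1 = med = q3 = math.nan
    return DemographicSummary(
        blocks=blocks, weight_median=float(med), weight_q1=float(q1), weight_q3=float(q3)
    )
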