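"""Reading, cleaning and assembly of FAERS-dialect ASCII report tables.

The spontaneous-report extract is split over five "$"-delimited tables sharing
a CASEID key: DEMO (one row per report version, demographics), DRUG (one row
per reported medication with a role code), REAC (reaction preferred terms),
THER (therapy start dates) and OUTC (outcome codes).  This module parses those
tables, collapses versioned duplicate cases to the most recent record,
normalizes demographic codes to analysis units (years, kilograms, F/M/Unknown)
and assembles a deduplicated case-level dataset with a drug-exposure flag
defined by primary-suspect (PS) role plus a synonym dictionary.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigError, FormatError

__all__ = [
    "TABLE_COLUMNS",
    "AGE_FACTORS",
    "WEIGHT_FACTORS",
    "REPORTER_CODES",
    "AGE_BIN_LABELS",
    "CleanDataset",
    "read_ascii_table",
    "write_ascii_table",
    "parse_faers_date",
    "parse_date_series",
    "deduplicate_cases",
    "normalize_demographics",
    "find_exposed_cases",
    "assemble_dataset",
    "load_synonyms",
]

DELIM = "$"

#: mandatory (first tuple) and optional (second tuple) columns per table kind
TABLE_COLUMNS: dict[str, tuple[tuple[str, ...], tuple[str, ...]]] = {
    "demo": (
        ("caseid", "caseversion", "fda_dt", "sex"),
        ("event_dt", "age", "age_cod", "wt", "wt_cod", "occp_cod", "occr_country"),
    ),
    "drug": (("caseid", "drug_seq", "drugname", "role_cod"), ("route",)),
    "reac": (("caseid", "pt"), ()),
    "ther": (("caseid", "dsg_drug_seq", "start_dt"), ()),
    "outc": (("caseid", "outc_cod"), ()),
}

# Conversion of FAERS age/weight unit codes to years / kilograms.
AGE_FACTORS = {
    "DEC": 10.0,
    "YR": 1.0,
    "MON": 1.0 / 12.0,
    "WK": 7.0 / 365.25,
    "DY": 1.0 / 365.25,
    "HR": 1.0 / 8766.0,
}
WEIGHT_FACTORS = {"KG": 1.0, "LBS": 0.453592, "GMS": 0.001}

REPORTER_CODES = {
    "MD": "Physician",
    "PH": "Pharmacist",
    "CN": "Consumer",
    "LW": "Lawyer",
    "HP": "Other health-professional",
    "RN": "Other health-professional",
    "OT": "Other health-professional",
}

AGE_BIN_LABELS = ("<18", "18-45", "45-65", ">=65", "Unknown")
# left-closed bins: [0,18), [18,45), [45,65), [65,inf)
_AGE_BIN_EDGES = (18.0, 45.0, 65.0)


def read_ascii_table(path, kind: str) -> pd.DataFrame:
    """Parse one "$"-delimited table into a string DataFrame.

    Column order is taken from the header line; unknown columns are dropped.
    A header missing a mandatory column, or a line whose field count differs
    from the header's, raises :class:`FormatError`.
    """
    if kind not in TABLE_COLUMNS:
        raise ConfigError(f"unknown table kind {kind!r}")
    mandatory, optional = TABLE_COLUMNS[kind]
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh, delimiter=DELIM)
        try:
            header = [h.strip().lower() for h in next(reader)]
        except StopIteration:
            raise FormatError(f"{path}: empty file, expected a header line") from None
        for col in mandatory:
            if col not in header:
                raise FormatError(f"{path}: header missing mandatory column {col!r}")
        ncol = len(header)
        rows: list[list[str]] = []
        for lineno, fields in enumerate(reader, start=2):
            if not fields:  # blank trailing line
                continue
            if len(fields) != ncol:
                raise FormatError(
                    f"{path}: line {lineno} has {len(fields)} fields, expected {ncol}"
                )
            rows.append(fields)
    df = pd.DataFrame(rows, columns=header, dtype=str)
    if df.empty:
        df = pd.DataFrame({c: pd.Series(dtype=str) for c in header})
    keep = [c for c in header if c in mandatory or c in optional]
    return df[keep]


def write_ascii_table(df: pd.DataFrame, path) -> None:
    """Write a table in the "$"-delimited dialect (empty string = missing)."""
    out = df.fillna("").astype(str)
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, delimiter=DELIM, lineterminator="\n")
        writer.writerow(list(out.columns))
        writer.writerows(out.itertuples(index=False, name=None))


def load_synonyms(path) -> frozenset[str]:
    """Read a drug-synonym file (one name per line, case-insensitive)."""
    with open(path, encoding="utf-8") as fh:
        names = {line.strip().casefold() for line in fh if line.strip()}
    if not names:
        raise ConfigError(f"{path}: synonym file contains no names")
    return frozenset(names)


def parse_faers_date(value: str):
    """Parse a possibly partial YYYYMMDD/YYYYMM/YYYY date.

    Returns ``(timestamp_or_NaT, approximate_flag)``.  Partial dates are
    imputed to the middle of their span (YYYYMM -> day 15, YYYY -> July 1) and
    flagged approximate; unparseable values map to NaT.
    """
    s = str(value).strip()
    if not s.isdigit():
        return pd.NaT, False
    try:
        if len(s) == 8:
            return pd.Timestamp(int(s[:4]), int(s[4:6]), int(s[6:8])), False
        if len(s) == 6:
            return pd.Timestamp(int(s[:4]), int(s[4:6]), 15), True
        if len(s) == 4:
            return pd.Timestamp(int(s), 7, 1), True
    except ValueError:
        pass
    return pd.NaT, False


def parse_date_series(series: pd.Series) -> tuple[pd.Series, pd.Series]:
    """Vectorized :func:`parse_faers_date` (maps unique raw values once)."""
    raw = series.fillna("").astype(str)
    uniq = raw.unique()
    parsed = {u: parse_faers_date(u) for u in uniq}
    dates = raw.map(lambda u: parsed[u][0])
    approx = raw.map(lambda u: parsed[u][1])
    return pd.to_datetime(dates), approx.astype(bool)


def deduplicate_cases(demo: pd.DataFrame) -> pd.DataFrame:
    """Keep one DEMO row per CASEID: the most recent report version.

    "Most recent" is the maximum under the lexicographic key
    (caseversion, fda_dt, input order); missing versions rank lowest.  Output
    is sorted by caseid for determinism.  Idempotent.
    """
    if demo.empty:
        return demo.copy()
    ver = pd.to_numeric(demo.get("caseversion"), errors="coerce").fillna(0)
    order = np.arange(len(demo))
    key = demo.assign(_ver=ver.values, _dt=demo["fda_dt"].fillna("").values, _ord=order)
    key = key.sort_values(["caseid", "_ver", "_dt", "_ord"], kind="stable")
    latest = key.groupby("caseid", sort=True).tail(1)
    latest = latest.sort_values("caseid", kind="stable")
    return latest.drop(columns=["_ver", "_dt", "_ord"]).reset_index(drop=True)


def _age_bin(age_years: float) -> str:
    if np.isnan(age_years) or age_years < 0:
        return "Unknown"
    for edge, label in zip(_AGE_BIN_EDGES, AGE_BIN_LABELS):
        if age_years < edge:
            return label
    return ">=65"


def normalize_demographics(demo: pd.DataFrame) -> pd.DataFrame:
    """Add analysis-unit columns to a (deduplicated) DEMO table.

    New columns: ``sex_norm`` (F/M/Unknown), ``age_years``, ``age_bin``,
    ``weight_kg``, ``reporter``, ``country``, ``year`` (from fda_dt) and
    ``event_date``/``event_approx``.  Unparseable values degrade to
    Unknown/NaN rather than raising.
    """
    out = demo.copy()
    sex = out.get("sex", pd.Series("", index=out.index)).fillna("").str.strip().str.upper()
    out["sex_norm"] = sex.where(sex.isin(["F", "M"]), "Unknown")

    age_val = pd.to_numeric(out.get("age"), errors="coerce")
    age_cod = out.get("age_cod", pd.Series("", index=out.index)).fillna("").str.strip().str.upper()
    factors = age_cod.map(AGE_FACTORS)
    # missing unit code on a plausible numeric age defaults to years
    factors = factors.where(~(factors.isna() & (age_cod == "")), 1.0)
    out["age_years"] = (age_val * factors).astype(float)
    out.loc[out["age_years"] < 0, "age_years"] = np.nan
    out["age_bin"] = out["age_years"].map(_age_bin)

    wt_val = pd.to_numeric(out.get("wt"), errors="coerce")
    wt_cod = out.get("wt_cod", pd.Series("", index=out.index)).fillna("").str.strip().str.upper()
    wt_factors = wt_cod.map(WEIGHT_FACTORS)
    wt_factors = wt_factors.where(~(wt_factors.isna() & (wt_cod == "")), 1.0)
    out["weight_kg"] = (wt_val * wt_factors).astype(float)
    out.loc[out["weight_kg"] <= 0, "weight_kg"] = np.nan

    occp = out.get("occp_cod", pd.Series("", index=out.index)).fillna("").str.strip().str.upper()
    out["reporter"] = occp.map(REPORTER_CODES).fillna("Unknown")

    country = out.get("occr_country", pd.Series("", index=out.index)).fillna("").str.strip()
    out["country"] = country.where(country != "", "Unknown")

    fda_dates, _ = parse_date_series(out["fda_dt"])
    out["year"] = fda_dates.dt.year.astype("Int64")
    ev_dates, ev_approx = parse_date_series(
        out.get("event_dt", pd.Series("", index=out.index))
    )
    out["event_date"] = ev_dates
    out["event_approx"] = ev_approx.values
    return out


def _normalize_name(name: str) -> str:
    return str(name).strip().casefold()


def find_exposed_cases(drug: pd.DataFrame, synonyms) -> set[str]:
    """CASEIDs with >= 1 primary-suspect (PS) record of the study drug."""
    syn = {_normalize_name(s) for s in synonyms}
    if not syn:
        raise ConfigError("synonym set is empty")
    if drug.empty:
        return set()
    mask = (drug["role_cod"].fillna("").str.strip().str.upper() == "PS") & (
        drug["drugname"].fillna("").map(_normalize_name).isin(syn)
    )
    return set(drug.loc[mask, "caseid"])


@dataclass
class CleanDataset:
    """Analysis-ready deduplicated case dataset.

    ``cases`` holds one row per caseid (normalized demographics, onset days);
    ``reactions`` and ``outcomes`` are long tables keyed by caseid;
    ``exposed`` is the set of caseids meeting the exposure definition;
    ``log`` records dropped/degraded rows from cleaning.
    """

    cases: pd.DataFrame
    reactions: pd.DataFrame
    outcomes: pd.DataFrame
    exposed: frozenset
    log: list = field(default_factory=list)

    @property
    def n_cases(self) -> int:
        return len(self.cases)

    @property
    def case_ids(self) -> set:
        return set(self.cases["caseid"])

    def pt_sets(self) -> dict:
        """Per-case set of reaction preferred terms."""
        if self.reactions.empty:
            return {}
        return self.reactions.groupby("caseid")["pt"].agg(set).to_dict()

    def subset(self, case_ids) -> "CleanDataset":
        """Restrict the dataset to a collection of caseids (e.g. a stratum)."""
        keep = set(case_ids)
        return CleanDataset(
            cases=self.cases[self.cases["caseid"].isin(keep)].reset_index(drop=True),
            reactions=self.reactions[self.reactions["caseid"].isin(keep)].reset_index(drop=True),
            outcomes=self.outcomes[self.outcomes["caseid"].isin(keep)].reset_index(drop=True),
            exposed=frozenset(self.exposed & keep),
            log=list(self.log),
        )


def assemble_dataset(demo, drug, reac, ther, outc, synonyms) -> CleanDataset:
    """Deduplicate, normalize and join the five tables into a CleanDataset.

    Onset days = event date minus the earliest therapy start linked to a
    primary-suspect record of the study drug, in days; negative or
    incomputable onsets are left missing.  Reaction/outcome rows whose caseid
    lacks a DEMO row are dropped and logged.
    """
    log: list[dict] = []
    deduped = deduplicate_cases(demo)
    n_dropped = len(demo) - len(deduped)
    if n_dropped:
        log.append({"step": "deduplicate", "dropped_rows": int(n_dropped)})
    cases = normalize_demographics(deduped)
    registry = set(cases["caseid"])

    exposed = find_exposed_cases(drug, synonyms) & registry

    def _filter(df: pd.DataFrame, name: str, col: str) -> pd.DataFrame:
        if df.empty:
            return df.copy()
        keep = df[df[col].fillna("") != ""]
        keep = keep[keep["caseid"].isin(registry)]
        n_orphan = len(df) - len(keep)
        if n_orphan:
            log.append({"step": f"filter_{name}", "dropped_rows": int(n_orphan)})
        return keep.reset_index(drop=True)

    reactions = _filter(reac, "reac", "pt")[["caseid", "pt"]]
    outcomes = _filter(outc, "outc", "outc_cod")[["caseid", "outc_cod"]]

    # onset: earliest therapy start among PS study-drug records per case
    onset = pd.Series(np.nan, index=cases.index, dtype=float)
    if not ther.empty and not drug.empty and exposed:
        syn = {_normalize_name(s) for s in synonyms}
        ps = drug[
            (drug["role_cod"].fillna("").str.strip().str.upper() == "PS")
            & drug["drugname"].fillna("").map(_normalize_name).isin(syn)
        ][["caseid", "drug_seq"]]
        th = ther.merge(
            ps, left_on=["caseid", "dsg_drug_seq"], right_on=["caseid", "drug_seq"]
        )
        if not th.empty:
            starts, _ = parse_date_series(th["start_dt"])
            th = th.assign(_start=starts).dropna(subset=["_start"])
            first_start = th.groupby("caseid")["_start"].min()
            ev = cases.set_index("caseid")["event_date"]
            days = (ev - first_start).dt.days.astype(float)
            days[days < 0] = np.nan  # negative onsets indicate data error
            onset = cases["caseid"].map(days)
    cases = cases.assign(onset_days=onset.values)

    # per-case route: first PS record's route, else first drug record's
    route = pd.Series("Unknown", index=cases.index)
    if not drug.empty and "route" in drug.columns:
        d = drug[drug["caseid"].isin(registry)]
        ps_rows = d[d["role_cod"].fillna("").str.strip().str.upper() == "PS"]
        pick = ps_rows.groupby("caseid")["route"].first()
        fallback = d.groupby("caseid")["route"].first()
        merged = cases["caseid"].map(pick).fillna(cases["caseid"].map(fallback))
        route = merged.fillna("Unknown").replace("", "Unknown")
    cases = cases.assign(route=route.values)

    return CleanDataset(
        cases=cases.reset_index(drop=True),
        reactions=reactions,
        outcomes=outcomes,
        exposed=frozenset(exposed),
        log=log,
    )
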