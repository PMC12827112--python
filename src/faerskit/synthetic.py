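"""Synthetic spontaneous-report and network-input generators with ground truth.

Every downstream stage of the pipeline is exercised against data whose
generative parameters are known exactly:

* :func:`simulate_reports` emits the five FAERS-dialect tables for a cohort
  of case reports.  Exposure to the study drug is Bernoulli(p_exposed); each
  vocabulary term t occurs independently per report with probability
  ``background_prob`` among the unexposed and ``background_prob *
  signal_multiplier`` among the exposed, so the population reporting odds
  ratio of every term is available in closed form
  (:func:`true_odds_ratio`).  Reports with zero events are retained and count
  in the b/d cells — a deliberate deviation from real spontaneous-report
  streams (where every report carries a reaction) that keeps the estimand
  exact.  Unexposed reports carry 1-3 decoy drugs so contingency
  denominators are non-degenerate.
* :func:`inject_duplicates` plants earlier-version records for a fraction of
  cases; a planted obsolete row is strictly smaller in BOTH caseversion and
  receipt date, so deduplication succeeds under either key.  To guarantee
  that, the chosen case's original version is raised to at least 2 before
  its version-(v-1) duplicate is added.  The duplicate count is
  round-half-up(rate * n_cases).
* :func:`simulate_network_inputs` emits a drug-target list and a scored
  disease-gene list sharing exactly ``overlap_size`` symbols, a STRING-style
  scored edge list over the shared symbols with planted hubs (each wired to
  ``hub_fraction`` of all nodes on top of an Erdos-Renyi background), and a
  GMT gene-set collection in which planted terms are over-represented in the
  shared set by a configured enrichment factor.

All generators are deterministic under their seed: identical configuration
and seed reproduce byte-identical output files.
"""

from __future__ import annotations

import json
import math
import os
from functools import lru_cache as _functools_lru_cache
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .enrich import CATEGORIES, GeneSet, GeneSetCollection, write_gmt
from .errors import ConfigError, DomainError
from .faers_io import write_ascii_table

__all__ = [
    "Distribution",
    "TermSpec",
    "SimConfig",
    "SimulationTruth",
    "FaersTables",
    "NetworkSimConfig",
    "NetworkInputs",
    "NetworkTruth",
    "default_vocabulary",
    "simulate_reports",
    "true_odds_ratio",
    "inject_duplicates",
    "simulate_network_inputs",
    "write_pt_soc_map",
    "DEFAULT_STUDY_DRUG",
    "DECOY_DRUGS",
]

DEFAULT_STUDY_DRUG = "BARICITINIB"

DECOY_DRUGS = (
    "ADALIMUMAB", "METHOTREXATE", "PREDNISONE", "TOFACITINIB", "IBUPROFEN",
    "METFORMIN", "LISINOPRIL", "ATORVASTATIN", "OMEPRAZOLE", "HYDROXYCHLOROQUINE",
    "AMLODIPINE", "LEVOTHYROXINE",
)

_EPOCH = np.datetime64("2018-01-01")
_PERIOD_DAYS = 2557  # merged 2018-2024 reporting window


@_functools_lru_cache(maxsize=4)
def _case_id_array(n: int) -> np.ndarray:
    """Deterministic caseid labels C00000001..; cached across simulations."""
    ids = np.char.add("C", np.char.zfill(np.arange(1, n + 1).astype(str), 8))
    ids.setflags(write=False)
    return ids


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


@dataclass(frozen=True)
class Distribution:
    """Small declarative distribution spec with a missingness rate.

    Families: ``normal(mean, sd)``, ``lognormal(log_mean, log_sd)``,
    ``uniform(low, high)``.  Missing draws are returned as NaN.
    """

    family: str
    params: tuple
    missing_rate: float = 0.0

    def sample(self, rng: np.random.Generator, size: int) -> np.ndarray:
        if self.family == "normal":
            values = rng.normal(self.params[0], self.params[1], size)
        elif self.family == "lognormal":
            values = rng.lognormal(self.params[0], self.params[1], size)
        elif self.family == "uniform":
            values = rng.uniform(self.params[0], self.params[1], size)
        else:
            raise ConfigError(f"unknown distribution family {self.family!r}")
        if self.missing_rate > 0:
            values = np.where(rng.random(size) < self.missing_rate, np.nan, values)
        return values


@dataclass(frozen=True)
class TermSpec:
    """One vocabulary event term with its generative parameters."""

    pt_name: str
    soc_name: str
    background_prob: float  # per-report probability among the unexposed
    signal_multiplier: float = 1.0  # relative reporting multiplier among exposed


def default_vocabulary(signal_multiplier: float = 1.0) -> tuple[TermSpec, ...]:
    """A self-consistent 24-term vocabulary over 6 organ classes (all null)."""
    socs = (
        "Infections and infestations",
        "Vascular disorders",
        "Respiratory disorders",
        "Gastrointestinal disorders",
        "Nervous system disorders",
        "Renal and urinary disorders",
    )
    probs = (0.002, 0.005, 0.01, 0.02)
    terms = []
    for i, soc in enumerate(socs):
        for j, p in enumerate(probs):
            terms.append(
                TermSpec(
                    pt_name=f"EVENT_{i * len(probs) + j + 1:02d}",
                    soc_name=soc,
                    background_prob=p,
                    signal_multiplier=signal_multiplier,
                )
            )
    return tuple(terms)


def _default_gender_probs():
    return {"F": 0.63, "M": 0.29, "Unknown": 0.08}


def _default_country_probs():
    return {
        "US": 0.557, "JP": 0.103, "GB": 0.044, "FR": 0.043, "DE": 0.041,
        "IT": 0.027, "ES": 0.018, "Other": 0.167,
    }


def _default_reporter_probs():
    # occupation codes; "" = not reported
    return {"CN": 0.5363, "PH": 0.2228, "MD": 0.1364, "OT": 0.0268, "": 0.0777}


def _default_route_probs():
    return {"Oral": 0.6264, "Subcutaneous": 0.0017, "Other": 0.3719}


def _default_outcome_probs():
    # per-case single outcome draw; "" = no outcome recorded
    return {
        "HO": 0.2737, "OT": 0.3090, "DE": 0.0872, "LT": 0.0564,
        "DS": 0.0158, "RI": 0.0157, "CA": 0.0007, "": 0.2415,
    }


@dataclass
class SimConfig:
    """Study conditions of the spontaneous-report simulator.

    Defaults emulate the demographic mix of a post-marketing report cohort
    (gender/reporter/country/route/outcome marginals, weight log-normal
    around a median of 80 kg, about 30% missing age) at a desk-scale
    exposure probability of 0.05.
    """

    n_reports: int = 50_000
    p_exposed: float = 0.05
    vocabulary: tuple = field(default_factory=default_vocabulary)
    study_drug: str = DEFAULT_STUDY_DRUG
    gender_probs: dict = field(default_factory=_default_gender_probs)
    age_years_distribution: Distribution = Distribution("normal", (58.0, 17.0), 0.30)
    weight_kg_distribution: Distribution = Distribution(
        "lognormal", (math.log(80.0), 0.30), 0.45
    )
    country_probs: dict = field(default_factory=_default_country_probs)
    reporter_probs: dict = field(default_factory=_default_reporter_probs)
    route_probs: dict = field(default_factory=_default_route_probs)
    outcome_probs: dict = field(default_factory=_default_outcome_probs)
    therapy_offset_days_distribution: Distribution = Distribution(
        "lognormal", (math.log(21.0), 1.4), 0.55
    )
    event_date_missing_rate: float = 0.10
    duplicate_rate: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_reports < 1:
            raise ConfigError("n_reports must be >= 1")
        if not (0.0 < self.p_exposed < 1.0):
            raise ConfigError("p_exposed must lie in (0, 1)")
        if not (0.0 <= self.duplicate_rate < 1.0):
            raise ConfigError("duplicate_rate must lie in [0, 1)")
        for name in ("gender_probs", "country_probs", "reporter_probs",
                     "route_probs", "outcome_probs"):
            table = getattr(self, name)
            total = float(sum(table.values()))
            if abs(total - 1.0) > 1e-9 or any(p < 0 for p in table.values()):
                raise ConfigError(f"{name} must be non-negative and sum to 1 (got {total})")
        seen = set()
        for t in self.vocabulary:
            if t.pt_name in seen:
                raise ConfigError(f"vocabulary: duplicate pt_name {t.pt_name!r}")
            seen.add(t.pt_name)
            if not (0.0 < t.background_prob < 1.0):
                raise ConfigError(f"vocabulary[{t.pt_name}]: background_prob outside (0, 1)")
            if t.signal_multiplier < 0:
                raise ConfigError(f"vocabulary[{t.pt_name}]: signal_multiplier < 0")
            if t.background_prob * t.signal_multiplier > 1.0:
                raise ConfigError(
                    f"vocabulary[{t.pt_name}]: background_prob * signal_multiplier > 1"
                )


@dataclass
class SimulationTruth:
    """Generative ground truth for one simulated report cohort."""

    case_ids: np.ndarray
    exposed: np.ndarray  # bool, aligned with case_ids
    true_or: dict  # pt_name -> population reporting odds ratio
    signal_terms: tuple  # pt names with signal_multiplier != 1
    duplicate_rows: list = field(default_factory=list)  # obsolete (caseid, caseversion)

    def exposure_map(self) -> dict:
        return dict(zip(self.case_ids.tolist(), self.exposed.tolist()))

    def exposed_ids(self) -> set:
        return set(self.case_ids[self.exposed].tolist())

    def to_json(self, path) -> None:
        payload = {
            "exposure": {c: bool(e) for c, e in zip(self.case_ids, self.exposed)},
            "true_or": self.true_or,
            "signal_terms": list(self.signal_terms),
            "duplicate_rows": [list(r) for r in self.duplicate_rows],
        }
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)


@dataclass
class FaersTables:
    """The five raw report tables in the "$"-delimited dialect."""

    demo: pd.DataFrame
    drug: pd.DataFrame
    reac: pd.DataFrame
    ther: pd.DataFrame
    outc: pd.DataFrame

    def write(self, outdir) -> dict:
        os.makedirs(outdir, exist_ok=True)
        paths = {}
        for kind in ("demo", "drug", "reac", "ther", "outc"):
            path = os.path.join(outdir, f"{kind}.txt")
            write_ascii_table(getattr(self, kind), path)
            paths[kind] = path
        return paths


def true_odds_ratio(q: float, lam: float) -> float:
    """Closed-form reporting odds ratio of a term under the generator.

    With per-report event probability ``q`` among the unexposed and
    ``q * lam`` among the exposed, the population odds ratio is
    ``[q*lam / (1 - q*lam)] / [q / (1 - q)]``.
    """
    if not (0.0 < q < 1.0):
        raise DomainError("q must lie in (0, 1)")
    if lam < 0:
        raise DomainError("lam must be >= 0")
    if q * lam >= 1.0:
        raise DomainError("q * lam must be < 1")
    if lam == 0.0:
        return 0.0
    return (q * lam / (1.0 - q * lam)) / (q / (1.0 - q))


def _yyyymmdd(dates: np.ndarray) -> np.ndarray:
    """datetime64[D] array -> YYYYMMDD digit strings (vectorized)."""
    d = dates.astype("datetime64[D]")
    years = d.astype("datetime64[Y]").astype(int) + 1970
    months = d.astype("datetime64[M]").astype(int) % 12 + 1
    days = (d - d.astype("datetime64[M]")).astype(int) + 1
    return pd.Series(years * 10000 + months * 100 + days).astype(str).to_numpy()


def _categorical(rng, table: dict, size: int) -> np.ndarray:
    keys = np.array(list(table.keys()), dtype=object)
    probs = np.array([table[k] for k in keys], dtype=float)
    probs = probs / probs.sum()  # guard rounding after validate()
    return rng.choice(keys, size=size, p=probs)


def simulate_reports(cfg: SimConfig) -> tuple[FaersTables, SimulationTruth]:
    """Generate one report cohort plus its ground truth.

    Emits exactly ``n_reports + round(duplicate_rate * n_reports)`` DEMO rows;
    deterministic (byte-identical files) under identical config and seed.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_reports

    case_ids = _case_id_array(n)
    exposed = rng.random(n) < cfg.p_exposed

    fda_dates = _EPOCH + rng.integers(0, _PERIOD_DAYS, n).astype("timedelta64[D]")
    event_lag = rng.integers(0, 120, n).astype("timedelta64[D]")
    event_dates = fda_dates - event_lag
    event_missing = rng.random(n) < cfg.event_date_missing_rate

    sex_draw = _categorical(rng, cfg.gender_probs, n)
    sex = np.where(sex_draw == "Unknown", "UNK", sex_draw).astype(object)

    age_years = cfg.age_years_distribution.sample(rng, n)
    age_years = np.where(age_years < 0, np.nan, age_years)
    # mix of unit codes exercises downstream normalization: YR / MON / DEC
    unit_pick = rng.random(n)
    age_cod = np.where(unit_pick < 0.90, "YR", np.where(unit_pick < 0.95, "MON", "DEC"))
    age_value = np.where(
        age_cod == "YR", np.round(age_years, 1),
        np.where(age_cod == "MON", np.round(age_years * 12.0, 1), np.round(age_years / 10.0, 2)),
    )
    age_missing = np.isnan(age_years)

    weight_kg = cfg.weight_kg_distribution.sample(rng, n)
    wt_pick = rng.random(n)
    wt_cod = np.where(wt_pick < 0.92, "KG", "LBS")
    wt_value = np.where(
        wt_cod == "KG", np.round(weight_kg, 1), np.round(weight_kg / 0.453592, 1)
    )
    wt_missing = np.isnan(weight_kg)

    occp = _categorical(rng, cfg.reporter_probs, n)
    country = _categorical(rng, cfg.country_probs, n)
    route = _categorical(rng, cfg.route_probs, n)
    outcome = _categorical(rng, cfg.outcome_probs, n)

    def _num_str(values, missing_mask):
        out = pd.Series(values).astype(str).to_numpy(dtype=object)
        out[missing_mask] = ""
        return out

    demo = pd.DataFrame(
        {
            "caseid": case_ids,
            "caseversion": np.array(["1", "2"], dtype=object)[rng.integers(0, 2, n)],
            "fda_dt": _yyyymmdd(fda_dates),
            "event_dt": np.where(event_missing, "", _yyyymmdd(event_dates)),
            "sex": sex,
            "age": _num_str(age_value, age_missing),
            "age_cod": np.where(age_missing, "", age_cod),
            "wt": _num_str(wt_value, wt_missing),
            "wt_cod": np.where(wt_missing, "", wt_cod),
            "occp_cod": occp,
            "occr_country": country,
        }
    )

    # DRUG: exposed cases carry the study drug as primary suspect; unexposed
    # cases carry 1-3 decoy drugs (first as PS).  A small fraction of
    # unexposed cases additionally list the study drug in a non-suspect role,
    # exercising the role filter downstream.
    drug_case, drug_seq, drug_name, drug_role, drug_route = [], [], [], [], []
    exp_idx = np.nonzero(exposed)[0]
    drug_case.append(case_ids[exp_idx])
    drug_seq.append(np.ones(exp_idx.size, dtype=int))
    drug_name.append(np.full(exp_idx.size, cfg.study_drug, dtype=object))
    drug_role.append(np.full(exp_idx.size, "PS", dtype=object))
    drug_route.append(route[exp_idx])

    unexp_idx = np.nonzero(~exposed)[0]
    n_decoys = rng.integers(1, 4, unexp_idx.size)
    decoy_roles = np.array(["PS", "SS", "C"], dtype=object)
    for k in (1, 2, 3):
        sel = unexp_idx[n_decoys >= k]
        if sel.size == 0:
            continue
        drug_case.append(case_ids[sel])
        drug_seq.append(np.full(sel.size, k, dtype=int))
        drug_name.append(rng.choice(np.array(DECOY_DRUGS, dtype=object), size=sel.size))
        drug_role.append(np.full(sel.size, decoy_roles[k - 1], dtype=object))
        drug_route.append(route[sel])
    nonsuspect = unexp_idx[rng.random(unexp_idx.size) < 0.01]
    if nonsuspect.size:
        drug_case.append(case_ids[nonsuspect])
        drug_seq.append(np.full(nonsuspect.size, 9, dtype=int))
        drug_name.append(np.full(nonsuspect.size, cfg.study_drug, dtype=object))
        drug_role.append(np.full(nonsuspect.size, "SS", dtype=object))
        drug_route.append(route[nonsuspect])

    drug = pd.DataFrame(
        {
            "caseid": np.concatenate(drug_case),
            "drug_seq": np.concatenate(drug_seq).astype(str),
            "drugname": np.concatenate(drug_name),
            "role_cod": np.concatenate(drug_role),
            "route": np.concatenate(drug_route),
        }
    ).sort_values(["caseid", "drug_seq"], kind="stable").reset_index(drop=True)

    # REAC: independent Bernoulli per term per report
    pts = [t.pt_name for t in cfg.vocabulary]
    pi = np.array([t.background_prob for t in cfg.vocabulary])
    lam = np.array([t.signal_multiplier for t in cfg.vocabulary])
    probs = np.where(exposed[:, None], pi * lam, pi)
    present = rng.random((n, len(pts))) < probs
    row_idx, col_idx = np.nonzero(present)
    reac = pd.DataFrame(
        {
            "caseid": case_ids[row_idx],
            "pt": np.array(pts, dtype=object)[col_idx],
        }
    )

    # THER: therapy start of drug_seq 1, start = event date - offset
    offsets = cfg.therapy_offset_days_distribution.sample(rng, n)
    has_start = ~np.isnan(offsets) & ~event_missing
    start_dates = event_dates - np.nan_to_num(np.round(offsets), nan=0.0).astype(
        "timedelta64[D]"
    )
    ther_idx = np.nonzero(has_start)[0]
    ther = pd.DataFrame(
        {
            "caseid": case_ids[ther_idx],
            "dsg_drug_seq": np.ones(ther_idx.size, dtype=int).astype(str),
            "start_dt": _yyyymmdd(start_dates[ther_idx]),
        }
    )

    outc_idx = np.nonzero(outcome != "")[0]
    outc = pd.DataFrame(
        {"caseid": case_ids[outc_idx], "outc_cod": outcome[outc_idx]}
    )

    truth = SimulationTruth(
        case_ids=case_ids,
        exposed=exposed,
        true_or={
            t.pt_name: true_odds_ratio(t.background_prob, t.signal_multiplier)
            for t in cfg.vocabulary
        },
        signal_terms=tuple(t.pt_name for t in cfg.vocabulary if t.signal_multiplier != 1.0),
    )
    tables = FaersTables(demo=demo, drug=drug, reac=reac, ther=ther, outc=outc)

    if cfg.duplicate_rate > 0:
        dup_seed = int(rng.integers(0, 2**31 - 1))
        tables, duplicate_rows = inject_duplicates(tables, cfg.duplicate_rate, dup_seed)
        truth.duplicate_rows = duplicate_rows
    return tables, truth


def inject_duplicates(
    tables: FaersTables, rate: float, seed: int
) -> tuple[FaersTables, list]:
    """Plant earlier-version DEMO records for round-half-up(rate * n) cases.

    Each planted row has strictly smaller caseversion AND fda_dt than the
    retained record (the original's version is raised to >= 2 first) and
    perturbed demographics.  Returns the new tables plus the obsolete
    (caseid, caseversion) pairs.
    """
    if not (0.0 <= rate < 1.0):
        raise ConfigError("duplicate rate must lie in [0, 1)")
    if rate == 0.0 or tables.demo.empty:
        return tables, []
    rng = np.random.default_rng(seed)
    demo = tables.demo.copy()
    n = len(demo)
    n_dup = _round_half_up(rate * n)
    chosen = np.sort(rng.choice(n, size=n_dup, replace=False))

    versions = pd.to_numeric(demo["caseversion"], errors="coerce").fillna(1).astype(int)
    bumped = versions.iloc[chosen].clip(lower=2)
    demo.iloc[chosen, demo.columns.get_loc("caseversion")] = bumped.astype(str).values

    dups = demo.iloc[chosen].copy()
    dups["caseversion"] = (bumped - 1).astype(str).values
    old_dates = dups["fda_dt"].to_numpy()
    parsed = pd.to_datetime(pd.Series(old_dates), format="%Y%m%d", errors="coerce")
    shift = rng.integers(30, 400, n_dup).astype("timedelta64[D]")
    new_dates = parsed.to_numpy(dtype="datetime64[D]") - shift
    dups["fda_dt"] = _yyyymmdd(new_dates)
    # perturbed demographics on the obsolete record
    dups["sex"] = "UNK"
    dups["wt"] = ""
    dups["wt_cod"] = ""

    out_demo = pd.concat([demo, dups], ignore_index=True)
    obsolete = list(zip(dups["caseid"].tolist(), dups["caseversion"].tolist()))
    return (
        FaersTables(
            demo=out_demo, drug=tables.drug, reac=tables.reac,
            ther=tables.ther, outc=tables.outc,
        ),
        obsolete,
    )


def write_pt_soc_map(vocabulary, path) -> None:
    """Emit the simulator vocabulary's PT->SOC dictionary as a two-column TSV."""
    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write("pt\tsoc\n")
        for t in vocabulary:
            fh.write(f"{t.pt_name}\t{t.soc_name}\n")


# ---------------------------------------------------------------------------
# network-track inputs


@dataclass
class NetworkSimConfig:
    """Study conditions of the network-input generator."""

    n_drug_targets: int = 300
    n_disease_genes: int = 2000
    overlap_size: int = 200
    relevance_score_distribution: Distribution = Distribution("uniform", (11.0, 100.0))
    edge_prob: float = 0.05
    n_hubs: int = 5
    hub_fraction: float = 0.5
    n_terms: int = 40
    term_size_range: tuple = (10, 60)
    n_planted_terms: int = 3
    enrichment_factor: float = 5.0
    seed: int = 0

    def validate(self) -> None:
        if self.overlap_size > min(self.n_drug_targets, self.n_disease_genes):
            raise ConfigError("overlap_size exceeds min(n_drug_targets, n_disease_genes)")
        if not (0.0 < self.hub_fraction <= 1.0):
            raise ConfigError("hub_fraction must lie in (0, 1]")
        if not (0.0 <= self.edge_prob <= 1.0):
            raise ConfigError("edge_prob must lie in [0, 1]")
        if self.n_hubs > self.overlap_size:
            raise ConfigError("n_hubs exceeds the graph size (overlap_size)")
        lo, hi = self.term_size_range
        if not (1 <= lo <= hi <= self.n_disease_genes):
            raise ConfigError("term_size_range out of bounds")
        if self.n_planted_terms > self.n_terms:
            raise ConfigError("n_planted_terms exceeds n_terms")
        if self.enrichment_factor < 1.0:
            raise ConfigError("enrichment_factor must be >= 1")


@dataclass
class NetworkTruth:
    overlap: frozenset
    hubs: frozenset
    planted_terms: tuple

    def to_json(self, path) -> None:
        payload = {
            "overlap": sorted(self.overlap),
            "hubs": sorted(self.hubs),
            "planted_terms": list(self.planted_terms),
        }
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)


@dataclass
class NetworkInputs:
    drug_targets: list
    disease_scores: pd.DataFrame  # columns: symbol, score
    edges: pd.DataFrame  # columns: node_a, node_b, combined_score
    genesets: GeneSetCollection
    truth: NetworkTruth

    def write(self, outdir) -> dict:
        os.makedirs(outdir, exist_ok=True)
        paths = {
            "drug_targets": os.path.join(outdir, "drug_targets.txt"),
            "disease_scores": os.path.join(outdir, "disease_scores.tsv"),
            "edges": os.path.join(outdir, "edges.tsv"),
            "genesets": os.path.join(outdir, "genesets.gmt"),
            "truth": os.path.join(outdir, "network_truth.json"),
        }
        with open(paths["drug_targets"], "w", encoding="utf-8") as fh:
            fh.write("\n".join(self.drug_targets) + "\n")
        self.disease_scores.to_csv(paths["disease_scores"], sep="\t", index=False)
        self.edges.to_csv(paths["edges"], sep="\t", index=False)
        write_gmt(self.genesets, paths["genesets"])
        self.truth.to_json(paths["truth"])
        return paths


def simulate_network_inputs(cfg: NetworkSimConfig) -> NetworkInputs:
    """Generate target lists, a scored edge list and a GMT collection.

    The drug and disease lists share exactly ``overlap_size`` symbols; each
    planted hub has expected degree >= hub_fraction * (n_nodes - 1); planted
    GMT terms contain round(factor * K * n / N) members of the shared set
    (their expected null overlap times the enrichment factor).
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)

    disease_symbols = [f"G{i:05d}" for i in range(1, cfg.n_disease_genes + 1)]
    overlap = sorted(
        rng.choice(np.array(disease_symbols, dtype=object), cfg.overlap_size, replace=False)
    )
    drug_only = [f"D{i:04d}" for i in range(1, cfg.n_drug_targets - cfg.overlap_size + 1)]
    drug_targets = list(overlap) + drug_only
    rng.shuffle(drug_targets)

    scores = cfg.relevance_score_distribution.sample(rng, cfg.n_disease_genes)
    disease_scores = pd.DataFrame(
        {"symbol": disease_symbols, "score": np.round(scores, 3)}
    )

    # graph over the shared symbols: Erdos-Renyi background + planted hubs
    nodes = np.array(overlap, dtype=object)
    n_nodes = nodes.size
    iu, ju = np.triu_indices(n_nodes, k=1)
    adj = rng.random(iu.size) < cfg.edge_prob
    hubs = sorted(rng.choice(nodes, cfg.n_hubs, replace=False))
    hub_pos = {np.flatnonzero(nodes == h)[0] for h in hubs}
    for h in hub_pos:
        wired = rng.random(n_nodes) < cfg.hub_fraction
        wired[h] = False
        sel = (iu == h) | (ju == h)
        partner = np.where(iu[sel] == h, ju[sel], iu[sel])
        adj[sel] |= wired[partner]
    kept = np.flatnonzero(adj)
    edge_scores = np.round(rng.uniform(0.401, 0.999, kept.size), 3)
    node_a = nodes[iu[kept]]
    node_b = nodes[ju[kept]]
    # sub-threshold decoy edges exercise the confidence filter on load
    n_decoy = max(1, kept.size // 10)
    decoy = rng.choice(np.flatnonzero(~adj), min(n_decoy, int((~adj).sum())), replace=False)
    edges = pd.DataFrame(
        {
            "node_a": np.concatenate([node_a, nodes[iu[decoy]]]),
            "node_b": np.concatenate([node_b, nodes[ju[decoy]]]),
            "combined_score": np.concatenate(
                [edge_scores, np.round(rng.uniform(0.05, 0.40, decoy.size), 3)]
            ),
        }
    )

    # gene sets over the disease-gene universe with planted enrichment in the
    # shared (query) set
    universe = np.array(disease_symbols, dtype=object)
    query = set(overlap)
    non_query = np.array(sorted(set(disease_symbols) - query), dtype=object)
    query_arr = np.array(sorted(query), dtype=object)
    lo, hi = cfg.term_size_range
    sets = []
    planted_ids = []
    for i in range(cfg.n_terms):
        size = int(rng.integers(lo, hi + 1))
        category = CATEGORIES[i % len(CATEGORIES)]
        if i < cfg.n_planted_terms:
            term_id = f"TERM_P{i + 1:02d}"
            planted_ids.append(term_id)
            expected_null = size * len(query) / cfg.n_disease_genes
            k_in = int(np.clip(
                _round_half_up(cfg.enrichment_factor * expected_null),
                0, min(size, len(query)),
            ))
            members = np.concatenate([
                rng.choice(query_arr, k_in, replace=False),
                rng.choice(non_query, size - k_in, replace=False),
            ])
        else:
            term_id = f"TERM_{i + 1:03d}"
            members = rng.choice(universe, size, replace=False)
        sets.append(
            GeneSet(
                term_id=term_id, name=term_id, category=category,
                members=frozenset(str(m).casefold() for m in members),
            )
        )

    truth = NetworkTruth(
        overlap=frozenset(str(s).casefold() for s in overlap),
        hubs=frozenset(hubs),
        planted_terms=tuple(planted_ids),
    )
    return NetworkInputs(
        drug_targets=drug_targets,
        disease_scores=disease_scores,
        edges=edges,
        genesets=GeneSetCollection(sets=sets),
        truth=truth,
    )
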