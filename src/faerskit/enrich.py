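"""Hypergeometric over-representation analysis (ORA).

Given a query gene set, an annotation collection (GMT terms grouped into the
GO-BP/GO-CC/GO-MF/KEGG categories) and a gene universe, each term is scored
with the one-sided hypergeometric upper tail

    p = P(X >= k),  X ~ Hypergeom(N population, K term members, n draws)

computed by exact integer summation of binomial coefficients.  Raw p-values
are adjusted with the Benjamini-Hochberg step-up procedure within each
category, and a term is significant under the dual threshold raw p < 0.05
and adjusted p < 0.05.  The gene ratio reported per term is k/n with n the
number of query symbols mappable to the universe.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from math import comb

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .errors import DomainError, FormatError

CATEGORIES = ("GO-BP", "GO-CC", "GO-MF", "KEGG")
#: per-category cap applied when selecting top terms
TOP_N = {"GO-BP": 10, "GO-CC": 10, "GO-MF": 10, "KEGG": 30}

__all__ = [
    "GeneSet",
    "GeneSetCollection",
    "EnrichmentRow",
    "hypergeom_pvalue",
    "bh_adjust",
    "run_ora",
    "select_top_terms",
    "read_gmt",
    "write_gmt",
    "CATEGORIES",
]


@dataclass(frozen=True)
class GeneSet:
    term_id: str
    name: str
    category: str  # one of CATEGORIES
    members: frozenset


@dataclass
class GeneSetCollection:
    sets: list = field(default_factory=list)

    def __iter__(self):
        return iter(self.sets)

    def __len__(self):
        return len(self.sets)

    def all_symbols(self) -> set[str]:
        out: set[str] = set()
        for gs in self.sets:
            out |= gs.members
        return out


@dataclass(frozen=True)
class EnrichmentRow:
    term_id: str
    name: str
    category: str
    k: int  # query symbols in the term
    n: int  # mappable query size (gene-ratio denominator)
    big_k: int  # term size within the universe
    big_n: int  # universe size
    p_raw: float
    p_adjusted: float
    overlap: frozenset

    @property
    def gene_ratio(self) -> float:
        return self.k / self.n

    @property
    def significant(self) -> bool:
        return self.p_raw < 0.05 and self.p_adjusted < 0.05


def hypergeom_pvalue(k: int, big_k: int, n: int, big_n: int) -> float:
    """Upper-tail P(X >= k) by exact summation.

    Population ``big_n`` with ``big_k`` successes, ``n`` draws.  Exact big-
    integer arithmetic keeps the sum accurate to machine precision.
    """
    if not (0 <= k <= min(n, big_k)) or big_k > big_n or n > big_n:
        raise DomainError(
            f"invalid hypergeometric bounds: k={k}, K={big_k}, n={n}, N={big_n}"
        )
    if k == 0:
        return 1.0
    numerator = sum(
        comb(big_k, i) * comb(big_n - big_k, n - i)
        for i in range(k, min(n, big_k) + 1)
        if n - i <= big_n - big_k
    )
    return min(numerator / comb(big_n, n), 1.0)


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order, capped at 1."""
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise DomainError("p-values must lie in [0, 1]")
    _, adjusted, _, _ = multipletests(p, method="fdr_bh")
    return adjusted


def _fold(symbols) -> set[str]:
    return {str(s).strip().casefold() for s in symbols if str(s).strip()}


def run_ora(query, collection: GeneSetCollection, universe=None) -> list[EnrichmentRow]:
    """Over-representation test of a query set against every annotated term.

    The universe defaults to all symbols appearing in the collection.  Query
    symbols outside the universe are dropped (counted as unmappable); an
    empty mappable query is a domain error.  One row is returned per term
    overlapping the query (k >= 1); BH adjustment runs within each category.
    """
    uni = _fold(universe) if universe is not None else collection.all_symbols()
    uni = {str(s).strip().casefold() for s in uni}
    if not uni:
        raise DomainError("empty universe")
    q = _fold(query)
    mappable = q & uni
    if not mappable:
        raise DomainError("no query symbol maps into the universe")
    n, big_n = len(mappable), len(uni)

    raw_rows = []
    for gs in collection:
        members = _fold(gs.members) & uni
        overlap = mappable & members
        if not overlap:
            continue
        p = hypergeom_pvalue(len(overlap), len(members), n, big_n)
        raw_rows.append((gs, overlap, len(members), p))

    rows: list[EnrichmentRow] = []
    for category in CATEGORIES:
        cat_rows = [r for r in raw_rows if r[0].category == category]
        if not cat_rows:
            continue
        adjusted = bh_adjust([p for _, _, _, p in cat_rows])
        for (gs, overlap, big_k, p), p_adj in zip(cat_rows, adjusted):
            rows.append(
                EnrichmentRow(
                    term_id=gs.term_id,
                    name=gs.name,
                    category=gs.category,
                    k=len(overlap),
                    n=n,
                    big_k=big_k,
                    big_n=big_n,
                    p_raw=p,
                    p_adjusted=float(p_adj),
                    overlap=frozenset(overlap),
                )
            )
    rows.sort(key=lambda r: (r.category, r.p_adjusted, r.p_raw, r.term_id))
    return rows


def select_top_terms(rows) -> list[EnrichmentRow]:
    """Significant terms capped per category (top 10 per GO subclass, 30 KEGG).

    Ranking is by adjusted p ascending, ties broken by raw p then term id.
    """
    out: list[EnrichmentRow] = []
    for category in CATEGORIES:
        significant = [r for r in rows if r.category == category and r.significant]
        significant.sort(key=lambda r: (r.p_adjusted, r.p_raw, r.term_id))
        out.extend(significant[: TOP_N[category]])
    return out


def enrichment_frame(rows) -> pd.DataFrame:
    records = [
        {
            "term": r.term_id,
            "name": r.name,
            "category": r.category,
            "k": r.k,
            "n": r.n,
            "K": r.big_k,
            "N": r.big_n,
            "gene_ratio": r.gene_ratio,
            "p": r.p_raw,
            "p_adjusted": r.p_adjusted,
            "genes": ",".join(sorted(r.overlap)),
        }
        for r in rows
    ]
    cols = ["term", "name", "category", "k", "n", "K", "N", "gene_ratio", "p", "p_adjusted", "genes"]
    return pd.DataFrame(records, columns=cols)


def read_gmt(path) -> GeneSetCollection:
    """Read a GMT file; the description field encodes the category when it
    matches one of GO-BP/GO-CC/GO-MF/KEGG (defaults to KEGG otherwise)."""
    sets = []
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh, delimiter="\t")
        for lineno, row in enumerate(reader, start=1):
            if not row or all(not c.strip() for c in row):
                continue
            if len(row) < 3:
                raise FormatError(f"{path}: line {lineno} needs id, description, members")
            term_id, desc = row[0].strip(), row[1].strip()
            category = desc if desc in CATEGORIES else "KEGG"
            members = frozenset(_fold(row[2:]))
            sets.append(GeneSet(term_id=term_id, name=term_id, category=category, members=members))
    return GeneSetCollection(sets=sets)


def write_gmt(collection: GeneSetCollection, path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        for gs in collection:
            writer.writerow([gs.term_id, gs.category, *sorted(gs.members)])
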