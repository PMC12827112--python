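"""Preferred-term to organ-class mapping.

The regulatory event dictionary (MedDRA) is licensed and never bundled; the
hierarchy is consumed as a plain two-column TSV (PT, SOC) supplied by the
user or emitted by the simulator.  Each PT maps to exactly one primary SOC;
multiaxial secondary assignments are out of scope.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field

from .errors import DictionaryError

UNMAPPED = "UNMAPPED"

__all__ = ["PtSocMap", "load_pt_soc_map", "soc_of", "UNMAPPED"]


@dataclass
class PtSocMap:
    """Case-insensitive PT -> primary SOC lookup with an unmapped counter."""

    mapping: dict[str, str] = field(default_factory=dict)
    _unmapped: set = field(default_factory=set)

    def soc_of(self, pt: str) -> str:
        key = str(pt).strip().casefold()
        if not key or key not in self.mapping:
            self._unmapped.add(key)
            return UNMAPPED
        return self.mapping[key]

    @property
    def unmapped_count(self) -> int:
        """Number of distinct PTs queried that had no SOC assignment."""
        return len(self._unmapped)

    def socs(self):
        return sorted(set(self.mapping.values()))

    @classmethod
    def from_pairs(cls, pairs) -> "PtSocMap":
        mapping: dict[str, str] = {}
        conflicts = []
        for pt, soc in pairs:
            key = str(pt).strip().casefold()
            soc = str(soc).strip()
            if not key or not soc:
                raise DictionaryError(f"empty PT or SOC label in row ({pt!r}, {soc!r})")
            if key in mapping and mapping[key] != soc:
                conflicts.append(pt)
            mapping[key] = soc
        if conflicts:
            raise DictionaryError(
                "conflicting SOC assignments for PT(s): " + ", ".join(sorted(set(conflicts)))
            )
        return cls(mapping=mapping)


def load_pt_soc_map(path) -> PtSocMap:
    """Read a two-column TSV (PT, SOC); a literal "pt"/"soc" header is skipped."""
    pairs = []
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh, delimiter="\t")
        for i, row in enumerate(reader):
            if not row or all(not c.strip() for c in row):
                continue
            if len(row) < 2:
                raise DictionaryError(f"{path}: line {i + 1} has fewer than 2 columns")
            if i == 0 and row[0].strip().lower() == "pt" and row[1].strip().lower() == "soc":
                continue
            pairs.append((row[0], row[1]))
    return PtSocMap.from_pairs(pairs)


def soc_of(pt: str, mapping: PtSocMap) -> str:
    """Functional wrapper around :meth:`PtSocMap.soc_of` (never raises)."""
    return mapping.soc_of(pt)
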