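"""Ingestion and canonicalisation of drug-drug interaction tables.

Each drug information resource (DIR) ships a raw table of interacting
name pairs with optional severity/evidence labels and free-text advice.
This module turns such a table into a clean, deduplicated ``DIRTable``:

1. class-level rows (e.g. "beta blockers" x verapamil) are expanded to
   one row per class member;
2. raw names are resolved through an authoritative mapping table to
   normalised ingredient concepts (rows with unmapped or non-drug
   interactants — herbs, foods, beverages, lab tests — are dropped and
   counted);
3. pairs are canonicalised so that swapped duplicates ([D1, D2] vs
   [D2, D1]) coincide;
4. duplicate rows per canonical pair are merged, accumulating every
   observed severity rank; the resolved severity is the most severe one
   (smallest rank), and the strongest evidence level is kept.

Rows whose two names collapse onto the same ingredient (salt variants of
one drug listed against each other) are dropped as self-pairs and
counted; a conservation check guarantees that every input row is either
merged into a surviving record's provenance or counted as dropped.
"""
from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .errors import SelfPairError
from .schemes import EvidenceScheme, SeverityScheme

logger = logging.getLogger(__name__)

#: Sentinel statuses in the name-mapping table.
UNMAPPED = "UNMAPPED"
NON_DRUG = "NON_DRUG"
INGREDIENT = "INGREDIENT"

RAW_TABLE_COLUMNS = ("dir", "drug_1", "drug_2", "severity", "evidence", "advice_text", "description")


def _order_key(name: str) -> tuple[str, str]:
    # case-insensitive lexicographic, with a byte-wise tie-break so the
    # ordering is total and locale-independent
    return (name.casefold(), name)


@dataclass(frozen=True, order=True)
class CanonicalPair:
    """Unordered pair of normalised ingredient identifiers.

    ``a`` sorts before ``b`` under a fixed case-insensitive ordering, so
    the representation is independent of the input order.
    """

    a: str
    b: str

    def members(self) -> tuple[str, str]:
        return (self.a, self.b)

    def __str__(self) -> str:  # pragma: no cover - debugging aid
        return f"{self.a} -- {self.b}"


def canonicalize_pair(name_a: str, name_b: str) -> CanonicalPair:
    """Order-normalised pair of ingredient ids; self-pairs are rejected."""
    if not name_a or not name_b:
        raise ValueError("ingredient ids must be non-empty")
    if name_a == name_b:
        raise SelfPairError(f"self-pair: {name_a!r}")
    if _order_key(name_a) <= _order_key(name_b):
        return CanonicalPair(name_a, name_b)
    return CanonicalPair(name_b, name_a)


@dataclass(frozen=True)
class RawDDIRecord:
    """One row of a resource's raw DDI table, prior to normalisation."""

    source_dir: str
    name_1: str
    name_2: str
    severity_raw: str | None = None
    evidence_raw: str | None = None
    advice_text: str | None = None
    description: str | None = None
    row_id: str | None = None

    def __post_init__(self) -> None:
        if not self.name_1 or not self.name_2:
            raise ValueError("interactant names must be non-empty")


class NameMapping:
    """Total lookup from raw names to normalised ingredient concepts.

    Entries map a raw name to a preferred ingredient name, or to the
    sentinels ``UNMAPPED`` / ``NON_DRUG``.  Names absent from the table
    are treated as ``UNMAPPED``.  Lookup is case-insensitive.
    """

    def __init__(self, entries: Mapping[str, str]):
        self._entries: dict[str, str] = {}
        for raw, target in entries.items():
            self._entries[raw.strip().casefold()] = target

    def resolve(self, raw_name: str) -> str:
        """Ingredient concept name, or UNMAPPED / NON_DRUG."""
        return self._entries.get(raw_name.strip().casefold(), UNMAPPED)

    def __len__(self) -> int:
        return len(self._entries)


@dataclass
class ClassMapping:
    """Drug-class name -> member ingredient raw names."""

    entries: dict[str, tuple[str, ...]] = field(default_factory=dict)

    def is_class(self, name: str) -> bool:
        return name.strip().casefold() in self._index

    def members(self, name: str) -> tuple[str, ...]:
        return self._index[name.strip().casefold()]

    def __post_init__(self) -> None:
        self._index = {k.strip().casefold(): tuple(v) for k, v in self.entries.items()}

    def validated(self, mapping: NameMapping) -> "ClassMapping":
        """Drop class members that do not resolve through the name mapping."""
        cleaned: dict[str, tuple[str, ...]] = {}
        for cls, members in self.entries.items():
            kept = tuple(m for m in members if mapping.resolve(m) not in (UNMAPPED, NON_DRUG))
            dropped = set(members) - set(kept)
            if dropped:
                logger.warning("class %r: dropping unresolvable members %s", cls, sorted(dropped))
            cleaned[cls] = kept
        return ClassMapping(cleaned)


def expand_classes(records: Sequence[RawDDIRecord], classes: ClassMapping) -> list[RawDDIRecord]:
    """Replace class-level rows by one row per member ingredient.

    Both sides of a pair may be classes, producing the Cartesian product
    of their member lists.  Expanded rows inherit severity, evidence and
    advice from the class row.  A class with no surviving members drops
    the row with a warning.
    """
    out: list[RawDDIRecord] = []
    for rec in records:
        side_1 = classes.members(rec.name_1) if classes.is_class(rec.name_1) else (rec.name_1,)
        side_2 = classes.members(rec.name_2) if classes.is_class(rec.name_2) else (rec.name_2,)
        if not side_1 or not side_2:
            logger.warning("row %s: class expansion produced no members; dropping", rec.row_id)
            continue
        if side_1 == (rec.name_1,) and side_2 == (rec.name_2,):
            out.append(rec)
            continue
        for i, m1 in enumerate(side_1):
            for j, m2 in enumerate(side_2):
                suffix = f"#{i}.{j}" if len(side_1) * len(side_2) > 1 else ""
                out.append(
                    RawDDIRecord(
                        source_dir=rec.source_dir,
                        name_1=m1,
                        name_2=m2,
                        severity_raw=rec.severity_raw,
                        evidence_raw=rec.evidence_raw,
                        advice_text=rec.advice_text,
                        description=rec.description,
                        row_id=(rec.row_id or "") + suffix,
                    )
                )
    return out


def resolve_severity(severity_set: Iterable[int], scheme: SeverityScheme) -> int:
    """Most severe rank in the set (levels are ranked most-severe = 1)."""
    ranks = list(severity_set)
    if not ranks:
        raise ValueError("cannot resolve an empty severity set")
    for r in ranks:
        scheme.label_of(r)  # validates range
    return min(ranks)


@dataclass(frozen=True)
class NormalizedDDI:
    """A merged, normalised DDI record for one canonical pair."""

    pair: CanonicalPair
    severity_set: frozenset[int]
    severity: int | None
    evidence: str | None
    advice_texts: tuple[str, ...]
    provenance: tuple[str, ...]


@dataclass
class DIRTable:
    """One resource's deduplicated set of normalised DDI records."""

    dir_id: str
    records: dict[CanonicalPair, NormalizedDDI]

    @property
    def pairs(self) -> set[CanonicalPair]:
        return set(self.records)

    @property
    def ingredient_set(self) -> set[str]:
        out: set[str] = set()
        for pair in self.records:
            out.add(pair.a)
            out.add(pair.b)
        return out

    def __len__(self) -> int:
        return len(self.records)


@dataclass
class ExclusionReport:
    """Accounting of rows dropped during normalisation."""

    dir_id: str
    input_rows: int = 0
    unmapped: int = 0
    non_drug: int = 0
    self_pair: int = 0
    kept_rows: int = 0
    kept_pairs: int = 0

    @property
    def dropped(self) -> int:
        return self.unmapped + self.non_drug + self.self_pair

    def as_dict(self) -> dict:
        return {
            "dir": self.dir_id,
            "input_rows": self.input_rows,
            "unmapped": self.unmapped,
            "non_drug": self.non_drug,
            "self_pair": self.self_pair,
            "kept_rows": self.kept_rows,
            "kept_pairs": self.kept_pairs,
        }


def normalize_table(
    records: Sequence[RawDDIRecord],
    mapping: NameMapping,
    scheme: SeverityScheme,
    evidence_scheme: EvidenceScheme | None = None,
) -> tuple[DIRTable, ExclusionReport]:
    """Map, canonicalise and merge class-expanded raw rows into a DIRTable.

    Exclusion precedence per row: NON_DRUG, then UNMAPPED, then self-pair
    (each dropped row is counted exactly once).  Unknown severity labels
    raise ``UnknownSeverityLabel`` — the schemes are closed vocabularies.
    Evidence labels, validated against ``evidence_scheme`` when given, are
    merged by keeping the strongest level.
    """
    dir_id = records[0].source_dir if records else scheme.dir_id
    report = ExclusionReport(dir_id=dir_id, input_rows=len(records))

    merged: dict[CanonicalPair, dict] = {}
    for idx, rec in enumerate(records):
        c1 = mapping.resolve(rec.name_1)
        c2 = mapping.resolve(rec.name_2)
        if NON_DRUG in (c1, c2):
            report.non_drug += 1
            continue
        if UNMAPPED in (c1, c2):
            report.unmapped += 1
            continue
        if c1 == c2:
            report.self_pair += 1
            logger.debug("row %s: names collapse to %r; dropped as self-pair", rec.row_id, c1)
            continue
        pair = canonicalize_pair(c1, c2)

        sev_rank: int | None = None
        if rec.severity_raw:
            sev_rank = scheme.rank_of(rec.severity_raw)
        ev_strength: int | None = None
        if rec.evidence_raw and evidence_scheme is not None:
            ev_strength = evidence_scheme.strength_of(rec.evidence_raw)

        slot = merged.setdefault(
            pair, {"severities": set(), "evidence": None, "advice": [], "provenance": []}
        )
        if sev_rank is not None:
            slot["severities"].add(sev_rank)
        if ev_strength is not None:
            if slot["evidence"] is None or ev_strength < slot["evidence"]:
                slot["evidence"] = ev_strength
        if rec.advice_text and rec.advice_text not in slot["advice"]:
            slot["advice"].append(rec.advice_text)
        slot["provenance"].append(rec.row_id if rec.row_id is not None else f"{dir_id}:{idx}")
        report.kept_rows += 1

    table: dict[CanonicalPair, NormalizedDDI] = {}
    for pair in sorted(merged):
        slot = merged[pair]
        severities = frozenset(slot["severities"])
        table[pair] = NormalizedDDI(
            pair=pair,
            severity_set=severities,
            severity=resolve_severity(severities, scheme) if severities else None,
            evidence=(
                evidence_scheme.label_of(slot["evidence"])
                if slot["evidence"] is not None and evidence_scheme is not None
                else None
            ),
            advice_texts=tuple(slot["advice"]),
            provenance=tuple(slot["provenance"]),
        )
    report.kept_pairs = len(table)
    logger.info(
        "%s: %d rows in, %d pairs out (%d unmapped, %d non-drug, %d self-pair)",
        dir_id, report.input_rows, report.kept_pairs,
        report.unmapped, report.non_drug, report.self_pair,
    )
    return DIRTable(dir_id=dir_id, records=table), report


# ---------------------------------------------------------------------------
# CSV I/O (UTF-8, header row; dialects described in the project docs)
# ---------------------------------------------------------------------------

def read_raw_table(path: str | Path) -> list[RawDDIRecord]:
    """Read a raw DIR table (dir, drug_1, drug_2, severity, evidence, ...)."""
    frame = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = {"dir", "drug_1", "drug_2"} - set(frame.columns)
    if missing:
        raise ValueError(f"{path}: missing required columns {sorted(missing)}")
    records = []
    for idx, row in enumerate(frame.itertuples(index=False)):
        get = lambda col: getattr(row, col, "") if col in frame.columns else ""
        records.append(
            RawDDIRecord(
                source_dir=row.dir,
                name_1=row.drug_1,
                name_2=row.drug_2,
                severity_raw=get("severity") or None,
                evidence_raw=get("evidence") or None,
                advice_text=get("advice_text") or None,
                description=get("description") or None,
                row_id=f"{row.dir}:{idx}",
            )
        )
    return records


def read_name_mapping(path: str | Path) -> NameMapping:
    """Read a mapping CSV with columns raw_name, status, concept_name."""
    frame = pd.read_csv(path, dtype=str, keep_default_na=False)
    entries: dict[str, str] = {}
    for row in frame.itertuples(index=False):
        status = row.status.strip().upper()
        if status == INGREDIENT:
            entries[row.raw_name] = row.concept_name
        elif status in (UNMAPPED, NON_DRUG):
            entries[row.raw_name] = status
        else:
            raise ValueError(f"{path}: unknown mapping status {row.status!r}")
    return NameMapping(entries)


def read_class_mapping(path: str | Path) -> ClassMapping:
    """Read a class table CSV with columns class_name, member_name."""
    frame = pd.read_csv(path, dtype=str, keep_default_na=False)
    entries: dict[str, list[str]] = {}
    for row in frame.itertuples(index=False):
        entries.setdefault(row.class_name, []).append(row.member_name)
    return ClassMapping({k: tuple(v) for k, v in entries.items()})


def write_dir_table(table: DIRTable, path: str | Path) -> None:
    rows = []
    for pair in sorted(table.records):
        rec = table.records[pair]
        rows.append(
            {
                "dir": table.dir_id,
                "ingredient_a": pair.a,
                "ingredient_b": pair.b,
                "severity_rank": "" if rec.severity is None else rec.severity,
                "severity_set": "|".join(str(r) for r in sorted(rec.severity_set)),
                "evidence": rec.evidence or "",
                "advice_texts": " || ".join(rec.advice_texts),
                "n_source_rows": len(rec.provenance),
            }
        )
    pd.DataFrame(
        rows,
        columns=[
            "dir", "ingredient_a", "ingredient_b", "severity_rank",
            "severity_set", "evidence", "advice_texts", "n_source_rows",
        ],
    ).to_csv(path, index=False)


def read_dir_table(path: str | Path, scheme: SeverityScheme) -> DIRTable:
    """Round-trip reader for :func:`write_dir_table` output."""
    frame = pd.read_csv(path, dtype=str, keep_default_na=False)
    records: dict[CanonicalPair, NormalizedDDI] = {}
    dir_id = scheme.dir_id
    for row in frame.itertuples(index=False):
        dir_id = row.dir
        pair = canonicalize_pair(row.ingredient_a, row.ingredient_b)
        severities = frozenset(int(x) for x in row.severity_set.split("|") if x)
        records[pair] = NormalizedDDI(
            pair=pair,
            severity_set=severities,
            severity=int(row.severity_rank) if row.severity_rank else None,
            evidence=row.evidence or None,
            advice_texts=tuple(t for t in row.advice_texts.split(" || ") if t),
            provenance=(),
        )
    return DIRTable(dir_id=dir_id, records=records)


def write_exclusion_report(reports: Sequence[ExclusionReport], path: str | Path) -> None:
    payload = {rep.dir_id: rep.as_dict() for rep in reports}
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
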