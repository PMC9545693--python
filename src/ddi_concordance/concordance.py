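"""Agreement statistics between drug information resources.

Set-level statistics (Venn partition of three DDI pair sets, coverage
rates, Jaccard indices), rating-level statistics (severity and evidence
cross-tabulations with Not-found margins) and critical-rating overlaps.
All internal computation is in full precision; percentages are rounded
half-up to two decimals only at presentation time via :func:`round2`.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Mapping, Sequence

import pandas as pd

from .errors import EmptyReferenceSet, MissingEvidence
from .ingest import CanonicalPair, DIRTable, NormalizedDDI
from .schemes import EvidenceScheme, SeverityScheme

NOT_FOUND = "Not found"
NO_RATING = "none"


def round2(x: float, ndigits: int = 2) -> float:
    """Round half-up (not banker's rounding) for printed percentages."""
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class VennPartition:
    """Exclusive region counts of three sets A, B, C."""

    only_a: int
    only_b: int
    only_c: int
    ab_only: int
    ac_only: int
    bc_only: int
    abc: int
    labels: tuple[str, str, str] = ("A", "B", "C")

    @property
    def regions(self) -> tuple[int, ...]:
        return (self.only_a, self.only_b, self.only_c,
                self.ab_only, self.ac_only, self.bc_only, self.abc)

    @property
    def total(self) -> int:
        """|A ∪ B ∪ C| — the collated number of distinct members."""
        return sum(self.regions)

    @property
    def single_only(self) -> int:
        return self.only_a + self.only_b + self.only_c

    @property
    def exactly_two(self) -> int:
        return self.ab_only + self.ac_only + self.bc_only

    @property
    def size_a(self) -> int:
        return self.only_a + self.ab_only + self.ac_only + self.abc

    @property
    def size_b(self) -> int:
        return self.only_b + self.ab_only + self.bc_only + self.abc

    @property
    def size_c(self) -> int:
        return self.only_c + self.ac_only + self.bc_only + self.abc

    @property
    def ab_total(self) -> int:
        """|A ∩ B| inclusive of the triple region."""
        return self.ab_only + self.abc

    @property
    def ac_total(self) -> int:
        return self.ac_only + self.abc

    @property
    def bc_total(self) -> int:
        return self.bc_only + self.abc

    def as_dict(self) -> dict:
        a, b, c = self.labels
        return {
            "labels": list(self.labels),
            "exclusive": {
                f"{a}_only": self.only_a, f"{b}_only": self.only_b, f"{c}_only": self.only_c,
                f"{a}&{b}_only": self.ab_only, f"{a}&{c}_only": self.ac_only,
                f"{b}&{c}_only": self.bc_only, f"{a}&{b}&{c}": self.abc,
            },
            "inclusive_intersections": {
                f"{a}&{b}": self.ab_total, f"{a}&{c}": self.ac_total, f"{b}&{c}": self.bc_total,
            },
            "sizes": {a: self.size_a, b: self.size_b, c: self.size_c},
            "total": self.total,
        }


def venn_partition(
    A: set[CanonicalPair],
    B: set[CanonicalPair],
    C: set[CanonicalPair],
    labels: tuple[str, str, str] = ("A", "B", "C"),
) -> VennPartition:
    """Exact exclusive 7-region counts of three sets."""
    abc = A & B & C
    ab = (A & B) - abc
    ac = (A & C) - abc
    bc = (B & C) - abc
    return VennPartition(
        only_a=len(A - B - C),
        only_b=len(B - A - C),
        only_c=len(C - A - B),
        ab_only=len(ab),
        ac_only=len(ac),
        bc_only=len(bc),
        abc=len(abc),
        labels=labels,
    )


def coverage_rate(A: set, B: set) -> float:
    """Percentage of A covered by B: 100 * |A ∩ B| / |A| (full precision)."""
    if not A:
        raise EmptyReferenceSet("coverage rate undefined for an empty reference set")
    return 100.0 * len(A & B) / len(A)


def jaccard(A: set, B: set) -> float:
    """|A ∩ B| / |A ∪ B|; symmetric similarity in [0, 1]."""
    union = A | B
    if not union:
        raise ValueError("Jaccard index undefined for two empty sets")
    return len(A & B) / len(union)


# ---------------------------------------------------------------------------
# Rating cross-tabulations
# ---------------------------------------------------------------------------

@dataclass
class RatingCrossTab:
    """Counts of one resource's rating levels against other resources'.

    Rows are the row resource's level labels; for each comparison
    resource there is one counts table whose columns are that resource's
    levels plus a Not-found column for shared-pair misses.
    """

    row_dir: str
    row_levels: tuple[str, ...]
    counts: dict[str, pd.DataFrame] = field(default_factory=dict)

    def row_percentages(self, other_dir: str) -> pd.DataFrame:
        tab = self.counts[other_dir]
        totals = tab.sum(axis=1)
        return tab.div(totals.where(totals > 0, other=1), axis=0) * 100.0

    def to_long(self) -> pd.DataFrame:
        rows = []
        for other_dir, tab in self.counts.items():
            pct = self.row_percentages(other_dir)
            for row_level in tab.index:
                for col_level in tab.columns:
                    rows.append(
                        {
                            "row_dir": self.row_dir,
                            "row_level": row_level,
                            "col_dir": other_dir,
                            "col_level": col_level,
                            "count": int(tab.loc[row_level, col_level]),
                            "row_pct": round2(float(pct.loc[row_level, col_level])),
                        }
                    )
        return pd.DataFrame(rows)


def severity_crosstab(
    row_table: DIRTable,
    other_tables: Sequence[DIRTable],
    schemes: Mapping[str, SeverityScheme],
) -> RatingCrossTab:
    """Severity agreement of ``row_table`` against each other resource.

    Every record of the row resource must carry a resolved severity; for
    each of its levels the table counts shared pairs per other-resource
    level plus a Not-found column for pairs absent from that resource.
    """
    row_scheme = schemes[row_table.dir_id]
    result = RatingCrossTab(row_dir=row_table.dir_id, row_levels=row_scheme.levels)
    for other in other_tables:
        other_scheme = schemes[other.dir_id]
        cols = list(other_scheme.levels) + [NOT_FOUND]
        tab = pd.DataFrame(0, index=list(row_scheme.levels), columns=cols, dtype=int)
        for pair, rec in row_table.records.items():
            if rec.severity is None:
                raise ValueError(
                    f"{row_table.dir_id}: record {pair} has no resolved severity"
                )
            row_label = row_scheme.label_of(rec.severity)
            other_rec = other.records.get(pair)
            if other_rec is None:
                tab.loc[row_label, NOT_FOUND] += 1
            else:
                if other_rec.severity is None:
                    raise ValueError(
                        f"{other.dir_id}: record {pair} has no resolved severity"
                    )
                tab.loc[row_label, other_scheme.label_of(other_rec.severity)] += 1
        result.counts[other.dir_id] = tab
    return result


@dataclass
class EvidenceCrossTab:
    """Evidence agreement between a partially rated and a fully rated resource.

    Rows: first resource's evidence levels plus a ``none`` bucket for its
    unrated records and a Not-found row for pairs it lacks.  Columns: the
    second resource's levels plus a Not-found column.
    """

    first_dir: str
    second_dir: str
    counts: pd.DataFrame

    def row_coverage(self) -> pd.DataFrame:
        totals = self.counts.sum(axis=1)
        return self.counts.div(totals.where(totals > 0, other=1), axis=0) * 100.0

    def col_coverage(self) -> pd.DataFrame:
        totals = self.counts.sum(axis=0)
        return self.counts.div(totals.where(totals > 0, other=1), axis=1) * 100.0

    def to_long(self) -> pd.DataFrame:
        rows = []
        rowcov, colcov = self.row_coverage(), self.col_coverage()
        for r in self.counts.index:
            for c in self.counts.columns:
                rows.append(
                    {
                        "row_dir": self.first_dir,
                        "row_level": r,
                        "col_dir": self.second_dir,
                        "col_level": c,
                        "count": int(self.counts.loc[r, c]),
                        "row_coverage_pct": round2(float(rowcov.loc[r, c])),
                        "col_coverage_pct": round2(float(colcov.loc[r, c])),
                    }
                )
        return pd.DataFrame(rows)


def evidence_crosstab(
    first: DIRTable,
    second: DIRTable,
    first_scheme: EvidenceScheme,
    second_scheme: EvidenceScheme,
) -> EvidenceCrossTab:
    """Cross-tabulate evidence ratings, bucketing unrated rows of ``first``.

    The first resource may lack evidence on some records (they form an
    explicit ``none`` row); the second must rate every shared record, else
    ``MissingEvidence`` is raised.
    """
    rows = list(first_scheme.levels) + [NO_RATING, NOT_FOUND]
    cols = list(second_scheme.levels) + [NOT_FOUND]
    tab = pd.DataFrame(0, index=rows, columns=cols, dtype=int)

    for pair, rec in first.records.items():
        row_label = rec.evidence if rec.evidence is not None else NO_RATING
        other = second.records.get(pair)
        if other is None:
            tab.loc[row_label, NOT_FOUND] += 1
        else:
            if other.evidence is None:
                raise MissingEvidence(
                    f"{second.dir_id}: shared record {pair} lacks an evidence rating"
                )
            tab.loc[row_label, other.evidence] += 1

    for pair, rec in second.records.items():
        if pair in first.records:
            continue
        if rec.evidence is None:
            # Not-found margin only involves the fully rated resource's
            # own records; unrated ones cannot be placed on its axis.
            raise MissingEvidence(
                f"{second.dir_id}: record {pair} lacks an evidence rating"
            )
        tab.loc[NOT_FOUND, rec.evidence] += 1

    return EvidenceCrossTab(first_dir=first.dir_id, second_dir=second.dir_id, counts=tab)


# ---------------------------------------------------------------------------
# Critical-rating overlap
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PairwiseCritical:
    joint: int
    coverage_first: float   # % of the first resource's critical set
    coverage_second: float  # % of the second resource's critical set


@dataclass
class CriticalOverlapReport:
    """Joint-critical counts and coverages across three resources."""

    critical_sizes: dict[str, int]
    pairwise: dict[tuple[str, str], PairwiseCritical]
    triple_joint: int
    intersection_size: int
    intersection_critical: dict[str, int]

    def intersection_critical_share(self, dir_id: str) -> float:
        if self.intersection_size == 0:
            return 0.0
        return 100.0 * self.intersection_critical[dir_id] / self.intersection_size

    @property
    def triple_share_of_intersection(self) -> float:
        if self.intersection_size == 0:
            return 0.0
        return 100.0 * self.triple_joint / self.intersection_size

    def as_dict(self) -> dict:
        return {
            "critical_sizes": dict(self.critical_sizes),
            "pairwise": {
                f"{a}|{b}": {
                    "joint": pc.joint,
                    f"coverage_of_{a}_pct": round2(pc.coverage_first),
                    f"coverage_of_{b}_pct": round2(pc.coverage_second),
                }
                for (a, b), pc in self.pairwise.items()
            },
            "triple_joint": self.triple_joint,
            "intersection_size": self.intersection_size,
            "intersection_critical": dict(self.intersection_critical),
            "intersection_critical_share_pct": {
                d: round2(self.intersection_critical_share(d))
                for d in self.intersection_critical
            },
            "triple_share_of_intersection_pct": round2(self.triple_share_of_intersection),
        }


def critical_pairs(table: DIRTable, scheme: SeverityScheme) -> set[CanonicalPair]:
    """Pairs whose resolved severity falls in the scheme's critical set."""
    crit_ranks = scheme.critical_ranks
    return {
        pair for pair, rec in table.records.items()
        if rec.severity is not None and rec.severity in crit_ranks
    }


def critical_overlap(
    tables: Sequence[DIRTable],
    schemes: Mapping[str, SeverityScheme],
) -> CriticalOverlapReport:
    """Joint-critical overlap report for three resources.

    A joint-critical pair must be listed in both resources AND rated
    critical by both; coverages are taken against each resource's full
    critical set size.
    """
    if len(tables) != 3:
        raise ValueError("critical_overlap expects exactly three tables")
    crit = {t.dir_id: critical_pairs(t, schemes[t.dir_id]) for t in tables}
    sizes = {d: len(s) for d, s in crit.items()}

    pairwise: dict[tuple[str, str], PairwiseCritical] = {}
    ids = [t.dir_id for t in tables]
    for i in range(3):
        for j in range(i + 1, 3):
            a, b = ids[i], ids[j]
            joint = len(crit[a] & crit[b])
            pairwise[(a, b)] = PairwiseCritical(
                joint=joint,
                coverage_first=100.0 * joint / sizes[a] if sizes[a] else 0.0,
                coverage_second=100.0 * joint / sizes[b] if sizes[b] else 0.0,
            )

    triple = len(crit[ids[0]] & crit[ids[1]] & crit[ids[2]])
    abc = tables[0].pairs & tables[1].pairs & tables[2].pairs
    inter_crit = {d: len(crit[d] & abc) for d in ids}
    return CriticalOverlapReport(
        critical_sizes=sizes,
        pairwise=pairwise,
        triple_joint=triple,
        intersection_size=len(abc),
        intersection_critical=inter_crit,
    )


# ---------------------------------------------------------------------------
# Ingredient-restricted analysis and the intersection list
# ---------------------------------------------------------------------------

def ingredient_restricted_partition(tables: Sequence[DIRTable]) -> VennPartition:
    """Venn partition after restricting every table to shared ingredients.

    Each table is filtered to pairs whose BOTH members lie in the
    three-way intersection of the ingredient sets.
    """
    if len(tables) != 3:
        raise ValueError("expected exactly three tables")
    common = tables[0].ingredient_set & tables[1].ingredient_set & tables[2].ingredient_set
    filtered = [
        {p for p in t.pairs if p.a in common and p.b in common}
        for t in tables
    ]
    return venn_partition(*filtered, labels=tuple(t.dir_id for t in tables))


@dataclass(frozen=True)
class IntersectionEntry:
    pair: CanonicalPair
    payloads: Mapping[str, NormalizedDDI]


def build_intersection_list(tables: Sequence[DIRTable]) -> list[IntersectionEntry]:
    """Pairs present in all three tables, with each resource's payload."""
    if len(tables) != 3:
        raise ValueError("expected exactly three tables")
    common = tables[0].pairs & tables[1].pairs & tables[2].pairs
    return [
        IntersectionEntry(pair=pair, payloads={t.dir_id: t.records[pair] for t in tables})
        for pair in sorted(common)
    ]
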