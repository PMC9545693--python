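"""Verification harness over the published summary counts.

The original compendia extracts are not redistributable, but the study
report prints its dataset-level counts (per-resource DDI pair totals,
pairwise and three-way intersections, severity-level counts, joint
critical counts) alongside derived percentages.  This module stores
those printed counts as input data and recomputes every derived
percentage with the package's own coverage / share arithmetic, flagging
any printed figure that is not arithmetically consistent with its own
constituent counts.

Known inconsistencies in the source report, flagged here rather than
"fixed": the Micromedex-side coverage of the joint BNF-Micromedex
critical set and both directional coverages of the joint
Thesaurus-Micromedex critical set do not follow from the severity-table
critical set sizes under any obvious denominator (both candidate
denominators are reported); the BNF severity column's counts and
percentages disagree internally (the four counts sum to 51 619, not the
51 481 pair total); and one Micromedex share differs in the last digit
under half-up rounding.
"""
from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .concordance import round2

#: Printed dataset-level counts (the harness's input data).
PRINTED_COUNTS: dict = {
    "pairs": {"bnf": 51481, "thesaurus": 38037, "micromedex": 65446},
    "ingredients": {"bnf": 984, "thesaurus": 1001, "micromedex": 1967},
    "initial_names": {"bnf": 1004, "thesaurus": 1049, "micromedex": 2602},
    "pairwise_intersections": {
        "bnf|thesaurus": 14576,
        "bnf|micromedex": 14433,
        "thesaurus|micromedex": 11574,
    },
    "triple_intersection": 6970,
    "collated_total": 121351,
    "single_only_total": 94708,
    "exactly_two_total": 19673,
    "severity_counts": {
        "bnf": {"1": 12644, "2": 4997, "3": 273, "4": 33705},
        "thesaurus": {"1": 2949, "2": 12779, "3": 8195, "4": 14114},
        "micromedex": {"1": 5730, "2": 41713, "3": 15890, "4": 2113},
    },
    #: levels counted as critical, by rank
    "critical_ranks": {"bnf": [1], "thesaurus": [1, 2], "micromedex": [1, 2]},
    "critical_joint": {
        "bnf|thesaurus": 2429,
        "bnf|micromedex": 6026,
        "thesaurus|micromedex": 5014,
        "triple": 1768,
    },
    "intersection_critical": {"bnf": 3024, "thesaurus": 3647, "micromedex": 5681},
}


def exclusive_regions(counts: dict) -> dict[str, int]:
    """Exclusive 7-region counts by inclusion-exclusion on printed totals."""
    sizes = counts["pairs"]
    inter = counts["pairwise_intersections"]
    triple = counts["triple_intersection"]
    ab, ac, bc = inter["bnf|thesaurus"], inter["bnf|micromedex"], inter["thesaurus|micromedex"]
    return {
        "bnf_only": sizes["bnf"] - ab - ac + triple,
        "thesaurus_only": sizes["thesaurus"] - ab - bc + triple,
        "micromedex_only": sizes["micromedex"] - ac - bc + triple,
        "bnf&thesaurus_only": ab - triple,
        "bnf&micromedex_only": ac - triple,
        "thesaurus&micromedex_only": bc - triple,
        "triple": triple,
    }


def critical_set_sizes(counts: dict) -> dict[str, int]:
    return {
        d: sum(counts["severity_counts"][d][str(r)] for r in ranks)
        for d, ranks in counts["critical_ranks"].items()
    }


@dataclass(frozen=True)
class DerivedStat:
    """One printed statistic recomputed from its constituent counts."""

    name: str
    printed: float
    recomputed: float
    reproducible: bool  # expected to match at the printed precision
    note: str = ""


def _pct(numerator: float, denominator: float) -> float:
    return 100.0 * numerator / denominator


def derived_statistics(counts: dict | None = None) -> list[DerivedStat]:
    """Recompute every printed derived statistic from the printed counts."""
    c = counts if counts is not None else PRINTED_COUNTS
    sizes = c["pairs"]
    inter = c["pairwise_intersections"]
    triple = c["triple_intersection"]
    regions = exclusive_regions(c)
    region_sum = sum(regions.values())
    single = regions["bnf_only"] + regions["thesaurus_only"] + regions["micromedex_only"]
    two = (
        regions["bnf&thesaurus_only"]
        + regions["bnf&micromedex_only"]
        + regions["thesaurus&micromedex_only"]
    )
    crit = critical_set_sizes(c)
    joint = c["critical_joint"]
    inter_crit = c["intersection_critical"]

    stats: list[DerivedStat] = [
        # consistency of the printed collated totals with inclusion-exclusion
        DerivedStat("collated_total", c["collated_total"], region_sum, True,
                    "sum of the seven exclusive regions"),
        DerivedStat("single_only_total", c["single_only_total"], single, True),
        DerivedStat("exactly_two_total", c["exactly_two_total"], two, True,
                    "sum of pairwise intersections each minus the triple region"),
        # three-way listing coverages
        DerivedStat("triple_coverage_of_bnf_pct", 13.54, _pct(triple, sizes["bnf"]), True),
        DerivedStat("triple_coverage_of_thesaurus_pct", 18.32, _pct(triple, sizes["thesaurus"]), True),
        DerivedStat("triple_coverage_of_micromedex_pct", 10.65, _pct(triple, sizes["micromedex"]), True),
        DerivedStat("triple_share_of_collated_pct", 5.74, _pct(triple, region_sum), True),
        DerivedStat("single_only_share_pct", 78.04, _pct(single, region_sum), True),
        DerivedStat("exactly_two_share_pct", 16.21, _pct(two, region_sum), True),
        # pairwise listing coverages
        DerivedStat("bnf_thesaurus_coverage_of_bnf_pct", 28.31,
                    _pct(inter["bnf|thesaurus"], sizes["bnf"]), True),
        DerivedStat("bnf_thesaurus_coverage_of_thesaurus_pct", 38.32,
                    _pct(inter["bnf|thesaurus"], sizes["thesaurus"]), True),
        DerivedStat("bnf_micromedex_coverage_of_bnf_pct", 28.04,
                    _pct(inter["bnf|micromedex"], sizes["bnf"]), True),
        DerivedStat("bnf_micromedex_coverage_of_micromedex_pct", 22.05,
                    _pct(inter["bnf|micromedex"], sizes["micromedex"]), True),
        DerivedStat("thesaurus_micromedex_coverage_of_thesaurus_pct", 30.43,
                    _pct(inter["thesaurus|micromedex"], sizes["thesaurus"]), True),
        DerivedStat("thesaurus_micromedex_coverage_of_micromedex_pct", 17.68,
                    _pct(inter["thesaurus|micromedex"], sizes["micromedex"]), True),
    ]

    # severity-table shares
    printed_severity_pct = {
        "bnf": {"1": 24.56, "2": 9.46, "3": 0.51, "4": 65.47},
        "thesaurus": {"1": 7.75, "2": 33.60, "3": 21.54, "4": 37.11},
        "micromedex": {"1": 8.76, "2": 63.73, "3": 24.28, "4": 3.23},
    }
    severity_notes = {
        ("bnf", "2"): "printed count/percentage internally inconsistent "
                      "(BNF severity counts sum to 51619, not 51481)",
        ("bnf", "3"): "printed count/percentage internally inconsistent",
        ("micromedex", "2"): "printed value truncated; half-up rounding gives 63.74",
    }
    for dir_id, shares in printed_severity_pct.items():
        for rank, printed in shares.items():
            recomputed = _pct(c["severity_counts"][dir_id][rank], sizes[dir_id])
            key = (dir_id, rank)
            stats.append(
                DerivedStat(
                    f"severity_share_{dir_id}_rank{rank}_pct",
                    printed,
                    recomputed,
                    reproducible=key not in severity_notes,
                    note=severity_notes.get(key, ""),
                )
            )

    # joint-critical coverages
    stats.extend(
        [
            DerivedStat("critical_bnf_thesaurus_coverage_of_bnf_pct", 19.21,
                        _pct(joint["bnf|thesaurus"], crit["bnf"]), True),
            DerivedStat("critical_bnf_thesaurus_coverage_of_thesaurus_pct", 15.44,
                        _pct(joint["bnf|thesaurus"], crit["thesaurus"]), True),
            DerivedStat("critical_bnf_micromedex_coverage_of_bnf_pct", 47.66,
                        _pct(joint["bnf|micromedex"], crit["bnf"]), True),
            DerivedStat(
                "critical_bnf_micromedex_coverage_of_micromedex_pct", 31.38,
                _pct(joint["bnf|micromedex"], crit["micromedex"]), False,
                "printed denominator unclear; full critical set gives "
                f"{round2(_pct(joint['bnf|micromedex'], crit['micromedex']))}",
            ),
            DerivedStat(
                "critical_thesaurus_micromedex_coverage_of_thesaurus_pct", 78.39,
                _pct(joint["thesaurus|micromedex"], crit["thesaurus"]), False,
                "printed denominator unclear; full critical set gives "
                f"{round2(_pct(joint['thesaurus|micromedex'], crit['thesaurus']))}",
            ),
            DerivedStat(
                "critical_thesaurus_micromedex_coverage_of_micromedex_pct", 26.33,
                _pct(joint["thesaurus|micromedex"], crit["micromedex"]), False,
                "printed denominator unclear; full critical set gives "
                f"{round2(_pct(joint['thesaurus|micromedex'], crit['micromedex']))}",
            ),
            DerivedStat("triple_critical_share_of_intersection_pct", 25.37,
                        _pct(joint["triple"], triple), True),
            DerivedStat("intersection_critical_share_bnf_pct", 43.39,
                        _pct(inter_crit["bnf"], triple), True),
            DerivedStat("intersection_critical_share_thesaurus_pct", 52.32,
                        _pct(inter_crit["thesaurus"], triple), True),
            DerivedStat("intersection_critical_share_micromedex_pct", 81.51,
                        _pct(inter_crit["micromedex"], triple), True),
        ]
    )
    return stats


def verify_printed_statistics(counts: dict | str | Path | None = None) -> pd.DataFrame:
    """Pass/fail table comparing recomputed statistics with printed ones.

    ``counts`` may be a counts dictionary, a path to a JSON counts file,
    or None for the built-in printed counts.  Comparison is at 2-decimal
    half-up rounding (counts compare exactly).
    """
    if isinstance(counts, (str, Path)):
        counts = json.loads(Path(counts).read_text())
    stats = derived_statistics(counts)
    rows = []
    for stat in stats:
        recomputed = round2(stat.recomputed)
        passed = recomputed == round2(stat.printed)
        rows.append(
            {
                "name": stat.name,
                "printed": stat.printed,
                "recomputed": recomputed,
                "passed": passed,
                "expected_reproducible": stat.reproducible,
                "note": stat.note,
            }
        )
    return pd.DataFrame(rows)
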