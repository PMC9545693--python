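"""Severity and evidence rating schemes of the drug information resources.

Each resource publishes its severity levels in descending order of
severity, so rank 1 is the most severe level and "keep the highest
rating" means keeping the smallest rank.  The critical subset of each
scheme marks the levels treated as critical in the overlap analyses
(BNF: Severe; Thesaurus: Contraindicated and Not recommended;
Micromedex: Contraindicated and Major).
"""
from __future__ import annotations

from dataclasses import dataclass, field

from .errors import UnknownEvidenceLabel, UnknownSeverityLabel


@dataclass(frozen=True)
class SeverityScheme:
    """Ordered, closed severity vocabulary of one resource.

    ``levels`` are listed most-severe first; ``critical`` is the subset of
    level names flagged as critical.
    """

    dir_id: str
    levels: tuple[str, ...]
    critical: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if not self.levels:
            raise ValueError("severity scheme needs at least one level")
        unknown = self.critical - set(self.levels)
        if unknown:
            raise ValueError(f"critical levels not in scheme: {sorted(unknown)}")
        object.__setattr__(self, "critical", frozenset(self.critical))

    def rank_of(self, label: str) -> int:
        """1-based rank of a level label (1 = most severe); case-insensitive."""
        wanted = label.strip().casefold()
        for i, level in enumerate(self.levels, start=1):
            if level.casefold() == wanted:
                return i
        raise UnknownSeverityLabel(f"{self.dir_id}: unknown severity label {label!r}")

    def label_of(self, rank: int) -> str:
        if not 1 <= rank <= len(self.levels):
            raise UnknownSeverityLabel(f"{self.dir_id}: no severity rank {rank}")
        return self.levels[rank - 1]

    @property
    def critical_ranks(self) -> frozenset[int]:
        return frozenset(self.rank_of(lbl) for lbl in self.critical)


@dataclass(frozen=True)
class EvidenceScheme:
    """Ordered evidence vocabulary, strongest level first."""

    dir_id: str
    levels: tuple[str, ...]

    def strength_of(self, label: str) -> int:
        """1-based strength (1 = strongest); case-insensitive."""
        wanted = label.strip().casefold()
        for i, level in enumerate(self.levels, start=1):
            if level.casefold() == wanted:
                return i
        raise UnknownEvidenceLabel(f"{self.dir_id}: unknown evidence label {label!r}")

    def label_of(self, strength: int) -> str:
        return self.levels[strength - 1]


BNF_SEVERITY = SeverityScheme(
    "bnf",
    ("Severe", "Moderate", "Mild", "Unknown"),
    frozenset({"Severe"}),
)
THESAURUS_SEVERITY = SeverityScheme(
    "thesaurus",
    ("Contraindicated", "Not recommended", "Precautions for use", "Take into consideration"),
    frozenset({"Contraindicated", "Not recommended"}),
)
MICROMEDEX_SEVERITY = SeverityScheme(
    "micromedex",
    ("Contraindicated", "Major", "Moderate", "Minor"),
    frozenset({"Contraindicated", "Major"}),
)

BNF_EVIDENCE = EvidenceScheme("bnf", ("Study", "Anecdotal", "Theoretical"))
MICROMEDEX_EVIDENCE = EvidenceScheme("micromedex", ("Established", "Theoretical", "Probable"))

DEFAULT_SEVERITY_SCHEMES: dict[str, SeverityScheme] = {
    "bnf": BNF_SEVERITY,
    "thesaurus": THESAURUS_SEVERITY,
    "micromedex": MICROMEDEX_SEVERITY,
}

DEFAULT_EVIDENCE_SCHEMES: dict[str, EvidenceScheme] = {
    "bnf": BNF_EVIDENCE,
    "micromedex": MICROMEDEX_EVIDENCE,
}
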