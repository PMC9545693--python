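"""Synthetic three-resource DDI datasets with known ground truth.

The generator emulates the structure of scraped compendia tables without
any real pharmacology: synthetic ingredient tokens ("drug0001", ...),
a configurable 7-region Venn overlap of the three pair sets, salt/ester
name variants that collapse under name normalisation, drug-class rows
(for the class-indexed resource) that expand to member ingredients,
per-resource categorical severity/evidence distributions, and
template-generated clinical-advice sentences with known multi-label
ground truth.

Default parameters mirror the analysed compendia: the region sizes are
the study's exclusive Venn regions scaled by 1/1000 and the severity /
evidence distributions are the empirical per-resource frequencies.  One
pseudo-random stream per artifact (pair universe, name variants,
severity, evidence, advice) is derived by hashing the master seed with
a stream label, so adding a stream never perturbs the others.
"""
from __future__ import annotations

import json
import math
import zlib
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .advice import ADVICE_CATEGORIES
from .errors import InfeasibleConfig, MissingTemplate
from .ingest import (
    CanonicalPair,
    ClassMapping,
    NameMapping,
    RawDDIRecord,
    canonicalize_pair,
)

DIR_IDS = ("bnf", "thesaurus", "micromedex")
REGION_NAMES = ("a_only", "b_only", "c_only", "ab_only", "ac_only", "bc_only", "abc")

#: Empirical per-resource severity frequencies (most-severe level first).
DEFAULT_SEVERITY_DISTRIBUTIONS: dict[str, dict[str, float]] = {
    "bnf": {"Severe": 0.2456, "Moderate": 0.0946, "Mild": 0.0051, "Unknown": 0.6547},
    "thesaurus": {
        "Contraindicated": 0.0775,
        "Not recommended": 0.3360,
        "Precautions for use": 0.2154,
        "Take into consideration": 0.3711,
    },
    "micromedex": {"Contraindicated": 0.0876, "Major": 0.6373, "Moderate": 0.2428, "Minor": 0.0323},
}

#: Evidence frequencies; the ``""`` key is the explicit no-rating bucket.
DEFAULT_EVIDENCE_DISTRIBUTIONS: dict[str, dict[str, float] | None] = {
    "bnf": {"": 0.6934, "Study": 0.1189, "Anecdotal": 0.0178, "Theoretical": 0.1699},
    "thesaurus": None,
    "micromedex": {"Established": 0.0873, "Theoretical": 0.7091, "Probable": 0.2036},
}

#: Keyword-bearing sentence templates per advice category. ``{a}``/``{b}``
#: are filled with (possibly salt-suffixed) ingredient names so the
#: blinding step is exercised.
DEFAULT_ADVICE_TEMPLATES: dict[str, tuple[str, ...]] = {
    "avoid": (
        "avoid concurrent use of {a} and {b}.",
        "concomitant administration of {a} with {b} should be avoided.",
    ),
    "use_with_caution": (
        "use {a} with caution when combined with {b}.",
        "caution is advised if {a} is given together with {b}.",
    ),
    "space_dosing_times": (
        "separate the dosing times of {a} and {b} by at least two hours.",
        "space administration of {a} and {b} as far apart as possible.",
    ),
    "wash_out": (
        "allow a washout period of several days before starting {b}.",
        "a washout interval is required after stopping {a}.",
    ),
    "monitor": (
        "monitor serum concentrations of {a} closely.",
        "monitor the patient for signs of toxicity during therapy with {b}.",
    ),
    "adjust_dose": (
        "reduce the dose of {a} during coadministration.",
        "dose adjustment of {b} may be necessary.",
    ),
    "modify_administration": (
        "administer {a} intravenously rather than orally while on {b}.",
        "modify the route of administration of {a}.",
    ),
    "use_alternative": (
        "consider an alternative agent in place of {b}.",
        "an alternative therapy to {a} should be considered.",
    ),
    "discontinue": (
        "discontinue {a} immediately if symptoms develop.",
        "therapy with {b} should be discontinued.",
    ),
}

DEFAULT_NOISE_TEMPLATES: tuple[str, ...] = (
    "the clinical significance of this interaction with {a} is unknown.",
    "pharmacokinetic data for {a} and {b} are limited.",
    "refer to the product label of {b} for further details.",
)

_SALT_SUFFIXES = ("tartrate", "succinate", "hydrochloride")


@dataclass
class SimulationConfig:
    """Study-condition parameters of the synthetic three-resource dataset."""

    seed: int = 20200901
    n_ingredients: int = 120
    #: Exclusive region sizes (a, b, c, ab, ac, bc, abc); defaults are the
    #: analysed compendia's exclusive regions scaled by 1/1000.
    venn_region_sizes: tuple[int, ...] = (29, 19, 46, 8, 7, 5, 7)
    dir_ids: tuple[str, str, str] = DIR_IDS
    salt_variant_rate: float = 0.10
    class_row_rate: float = 0.10  # class-indexed resource (second) only
    severity_distributions: dict[str, dict[str, float]] = field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_SEVERITY_DISTRIBUTIONS.items()}
    )
    evidence_distributions: dict[str, dict[str, float] | None] = field(
        default_factory=lambda: {
            k: (dict(v) if v else None) for k, v in DEFAULT_EVIDENCE_DISTRIBUTIONS.items()
        }
    )
    advice_templates: dict[str, tuple[str, ...]] = field(
        default_factory=lambda: {k: tuple(v) for k, v in DEFAULT_ADVICE_TEMPLATES.items()}
    )
    noise_templates: tuple[str, ...] = DEFAULT_NOISE_TEMPLATES
    advice_noise_rate: float = 0.10
    multi_label_rate: float = 0.20

    def validate(self) -> None:
        if len(self.venn_region_sizes) != 7 or any(r < 0 for r in self.venn_region_sizes):
            raise InfeasibleConfig("venn_region_sizes must be 7 non-negative integers")
        capacity = math.comb(self.n_ingredients, 2)
        if sum(self.venn_region_sizes) > capacity:
            raise InfeasibleConfig(
                f"{sum(self.venn_region_sizes)} pairs requested but only "
                f"C({self.n_ingredients},2)={capacity} exist"
            )
        for rate in (self.salt_variant_rate, self.class_row_rate,
                     self.advice_noise_rate, self.multi_label_rate):
            if not 0.0 <= rate <= 1.0:
                raise InfeasibleConfig("rates must lie in [0, 1]")
        for dir_id, dist in self.severity_distributions.items():
            if abs(sum(dist.values()) - 1.0) > 1e-6:
                raise InfeasibleConfig(f"severity distribution for {dir_id} does not sum to 1")
        for dir_id, dist in self.evidence_distributions.items():
            if dist is not None and abs(sum(dist.values()) - 1.0) > 1e-6:
                raise InfeasibleConfig(f"evidence distribution for {dir_id} does not sum to 1")


def _stream(seed: int, label: str) -> np.random.Generator:
    return np.random.default_rng([seed & 0x7FFFFFFF, zlib.crc32(label.encode())])


@dataclass
class GroundTruth:
    """Everything the generator knows about the emitted dataset."""

    ingredients: tuple[str, ...]
    regions: dict[str, frozenset[CanonicalPair]]
    sets: dict[str, set[CanonicalPair]]
    severity: dict[tuple[str, CanonicalPair], str] = field(default_factory=dict)
    evidence: dict[tuple[str, CanonicalPair], str | None] = field(default_factory=dict)
    name_variant_map: dict[str, str] = field(default_factory=dict)
    class_membership: dict[str, tuple[str, ...]] = field(default_factory=dict)

    @property
    def region_sizes(self) -> tuple[int, ...]:
        return tuple(len(self.regions[name]) for name in REGION_NAMES)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "region_sizes": dict(zip(REGION_NAMES, self.region_sizes)),
            "set_sizes": {d: len(s) for d, s in self.sets.items()},
            "n_ingredients": len(self.ingredients),
            "name_variant_map": self.name_variant_map,
            "class_membership": {k: list(v) for k, v in self.class_membership.items()},
            "severity": {
                f"{d}|{p.a}|{p.b}": lbl for (d, p), lbl in sorted(
                    self.severity.items(), key=lambda kv: (kv[0][0], kv[0][1])
                )
            },
        }
        Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")


def generate_universe(config: SimulationConfig) -> tuple[dict[str, set[CanonicalPair]], GroundTruth]:
    """Realise the configured 7-region overlap structure exactly.

    Deterministic given the seed: pairs are sampled without replacement
    from the C(n, 2) pair universe and assigned to regions in order.
    """
    config.validate()
    ingredients = tuple(f"drug{i:04d}" for i in range(1, config.n_ingredients + 1))
    all_pairs = list(combinations(ingredients, 2))
    total = sum(config.venn_region_sizes)
    rng = _stream(config.seed, "universe")
    chosen = rng.choice(len(all_pairs), size=total, replace=False)

    regions: dict[str, frozenset[CanonicalPair]] = {}
    offset = 0
    for name, size in zip(REGION_NAMES, config.venn_region_sizes):
        block = chosen[offset : offset + size]
        regions[name] = frozenset(canonicalize_pair(*all_pairs[k]) for k in block)
        offset += size

    a, b, c = config.dir_ids
    sets = {
        a: set().union(regions["a_only"], regions["ab_only"], regions["ac_only"], regions["abc"]),
        b: set().union(regions["b_only"], regions["ab_only"], regions["bc_only"], regions["abc"]),
        c: set().union(regions["c_only"], regions["ac_only"], regions["bc_only"], regions["abc"]),
    }
    truth = GroundTruth(ingredients=ingredients, regions=regions, sets=sets)
    return sets, truth


@dataclass
class SyntheticDataset:
    """Raw tables plus the mapping tables that ingest them."""

    records: dict[str, list[RawDDIRecord]]
    name_mapping: NameMapping
    class_mapping: ClassMapping
    truth: GroundTruth


def _variant_name(base: str, rng: np.random.Generator, variant_map: dict[str, str]) -> str:
    suffix = _SALT_SUFFIXES[rng.integers(len(_SALT_SUFFIXES))]
    variant = f"{base} {suffix}"
    variant_map[variant] = base
    return variant


def emit_raw_tables(
    universe: Mapping[str, set[CanonicalPair]],
    truth: GroundTruth,
    config: SimulationConfig,
) -> SyntheticDataset:
    """Emit per-resource raw rows that normalise back to the universe.

    Obfuscations applied on top of the clean pair lists:

    * each name is independently replaced by a salt variant with
      probability ``salt_variant_rate``, and with the same probability a
      duplicate row (with variant spellings and an independently drawn
      severity) is appended, so raw row counts exceed pair counts;
    * for the class-indexed resource, a fraction of pairs is re-expressed
      as class-level rows (one class per shared partner ingredient) whose
      members are exactly the grouped pairs' other ingredients, keeping
      the normalised result identical to the universe;
    * interactant order is swapped at random to exercise
      canonicalisation.
    """
    name_rng = _stream(config.seed, "names")
    sev_rng = _stream(config.seed, "severity")
    ev_rng = _stream(config.seed, "evidence")
    class_rng = _stream(config.seed, "classes")

    mapping_entries: dict[str, str] = {ing: ing for ing in truth.ingredients}
    records: dict[str, list[RawDDIRecord]] = {}
    class_entries: dict[str, tuple[str, ...]] = {}
    class_dir = config.dir_ids[1]

    for dir_id in config.dir_ids:
        sev_dist = config.severity_distributions[dir_id]
        sev_labels = list(sev_dist)
        sev_probs = np.array([sev_dist[k] for k in sev_labels])
        ev_dist = config.evidence_distributions.get(dir_id)
        if ev_dist:
            ev_labels = list(ev_dist)
            ev_probs = np.array([ev_dist[k] for k in ev_labels])

        pairs = sorted(universe[dir_id])
        rows: list[RawDDIRecord] = []

        # class grouping for the class-indexed resource
        class_partner: dict[CanonicalPair, str] = {}
        if dir_id == class_dir and config.class_row_rate > 0:
            buckets: dict[str, list[CanonicalPair]] = {}
            for pair in pairs:
                if class_rng.random() < config.class_row_rate:
                    buckets.setdefault(pair.b, []).append(pair)
            for partner, members in sorted(buckets.items()):
                cls = f"class{len(class_entries) + 1:04d}"
                class_entries[cls] = tuple(p.a for p in members)
                for p in members:
                    class_partner[p] = cls

        emitted_classes: set[str] = set()
        for pair in pairs:
            cls = class_partner.get(pair)
            if cls is not None and cls in emitted_classes:
                continue

            sev = sev_labels[sev_rng.choice(len(sev_labels), p=sev_probs)]
            truth.severity[(dir_id, pair)] = sev
            evidence = None
            if ev_dist:
                evidence = ev_labels[ev_rng.choice(len(ev_labels), p=ev_probs)] or None
            truth.evidence[(dir_id, pair)] = evidence

            if cls is not None:
                emitted_classes.add(cls)
                n1, n2 = cls, pair.b
                if class_rng.random() < 0.5:
                    n1, n2 = n2, n1
                rows.append(
                    RawDDIRecord(
                        source_dir=dir_id, name_1=n1, name_2=n2,
                        severity_raw=sev, evidence_raw=evidence,
                        advice_text=None,
                        row_id=f"{dir_id}:{len(rows)}",
                    )
                )
                # all pairs of this class share the class row's rating
                for member in class_entries[cls]:
                    member_pair = canonicalize_pair(member, pair.b)
                    truth.severity[(dir_id, member_pair)] = sev
                    truth.evidence[(dir_id, member_pair)] = evidence
                continue

            n1, n2 = pair.a, pair.b
            if name_rng.random() < config.salt_variant_rate:
                n1 = _variant_name(n1, name_rng, truth.name_variant_map)
            if name_rng.random() < config.salt_variant_rate:
                n2 = _variant_name(n2, name_rng, truth.name_variant_map)
            if name_rng.random() < 0.5:
                n1, n2 = n2, n1
            rows.append(
                RawDDIRecord(
                    source_dir=dir_id, name_1=n1, name_2=n2,
                    severity_raw=sev, evidence_raw=evidence,
                    advice_text=None,
                    row_id=f"{dir_id}:{len(rows)}",
                )
            )
            if name_rng.random() < config.salt_variant_rate:
                # duplicate row under variant spelling; the merged severity
                # set then resolves to the most severe of the two draws
                dup_sev = sev_labels[sev_rng.choice(len(sev_labels), p=sev_probs)]
                ranks = {sev_labels.index(sev), sev_labels.index(dup_sev)}
                truth.severity[(dir_id, pair)] = sev_labels[min(ranks)]
                v1 = _variant_name(pair.a, name_rng, truth.name_variant_map)
                rows.append(
                    RawDDIRecord(
                        source_dir=dir_id, name_1=v1, name_2=pair.b,
                        severity_raw=dup_sev, evidence_raw=evidence,
                        advice_text=None,
                        row_id=f"{dir_id}:{len(rows)}",
                    )
                )
        records[dir_id] = rows

    mapping_entries.update(truth.name_variant_map)
    truth.class_membership = dict(class_entries)
    return SyntheticDataset(
        records=records,
        name_mapping=NameMapping(mapping_entries),
        class_mapping=ClassMapping(class_entries),
        truth=truth,
    )


# ---------------------------------------------------------------------------
# Advice corpus
# ---------------------------------------------------------------------------

@dataclass
class AdviceCorpus:
    """Template-generated sentences with known multi-label ground truth."""

    frame: pd.DataFrame  # sentence_id, record_id, dir, text
    labels: dict[str, frozenset[str]]
    lexicon: set[str]

    def write(self, corpus_path: str | Path, labels_path: str | Path) -> None:
        self.frame.to_csv(corpus_path, index=False)
        rows = []
        for sid in self.frame["sentence_id"]:
            for category in ADVICE_CATEGORIES:
                rows.append(
                    {
                        "sentence_id": sid,
                        "category": category,
                        "value": int(category in self.labels[sid]),
                    }
                )
        pd.DataFrame(rows).to_csv(labels_path, index=False)


def emit_advice_corpus(
    config: SimulationConfig,
    n_sentences: int = 400,
    stream_label: str = "advice",
    categories: Sequence[str] = ADVICE_CATEGORIES,
) -> AdviceCorpus:
    """Generate an advice-sentence corpus with known label sets.

    Each sentence is noise (empty label set) with probability
    ``advice_noise_rate``; otherwise it realises one category's template,
    and with probability ``multi_label_rate`` a second category's clause
    is appended so the sentence carries both labels.  Drug-name slots are
    filled with synthetic ingredient names (occasionally salt variants)
    so blinding is exercised.  Deterministic given seed and label.
    """
    for category in categories:
        if not config.advice_templates.get(category):
            raise MissingTemplate(f"no sentence template for category {category!r}")
    rng = _stream(config.seed, stream_label)
    ingredients = [f"drug{i:04d}" for i in range(1, config.n_ingredients + 1)]
    lexicon: set[str] = set(ingredients)

    def draw_name() -> str:
        base = ingredients[rng.integers(len(ingredients))]
        if rng.random() < config.salt_variant_rate:
            variant = f"{base} {_SALT_SUFFIXES[rng.integers(len(_SALT_SUFFIXES))]}"
            lexicon.add(variant)
            return variant
        return base

    def fill(template: str) -> str:
        return template.format(a=draw_name(), b=draw_name())

    rows = []
    labels: dict[str, frozenset[str]] = {}
    for i in range(n_sentences):
        sid = f"s{i:05d}"
        if rng.random() < config.advice_noise_rate:
            template = config.noise_templates[rng.integers(len(config.noise_templates))]
            text, label_set = fill(template), frozenset()
        else:
            cat = categories[rng.integers(len(categories))]
            templates = config.advice_templates[cat]
            text = fill(templates[rng.integers(len(templates))])
            label_set = frozenset({cat})
            if rng.random() < config.multi_label_rate:
                other = categories[rng.integers(len(categories))]
                if other != cat:
                    other_templates = config.advice_templates[other]
                    clause = fill(other_templates[rng.integers(len(other_templates))])
                    text = text.rstrip(".") + "; in addition, " + clause
                    label_set = frozenset({cat, other})
        rows.append({"sentence_id": sid, "record_id": f"r{i:05d}", "dir": "micromedex", "text": text})
        labels[sid] = label_set
    frame = pd.DataFrame(rows, columns=["sentence_id", "record_id", "dir", "text"])
    return AdviceCorpus(frame=frame, labels=labels, lexicon=lexicon)


# ---------------------------------------------------------------------------
# Dataset writer (the CSV dialects the ingest module consumes)
# ---------------------------------------------------------------------------

def write_dataset(dataset: SyntheticDataset, outdir: str | Path) -> dict[str, Path]:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    for dir_id, rows in dataset.records.items():
        path = outdir / f"{dir_id}_raw.csv"
        pd.DataFrame(
            [
                {
                    "dir": r.source_dir,
                    "drug_1": r.name_1,
                    "drug_2": r.name_2,
                    "severity": r.severity_raw or "",
                    "evidence": r.evidence_raw or "",
                    "advice_text": r.advice_text or "",
                    "description": r.description or "",
                }
                for r in rows
            ],
            columns=["dir", "drug_1", "drug_2", "severity", "evidence", "advice_text", "description"],
        ).to_csv(path, index=False)
        paths[dir_id] = path

    mapping_rows = [
        {"raw_name": ing, "status": "INGREDIENT", "concept_name": ing}
        for ing in dataset.truth.ingredients
    ] + [
        {"raw_name": variant, "status": "INGREDIENT", "concept_name": base}
        for variant, base in sorted(dataset.truth.name_variant_map.items())
    ]
    mapping_path = outdir / "name_mapping.csv"
    pd.DataFrame(mapping_rows, columns=["raw_name", "status", "concept_name"]).to_csv(
        mapping_path, index=False
    )
    paths["mapping"] = mapping_path

    class_rows = [
        {"class_name": cls, "member_name": member}
        for cls, members in sorted(dataset.truth.class_membership.items())
        for member in members
    ]
    class_path = outdir / "class_mapping.csv"
    pd.DataFrame(class_rows, columns=["class_name", "member_name"]).to_csv(class_path, index=False)
    paths["classes"] = class_path

    truth_path = outdir / "ground_truth.json"
    dataset.truth.to_json(truth_path)
    paths["truth"] = truth_path
    return paths
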