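"""End-to-end pipeline: ingest -> concordance -> advice -> report bundle.

The bundle mirrors the study's result tables: per-resource size summary
(initial names, normalised ingredients, DDI counts), severity
distribution, full and ingredient-restricted Venn partitions, severity
and evidence cross-tabs, critical-overlap report and, when an advice
corpus is configured, classifier statuses, sentence annotations and the
per-DDI advice distribution.  Every percentage written to disk is
recomputable from counts in the same bundle.
"""
from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd
import yaml

from . import advice as adv
from .concordance import (
    CriticalOverlapReport,
    EvidenceCrossTab,
    IntersectionEntry,
    RatingCrossTab,
    VennPartition,
    build_intersection_list,
    critical_overlap,
    evidence_crosstab,
    ingredient_restricted_partition,
    round2,
    severity_crosstab,
    venn_partition,
)
from .errors import ConfigError
from .ingest import (
    DIRTable,
    ExclusionReport,
    RawDDIRecord,
    expand_classes,
    normalize_table,
    read_class_mapping,
    read_name_mapping,
    read_raw_table,
    write_dir_table,
    write_exclusion_report,
)
from .schemes import (
    DEFAULT_EVIDENCE_SCHEMES,
    DEFAULT_SEVERITY_SCHEMES,
    EvidenceScheme,
    SeverityScheme,
)

logger = logging.getLogger(__name__)


@dataclass
class AdviceStageConfig:
    corpus_path: Path
    labels_path: Path
    lexicon_path: Path | None = None
    holdout_labels_path: Path | None = None
    min_ppv: float = 0.80


@dataclass
class RunConfig:
    """Paths and parameters of one pipeline run."""

    dir_tables: dict[str, Path]
    mapping_path: Path
    class_path: Path | None = None
    severity_schemes: Mapping[str, SeverityScheme] = field(
        default_factory=lambda: dict(DEFAULT_SEVERITY_SCHEMES)
    )
    evidence_schemes: Mapping[str, EvidenceScheme] = field(
        default_factory=lambda: dict(DEFAULT_EVIDENCE_SCHEMES)
    )
    advice: AdviceStageConfig | None = None
    seed: int = 20200901
    rounding: int = 2

    def validate(self) -> None:
        if len(self.dir_tables) != 3:
            raise ConfigError("exactly three resource tables are required")
        for dir_id, path in self.dir_tables.items():
            if dir_id not in self.severity_schemes:
                raise ConfigError(f"no severity scheme configured for {dir_id!r}")
            if not Path(path).exists():
                raise ConfigError(f"missing resource table: {path}")
        if not Path(self.mapping_path).exists():
            raise ConfigError(f"missing name-mapping table: {self.mapping_path}")
        if self.class_path is not None and not Path(self.class_path).exists():
            raise ConfigError(f"missing class table: {self.class_path}")
        if self.advice is not None:
            for p in (self.advice.corpus_path, self.advice.labels_path):
                if not Path(p).exists():
                    raise ConfigError(f"missing advice input: {p}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        if not isinstance(raw, dict) or "dir_tables" not in raw:
            raise ConfigError(f"{path}: expected a mapping with a dir_tables section")
        base = Path(path).parent

        def _p(value: str) -> Path:
            p = Path(value)
            return p if p.is_absolute() else base / p

        advice_cfg = None
        if raw.get("advice"):
            a = raw["advice"]
            advice_cfg = AdviceStageConfig(
                corpus_path=_p(a["corpus"]),
                labels_path=_p(a["labels"]),
                lexicon_path=_p(a["lexicon"]) if a.get("lexicon") else None,
                holdout_labels_path=_p(a["holdout_labels"]) if a.get("holdout_labels") else None,
                min_ppv=float(a.get("min_ppv", 0.80)),
            )
        return cls(
            dir_tables={k: _p(v) for k, v in raw["dir_tables"].items()},
            mapping_path=_p(raw["mapping"]),
            class_path=_p(raw["classes"]) if raw.get("classes") else None,
            advice=advice_cfg,
            seed=int(raw.get("seed", 20200901)),
            rounding=int(raw.get("rounding", 2)),
        )


@dataclass
class AdviceReport:
    classifier_report: dict
    annotations: pd.DataFrame  # sentence_id, category, decision
    ddi_advice: pd.DataFrame   # record_id, category counts (long)
    validation: dict | None = None


@dataclass
class ReportBundle:
    """All result tables of one run."""

    listing: pd.DataFrame
    severity_distribution: pd.DataFrame
    venn_pairs: VennPartition
    venn_ingredients: VennPartition
    venn_restricted: VennPartition
    severity_crosstabs: dict[str, RatingCrossTab]
    evidence: EvidenceCrossTab | None
    critical: CriticalOverlapReport
    intersection: list[IntersectionEntry]
    exclusions: list[ExclusionReport]
    tables: dict[str, DIRTable]
    advice: AdviceReport | None = None

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.listing.to_csv(outdir / "listing_summary.csv", index=False)
        self.severity_distribution.to_csv(outdir / "severity_distribution.csv", index=False)
        for name, venn in (
            ("venn_pairs", self.venn_pairs),
            ("venn_ingredients", self.venn_ingredients),
            ("venn_pairs_ingredient_restricted", self.venn_restricted),
        ):
            (outdir / f"{name}.json").write_text(
                json.dumps(venn.as_dict(), indent=2, sort_keys=True) + "\n"
            )
        for dir_id, xtab in self.severity_crosstabs.items():
            xtab.to_long().to_csv(outdir / f"severity_crosstab_{dir_id}.csv", index=False)
        if self.evidence is not None:
            self.evidence.to_long().to_csv(outdir / "evidence_crosstab.csv", index=False)
        (outdir / "critical_overlap.json").write_text(
            json.dumps(self.critical.as_dict(), indent=2, sort_keys=True) + "\n"
        )
        inter_rows = [
            {
                "ingredient_a": e.pair.a,
                "ingredient_b": e.pair.b,
                **{
                    f"{d}_severity_rank": (rec.severity if rec.severity is not None else "")
                    for d, rec in e.payloads.items()
                },
            }
            for e in self.intersection
        ]
        pd.DataFrame(inter_rows).to_csv(outdir / "intersection_list.csv", index=False)
        write_exclusion_report(self.exclusions, outdir / "exclusions.json")
        for dir_id, table in self.tables.items():
            write_dir_table(table, outdir / f"{dir_id}_normalised.csv")
        if self.advice is not None:
            advdir = outdir / "advice"
            advdir.mkdir(exist_ok=True)
            (advdir / "classifier_report.json").write_text(
                json.dumps(self.advice.classifier_report, indent=2, sort_keys=True) + "\n"
            )
            self.advice.annotations.to_csv(advdir / "annotations.csv", index=False)
            self.advice.ddi_advice.to_csv(advdir / "ddi_advice.csv", index=False)
            if self.advice.validation is not None:
                (advdir / "validation_report.json").write_text(
                    json.dumps(self.advice.validation, indent=2, sort_keys=True) + "\n"
                )


def ingest_all(config: RunConfig) -> tuple[dict[str, DIRTable], list[ExclusionReport], dict[str, int]]:
    """Read, class-expand and normalise every configured resource table."""
    mapping = read_name_mapping(config.mapping_path)
    classes = (
        read_class_mapping(config.class_path).validated(mapping)
        if config.class_path is not None
        else None
    )
    tables: dict[str, DIRTable] = {}
    reports: list[ExclusionReport] = []
    initial_names: dict[str, int] = {}
    for dir_id, path in config.dir_tables.items():
        records: Sequence[RawDDIRecord] = read_raw_table(path)
        initial_names[dir_id] = len(
            {r.name_1.strip().casefold() for r in records}
            | {r.name_2.strip().casefold() for r in records}
        )
        if classes is not None:
            records = expand_classes(records, classes)
        table, report = normalize_table(
            records,
            mapping,
            config.severity_schemes[dir_id],
            config.evidence_schemes.get(dir_id),
        )
        table.dir_id = dir_id
        tables[dir_id] = table
        reports.append(report)
    return tables, reports, initial_names


def read_label_file(path: str | Path) -> dict[str, frozenset[str]]:
    """Read a label CSV (sentence_id, category, value) into label sets."""
    frame = pd.read_csv(path, dtype={"sentence_id": str, "category": str, "value": int})
    labels: dict[str, set[str]] = {}
    for row in frame.itertuples(index=False):
        labels.setdefault(row.sentence_id, set())
        if row.value:
            labels[row.sentence_id].add(row.category)
    return {sid: frozenset(cats) for sid, cats in labels.items()}


def run_advice_stage(config: AdviceStageConfig) -> AdviceReport:
    corpus = pd.read_csv(config.corpus_path, dtype=str, keep_default_na=False)
    labels = read_label_file(config.labels_path)
    lexicon: set[str] = set()
    if config.lexicon_path is not None:
        lexicon = {
            line.strip()
            for line in Path(config.lexicon_path).read_text().splitlines()
            if line.strip()
        }

    sentences, label_sets, sentence_ids = [], [], []
    for row in corpus.itertuples(index=False):
        units = adv.preprocess(
            row.text, lexicon, provenance=row.sentence_id, split_sentences=False
        )
        if not units:
            continue
        sentences.append(units[0])
        sentence_ids.append(row.sentence_id)
        label_sets.append(labels.get(row.sentence_id, frozenset()))

    model = adv.fit_advice_classifiers(sentences, label_sets, min_ppv=config.min_ppv)
    annotations = model.annotate(sentences) if model.active_categories else [frozenset()] * len(sentences)

    ann_rows = [
        {"sentence_id": sid, "category": cat, "decision": int(cat in found)}
        for sid, found in zip(sentence_ids, annotations)
        for cat in adv.ADVICE_CATEGORIES
    ]
    record_ids = dict(zip(corpus["sentence_id"], corpus["record_id"]))
    per_record: dict[str, set[str]] = {}
    for sid, found in zip(sentence_ids, annotations):
        per_record.setdefault(record_ids[sid], set()).update(found)
    ddi_rows = [
        {"record_id": rid, "category": cat, "present": int(cat in cats)}
        for rid, cats in sorted(per_record.items())
        for cat in adv.ADVICE_CATEGORIES
    ]

    validation = None
    if config.holdout_labels_path is not None:
        manual = read_label_file(config.holdout_labels_path)
        auto = {
            sid: annotations[i] for i, sid in enumerate(sentence_ids) if sid in manual
        }
        validation = adv.validate_holdout(auto, {k: manual[k] for k in auto}).as_dict()

    return AdviceReport(
        classifier_report=model.report(),
        annotations=pd.DataFrame(ann_rows),
        ddi_advice=pd.DataFrame(ddi_rows),
        validation=validation,
    )


def run_pipeline(config: RunConfig) -> ReportBundle:
    """Execute ingest -> concordance -> (optional) advice annotation."""
    config.validate()
    tables, exclusions, initial_names = ingest_all(config)
    dir_ids = list(config.dir_tables)
    ordered = [tables[d] for d in dir_ids]

    listing = pd.DataFrame(
        [
            {
                "dir": d,
                "initial_names": initial_names[d],
                "normalised_ingredients": len(tables[d].ingredient_set),
                "ddi_count": len(tables[d]),
            }
            for d in dir_ids
        ]
    )

    sev_rows = []
    for d in dir_ids:
        scheme = config.severity_schemes[d]
        counts = {lvl: 0 for lvl in scheme.levels}
        unrated = 0
        for rec in tables[d].records.values():
            if rec.severity is None:
                unrated += 1
            else:
                counts[scheme.label_of(rec.severity)] += 1
        total = len(tables[d]) or 1
        for rank, lvl in enumerate(scheme.levels, start=1):
            sev_rows.append(
                {
                    "dir": d, "rank": rank, "level": lvl,
                    "count": counts[lvl], "pct": round2(100.0 * counts[lvl] / total),
                }
            )
        if unrated:
            sev_rows.append(
                {"dir": d, "rank": "", "level": "(unrated)",
                 "count": unrated, "pct": round2(100.0 * unrated / total)}
            )
    severity_distribution = pd.DataFrame(sev_rows)

    labels3 = tuple(dir_ids)
    venn_pairs = venn_partition(*(t.pairs for t in ordered), labels=labels3)
    venn_ings = venn_partition(*(set(t.ingredient_set) for t in ordered), labels=labels3)
    venn_restricted = ingredient_restricted_partition(ordered)

    # severity cross-tabs need fully rated tables; skip row resources with
    # unrated records (logged) rather than failing the whole run
    crosstabs: dict[str, RatingCrossTab] = {}
    for d in dir_ids:
        if any(rec.severity is None for rec in tables[d].records.values()):
            logger.warning("%s: unrated records present; severity cross-tab skipped", d)
            continue
        others = [tables[o] for o in dir_ids if o != d]
        if any(
            rec.severity is None for o in others for rec in o.records.values()
        ):
            logger.warning("severity cross-tab for %s skipped: unrated comparison table", d)
            continue
        crosstabs[d] = severity_crosstab(tables[d], others, config.severity_schemes)

    evidence = None
    ev_dirs = [d for d in dir_ids if d in config.evidence_schemes]
    if len(ev_dirs) >= 2:
        first, second = ev_dirs[0], ev_dirs[1]
        evidence = evidence_crosstab(
            tables[first], tables[second],
            config.evidence_schemes[first], config.evidence_schemes[second],
        )

    critical = critical_overlap(ordered, config.severity_schemes)
    intersection = build_intersection_list(ordered)

    advice_report = run_advice_stage(config.advice) if config.advice is not None else None

    return ReportBundle(
        listing=listing,
        severity_distribution=severity_distribution,
        venn_pairs=venn_pairs,
        venn_ingredients=venn_ings,
        venn_restricted=venn_restricted,
        severity_crosstabs=crosstabs,
        evidence=evidence,
        critical=critical,
        intersection=intersection,
        exclusions=exclusions,
        tables=tables,
        advice=advice_report,
    )
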