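#!/usr/bin/env python
"""Normalise the raw resource tables into clean canonical-pair tables.

Class-level rows are expanded to member ingredients, names are resolved
through the mapping table, swapped duplicates and salt variants merge,
and exclusion counts (unmapped / non-drug / self-pair) are reported.

Reads results/synthetic/, writes results/tables/.
"""
from pathlib import Path

from ddi_concordance.ingest import write_dir_table, write_exclusion_report
from ddi_concordance.pipeline import RunConfig, ingest_all

ROOT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    config = RunConfig(
        dir_tables={d: ROOT / "synthetic" / f"{d}_raw.csv" for d in ("bnf", "thesaurus", "micromedex")},
        mapping_path=ROOT / "synthetic" / "name_mapping.csv",
        class_path=ROOT / "synthetic" / "class_mapping.csv",
    )
    config.validate()
    tables, reports, initial_names = ingest_all(config)
    out = ROOT / "tables"
    out.mkdir(parents=True, exist_ok=True)
    for dir_id, table in tables.items():
        write_dir_table(table, out / f"{dir_id}_normalised.csv")
    write_exclusion_report(reports, out / "exclusions.json")

    for rep in reports:
        print(f"{rep.dir_id}: {rep.input_rows} raw rows -> {rep.kept_pairs} canonical pairs "
              f"({rep.unmapped} unmapped, {rep.non_drug} non-drug, {rep.self_pair} self-pair; "
              f"{initial_names[rep.dir_id]} distinct raw names)")
    print(f"wrote {out}")


if __name__ == "__main__":
    main()
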