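#!/usr/bin/env python
"""Concordance analysis: Venn partitions, cross-tabs, critical overlap.

Runs the full listing / severity / evidence comparison over the
normalised synthetic tables and reports how well the three resources
agree — by construction they share exactly the configured triple region.

Reads results/synthetic/, writes results/concordance/.
"""
from pathlib import Path

from ddi_concordance.pipeline import RunConfig, run_pipeline
from ddi_concordance.concordance import round2

ROOT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    config = RunConfig(
        dir_tables={d: ROOT / "synthetic" / f"{d}_raw.csv" for d in ("bnf", "thesaurus", "micromedex")},
        mapping_path=ROOT / "synthetic" / "name_mapping.csv",
        class_path=ROOT / "synthetic" / "class_mapping.csv",
    )
    bundle = run_pipeline(config)
    out = ROOT / "concordance"
    bundle.write(out)

    vp = bundle.venn_pairs
    print(f"collated pairs: {vp.total}; single-resource only: {vp.single_only} "
          f"({round2(100 * vp.single_only / vp.total)}%)")
    print(f"three-way intersection: {vp.abc} "
          f"({round2(100 * vp.abc / vp.size_a)}% of bnf, "
          f"{round2(100 * vp.abc / vp.size_b)}% of thesaurus, "
          f"{round2(100 * vp.abc / vp.size_c)}% of micromedex)")
    crit = bundle.critical
    print(f"critical set sizes: {crit.critical_sizes}; "
          f"triple-critical: {crit.triple_joint} "
          f"({round2(crit.triple_share_of_intersection)}% of the intersection list)")
    print(f"wrote {out}")


if __name__ == "__main__":
    main()
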