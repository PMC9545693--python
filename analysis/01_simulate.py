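#!/usr/bin/env python
"""Generate the synthetic three-resource study dataset.

Emits raw DDI tables for the three resources (with salt-name variants,
class-level rows and randomly swapped pair order), the name-mapping and
class-membership tables that resolve them, the advice-sentence corpus
with its known multi-label ground truth, and a ground-truth JSON.

Writes everything under results/synthetic/.
"""
from pathlib import Path

from ddi_concordance.synthetic import (
    SimulationConfig,
    emit_advice_corpus,
    emit_raw_tables,
    generate_universe,
    write_dataset,
)

OUT = Path(__file__).resolve().parent.parent / "results" / "synthetic"


def main() -> None:
    cfg = SimulationConfig()
    sets, truth = generate_universe(cfg)
    dataset = emit_raw_tables(sets, truth, cfg)
    write_dataset(dataset, OUT)
    corpus = emit_advice_corpus(cfg, n_sentences=400)
    corpus.write(OUT / "advice_corpus.csv", OUT / "advice_labels.csv")
    (OUT / "drug_lexicon.txt").write_text("\n".join(sorted(corpus.lexicon)) + "\n")

    print(f"seed {cfg.seed}: {len(truth.ingredients)} ingredients, "
          f"{sum(cfg.venn_region_sizes)} distinct pairs across the 7 regions")
    for dir_id, rows in dataset.records.items():
        print(f"  {dir_id}: {len(rows)} raw rows for {len(sets[dir_id])} true pairs")
    print(f"  advice corpus: {len(corpus.frame)} sentences, "
          f"{sum(1 for l in corpus.labels.values() if not l)} noise")
    print(f"wrote {OUT}")


if __name__ == "__main__":
    main()
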