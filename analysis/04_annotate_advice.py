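#!/usr/bin/env python
"""Train the advice classifiers and annotate the sentence corpus.

Fits one tf-idf + linear-SVM classifier per advice category on the
labelled synthetic corpus, selects each decision threshold by
leave-one-out ROC under the PPV >= 0.80 constraint, annotates the
corpus, and reports LOO operating points per category.

Reads results/synthetic/, writes results/advice/.
"""
import json
from pathlib import Path

from ddi_concordance.pipeline import AdviceStageConfig, run_advice_stage

ROOT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    report = run_advice_stage(
        AdviceStageConfig(
            corpus_path=ROOT / "synthetic" / "advice_corpus.csv",
            labels_path=ROOT / "synthetic" / "advice_labels.csv",
            lexicon_path=ROOT / "synthetic" / "drug_lexicon.txt",
        )
    )
    out = ROOT / "advice"
    out.mkdir(parents=True, exist_ok=True)
    (out / "classifier_report.json").write_text(
        json.dumps(report.classifier_report, indent=2, sort_keys=True) + "\n"
    )
    report.annotations.to_csv(out / "annotations.csv", index=False)
    report.ddi_advice.to_csv(out / "ddi_advice.csv", index=False)

    for category, row in sorted(report.classifier_report.items()):
        if row["status"] == "ACTIVE":
            print(f"  {category:22s} ACTIVE   LOO PPV {row['loo_ppv']:.3f} "
                  f"sensitivity {row['loo_sensitivity']:.3f}")
        else:
            print(f"  {category:22s} REJECTED")
    n_pos = int(report.annotations["decision"].sum())
    print(f"{n_pos} positive sentence-category decisions; wrote {out}")


if __name__ == "__main__":
    main()
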