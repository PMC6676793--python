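"""Compare recovered topic structure against the planted ground truth.

Runs the full pipeline on the simulated corpus and tabulates planted vs
recovered prevalence per topic, the contamination accounting, and the
per-tweet exact-agreement rate. On the default clean-keyword generator
the pipeline should recover every planted label exactly, so any nonzero
deviation here signals a pipeline defect.

Run:  python analysis/03_evaluate_recovery.py
"""

import csv
import sys
from pathlib import Path

from cigartopics.ingest import read_corpus
from cigartopics.synthetic import GroundTruth, recover_and_compare

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    corpus_path = ROOT / "scratch" / "corpus.jsonl"
    truth_path = ROOT / "scratch" / "ground_truth.json"
    if not (corpus_path.is_file() and truth_path.is_file()):
        sys.exit("no simulated corpus — run analysis/01_simulate_corpus.py first")

    corpus = read_corpus(corpus_path)
    truth = GroundTruth.from_json(truth_path)
    rep = recover_and_compare(corpus, truth)

    results = ROOT / "results"
    results.mkdir(exist_ok=True)
    with (results / "recovery.csv").open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["topic", "planted_count", "recovered_count",
                        "planted_pct", "recovered_pct", "abs_dev_pct"])
        for topic, row in rep.per_topic.items():
            writer.writerow([topic, row["planted_count"], row["recovered_count"],
                             row["planted_pct"], row["recovered_pct"], row["abs_dev_pct"]])
    rep.to_json(results / "recovery_report.json")

    print(f"retained {rep.n_retained} tweets; planted clean {rep.n_clean}")
    print(f"per-tweet exact agreement: {100 * rep.exact_match_fraction:.2f}%")
    print(f"max prevalence deviation: {rep.max_abs_deviation_pct:.4f} percentage points")
    for rule, check in rep.contamination_check.items():
        flag = "OK" if check["filtered"] == check["planted"] else "MISMATCH"
        print(f"  {rule:12s} filtered {check['filtered']:6d} planted {check['planted']:6d}  {flag}")


if __name__ == "__main__":
    main()
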