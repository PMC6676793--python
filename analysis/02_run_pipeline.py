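"""Run the full surveillance pipeline on the simulated corpus.

Reads scratch/corpus.jsonl (produced by 01_simulate_corpus.py), applies
the exclusion filters, normalizes, classifies against the shipped
eight-topic lexicons, and writes the report artifacts under results/:
the per-rule filter report, the topic prevalence/overlap matrix in the
published n (%) layout, and the coverage statistic.

Run:  python analysis/02_run_pipeline.py
"""

import sys
from pathlib import Path

from cigartopics.aggregate import build_matrix, coverage, write_matrix
from cigartopics.classify import classify_corpus, default_lexicons, write_assignments
from cigartopics.ingest import count_unique_users, filter_corpus, read_corpus
from cigartopics.normalize import NormalizedTweet, normalize_text
from cigartopics.synthetic import GroundTruth

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    corpus_path = ROOT / "scratch" / "corpus.jsonl"
    truth_path = ROOT / "scratch" / "ground_truth.json"
    if not corpus_path.is_file():
        sys.exit("no corpus found — run analysis/01_simulate_corpus.py first")

    corpus = read_corpus(corpus_path)
    bot_accounts = (
        GroundTruth.from_json(truth_path).bot_accounts if truth_path.is_file() else frozenset()
    )
    retained, report = filter_corpus(corpus, bot_accounts=bot_accounts)
    normalized = [NormalizedTweet(t.tweet_id, normalize_text(t.text)) for t in retained]
    lexicons = default_lexicons()
    assignments = classify_corpus(normalized, lexicons)
    labels = [lex.topic for lex in lexicons]
    matrix = build_matrix(assignments, labels, len(retained))
    cov = coverage(assignments, len(retained))

    results = ROOT / "results"
    results.mkdir(exist_ok=True)
    report.to_json(results / "filter_report.json")
    write_matrix(matrix, results / "topic_matrix.csv")
    cov.to_json(results / "coverage.json")
    write_assignments(assignments[:200], results / "assignments_head.csv")

    print(f"analytic sample: {report.n_retained} of {report.n_input} tweets "
          f"({100 * report.n_retained / report.n_input:.2f}%) "
          f"from {count_unique_users(retained)} unique users")
    print(f"excluded: {report.n_non_english} non-English, {report.n_retweet} retweets, "
          f"{report.n_bot} bot, {report.n_surname} surname, {report.n_no_keyword} no-keyword")
    for label in labels:
        c = matrix.cell(label, label)
        print(f"  {label:18s} {c:6d} ({100 * c / len(retained):5.2f}%)")
    print(f"coverage: {cov.pct_classified:.2f}% of tweets carry at least one topic")


if __name__ == "__main__":
    main()
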