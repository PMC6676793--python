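"""Generate the study-scale synthetic tweet corpus.

Builds a year-of-brand-chatter stand-in for the private Twitter corpus:
111,263 tweets with the eight-topic prevalence structure and the
strongest pairwise overlap planted, contaminated with retweets,
non-English tweets, bot-account tweets and surname uses at fractions
totalling 26.9%. Writes the corpus (JSONL) and its ground truth under
scratch/ (they are large), and a small generation summary under
results/.

Run:  python analysis/01_simulate_corpus.py [--seed 2018] [--n 111263]
"""

import argparse
import json
from pathlib import Path

from cigartopics.ingest import write_corpus
from cigartopics.synthetic import generate_corpus, study_spec

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    parser = argparse.ArgumentParser()
    parser.add_argument("--seed", type=int, default=2018)
    parser.add_argument("--n", type=int, default=111_263)
    args = parser.parse_args()

    spec = study_spec(seed=args.seed, n_tweets=args.n)
    corpus, truth = generate_corpus(spec)

    scratch = ROOT / "scratch"
    scratch.mkdir(exist_ok=True)
    write_corpus(corpus, scratch / "corpus.jsonl")
    truth.to_json(scratch / "ground_truth.json")

    results = ROOT / "results"
    results.mkdir(exist_ok=True)
    summary = {
        "seed": args.seed,
        "n_tweets": spec.n_tweets,
        "n_clean": truth.n_clean,
        "contamination_counts": truth.contamination_counts(),
        "planted_marginal_counts": truth.marginal_counts,
        "planted_flavors_swisher_use_overlap": truth.pairwise_counts.get(
            "Flavors|Swisher use", 0
        ),
    }
    (results / "simulation_summary.json").write_text(
        json.dumps(summary, indent=2) + "\n", "utf-8"
    )

    print(f"wrote {spec.n_tweets} tweets to scratch/corpus.jsonl (seed {args.seed})")
    print(f"clean tweets: {truth.n_clean} ({100 * truth.n_clean / spec.n_tweets:.2f}%)")
    print("contamination:", summary["contamination_counts"])


if __name__ == "__main__":
    main()
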