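"""Rule-based multi-label topic classification.

A tweet belongs to every topic whose lexicon shares at least one unigram
or adjacent-bigram with the tweet's normalized token sequence — pure set
membership, no scoring, no mutual exclusion. The shipped default lexicons
cover the eight dominant topics of Swisher little-cigar chatter on
Twitter (person tagging, flavors, use, cannabis, appeal, dislike,
purchases, comparison with other cigar brands); they are deliberately
user-replaceable since no keyword list of this kind is exhaustive.

Bigrams are formed on the post-stop-word-removal sequence, so "smoke a
swisher" matches the bigram (smoke, swisher).
"""

from __future__ import annotations

import csv
import json
from collections import Counter
from dataclasses import dataclass
from functools import lru_cache
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import yaml

from .normalize import NormalizedTweet, normalize_text

__all__ = [
    "TopicLexicon",
    "TopicAssignment",
    "extract_ngrams",
    "classify_tweet",
    "classify_corpus",
    "load_lexicons",
    "default_lexicons",
    "ngram_frequencies",
    "write_assignments",
]

Bigram = tuple[str, str]


@dataclass(frozen=True)
class TopicLexicon:
    """A named topic with its unigram and bigram keyword sets (lemmas,
    same normalization convention as the tweet pipeline)."""

    topic: str
    unigrams: frozenset[str]
    bigrams: frozenset[Bigram]

    def __post_init__(self):
        if not self.topic:
            raise ValueError("topic label must be non-empty")
        if not (self.unigrams or self.bigrams):
            raise ValueError(f"lexicon {self.topic!r} is empty")


@dataclass(frozen=True)
class TopicAssignment:
    """The (possibly empty) topic label set attached to one tweet."""

    tweet_id: str
    topics: frozenset[str]


def extract_ngrams(tokens: Sequence[str]) -> tuple[set[str], set[Bigram]]:
    """Unigram set and adjacent ordered-bigram set of a normalized
    token sequence."""
    unigrams = set(tokens)
    bigrams = {(tokens[i], tokens[i + 1]) for i in range(len(tokens) - 1)}
    return unigrams, bigrams


def classify_tweet(
    tokens: Sequence[str],
    lexicons: Sequence[TopicLexicon],
    tweet_id: str = "",
) -> TopicAssignment:
    """Assign every topic whose lexicon intersects the tweet's n-grams."""
    unigrams, bigrams = extract_ngrams(tokens)
    topics = frozenset(
        lex.topic
        for lex in lexicons
        if not unigrams.isdisjoint(lex.unigrams) or not bigrams.isdisjoint(lex.bigrams)
    )
    return TopicAssignment(tweet_id=tweet_id, topics=topics)


def classify_corpus(
    corpus: Iterable[NormalizedTweet], lexicons: Sequence[TopicLexicon]
) -> list[TopicAssignment]:
    return [classify_tweet(t.tokens, lexicons, t.tweet_id) for t in corpus]


def _normalize_entry(entry: str) -> tuple[str, ...]:
    # lexicon entries go through the tweet normalization chain minus
    # stop-word removal, so entries like "no" and "don't" survive intact
    return normalize_text(str(entry), stop_words=frozenset())


def _build_lexicon(topic: str, spec: dict) -> TopicLexicon:
    unigrams: set[str] = set()
    bigrams: set[Bigram] = set()
    entries = list(spec.get("unigrams", [])) + list(spec.get("bigrams", []))
    for entry in entries:
        toks = _normalize_entry(entry)
        if len(toks) == 1:
            unigrams.add(toks[0])
        elif len(toks) == 2:
            bigrams.add((toks[0], toks[1]))
        else:
            raise ValueError(
                f"lexicon {topic!r}: entry {entry!r} normalizes to "
                f"{len(toks)} tokens; only unigrams and bigrams are supported"
            )
    return TopicLexicon(topic=topic, unigrams=frozenset(unigrams), bigrams=frozenset(bigrams))


def load_lexicons(path: str | Path | None = None) -> list[TopicLexicon]:
    """Load topic lexicons from a YAML/JSON mapping
    ``topic -> {unigrams: [...], bigrams: [...]}`` (bigrams written as
    two-token strings), in file order. ``None`` loads the shipped default
    set."""
    if path is None:
        raw = resources.files("cigartopics.data").joinpath("lexicons.yaml").read_text("utf-8")
    else:
        path = Path(path)
        if not path.is_file():
            raise FileNotFoundError(f"lexicon file not found: {path}")
        raw = path.read_text("utf-8")
    data = yaml.safe_load(raw)
    if not isinstance(data, dict) or not data:
        raise ValueError("lexicon file must be a non-empty mapping of topic -> entry lists")
    labels = list(data)
    if len(set(labels)) != len(labels):
        raise ValueError("duplicate topic labels in lexicon file")
    return [_build_lexicon(topic, spec or {}) for topic, spec in data.items()]


@lru_cache(maxsize=1)
def _default_lexicons() -> tuple[TopicLexicon, ...]:
    return tuple(load_lexicons(None))


def default_lexicons() -> list[TopicLexicon]:
    """The eight shipped topic lexicons, in overlap-matrix order."""
    return list(_default_lexicons())


def ngram_frequencies(
    corpus: Iterable[NormalizedTweet], top_k: int
) -> list[tuple[str | Bigram, int]]:
    """Top-``top_k`` unigram and bigram occurrence counts over a corpus —
    the exploratory word-frequency step used to discover topics.

    Sorted by count descending; ties broken unigrams-first, then
    lexicographically.
    """
    if top_k < 1:
        raise ValueError("top_k must be >= 1")
    counts: Counter = Counter()
    for tweet in corpus:
        toks = tweet.tokens
        counts.update(toks)
        counts.update((toks[i], toks[i + 1]) for i in range(len(toks) - 1))

    def sort_key(item):
        ngram, count = item
        arity = 1 if isinstance(ngram, str) else 2
        key = (ngram,) if isinstance(ngram, str) else ngram
        return (-count, arity, key)

    return sorted(counts.items(), key=sort_key)[:top_k]


def write_assignments(
    assignments: Iterable[TopicAssignment], path: str | Path, format: str = "csv"
) -> None:
    """Write assignments as CSV (pipe-delimited labels) or JSONL."""
    path = Path(path)
    if format == "csv":
        with path.open("w", encoding="utf-8", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["tweet_id", "topics"])
            for a in assignments:
                writer.writerow([a.tweet_id, "|".join(sorted(a.topics))])
    elif format == "jsonl":
        with path.open("w", encoding="utf-8") as fh:
            for a in assignments:
                fh.write(
                    json.dumps(
                        {"tweet_id": a.tweet_id, "topics": sorted(a.topics)},
                        ensure_ascii=False,
                    )
                    + "\n"
                )
    else:
        raise ValueError(f"unknown assignments format: {format!r}")
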