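"""Corpus ingestion and exclusion filtering.

Reads tweet corpora from JSON-lines or CSV and applies the analytic-sample
exclusion rules: non-English tweets, retweets, tweets from known bot
accounts, surname uses of the brand keyword, and tweets not containing the
keyword at all. Rules are applied in that fixed order so every excluded
tweet is counted under exactly one reason and the filter report always
balances.

Bot detection is list-based (the caller supplies account ids); surname
detection is a documented heuristic — a capitalized given name immediately
before the keyword. Both choices are pluggable/disableable.
"""

from __future__ import annotations

import csv
import json
import logging
import re
from dataclasses import asdict, dataclass, field
from functools import lru_cache
from pathlib import Path
from typing import Callable, Iterable, Sequence

from .normalize import _read_wordfile, load_stopwords

__all__ = [
    "RawTweet",
    "FilterReport",
    "read_corpus",
    "write_corpus",
    "contains_keyword",
    "is_surname_use",
    "filter_corpus",
    "count_unique_users",
    "read_bot_list",
    "load_first_names",
    "stopword_overlap_detector",
]

log = logging.getLogger(__name__)

DEFAULT_KEYWORD = "swisher"

_CSV_COLUMNS = ["tweet_id", "text", "lang", "is_retweet", "author_id", "timestamp"]
_TRUE_STRINGS = {"true", "1", "t", "yes"}


@dataclass(frozen=True)
class RawTweet:
    """One ingested post with the metadata the exclusion rules need."""

    tweet_id: str
    text: str
    lang: str = ""
    is_retweet: bool = False
    author_id: str = ""
    timestamp: str = ""


@dataclass
class FilterReport:
    """Per-rule exclusion tally; each excluded tweet counts exactly once,
    under the first rule that matched."""

    n_input: int = 0
    n_non_english: int = 0
    n_retweet: int = 0
    n_bot: int = 0
    n_surname: int = 0
    n_no_keyword: int = 0
    n_retained: int = 0

    @property
    def n_excluded(self) -> int:
        return (
            self.n_non_english
            + self.n_retweet
            + self.n_bot
            + self.n_surname
            + self.n_no_keyword
        )

    def to_dict(self) -> dict:
        d = asdict(self)
        d["n_excluded"] = self.n_excluded
        return d

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n", "utf-8")


def _coerce_tweet(record: dict) -> RawTweet:
    tid = str(record["tweet_id"])
    if not tid:
        raise ValueError("empty tweet_id")
    retweet = record.get("is_retweet", False)
    if isinstance(retweet, str):
        retweet = retweet.strip().lower() in _TRUE_STRINGS
    return RawTweet(
        tweet_id=tid,
        text=str(record.get("text") or ""),
        lang=str(record.get("lang") or "").strip().lower(),
        is_retweet=bool(retweet),
        author_id=str(record.get("author_id") or ""),
        timestamp=str(record.get("timestamp") or ""),
    )


def read_corpus(path: str | Path, format: str | None = None) -> list[RawTweet]:
    """Read a tweet corpus from a JSONL or CSV file, in file order.

    ``format`` is inferred from the extension when omitted. Malformed
    records are skipped with a logged warning and a final tally; an
    unreadable file is a fatal error naming the path.
    """
    path = Path(path)
    if not path.is_file():
        raise FileNotFoundError(f"corpus file not found: {path}")
    if format is None:
        format = "csv" if path.suffix.lower() == ".csv" else "jsonl"
    if format not in ("jsonl", "csv"):
        raise ValueError(f"unknown corpus format: {format!r}")

    tweets: list[RawTweet] = []
    n_bad = 0
    if format == "jsonl":
        with path.open(encoding="utf-8") as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.strip()
                if not line:
                    continue
                try:
                    record = json.loads(line)
                    tweets.append(_coerce_tweet(record))
                except (ValueError, KeyError, TypeError) as exc:
                    n_bad += 1
                    log.warning("%s:%d: skipping malformed record (%s)", path, lineno, exc)
    else:
        with path.open(encoding="utf-8", newline="") as fh:
            for lineno, record in enumerate(csv.DictReader(fh), 2):
                try:
                    if record.get("tweet_id") is None:
                        raise KeyError("tweet_id")
                    tweets.append(_coerce_tweet(record))
                except (ValueError, KeyError, TypeError) as exc:
                    n_bad += 1
                    log.warning("%s:%d: skipping malformed record (%s)", path, lineno, exc)
    if n_bad:
        log.warning("%s: skipped %d malformed record(s)", path, n_bad)
    return tweets


def write_corpus(tweets: Iterable[RawTweet], path: str | Path, format: str = "jsonl") -> None:
    """Write a corpus in the same JSONL/CSV dialect :func:`read_corpus` reads."""
    path = Path(path)
    if format == "jsonl":
        with path.open("w", encoding="utf-8") as fh:
            for t in tweets:
                fh.write(json.dumps(asdict(t), ensure_ascii=False) + "\n")
    elif format == "csv":
        with path.open("w", encoding="utf-8", newline="") as fh:
            writer = csv.DictWriter(fh, fieldnames=_CSV_COLUMNS)
            writer.writeheader()
            for t in tweets:
                writer.writerow(asdict(t))
    else:
        raise ValueError(f"unknown corpus format: {format!r}")


@lru_cache(maxsize=32)
def _keyword_re(keyword: str) -> re.Pattern:
    # token or token-prefix: the keyword must start at a word boundary, so
    # "Swisher's" and "SWISHERS" match "swisher" but "asswisher" does not
    return re.compile(rf"(?<![a-z0-9]){re.escape(keyword.lower())}")


def contains_keyword(text: str, keyword: str = DEFAULT_KEYWORD) -> bool:
    """True iff ``keyword`` occurs case-insensitively as a token or token
    prefix in ``text`` (possessives and plurals count)."""
    if not keyword:
        raise ValueError("keyword must be non-empty")
    return _keyword_re(keyword).search(text.lower()) is not None


@lru_cache(maxsize=None)
def load_first_names() -> frozenset[str]:
    """The shipped given-name list backing the surname heuristic."""
    return frozenset(_read_wordfile("first_names.txt"))


def _strip_token(tok: str) -> str:
    return tok.strip("\"'“”‘’.,!?;:()[]{}#*~-")


def is_surname_use(
    text: str,
    keyword: str = DEFAULT_KEYWORD,
    first_names: frozenset[str] | set[str] | None = None,
) -> bool:
    """Heuristic: does the keyword appear as a person's surname?

    True iff some occurrence of the keyword is immediately preceded by a
    capitalized token found in the given-name list ("Interview with Kara
    Swisher"). Sentence-initial or brand uses ("Swisher sweets") are not
    flagged. This is a heuristic stand-in for manual review and can be
    disabled in :func:`filter_corpus`.
    """
    if first_names is None:
        first_names = load_first_names()
    kw = keyword.lower()
    words = text.split()
    for i, raw in enumerate(words):
        tok = _strip_token(raw)
        if not tok.lower().startswith(kw):
            continue
        if i == 0:
            continue
        prev = _strip_token(words[i - 1])
        if prev and prev[0].isupper() and prev.lower() in first_names:
            return True
    return False


def stopword_overlap_detector(text: str) -> bool:
    """Cheap language hook for tweets with no ``lang`` metadata: accept as
    English when any common English function word appears. Permissive by
    design — short keyword-only tweets pass."""
    tokens = {t.lower() for t in re.findall(r"[a-z']+", text.lower())}
    return not tokens or bool(tokens & load_stopwords())


def filter_corpus(
    tweets: Sequence[RawTweet],
    keyword: str = DEFAULT_KEYWORD,
    bot_accounts: frozenset[str] | set[str] = frozenset(),
    first_names: frozenset[str] | set[str] | None = None,
    lang_detector: Callable[[str], bool] | None = None,
    surname_filter: bool = True,
) -> tuple[list[RawTweet], FilterReport]:
    """Apply the exclusion rules and return the analytic sample.

    Rule order is fixed: non-English -> retweet -> bot -> surname ->
    no-keyword. A tweet with ``lang == "en"`` is English; an empty ``lang``
    goes through ``lang_detector`` (default: assume English). Retained
    tweets satisfy every rule, so filtering is idempotent.
    """
    report = FilterReport(n_input=len(tweets))
    retained: list[RawTweet] = []
    for t in tweets:
        if t.lang == "en" or (not t.lang and (lang_detector is None or lang_detector(t.text))):
            pass
        else:
            report.n_non_english += 1
            continue
        if t.is_retweet:
            report.n_retweet += 1
            continue
        if t.author_id and t.author_id in bot_accounts:
            report.n_bot += 1
            continue
        if surname_filter and is_surname_use(t.text, keyword, first_names):
            report.n_surname += 1
            continue
        if not contains_keyword(t.text, keyword):
            report.n_no_keyword += 1
            continue
        retained.append(t)
    report.n_retained = len(retained)
    assert report.n_retained + report.n_excluded == report.n_input
    return retained, report


def read_bot_list(path: str | Path) -> frozenset[str]:
    """Read a bot-account exclusion list: one author id per line, "#"
    comments and blank lines allowed."""
    path = Path(path)
    if not path.is_file():
        raise FileNotFoundError(f"bot list not found: {path}")
    ids = set()
    for line in path.read_text("utf-8").splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            ids.add(line)
    return frozenset(ids)


def count_unique_users(tweets: Iterable[RawTweet]) -> int:
    """Number of distinct author ids in a corpus."""
    return len({t.author_id for t in tweets})
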