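"""Tweet text normalization.

Turns raw tweet text into the ordered lowercase lemma sequence the
rule-based topic classifier consumes. The chain runs in a fixed stage
order — URLs, @-mentions, hashtags, case, punctuation, non-printables,
tokenization, stop words, lemmatization — because the URL/mention/hashtag
patterns are destroyed by punctuation stripping and must be handled first.

The lemmatizer is deterministic: an irregular-form table, then suffix
rules (-ies/-ing/-ed/-es/-s) whose stripped candidates are validated
against a shipped vocabulary; unknown tokens pass through unchanged.
Stop-word list, irregular table and vocabulary are versioned files in
``cigartopics/data`` so results are reproducible across installations.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from functools import lru_cache
from importlib import resources

__all__ = [
    "NormalizedTweet",
    "DEFAULT_MENTION_TOKEN",
    "load_stopwords",
    "replace_mentions",
    "lemmatize_token",
    "normalize_text",
    "detokenize",
]

DEFAULT_MENTION_TOKEN = "@person"

_URL_RE = re.compile(r"(?:https?://|www\.)\S+", re.IGNORECASE)
# "@" must begin a whitespace-delimited token, so e-mail addresses survive
_MENTION_RE = re.compile(r"(?<!\S)@\w+")
_HASHTAG_RE = re.compile(r"(?<!\S)#(\w+)")
# apostrophes/hyphens inside a word are deleted (don't -> dont,
# white-owl -> whiteowl); every other punctuation mark becomes a space
_INWORD_JOIN_RE = re.compile(r"(?<=\w)['’‘-](?=\w)")
_PUNCT_RE = re.compile(r"[^\w\s@]")
_MIDTOKEN_AT_RE = re.compile(r"(?<=\S)@")
_NON_ASCII_RE = re.compile(r"[^\x20-\x7e\s]")

_VOWELS = set("aeiou")


@dataclass(frozen=True)
class NormalizedTweet:
    """Ordered token sequence produced by :func:`normalize_text`, linked
    to the source tweet id."""

    tweet_id: str
    tokens: tuple[str, ...]


def _read_wordfile(name: str) -> list[str]:
    text = resources.files("cigartopics.data").joinpath(name).read_text("utf-8")
    out = []
    for line in text.splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            out.append(line)
    return out


@lru_cache(maxsize=None)
def load_stopwords() -> frozenset[str]:
    """The shipped English stop-word snapshot (lowercase)."""
    return frozenset(_read_wordfile("stopwords.txt"))


@lru_cache(maxsize=None)
def _lemma_exceptions() -> dict[str, str]:
    table = {}
    for line in _read_wordfile("lemma_exceptions.txt"):
        form, lemma = line.split()
        table[form] = lemma
    return table


@lru_cache(maxsize=None)
def _lemma_vocab() -> frozenset[str]:
    return frozenset(_read_wordfile("lemma_vocab.txt"))


def _dedouble(stem: str) -> str | None:
    if len(stem) >= 3 and stem[-1] == stem[-2] and stem[-1] not in _VOWELS:
        return stem[:-1]
    return None


@lru_cache(maxsize=65536)
def lemmatize_token(token: str) -> str:
    """Reduce a lowercased token to its base form.

    Deterministic for a fixed data-file version; identity for unknown
    tokens. Tokens starting with "@" (the mention token) pass through.
    """
    if not token or token.startswith("@"):
        return token
    exceptions = _lemma_exceptions()
    if token in exceptions:
        return exceptions[token]
    vocab = _lemma_vocab()
    if token in vocab:
        return token

    if token.endswith("ies") and len(token) >= 5:
        return token[:-3] + "y"
    for suffix in ("ing", "ed"):
        if token.endswith(suffix) and len(token) >= len(suffix) + 2:
            stem = token[: -len(suffix)]
            for cand in (stem, stem + "e", _dedouble(stem)):
                if cand and cand in vocab:
                    return cand
    if token.endswith("es") and len(token) >= 4:
        stem = token[:-2]
        if stem in vocab:
            return stem
        if stem.endswith(("s", "x", "z", "ch", "sh")):
            return stem
    if token.endswith("s") and not token.endswith("ss") and len(token) >= 4:
        return token[:-1]
    return token


def replace_mentions(text: str, mention_token: str = DEFAULT_MENTION_TOKEN) -> str:
    """Replace every token-initial @-handle with the canonical mention
    token; everything else is unchanged."""
    return _MENTION_RE.sub(mention_token, text)


def strip_urls(text: str) -> str:
    return _URL_RE.sub(" ", text)


def strip_hashtags(text: str, keep_words: bool = False) -> str:
    """Delete hashtag tokens wholesale; with ``keep_words`` retain the
    bare word (the tag minus "#")."""
    return _HASHTAG_RE.sub(r"\1" if keep_words else " ", text)


def normalize_text(
    text: str,
    stop_words: frozenset[str] | set[str] | None = None,
    mention_token: str = DEFAULT_MENTION_TOKEN,
    keep_hashtag_words: bool = False,
    lemmatize: bool = True,
) -> tuple[str, ...]:
    """Run the full normalization chain on one tweet's text.

    Stage order: URLs removed, mentions canonicalized, hashtags deleted,
    lowercased, punctuation stripped (in-word apostrophes/hyphens collapse
    the word), non-printables and emoji removed, whitespace-tokenized,
    stop words dropped, tokens lemmatized. Stop words are filtered once
    more after lemmatization so no base form in the stop list survives.
    """
    if stop_words is None:
        stop_words = load_stopwords()
    s = strip_urls(text)
    s = replace_mentions(s, mention_token)
    s = strip_hashtags(s, keep_words=keep_hashtag_words)
    s = s.lower()
    s = _INWORD_JOIN_RE.sub("", s)
    s = _PUNCT_RE.sub(" ", s)
    s = _MIDTOKEN_AT_RE.sub("", s)
    s = _NON_ASCII_RE.sub("", s)
    tokens = [t for t in s.split() if t and t != "@" and t not in stop_words]
    if lemmatize:
        tokens = [lemmatize_token(t) for t in tokens]
        tokens = [t for t in tokens if t and t not in stop_words]
    return tuple(tokens)


def detokenize(tokens: tuple[str, ...] | list[str]) -> str:
    """Inverse-ish of tokenization: join tokens with single spaces."""
    return " ".join(tokens)
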