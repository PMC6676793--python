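"""Corpus reading and exclusion-rule filtering."""

import json

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cigartopics.ingest import (
    FilterReport,
    RawTweet,
    contains_keyword,
    count_unique_users,
    filter_corpus,
    is_surname_use,
    read_bot_list,
    read_corpus,
    write_corpus,
)


def _write_jsonl(path, records):
    path.write_text("\n".join(json.dumps(r) for r in records) + "\n", "utf-8")


class TestReadCorpus:
    def test_jsonl_field_mapping(self, tmp_path, valid_records):
        p = tmp_path / "c.jsonl"
        _write_jsonl(p, valid_records)
        tweets = read_corpus(p)
        assert [t.tweet_id for t in tweets] == ["1", "2", "3"]
        assert tweets[0] == RawTweet("1", "swisher time", "en", False, "a",
                                     "2018-01-01T00:00:00Z")
        assert tweets[1].is_retweet and tweets[2].lang == ""

    def test_csv_and_jsonl_twins_agree(self, tmp_path, valid_records):
        tweets = [RawTweet(**{k: v for k, v in r.items()}) for r in valid_records]
        write_corpus(tweets, tmp_path / "c.jsonl", "jsonl")
        write_corpus(tweets, tmp_path / "c.csv", "csv")
        assert read_corpus(tmp_path / "c.jsonl") == read_corpus(tmp_path / "c.csv")

    def test_empty_file(self, tmp_path):
        p = tmp_path / "empty.jsonl"
        p.write_text("", "utf-8")
        assert read_corpus(p) == []

    def test_missing_file_is_fatal_and_names_path(self, tmp_path):
        with pytest.raises(FileNotFoundError, match="nope.jsonl"):
            read_corpus(tmp_path / "nope.jsonl")

    def test_malformed_records_skipped_with_tally(self, tmp_path, caplog):
        p = tmp_path / "c.jsonl"
        p.write_text('{"tweet_id":"1","text":"swisher"}\nnot json\n{"text":"no id"}\n', "utf-8")
        with caplog.at_level("WARNING"):
            tweets = read_corpus(p)
        assert [t.tweet_id for t in tweets] == ["1"]
        assert "skipped 2 malformed" in caplog.text

    def test_missing_optional_fields_default(self, tmp_path):
        p = tmp_path / "c.jsonl"
        _write_jsonl(p, [{"tweet_id": "9", "text": "a swisher"}])
        (t,) = read_corpus(p)
        assert (t.lang, t.is_retweet, t.author_id, t.timestamp) == ("", False, "", "")


class TestContainsKeyword:
    @pytest.mark.parametrize(
        "text,expected",
        [
            ("Smoking a Swisher tonight", True),
            ("smoking tonight", False),
            ("swisher's new flavor", True),          # possessive = token prefix
            ("SWISHERS on deck", True),              # plural, case-insensitive
            ("#swisher gang", True),                 # hashtag still contains the term
            ("that asswisher guy", False),           # not at a token start
            ("", False),
        ],
    )
    def test_token_prefix_matching(self, text, expected):
        assert contains_keyword(text, "swisher") is expected

    def test_empty_keyword_rejected(self):
        with pytest.raises(ValueError):
            contains_keyword("anything", "")


class TestSurnameHeuristic:
    @pytest.mark.parametrize(
        "text,expected",
        [
            ("Interview with John Swisher today", True),
            ("buy a swisher today", False),
            ("Swisher sweets on deck", False),        # sentence-initial, no preceding token
            ("great talk by Kara Swisher!", True),
            ("with john swisher", False),             # name not capitalized
            ("Tower Swisher combo", False),           # preceding token not a given name
        ],
    )
    def test_preceding_capitalized_given_name(self, text, expected):
        assert is_surname_use(text, "swisher") is expected


class TestFilterCorpus:
    def test_one_exclusion_per_rule(self, mixed_corpus):
        retained, rep = filter_corpus(mixed_corpus, bot_accounts={"bot1"})
        assert [t.tweet_id for t in retained] == ["5"]
        assert (rep.n_input, rep.n_non_english, rep.n_retweet, rep.n_bot,
                rep.n_surname, rep.n_no_keyword, rep.n_retained) == (5, 1, 1, 1, 1, 0, 1)

    def test_all_valid_corpus_untouched(self):
        tweets = [RawTweet(str(i), "a swisher run", "en", False, f"u{i}") for i in range(7)]
        retained, rep = filter_corpus(tweets)
        assert len(retained) == 7 and rep.n_excluded == 0

    def test_empty_corpus(self):
        retained, rep = filter_corpus([])
        assert retained == [] and rep == FilterReport()

    def test_idempotent(self, mixed_corpus):
        retained, _ = filter_corpus(mixed_corpus, bot_accounts={"bot1"})
        again, rep = filter_corpus(retained, bot_accounts={"bot1"})
        assert again == retained and rep.n_excluded == 0

    def test_surname_filter_can_be_disabled(self, mixed_corpus):
        retained, rep = filter_corpus(mixed_corpus, bot_accounts={"bot1"}, surname_filter=False)
        assert rep.n_surname == 0 and len(retained) == 2

    def test_empty_lang_uses_detector_hook(self):
        tweets = [RawTweet("1", "swisher time", lang="")]
        kept, _ = filter_corpus(tweets)                     # default: assume English
        assert len(kept) == 1
        dropped, rep = filter_corpus(tweets, lang_detector=lambda s: False)
        assert dropped == [] and rep.n_non_english == 1


tweet_strategy = st.builds(
    RawTweet,
    tweet_id=st.uuids().map(str),
    text=st.sampled_from(
        ["a swisher run", "nothing here", "Kara Swisher speaks", "RT swisher time"]
    ),
    lang=st.sampled_from(["en", "fr", "es", ""]),
    is_retweet=st.booleans(),
    author_id=st.sampled_from(["u1", "u2", "bot1"]),
)


class TestFilterProperties:
    @given(st.lists(tweet_strategy, max_size=50))
    @settings(max_examples=50, deadline=None)
    def test_counts_always_balance(self, tweets):
        _, rep = filter_corpus(tweets, bot_accounts={"bot1"})
        assert rep.n_retained + rep.n_excluded == rep.n_input

    @given(st.lists(tweet_strategy, max_size=30), st.randoms(use_true_random=False))
    @settings(max_examples=30, deadline=None)
    def test_retained_set_permutation_invariant(self, tweets, rnd):
        retained, _ = filter_corpus(tweets, bot_accounts={"bot1"})
        shuffled = list(tweets)
        rnd.shuffle(shuffled)
        retained2, _ = filter_corpus(shuffled, bot_accounts={"bot1"})
        assert {t.tweet_id for t in retained} == {t.tweet_id for t in retained2}

    @given(st.lists(tweet_strategy, max_size=50))
    @settings(max_examples=30, deadline=None)
    def test_filtering_is_idempotent(self, tweets):
        retained, _ = filter_corpus(tweets, bot_accounts={"bot1"})
        again, rep = filter_corpus(retained, bot_accounts={"bot1"})
        assert again == retained and rep.n_excluded == 0


class TestUniqueUsers:
    def test_distinct_authors(self):
        tweets = [RawTweet("1", "x", author_id="a"), RawTweet("2", "y", author_id="a"),
                  RawTweet("3", "z", author_id="b")]
        assert count_unique_users(tweets) == 2

    def test_empty(self):
        assert count_unique_users([]) == 0


def test_bot_list_reader(tmp_path):
    p = tmp_path / "bots.txt"
    p.write_text("# known bots\nbot1\n\nbot2\n", "utf-8")
    assert read_bot_list(p) == {"bot1", "bot2"}
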