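import pytest
from hypothesis import settings

from cigartopics.ingest import RawTweet

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture
def mixed_corpus():
    """Five tweets, one per exclusion rule plus one valid, for hand-counted
    filter arithmetic."""
    return [
        RawTweet("1", "je fume un swisher ce soir", lang="fr"),
        RawTweet("2", "RT smoking a swisher tonight", lang="en", is_retweet=True),
        RawTweet("3", "swisher deals every day", lang="en", author_id="bot1"),
        RawTweet("4", "Interview with Kara Swisher today", lang="en", author_id="u1"),
        RawTweet("5", "smoking a grape swisher tonight", lang="en", author_id="u2"),
    ]


@pytest.fixture
def valid_records():
    return [
        {"tweet_id": "1", "text": "swisher time", "lang": "en",
         "is_retweet": False, "author_id": "a", "timestamp": "2018-01-01T00:00:00Z"},
        {"tweet_id": "2", "text": "try a grape swisher", "lang": "en",
         "is_retweet": True, "author_id": "b", "timestamp": "2018-06-15T12:00:00Z"},
        {"tweet_id": "3", "text": "no swishers left", "lang": "",
         "is_retweet": False, "author_id": "a", "timestamp": ""},
    ]
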