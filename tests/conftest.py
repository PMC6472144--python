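from datetime import datetime, timezone

import pytest

from emosync.corpus import TweetRecord
from emosync.lexicon import demo_lexicons


@pytest.fixture(scope="session")
def lexicons():
    return demo_lexicons()


@pytest.fixture(scope="session")
def negemo(lexicons):
    return lexicons["negemo"]


@pytest.fixture(scope="session")
def posemo(lexicons):
    return lexicons["posemo"]


def make_tweet(user="u1", ts="2015-11-13T12:00:00+01:00", text="le jour",
               is_retweet=None):
    return TweetRecord(
        user_id=user,
        timestamp=datetime.fromisoformat(ts) if isinstance(ts, str) else ts,
        text=text,
        is_retweet=is_retweet,
    )


@pytest.fixture
def tweet_factory():
    return make_tweet
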