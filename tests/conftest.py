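from datetime import datetime

import pytest
from hypothesis import HealthCheck, settings

from crisispulse import (
    BoosterEntry,
    Corpus,
    LexiconEntry,
    SentimentLexicon,
    Tweet,
)

settings.register_profile(
    "suite",
    derandomize=True,
    deadline=None,
    suppress_health_check=[
        HealthCheck.too_slow,
        # read-only fixtures are safely shared across examples
        HealthCheck.function_scoped_fixture,
    ],
)
settings.load_profile("suite")


@pytest.fixture
def toy_lexicon() -> SentimentLexicon:
    """1 positive word, 1 negative word, 1 booster, 1 negator."""
    return SentimentLexicon(
        language="en",
        entries={
            "good": LexiconEntry("good", 2),
            "bad": LexiconEntry("bad", -2),
        },
        boosters={"very": BoosterEntry("very", 1)},
        negators={"not"},
    )


@pytest.fixture
def competent_lexicon() -> SentimentLexicon:
    return SentimentLexicon(
        language="en",
        entries={"competent": LexiconEntry("competent", 1)},
        negators={"not"},
    )


def make_tweet(
    tid: str = "t1",
    user: str = "user01",
    when: str = "2020-03-15T12:00:00",
    text: str = "hello world",
    country: str = "DK",
    language: str = "",
    is_retweet: bool = False,
    phase: str = "none",
) -> Tweet:
    return Tweet(
        id=tid,
        user=user,
        timestamp=datetime.fromisoformat(when),
        text=text,
        language=language,
        country=country,
        is_retweet=is_retweet,
        phase=phase,
    )


@pytest.fixture
def small_corpus() -> Corpus:
    return Corpus(
        [
            make_tweet("a", when="2019-06-01T08:00:00", text="quiet year"),
            make_tweet("b", when="2020-03-01T09:00:00", text="first cases"),
            make_tweet("c", when="2020-03-12T10:00:00", text="lockdown now"),
            make_tweet("d", when="2020-04-20T11:00:00", text="a month in"),
        ]
    )
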