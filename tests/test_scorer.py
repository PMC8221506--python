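"""Tokenization and dual-polarity scoring rules.

Includes a brute-force oracle: an independent evaluator of the stated
scoring rules (modifier look-back window, nearest-first selection,
consume-on-apply, boost-then-negate, magnitude clipping, per-polarity
extremes), checked against the scorer on every token sequence of length
up to 5 over a six-word toy vocabulary.
"""

import itertools

import pytest
from hypothesis import given
from hypothesis import strategies as st

from crisispulse import (
    BoosterEntry,
    ConfigurationError,
    Corpus,
    LexiconEntry,
    SentimentLexicon,
    score_corpus,
    score_tweet,
    tokenize,
)

from conftest import make_tweet


@pytest.mark.parametrize(
    ("text", "expected"),
    [
        ("Merkel is a competent leader",
         ["merkel", "is", "a", "competent", "leader"]),
        ("Danke, Merkel!", ["danke", "merkel"]),
        ("#StayAtHome", ["#stayathome"]),
        ("@user: hello... world?!", ["@user", "hello", "world"]),
        ("  # @  ", []),
        ("", []),
    ],
)
def test_tokenize(text, expected):
    assert tokenize(text) == expected


def test_worked_examples(competent_lexicon):
    """The four canonical sentences: positive, negated, boosted, neutral."""
    score, ann = score_tweet(
        tokenize("Merkel is a competent leader"), competent_lexicon
    )
    assert score.as_tuple() == (1, 0)
    assert [a.applied_valence for a in ann] == [0, 0, 0, 1, 0]

    score, ann = score_tweet(
        tokenize("Merkel is not a competent leader"), competent_lexicon
    )
    assert score.as_tuple() == (0, -1)
    assert ann[2].role == "negator" and ann[4].applied_valence == -1

    boost_lex = SentimentLexicon(
        language="en",
        entries={"incompetent": LexiconEntry("incompetent", -1)},
        boosters={"extremely": BoosterEntry("extremely", 2)},
    )
    score, _ = score_tweet(
        tokenize("Merkel is an extremely incompetent leader"), boost_lex
    )
    assert score.as_tuple() == (0, -3)

    score, ann = score_tweet(
        tokenize("Merkel is holding a speech now"), competent_lexicon
    )
    assert score.as_tuple() == (0, 0)
    assert all(a.role == "plain" for a in ann)


def test_magnitude_clips_at_four():
    lex = SentimentLexicon(
        language="en",
        entries={"atrocious": LexiconEntry("atrocious", -4)},
        boosters={"extremely": BoosterEntry("extremely", 2)},
    )
    score, _ = score_tweet(["extremely", "atrocious"], lex)
    assert score.as_tuple() == (0, -4)


def test_diminisher_floors_at_one():
    lex = SentimentLexicon(
        language="en",
        entries={"fine": LexiconEntry("fine", 1)},
        boosters={"slightly": BoosterEntry("slightly", -2)},
    )
    score, _ = score_tweet(["slightly", "fine"], lex)
    assert score.as_tuple() == (1, 0)


def test_modifier_window_is_three_tokens(toy_lexicon):
    # negator 3 tokens back still applies; 4 tokens back does not
    score, _ = score_tweet(["not", "x", "y", "good"], toy_lexicon)
    assert score.as_tuple() == (0, -2)
    score, _ = score_tweet(["not", "x", "y", "z", "good"], toy_lexicon)
    assert score.as_tuple() == (2, 0)


def test_per_polarity_maximum_aggregation(toy_lexicon):
    score, _ = score_tweet(["good", "very", "good", "bad"], toy_lexicon)
    assert score.as_tuple() == (3, -2)  # max positive, min negative


@pytest.mark.parametrize("valence", [1, 2, 3, 4])
def test_negation_antisymmetry(valence):
    """not + lone sentiment word maps (p,0) to (0,-p) and back."""
    pos_lex = SentimentLexicon(
        language="en",
        entries={"w": LexiconEntry("w", valence)},
        negators={"not"},
    )
    neg_lex = SentimentLexicon(
        language="en",
        entries={"w": LexiconEntry("w", -valence)},
        negators={"not"},
    )
    assert score_tweet(["w"], pos_lex)[0].as_tuple() == (valence, 0)
    assert score_tweet(["not", "w"], pos_lex)[0].as_tuple() == (0, -valence)
    assert score_tweet(["w"], neg_lex)[0].as_tuple() == (0, -valence)
    assert score_tweet(["not", "w"], neg_lex)[0].as_tuple() == (valence, 0)


# --- brute-force oracle -----------------------------------------------------

ORACLE_VOCAB = ("good", "bad", "very", "not", "the", "dog")


def oracle_score(tokens, window=3):
    """Direct rule evaluation over the toy vocabulary.

    Written independently of the scorer: modifiers are kept as a pool of
    available positions; each sentiment word draws the closest available
    booster and negator from the pool.
    """
    valence_of = {"good": 2, "bad": -2}
    booster_pool = {i for i, t in enumerate(tokens) if t == "very"}
    negator_pool = {i for i, t in enumerate(tokens) if t == "not"}
    values = []
    for i, tok in enumerate(tokens):
        if tok not in valence_of:
            continue
        in_reach = lambda pool: {j for j in pool if i - window <= j < i}
        magnitude = abs(valence_of[tok])
        candidates = in_reach(booster_pool)
        if candidates:
            j = max(candidates)
            booster_pool.remove(j)
            magnitude = min(4, max(1, magnitude + 1))  # "very" has delta +1
        value = magnitude if valence_of[tok] > 0 else -magnitude
        candidates = in_reach(negator_pool)
        if candidates:
            negator_pool.remove(max(candidates))
            value = -value
        values.append(value)
    pos = max([v for v in values if v > 0], default=0)
    neg = min([v for v in values if v < 0], default=0)
    return pos, neg


def test_scorer_matches_oracle_on_all_short_sequences(toy_lexicon):
    """Exhaustive agreement on all <=5-token sequences (9331 cases)."""
    n_checked = 0
    for length in range(6):
        for tokens in itertools.product(ORACLE_VOCAB, repeat=length):
            score, _ = score_tweet(list(tokens), toy_lexicon)
            assert score.as_tuple() == oracle_score(list(tokens)), tokens
            n_checked += 1
    assert n_checked == 9331


@given(
    st.lists(st.sampled_from(ORACLE_VOCAB), max_size=10),
    st.sampled_from(["zzz", "#tag", "@who"]),
)
def test_appending_unmatched_token_never_changes_score(toy_lexicon, tokens, extra):
    base, _ = score_tweet(tokens, toy_lexicon)
    assert score_tweet(tokens + [extra], toy_lexicon)[0] == base
    assert score_tweet([extra] + tokens, toy_lexicon)[0] == base


@given(st.lists(st.sampled_from(ORACLE_VOCAB), max_size=10))
def test_scores_always_in_bounds(toy_lexicon, tokens):
    score, ann = score_tweet(tokens, toy_lexicon)
    assert 0 <= score.pos <= 4 and -4 <= score.neg <= 0
    for a in ann:
        assert (a.applied_valence != 0) == (a.role == "sentiment")


# --- corpus scoring ---------------------------------------------------------


def test_score_corpus_one_row_per_tweet_and_deterministic(toy_lexicon):
    corpus = Corpus(
        [
            make_tweet("a", text="a good day", phase="1"),
            make_tweet("b", text="not good at all", phase="1"),
            make_tweet("c", text="nothing here", phase="2"),
        ]
    )
    table = score_corpus(corpus, toy_lexicon)
    assert list(table["id"]) == ["a", "b", "c"]
    assert list(table["pos"]) == [2, 0, 0]
    assert list(table["neg"]) == [0, -2, 0]
    assert table.equals(score_corpus(corpus, toy_lexicon))


def test_neutral_tweets_retained(toy_lexicon):
    corpus = Corpus([make_tweet(str(i), text="just words") for i in range(4)])
    table = score_corpus(corpus, toy_lexicon)
    assert len(table) == 4
    assert (table[["pos", "neg"]] == 0).all().all()


def test_language_mismatch_raises(toy_lexicon):
    corpus = Corpus([make_tweet("a", text="hej", language="da")])
    with pytest.raises(ConfigurationError):
        score_corpus(corpus, toy_lexicon)
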