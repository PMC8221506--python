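"""The synthetic corpus generator and its exact ground truth."""

import math

import numpy as np
import pytest

from crisispulse import (
    BoosterEntry,
    ConfigurationError,
    LexiconEntry,
    SentimentLexicon,
    SyntheticConfig,
    clean_corpus,
    evaluate_dictionary,
    generate_annotations,
    generate_corpus,
    score_corpus,
    summarize_phase,
    write_corpus,
)
from crisispulse.synthetic import _perturb, sample_scores, score_distribution
from crisispulse.scorer import SentimentScore


SMALL = {"base": 400, "1": 200, "2": 200, "3": 200}


def test_fixed_seed_reproduces_byte_identical_corpus(tmp_path):
    for run in ("a", "b"):
        corpus, _ = generate_corpus(
            SyntheticConfig(seed=123, tweets_per_phase=SMALL)
        )
        write_corpus(corpus, tmp_path / f"{run}.csv")
    assert (tmp_path / "a.csv").read_bytes() == (tmp_path / "b.csv").read_bytes()


def test_no_sentiment_probability_zero_forces_neutral_corpus():
    cfg = SyntheticConfig(seed=5, tweets_per_phase=SMALL, p_sentiment_word=0.0)
    corpus, truth = generate_corpus(cfg)
    assert all(s.is_neutral for s in truth.true_scores.values())
    scores = score_corpus(corpus, cfg.lexicon)
    for phase in SMALL:
        s = summarize_phase(scores, cfg.country, phase)
        assert s.aps == 0.0 and s.ans == 0.0


def test_full_negation_with_positive_lexicon_flips_everything():
    lex = SentimentLexicon(
        language="da",
        entries={"god": LexiconEntry("god", 2), "fin": LexiconEntry("fin", 1)},
        boosters={"meget": BoosterEntry("meget", 1)},
        negators={"ikke"},
    )
    cfg = SyntheticConfig(
        seed=6, tweets_per_phase={"base": 500}, lexicon=lex,
        p_sentiment_word=1.0, p_negation=1.0,
    )
    _, truth = generate_corpus(cfg)
    for score in truth.true_scores.values():
        assert score.pos == 0 and score.neg < 0


def test_inconsistent_configs_rejected():
    with pytest.raises(ConfigurationError):
        generate_corpus(
            SyntheticConfig(vocab=(), tweets_per_phase={"base": 10})
        )
    with pytest.raises(ConfigurationError):
        generate_corpus(SyntheticConfig(p_negation=1.5))
    with pytest.raises(ConfigurationError):
        generate_corpus(SyntheticConfig(tweets_per_phase={"phase9": 5}))
    with pytest.raises(ConfigurationError):
        # plain vocab colliding with a lexicon term
        generate_corpus(SyntheticConfig(vocab=("god", "dag")))


def test_generated_phases_match_timestamps():
    corpus, _ = generate_corpus(SyntheticConfig(seed=2, tweets_per_phase=SMALL))
    by_phase = {ph: 0 for ph in SMALL}
    for t in corpus:
        assert t.phase in SMALL  # every tweet lands in its intended window
        by_phase[t.phase] += 1
    assert by_phase == SMALL


def test_scorer_recovers_planted_scores_exactly():
    """After cleaning, the scorer reproduces every planted true score."""
    cfg = SyntheticConfig(seed=7, tweets_per_phase=SMALL)
    corpus, truth = generate_corpus(cfg)
    cleaned, _ = clean_corpus(corpus)
    scores = score_corpus(cleaned, cfg.lexicon).set_index("id")
    assert len(cleaned) == len(corpus)
    for tid, row in scores.iterrows():
        assert (row["pos"], row["neg"]) == truth.true_scores[tid].as_tuple()


def test_score_distribution_sums_to_one_and_matches_moments():
    cfg = SyntheticConfig(seed=0)
    dist = score_distribution(cfg, "base")
    assert sum(dist.values()) == pytest.approx(1.0)
    assert dist[(0, 0)] >= 1.0 - cfg.p_sent("base")
    exp = cfg and generate_corpus(
        SyntheticConfig(seed=0, tweets_per_phase={"base": 10})
    )[1].expected["base"]
    assert exp["aps"] == pytest.approx(
        sum(p * s[0] for s, p in dist.items())
    )


def test_sample_scores_match_distribution_mean():
    cfg = SyntheticConfig(seed=0)
    rng = np.random.default_rng(1)
    pos, neg = sample_scores(cfg, "base", 20000, rng)
    exp = score_distribution(cfg, "base")
    mean_pos = sum(p * s[0] for s, p in exp.items())
    se = math.sqrt(sum(p * s[0] ** 2 for s, p in exp.items()) / 20000)
    assert abs(pos.mean() - mean_pos) < 4 * se
    assert set(np.unique(pos)) <= set(range(5))
    assert set(np.unique(neg)) <= set(range(-4, 1))


def test_planted_phase_shift_moves_expected_aps():
    cfg = SyntheticConfig(
        seed=0,
        tweets_per_phase={"base": 50, "2": 50},
        p_sentiment_word={"base": 0.4, "2": 0.8},
    )
    _, truth = generate_corpus(cfg)
    assert truth.expected["2"]["aps"] == pytest.approx(
        2 * truth.expected["base"]["aps"]
    )


def test_nonascii_injection_is_invertible():
    """Injected letters transliterate back to canonical vocabulary tokens."""
    from crisispulse import transliterate
    from crisispulse.scorer import tokenize

    cfg = SyntheticConfig(
        seed=3, tweets_per_phase={"base": 400}, nonascii_rate=1.0,
        p_repetitive_user=0.0, p_sentiment_word=0.0,
    )
    corpus, _ = generate_corpus(cfg)
    n_nonascii = sum(1 for t in corpus if not t.text.isascii())
    assert n_nonascii > 300  # nearly every tweet has an injectable digraph
    allowed = set(cfg.vocab)
    for t in corpus:
        assert set(tokenize(transliterate(t.text))) <= allowed


def test_repetitive_users_always_prefixed():
    cfg = SyntheticConfig(
        seed=4, tweets_per_phase={"base": 600}, p_repetitive_user=0.1
    )
    corpus, _ = generate_corpus(cfg)
    prefixed_users = {
        t.user for t in corpus if t.text.startswith(cfg.repetitive_prefix)
    }
    assert prefixed_users  # designated users exist
    for t in corpus:
        if t.user in prefixed_users:
            assert t.text.startswith(cfg.repetitive_prefix)


# --- annotation noise -------------------------------------------------------


def _tiny_annotated(noise, seed=0, n=300, p_sent=1.0):
    cfg = SyntheticConfig(
        seed=seed, tweets_per_phase={"base": n}, p_sentiment_word=p_sent
    )
    corpus, truth = generate_corpus(cfg)
    return cfg, corpus, truth, generate_annotations(corpus, truth, noise, seed=seed)


def test_zero_noise_yields_all_correct():
    cfg, corpus, truth, ann = _tiny_annotated({0: 1.0})
    summary = evaluate_dictionary(ann.tweets, cfg.lexicon)
    assert summary.correct == summary.n
    assert ann.expected_fractions["correct"] == pytest.approx(1.0)


def test_all_presence_flip_noise_all_incorrect():
    cfg, corpus, truth, ann = _tiny_annotated({"flip": 1.0})
    summary = evaluate_dictionary(ann.tweets, cfg.lexicon)
    assert summary.incorrect == summary.n
    assert ann.expected_fractions["incorrect"] == pytest.approx(1.0)


def test_deviation_noise_never_flips_presence_on_sentiment_tweets():
    for pos, neg in [(1, 0), (4, 0), (0, -1), (0, -4), (2, -3), (2, 0)]:
        true = SentimentScore(pos, neg)
        for d in (1, 2, 3):
            noisy = _perturb(true, d)
            assert not noisy.is_neutral
            dev = max(abs(noisy.pos - pos), abs(noisy.neg - neg))
            assert dev == d, (true, d, noisy)


def test_deviation_noise_clips_when_no_exact_move_exists():
    # (2,-2) cannot move either component by exactly 3 within the scale
    noisy = _perturb(SentimentScore(2, -2), 3)
    assert not noisy.is_neutral
    dev = max(abs(noisy.pos - 2), abs(noisy.neg + 2))
    assert 0 < dev <= 3


def test_expected_fractions_account_for_neutral_tweets():
    # with neutral tweets present, deviation-2 noise becomes 'incorrect'
    # for them (presence flip); expected fractions must reflect that
    cfg, corpus, truth, ann = _tiny_annotated({2: 1.0}, p_sent=0.0)
    assert ann.expected_fractions["incorrect"] == pytest.approx(1.0)
    summary = evaluate_dictionary(ann.tweets, cfg.lexicon)
    assert summary.incorrect == summary.n
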