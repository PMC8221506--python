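"""Synthetic tweet corpora with planted, exactly-known structure.

The generator emulates the features of crisis-period Twitter data the
pipeline must handle — short multilingual posts, planted sentiment words
with negators and boosters, per-user boilerplate hashtag prefixes,
non-English letters, retweets, per-phase topic mixtures — while
recording the exact ground truth: every tweet's true sentiment score,
its generating topic, and closed-form per-phase expectations for the
average positive and negative sentiment.

A tweet is built as ``[boilerplate prefix?] + body``, where the body is
``tweet_len`` tokens drawn from the phase's topic mixture (one topic per
tweet) with, at probability ``p_sentiment_word``, a short sentiment
construction ``<filler> <negator?> <booster?> <sentiment-word>``
spliced in at a random position, exercising the scorer's look-back
window.  Non-ASCII letters are injected invertibly (a transliteration
digraph such as ``aa`` is replaced by the letter ``å``), so cleaning
restores the canonical token exactly.

The per-phase sentiment score distribution is enumerated exactly from
the configuration, so tests can compare pipeline output against true
expectations rather than against a second simulation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from datetime import date, datetime, timedelta

import numpy as np

from .corpus import NO_PHASE, PHASES, Corpus, Tweet
from .dict_eval import AnnotatedTweet, classify_prediction
from .errors import ConfigurationError
from .lexicon import BoosterEntry, LexiconEntry, SentimentLexicon
from .preprocess import PhaseCalendar, assign_phases
from .scorer import SentimentScore

# digraph -> letter pairs used for invertible non-ASCII injection
_DIGRAPH_TO_LETTER = [("aa", "å"), ("oe", "ø"), ("ae", "æ"), ("ue", "ü")]


def default_lexicon() -> SentimentLexicon:
    """A small Danish-flavoured lexicon (transliterated ASCII terms)."""
    entries = {
        "fantastisk": 4, "glad": 3, "god": 2, "kompetent": 2, "fin": 1,
        "forfaerdelig": -4, "vred": -3, "daarlig": -2, "inkompetent": -2,
        "bekymret": -1,
    }
    boosters = {"ekstremt": 2, "meget": 1, "lidt": -1}
    return SentimentLexicon(
        language="da",
        entries={t: LexiconEntry(t, v) for t, v in entries.items()},
        boosters={t: BoosterEntry(t, d) for t, d in boosters.items()},
        negators={"ikke", "aldrig"},
    )


#: plain (non-sentiment) vocabulary; many terms carry transliteration
#: digraphs so non-ASCII injection has a target.
DEFAULT_VOCAB = (
    "regeringen", "landet", "corona", "virus", "smitte", "sundhed",
    "laege", "hospital", "karantaene", "graenser", "skole", "arbejde",
    "oekonomi", "hjaelp", "presse", "moede", "tale", "plan", "krise",
    "folk", "nyheder", "aftale", "stoette", "paaske", "haand", "boern",
    "tid", "uge", "aar", "leder", "minister", "beslutning",
)

DEFAULT_PREFIX = "#covid19 #regering #politik #breakingnews"


@dataclass(frozen=True)
class TopicSpec:
    """K generating topics and their per-phase mixture weights."""

    topics: tuple[tuple[tuple[str, ...], tuple[float, ...]], ...]
    phase_mixtures: dict[str, tuple[float, ...]]

    def __post_init__(self) -> None:
        for terms, probs in self.topics:
            if len(terms) != len(probs) or not math.isclose(sum(probs), 1.0):
                raise ConfigurationError("topic word probabilities must sum to 1")
        for phase, mix in self.phase_mixtures.items():
            if len(mix) != len(self.topics) or not math.isclose(sum(mix), 1.0):
                raise ConfigurationError(
                    f"phase {phase!r}: mixture must have one weight per topic, "
                    "summing to 1"
                )


def default_topic_spec(vocab: tuple[str, ...], k: int = 3) -> TopicSpec:
    """Split the vocabulary into ``k`` disjoint uniform topics.

    Mixtures drift across phases so each phase has a different dominant
    discourse, as crisis timelines do.
    """
    chunks = [tuple(vocab[i::k]) for i in range(k)]
    topics = tuple(
        (chunk, tuple([1.0 / len(chunk)] * len(chunk))) for chunk in chunks
    )
    if k == 3:
        mixtures = {
            "base": (1 / 3, 1 / 3, 1 / 3),
            "1": (0.6, 0.25, 0.15),
            "2": (0.2, 0.6, 0.2),
            "3": (0.15, 0.25, 0.6),
        }
    else:
        uniform = tuple([1.0 / k] * k)
        mixtures = {phase: uniform for phase in PHASES}
    return TopicSpec(topics=topics, phase_mixtures=mixtures)


def _default_tweets_per_phase() -> dict[str, int]:
    # desk-scale echo of real collection-volume proportions: a large
    # pre-crisis base set, a burst at lockdown onset, thinner tails
    return {"base": 8000, "1": 3000, "2": 5000, "3": 2000}


@dataclass(frozen=True)
class SyntheticConfig:
    """All knobs of the generator; every draw is governed by ``seed``."""

    seed: int = 0
    country: str = "DK"
    language: str = "da"
    n_users: int = 50
    tweets_per_phase: dict[str, int] = field(
        default_factory=_default_tweets_per_phase
    )
    vocab: tuple[str, ...] = DEFAULT_VOCAB
    lexicon: SentimentLexicon = field(default_factory=default_lexicon)
    #: probability a tweet contains a sentiment construction; either a
    #: single float or a per-phase mapping (to plant phase shifts)
    p_sentiment_word: float | dict[str, float] = 0.7
    p_negation: float = 0.15
    p_booster: float = 0.15
    topic_spec: TopicSpec | None = None
    p_retweet: float = 0.15
    p_repetitive_user: float = 0.05
    nonascii_rate: float = 0.1
    tweet_len: int = 8
    filler: str = "er"
    repetitive_prefix: str = DEFAULT_PREFIX
    calendar: PhaseCalendar = field(default_factory=PhaseCalendar)

    def p_sent(self, phase: str) -> float:
        if isinstance(self.p_sentiment_word, dict):
            return self.p_sentiment_word[phase]
        return self.p_sentiment_word

    def resolved_topic_spec(self) -> TopicSpec:
        return self.topic_spec or default_topic_spec(self.vocab)

    def validate(self) -> None:
        probs = {
            "p_negation": self.p_negation,
            "p_booster": self.p_booster,
            "p_retweet": self.p_retweet,
            "p_repetitive_user": self.p_repetitive_user,
            "nonascii_rate": self.nonascii_rate,
        }
        for phase in self.tweets_per_phase:
            if phase not in PHASES:
                raise ConfigurationError(f"unknown phase {phase!r}")
            probs[f"p_sentiment_word[{phase}]"] = self.p_sent(phase)
        for name, p in probs.items():
            if not 0.0 <= p <= 1.0:
                raise ConfigurationError(f"{name} must be in [0, 1], got {p}")
        if any(n < 0 for n in self.tweets_per_phase.values()):
            raise ConfigurationError("tweet counts must be >= 0")
        total = sum(self.tweets_per_phase.values())
        if total > 0 and not self.vocab:
            raise ConfigurationError("empty vocab with positive tweet counts")
        if self.n_users < 1:
            raise ConfigurationError("n_users must be >= 1")
        lex_terms = (
            set(self.lexicon.entries)
            | set(self.lexicon.boosters)
            | self.lexicon.negators
        )
        clash = lex_terms & set(self.vocab) | ({self.filler} & lex_terms)
        if clash:
            raise ConfigurationError(
                f"plain vocab/filler must not collide with lexicon terms: "
                f"{sorted(clash)}"
            )
        if any(self.p_sent(ph) > 0 for ph in self.tweets_per_phase) and not (
            self.lexicon.entries
        ):
            raise ConfigurationError("p_sentiment_word > 0 needs lexicon entries")
        if self.p_booster > 0 and not self.lexicon.boosters:
            raise ConfigurationError("p_booster > 0 needs booster entries")
        if self.p_negation > 0 and not self.lexicon.negators:
            raise ConfigurationError("p_negation > 0 needs negators")


def score_distribution(
    cfg: SyntheticConfig, phase: str
) -> dict[tuple[int, int], float]:
    """Exact distribution of the true (pos, neg) score for one phase.

    Enumerates entry × booster × negation outcomes with the same
    magnitude-clipping semantics the scorer applies.
    """
    p_s = cfg.p_sent(phase)
    dist: dict[tuple[int, int], float] = {(0, 0): 1.0 - p_s}
    if p_s == 0:
        return dist
    entries = list(cfg.lexicon.entries.values())
    boosters = list(cfg.lexicon.boosters.values())
    booster_opts: list[tuple[int | None, float]] = [(None, 1.0 - cfg.p_booster)]
    if boosters:
        booster_opts += [
            (b.delta, cfg.p_booster / len(boosters)) for b in boosters
        ]
    for entry in entries:
        p_entry = p_s / len(entries)
        for delta, p_boost in booster_opts:
            for negated, p_neg in ((False, 1 - cfg.p_negation),
                                   (True, cfg.p_negation)):
                prob = p_entry * p_boost * p_neg
                if prob == 0:
                    continue
                value = _construction_value(entry.valence, delta, negated)
                key = (max(value, 0), min(value, 0))
                dist[key] = dist.get(key, 0.0) + prob
    return dist


def _construction_value(valence: int, delta: int | None, negated: bool) -> int:
    sign = 1 if valence > 0 else -1
    magnitude = abs(valence)
    if delta is not None:
        magnitude = max(1, min(4, magnitude + delta))
    value = sign * magnitude
    return -value if negated else value


def _moments(dist: dict[tuple[int, int], float]) -> dict[str, float]:
    e_pos = sum(p * s[0] for s, p in dist.items())
    e_pos2 = sum(p * s[0] ** 2 for s, p in dist.items())
    e_neg = sum(p * s[1] for s, p in dist.items())
    e_neg2 = sum(p * s[1] ** 2 for s, p in dist.items())
    return {
        "aps": e_pos,
        "ans": e_neg,
        "var_pos": e_pos2 - e_pos**2,
        "var_neg": e_neg2 - e_neg**2,
    }


@dataclass(frozen=True)
class GroundTruth:
    """What the generator actually planted."""

    true_scores: dict[str, SentimentScore]
    topic_of: dict[str, int]
    #: phase -> exact {aps, ans, var_pos, var_neg} under the config
    expected: dict[str, dict[str, float]]


def sample_scores(
    cfg: SyntheticConfig, phase: str, n: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Draw ``n`` true (pos, neg) score pairs for a phase.

    Samples from the exact score distribution — the same law full
    corpus generation plants — without rendering text; used for
    large-replicate power studies.
    """
    dist = score_distribution(cfg, phase)
    outcomes = sorted(dist)
    probs = np.array([dist[o] for o in outcomes])
    idx = rng.choice(len(outcomes), size=n, p=probs / probs.sum())
    pos = np.array([outcomes[i][0] for i in idx])
    neg = np.array([outcomes[i][1] for i in idx])
    return pos, neg


def _random_timestamp(
    cfg: SyntheticConfig, phase: str, rng: np.random.Generator
) -> datetime:
    cal = cfg.calendar
    if phase == "base":
        start = date(cal.base_year, 1, 1)
        end = date(cal.base_year, 12, 31)
    elif phase == "1":
        start = cal.phase1_start.get(cfg.country)
        if start is None:
            raise ConfigurationError(f"no calendar entry for {cfg.country!r}")
        end = cal.phase1_end
    elif phase == "2":
        start, end = cal.phase2
    else:
        start, end = cal.phase3
    day = start + timedelta(days=int(rng.integers((end - start).days + 1)))
    seconds = int(rng.integers(86400))
    return datetime(day.year, day.month, day.day) + timedelta(seconds=seconds)


def _inject_nonascii(tokens: list[str], rng: np.random.Generator) -> None:
    candidates = [
        (i, digraph, letter)
        for i, tok in enumerate(tokens)
        for digraph, letter in _DIGRAPH_TO_LETTER
        if digraph in tok
    ]
    if not candidates:
        return
    i, digraph, letter = candidates[int(rng.integers(len(candidates)))]
    tokens[i] = tokens[i].replace(digraph, letter, 1)


def generate_corpus(cfg: SyntheticConfig) -> tuple[Corpus, GroundTruth]:
    """Generate a corpus and its ground truth; deterministic under seed."""
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    spec = cfg.resolved_topic_spec()
    n_repetitive = math.ceil(cfg.p_repetitive_user * cfg.n_users)
    entries = list(cfg.lexicon.entries.values())
    boosters = list(cfg.lexicon.boosters.values())
    negators = sorted(cfg.lexicon.negators)

    tweets: list[Tweet] = []
    true_scores: dict[str, SentimentScore] = {}
    topic_of: dict[str, int] = {}
    expected: dict[str, dict[str, float]] = {}

    for phase in PHASES:
        n = cfg.tweets_per_phase.get(phase, 0)
        if n == 0:
            continue
        expected[phase] = _moments(score_distribution(cfg, phase))
        mixture = np.array(spec.phase_mixtures[phase])
        for i in range(n):
            tid = f"t{phase}_{i:06d}"
            user_idx = int(rng.integers(cfg.n_users))
            user = f"user{user_idx:04d}"
            topic_idx = int(rng.choice(len(spec.topics), p=mixture))
            terms, probs = spec.topics[topic_idx]
            body = [
                terms[int(j)]
                for j in rng.choice(len(terms), size=cfg.tweet_len,
                                    p=np.array(probs))
            ]

            if rng.random() < cfg.p_sent(phase):
                entry = entries[int(rng.integers(len(entries)))]
                delta = None
                block = [cfg.filler]
                if rng.random() < cfg.p_negation:
                    block.append(negators[int(rng.integers(len(negators)))])
                    negated = True
                else:
                    negated = False
                if rng.random() < cfg.p_booster:
                    booster = boosters[int(rng.integers(len(boosters)))]
                    delta = booster.delta
                    block.append(booster.term)
                block.append(entry.term)
                value = _construction_value(entry.valence, delta, negated)
                score = SentimentScore(max(value, 0), min(value, 0))
                at = int(rng.integers(len(body) + 1))
                body = body[:at] + block + body[at:]
            else:
                score = SentimentScore(0, 0)

            if rng.random() < cfg.nonascii_rate:
                _inject_nonascii(body, rng)
            text_parts = []
            if user_idx < n_repetitive:
                text_parts.append(cfg.repetitive_prefix)
            text_parts.append(" ".join(body))
            tweets.append(
                Tweet(
                    id=tid,
                    user=user,
                    timestamp=_random_timestamp(cfg, phase, rng),
                    text=" ".join(text_parts),
                    language=cfg.language,
                    country=cfg.country,
                    is_retweet=bool(rng.random() < cfg.p_retweet),
                    phase=NO_PHASE,
                )
            )
            true_scores[tid] = score
            topic_of[tid] = topic_idx

    corpus = assign_phases(Corpus(tweets), cfg.calendar)
    return corpus, GroundTruth(
        true_scores=true_scores, topic_of=topic_of, expected=expected
    )


# ---------------------------------------------------------------------------
# annotation generation


@dataclass(frozen=True)
class AnnotationSet:
    """Annotated tweets plus the exact expected category fractions."""

    tweets: list[AnnotatedTweet]
    #: exact expected {correct, partial, incorrect} fractions under the
    #: noise spec, accounting for clipping and presence flips
    expected_fractions: dict[str, float]


def _perturb(score: SentimentScore, key) -> SentimentScore:
    """Deterministically apply one noise outcome to a true score.

    Integer deviations d perturb a single component by exactly d while
    keeping tweet-level sentiment presence unchanged whenever the true
    score is non-neutral; ``"flip"`` toggles presence.
    """
    pos, neg = score.pos, score.neg
    if key == "flip":
        return SentimentScore(1, 0) if score.is_neutral else SentimentScore(0, 0)
    d = int(key)
    if d == 0:
        return score
    if score.is_neutral:  # unavoidable presence flip
        return SentimentScore(min(d, 4), 0)
    # exact +-d move on one component, primary (nonzero pos, else neg) first
    components = ("pos", "neg") if pos > 0 else ("neg", "pos")
    for comp in components:
        magnitude = pos if comp == "pos" else -neg
        for cand in (magnitude + d, magnitude - d):
            if not 0 <= cand <= 4:
                continue
            new = (cand, neg) if comp == "pos" else (pos, -cand)
            if new != (0, 0):
                return SentimentScore(*new)
    # no exact move stays on scale: clip the primary component upward
    if pos > 0:
        return SentimentScore(min(4, pos + d), neg)
    return SentimentScore(pos, -min(4, -neg + d))


def generate_annotations(
    corpus: Corpus,
    truth: GroundTruth,
    noise_spec: dict,
    seed: int = 0,
) -> AnnotationSet:
    """Simulate human annotations as true scores plus discrete noise.

    ``noise_spec`` maps noise outcomes to probabilities summing to 1;
    keys are integer deviations (0–3) or ``"flip"`` for a presence
    flip.  The returned expected fractions are computed by exact
    enumeration of the noise law over this corpus's true scores, so they
    are the oracle the empirical classification fractions converge to.
    """
    if not math.isclose(sum(noise_spec.values()), 1.0):
        raise ConfigurationError("noise_spec probabilities must sum to 1")
    for key in noise_spec:
        if key != "flip" and int(key) not in (0, 1, 2, 3):
            raise ConfigurationError(f"unsupported noise key {key!r}")
    rng = np.random.default_rng(seed)
    keys = sorted(noise_spec, key=str)
    probs = np.array([noise_spec[k] for k in keys])

    annotated: list[AnnotatedTweet] = []
    totals = {"correct": 0.0, "partial": 0.0, "incorrect": 0.0}
    for tweet in corpus:
        true = truth.true_scores[tweet.id]
        key = keys[int(rng.choice(len(keys), p=probs))]
        human = _perturb(true, key)
        annotated.append(AnnotatedTweet(text=tweet.text, human=human))
        for k, p in noise_spec.items():
            totals[classify_prediction(_perturb(true, k), true)] += p
    n = len(corpus)
    fractions = {cat: total / n for cat, total in totals.items()}
    return AnnotationSet(tweets=annotated, expected_fractions=fractions)
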