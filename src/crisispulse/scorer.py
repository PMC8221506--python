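"""Dual-polarity lexicon scoring of tweets.

Each tweet receives a pair of integer scores: a positive component on
0..4 and a negative component on 0..−4, where (0, 0) means the tweet
carries no sentiment at all.  Scoring walks the token stream once:

* a token in the sentiment table contributes its valence;
* a **booster** within the preceding look-back window (default 3
  tokens) adds its delta to the magnitude of the next sentiment word,
  sign preserved; the nearest unconsumed booster applies, once;
* a **negator** within the window reverses the sign of the (boosted)
  valence, applied at most once per sentiment word;
* magnitudes clip to 4 and floor at 1 (a diminisher weakens a word, it
  never erases it);
* the tweet's positive component is the maximum over positive applied
  valences, the negative component the minimum over negative ones.

Modifiers are consumed when applied, so one negator cannot flip two
sentiment words; a second negator in the same window is ignored for that
word but remains available for a later one.
"""

from __future__ import annotations

import string
from dataclasses import dataclass

import pandas as pd

from .corpus import Corpus
from .errors import ConfigurationError
from .lexicon import SentimentLexicon

#: how far back (in tokens) a booster or negator can reach; the worked
#: example "not a competent" requires at least 2.
DEFAULT_WINDOW = 3

_STRIP_CHARS = string.punctuation + "«»„“”‘’…–—"


@dataclass(frozen=True)
class SentimentScore:
    """Per-tweet (positive, negative) score pair; (0, 0) = no sentiment."""

    pos: int
    neg: int

    def __post_init__(self) -> None:
        if not 0 <= self.pos <= 4:
            raise ValueError(f"pos component out of range: {self.pos}")
        if not -4 <= self.neg <= 0:
            raise ValueError(f"neg component out of range: {self.neg}")

    @property
    def is_neutral(self) -> bool:
        return self.pos == 0 and self.neg == 0

    def as_tuple(self) -> tuple[int, int]:
        return (self.pos, self.neg)


@dataclass(frozen=True)
class TokenAnnotation:
    """Role and applied valence of one token, for audit output.

    ``applied_valence`` is nonzero only for sentiment tokens and records
    the value after boosting/negation, i.e. what entered the tweet score.
    """

    token: str
    role: str  # sentiment | booster | negator | plain
    applied_valence: int = 0


def tokenize(text: str) -> list[str]:
    """Lowercase, split on whitespace, strip edge punctuation.

    Leading ``#`` and ``@`` prefixes are kept attached (hashtags and
    mentions are meaningful units); tokens that reduce to nothing are
    dropped.  Text is expected to be transliterated already.
    """
    tokens: list[str] = []
    for raw in text.lower().split():
        prefix = raw[0] if raw[:1] in ("#", "@") else ""
        core = raw[len(prefix):].strip(_STRIP_CHARS)
        if core:
            tokens.append(prefix + core)
    return tokens


def _clip_magnitude(m: int) -> int:
    return max(1, min(4, m))


def score_tweet(
    tokens: list[str],
    lex: SentimentLexicon,
    window: int = DEFAULT_WINDOW,
) -> tuple[SentimentScore, list[TokenAnnotation]]:
    """Score one tokenized tweet; see module docstring for the rules."""
    annotations: list[TokenAnnotation] = []
    applied: list[int] = []
    consumed: set[int] = set()

    for i, token in enumerate(tokens):
        valence = lex.lookup(token)
        if valence != 0:
            lo = max(0, i - window)
            booster_at = negator_at = None
            for j in range(i - 1, lo - 1, -1):  # nearest first
                if j in consumed:
                    continue
                if booster_at is None and lex.booster_delta(tokens[j]) is not None:
                    booster_at = j
                elif negator_at is None and lex.is_negator(tokens[j]):
                    negator_at = j
            sign = 1 if valence > 0 else -1
            magnitude = abs(valence)
            if booster_at is not None:
                magnitude = _clip_magnitude(
                    magnitude + lex.booster_delta(tokens[booster_at])
                )
                consumed.add(booster_at)
            value = sign * magnitude
            if negator_at is not None:
                value = -value
                consumed.add(negator_at)
            applied.append(value)
            annotations.append(TokenAnnotation(token, "sentiment", value))
        elif lex.booster_delta(token) is not None:
            annotations.append(TokenAnnotation(token, "booster"))
        elif lex.is_negator(token):
            annotations.append(TokenAnnotation(token, "negator"))
        else:
            annotations.append(TokenAnnotation(token, "plain"))

    pos = max((v for v in applied if v > 0), default=0)
    neg = min((v for v in applied if v < 0), default=0)
    return SentimentScore(pos, neg), annotations


def score_text(
    text: str, lex: SentimentLexicon, window: int = DEFAULT_WINDOW
) -> SentimentScore:
    """Convenience wrapper: tokenize then score."""
    return score_tweet(tokenize(text), lex, window)[0]


def score_corpus(
    corpus: Corpus,
    lex: SentimentLexicon,
    window: int = DEFAULT_WINDOW,
) -> pd.DataFrame:
    """Score every tweet; returns columns id, country, phase, pos, neg.

    No tweet is excluded for scoring (0, 0) — neutral tweets are a
    category of their own downstream.  Tweets whose language field is
    set and differs from the lexicon's language raise a configuration
    error.
    """
    rows = []
    for t in corpus:
        if t.language and lex.language and t.language != lex.language:
            raise ConfigurationError(
                f"tweet {t.id!r} has language {t.language!r} but lexicon "
                f"is {lex.language!r}"
            )
        score, _ = score_tweet(tokenize(t.text), lex, window)
        rows.append(
            {
                "id": t.id,
                "country": t.country,
                "phase": t.phase,
                "pos": score.pos,
                "neg": score.neg,
            }
        )
    return pd.DataFrame(rows, columns=["id", "country", "phase", "pos", "neg"])
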