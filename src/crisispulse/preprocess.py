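"""Corpus cleaning and phase assignment.

Three operations prepare a raw corpus for analysis:

* :func:`transliterate` maps the Danish/German/Dutch/Swedish letters
  æ ø å ä ö ü ï ë (and uppercase forms) to ASCII digraphs so downstream
  tooling that only handles English letters can process the text;
* :func:`remove_repetitive_patterns` strips boilerplate leading
  hashtag/phrase runs that single users prepend to most of their tweets,
  which would otherwise dominate topic models — retweets are left
  untouched;
* :func:`assign_phase` labels each tweet with the collection period it
  falls in: a ``base`` calendar year before the crisis, or one of three
  two-to-six-week phases of the first pandemic wave.
"""

from __future__ import annotations

import logging
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from datetime import date, datetime

from .corpus import Corpus, Tweet
from .errors import ConfigurationError

log = logging.getLogger(__name__)

# Letter conversion table; ß is deliberately absent (no standard single
# mapping is defined here) and is only flagged by clean_corpus.
_LETTER_MAP = {
    "æ": "ae", "ø": "oe", "å": "aa", "ä": "ae",
    "ö": "oe", "ü": "ue", "ï": "i", "ë": "e",
}
_LETTER_MAP.update({k.upper(): v.upper() for k, v in _LETTER_MAP.items()})
_TRANSLATE = str.maketrans(_LETTER_MAP)


def transliterate(text: str) -> str:
    """Replace mapped non-English letters with ASCII digraphs.

    Total and idempotent: no output character is itself a mapped letter.
    """
    return text.translate(_TRANSLATE)


#: default first-phase start dates; the outbreak reached Germany a month
#: before sustained transmission began in the other three countries.
DEFAULT_PHASE1_START = {
    "DE": date(2020, 1, 27),
    "DK": date(2020, 2, 27),
    "NL": date(2020, 2, 27),
    "SE": date(2020, 2, 27),
}


@dataclass(frozen=True)
class PhaseCalendar:
    """Per-country phase windows; all interval endpoints inclusive.

    Phase 1 runs from a country-specific start (first sustained local
    case) to the eve of the pandemic declaration; phase 2 covers the two
    weeks from the declaration; phase 3 a two-week window one month
    later.  The base period is the full calendar year before the crisis.
    """

    phase1_start: dict[str, date] = field(
        default_factory=lambda: dict(DEFAULT_PHASE1_START)
    )
    phase1_end: date = date(2020, 3, 10)
    phase2: tuple[date, date] = (date(2020, 3, 11), date(2020, 3, 25))
    phase3: tuple[date, date] = (date(2020, 4, 11), date(2020, 4, 25))
    base_year: int = 2019

    def phase_of(self, when: datetime | date, country: str) -> str:
        d = when.date() if isinstance(when, datetime) else when
        if d.year == self.base_year:
            return "base"
        start = self.phase1_start.get(country)
        if start is None:
            raise ConfigurationError(
                f"no phase calendar entry for country {country!r}"
            )
        if start <= d <= self.phase1_end:
            return "1"
        if self.phase2[0] <= d <= self.phase2[1]:
            return "2"
        if self.phase3[0] <= d <= self.phase3[1]:
            return "3"
        return "none"


def assign_phase(tweet: Tweet, cal: PhaseCalendar) -> Tweet:
    """Return a copy of ``tweet`` with its phase label set."""
    return tweet.with_(phase=cal.phase_of(tweet.timestamp, tweet.country))


def assign_phases(corpus: Corpus, cal: PhaseCalendar) -> Corpus:
    return Corpus([assign_phase(t, cal) for t in corpus])


def remove_repetitive_patterns(
    corpus: Corpus,
    min_user_tweets: int = 5,
    share_threshold: float = 0.8,
) -> tuple[Corpus, list[dict]]:
    """Strip per-user boilerplate tweet openings.

    For each author with at least ``min_user_tweets`` non-retweet tweets,
    the longest leading token sequence (two or more tokens — hashtag runs
    or repeated phrasing) shared by at least ``share_threshold`` of that
    author's non-retweet tweets is removed from those tweets.  Retweets
    are never modified.  Tweets emptied by stripping are dropped.

    Returns the cleaned corpus and a removal log, one record per
    (user, pattern) with the number of tweets stripped and dropped.
    """
    if not 0 < share_threshold <= 1:
        raise ConfigurationError("share_threshold must be in (0, 1]")
    if min_user_tweets < 1:
        raise ConfigurationError("min_user_tweets must be >= 1")

    by_user: dict[str, list[int]] = defaultdict(list)
    for idx, t in enumerate(corpus):
        if not t.is_retweet:
            by_user[t.user].append(idx)

    strip_len: dict[int, int] = {}  # corpus index -> number of leading tokens
    removal_log: list[dict] = []
    for user, indices in by_user.items():
        if len(indices) < min_user_tweets:
            continue
        token_lists = [corpus[i].text.split() for i in indices]
        needed = share_threshold * len(indices)
        counts: Counter = Counter()
        for tokens in token_lists:
            for length in range(2, len(tokens) + 1):
                counts[tuple(tokens[:length])] += 1
        qualifying = [p for p, c in counts.items() if c >= needed]
        if not qualifying:
            continue
        pattern = max(qualifying, key=lambda p: (len(p), counts[p]))
        n_stripped = n_dropped = 0
        for i, tokens in zip(indices, token_lists):
            if tuple(tokens[: len(pattern)]) == pattern:
                strip_len[i] = len(pattern)
                n_stripped += 1
                if len(tokens) == len(pattern):
                    n_dropped += 1
        removal_log.append(
            {
                "user": user,
                "pattern": " ".join(pattern),
                "n_stripped": n_stripped,
                "n_dropped": n_dropped,
            }
        )
        log.info(
            "user %s: stripped leading pattern %r from %d tweets",
            user, " ".join(pattern), n_stripped,
        )

    cleaned: list[Tweet] = []
    for idx, t in enumerate(corpus):
        k = strip_len.get(idx)
        if k is None:
            cleaned.append(t)
            continue
        rest = t.text.split()[k:]
        if rest:
            cleaned.append(t.with_(text=" ".join(rest)))
    return Corpus(cleaned), removal_log


def clean_corpus(
    corpus: Corpus,
    min_user_tweets: int = 5,
    share_threshold: float = 0.8,
) -> tuple[Corpus, dict]:
    """Full cleaning pass: transliterate, then strip repetitive openings.

    The log flags tweets containing ß, which the letter table does not
    cover and which is left unchanged.
    """
    n_eszett = sum(1 for t in corpus if "ß" in t.text)
    if n_eszett:
        log.warning("%d tweets contain 'ß', left unchanged", n_eszett)
    translit = Corpus([t.with_(text=transliterate(t.text)) for t in corpus])
    cleaned, removal_log = remove_repetitive_patterns(
        translit, min_user_tweets, share_threshold
    )
    report = {
        "n_in": len(corpus),
        "n_out": len(cleaned),
        "n_eszett_flagged": n_eszett,
        "removals": removal_log,
    }
    return cleaned, report
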