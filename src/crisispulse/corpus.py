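"""Tweet records and corpus I/O.

A corpus is an ordered collection of :class:`Tweet` records.  On disk it
is a UTF-8 comma-delimited table with header
``id,user,timestamp,text,language,country,is_retweet,phase``.  Records
that cannot be parsed (bad timestamp, empty text) are dropped on load and
counted, mirroring the occasional unprocessable rows real collection
pipelines produce.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from datetime import datetime
from pathlib import Path
from typing import Iterable, Iterator

import pandas as pd

from .errors import InputError

log = logging.getLogger(__name__)

PHASES = ("base", "1", "2", "3")
NO_PHASE = "none"

_COLUMNS = [
    "id", "user", "timestamp", "text", "language", "country",
    "is_retweet", "phase",
]


@dataclass(frozen=True)
class Tweet:
    """One social-media post.

    ``phase`` is ``"none"`` until set by phase assignment; valid values
    are ``base``, ``1``, ``2``, ``3`` and ``none``.
    """

    id: str
    user: str
    timestamp: datetime
    text: str
    language: str = ""
    country: str = ""
    is_retweet: bool = False
    phase: str = NO_PHASE

    def with_(self, **changes) -> "Tweet":
        return replace(self, **changes)


class Corpus:
    """An ordered, immutable-by-convention collection of tweets."""

    def __init__(self, tweets: Iterable[Tweet], n_dropped: int = 0):
        self.tweets: list[Tweet] = list(tweets)
        #: records dropped as unparseable when this corpus was loaded
        self.n_dropped = n_dropped

    def __len__(self) -> int:
        return len(self.tweets)

    def __iter__(self) -> Iterator[Tweet]:
        return iter(self.tweets)

    def __getitem__(self, i):
        return self.tweets[i]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Corpus):
            return NotImplemented
        return self.tweets == other.tweets

    def filter(self, predicate) -> "Corpus":
        return Corpus(t for t in self.tweets if predicate(t))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "id": t.id,
                    "user": t.user,
                    "timestamp": t.timestamp.isoformat(),
                    "text": t.text,
                    "language": t.language,
                    "country": t.country,
                    "is_retweet": t.is_retweet,
                    "phase": t.phase,
                }
                for t in self.tweets
            ],
            columns=_COLUMNS,
        )


def read_corpus(path: str | Path) -> Corpus:
    """Read a corpus table, dropping and counting unparseable records."""
    path = Path(path)
    if not path.exists():
        raise InputError(f"corpus file not found: {path}")
    frame = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in _COLUMNS if c not in frame.columns]
    if missing:
        raise InputError(f"{path}: missing corpus columns {missing}")

    tweets: list[Tweet] = []
    n_dropped = 0
    for row in frame.itertuples(index=False):
        try:
            ts = datetime.fromisoformat(row.timestamp)
            text = row.text
            if not text.strip():
                raise ValueError("empty text")
            tweets.append(
                Tweet(
                    id=row.id,
                    user=row.user,
                    timestamp=ts,
                    text=text,
                    language=row.language,
                    country=row.country,
                    is_retweet=str(row.is_retweet).strip().lower()
                    in ("true", "1", "yes"),
                    phase=row.phase or NO_PHASE,
                )
            )
        except (ValueError, TypeError) as exc:
            n_dropped += 1
            log.warning("dropping unparseable record %r: %s", row.id, exc)
    if n_dropped:
        log.info("dropped %d unparseable records from %s", n_dropped, path)
    return Corpus(tweets, n_dropped=n_dropped)


def write_corpus(corpus: Corpus, path: str | Path) -> Path:
    """Write a corpus as a UTF-8 delimited table; deterministic."""
    path = Path(path)
    try:
        corpus.to_frame().to_csv(path, index=False)
    except OSError as exc:
        raise InputError(f"cannot write corpus to {path}: {exc}") from exc
    return path
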