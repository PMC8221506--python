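"""Dictionary validation against human-annotated test sets.

A machine score is compared with a human assessment of the same tweet
and classified as:

* **correct** — at most 1 point deviation on either component,
* **partially correct** — exactly 2 points deviation,
* **incorrect** — 3 or more points deviation, *or* a presence mismatch:
  one assessment says the tweet carries no sentiment at all (0, 0) while
  the other finds some.

Deviation is the maximum absolute difference over the two score
components.  The presence-mismatch rule takes precedence over the
deviation bands (so human (0,0) vs machine (1,0) is incorrect, not
correct); it can be disabled via ``presence_rule=False``, in which case
only the deviation bands apply.

The *identification rate* of a dictionary on a test set is the
percentage of tweets classified correct; rates from several test sets
(e.g. one per language) are combined by a plain mean.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .errors import ConfigurationError, InputError
from .lexicon import SentimentLexicon
from .preprocess import transliterate
from .scorer import DEFAULT_WINDOW, SentimentScore, score_tweet, tokenize

CORRECT = "correct"
PARTIAL = "partial"
INCORRECT = "incorrect"


@dataclass(frozen=True)
class AnnotatedTweet:
    """A tweet text with a human score and (optionally) a machine score."""

    text: str
    human: SentimentScore
    machine: SentimentScore | None = None


@dataclass(frozen=True)
class EvalSummary:
    """Classification counts for one test set."""

    n: int
    correct: int
    partial: int
    incorrect: int

    def __post_init__(self) -> None:
        if self.correct + self.partial + self.incorrect != self.n:
            raise ConfigurationError("category counts must sum to n")

    @property
    def identification_rate(self) -> float:
        """Percentage of the test set classified correct."""
        return 100.0 * self.correct / self.n


def classify_prediction(
    human: SentimentScore,
    machine: SentimentScore,
    presence_rule: bool = True,
) -> str:
    """Classify one machine score against the human assessment."""
    if presence_rule and (human.is_neutral != machine.is_neutral):
        return INCORRECT
    deviation = max(
        abs(human.pos - machine.pos), abs(human.neg - machine.neg)
    )
    if deviation <= 1:
        return CORRECT
    if deviation == 2:
        return PARTIAL
    return INCORRECT


def evaluate_dictionary(
    annotated: list[AnnotatedTweet],
    lex: SentimentLexicon,
    window: int = DEFAULT_WINDOW,
    presence_rule: bool = True,
) -> EvalSummary:
    """Score each annotated tweet with ``lex`` and tally classifications.

    Machine scores are computed with the same transliterate → tokenize →
    score path the corpus pipeline uses; a pre-filled ``machine`` score
    on an annotated tweet is respected.
    """
    if not annotated:
        raise InputError("annotated test set is empty")
    counts = {CORRECT: 0, PARTIAL: 0, INCORRECT: 0}
    for item in annotated:
        machine = item.machine
        if machine is None:
            machine, _ = score_tweet(
                tokenize(transliterate(item.text)), lex, window
            )
        counts[classify_prediction(item.human, machine, presence_rule)] += 1
    return EvalSummary(
        n=len(annotated),
        correct=counts[CORRECT],
        partial=counts[PARTIAL],
        incorrect=counts[INCORRECT],
    )


def mean_identification_rate(summaries: list[EvalSummary]) -> float:
    """Mean identification rate across test sets (one per dictionary)."""
    if not summaries:
        raise InputError("no summaries to average")
    return sum(s.identification_rate for s in summaries) / len(summaries)


def summaries_to_frame(
    summaries: dict[str, EvalSummary]
) -> pd.DataFrame:
    """Tabulate evaluation summaries keyed by label (e.g. language)."""
    rows = [
        {
            "set": label,
            "n": s.n,
            "correct": s.correct,
            "partial": s.partial,
            "incorrect": s.incorrect,
            "identification_rate": round(s.identification_rate, 1),
        }
        for label, s in summaries.items()
    ]
    return pd.DataFrame(rows)


def read_annotations(path) -> list[AnnotatedTweet]:
    """Read a delimited annotation file (text, human_pos, human_neg)."""
    frame = pd.read_csv(path)
    required = {"text", "human_pos", "human_neg"}
    if not required.issubset(frame.columns):
        raise InputError(f"{path}: annotation file needs columns {sorted(required)}")
    return [
        AnnotatedTweet(
            text=str(row.text),
            human=SentimentScore(int(row.human_pos), int(row.human_neg)),
        )
        for row in frame.itertuples(index=False)
    ]


def write_annotations(annotated: list[AnnotatedTweet], path) -> None:
    pd.DataFrame(
        [
            {"text": a.text, "human_pos": a.human.pos, "human_neg": a.human.neg}
            for a in annotated
        ]
    ).to_csv(path, index=False)
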