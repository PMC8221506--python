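"""Topic models, bigrams, and corpus term statistics.

The topic model is latent Dirichlet allocation with symmetric priors
(document–topic prior α = 50/K, topic–word prior β = 0.01 by default),
fit with batch variational inference.  The analyst chooses the number of
topics K and the number of words per topic *a* and receives K ranked
word lists.  Each topic carries a *weight* — its average fit to the
corpus, implemented as the topic's expected share of corpus tokens — and
topics are returned best-fitting first.

Because short noisy texts produce noise topics, topics whose top words
are dominated by corpus-wide high-frequency terms are flagged (not
removed); inspection stays with the analyst.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.decomposition import LatentDirichletAllocation
from sklearn.feature_extraction.text import CountVectorizer

from .corpus import Corpus
from .errors import ConfigurationError
from .scorer import tokenize

_STOPWORD_LANGS = ("da", "de", "en", "nl", "sv")


def load_stopwords(language: str) -> frozenset[str]:
    """Load the bundled stopword list for an ISO language code.

    Lists are stored transliterated (ASCII digraphs), matching cleaned
    corpora.  Unknown codes raise a configuration error.
    """
    if language not in _STOPWORD_LANGS:
        raise ConfigurationError(
            f"no bundled stopword list for {language!r}; "
            f"available: {_STOPWORD_LANGS}"
        )
    text = (
        resources.files("crisispulse.data.stopwords")
        .joinpath(f"{language}.txt")
        .read_text(encoding="utf-8")
    )
    return frozenset(
        w.strip().lower()
        for w in text.splitlines()
        if w.strip() and not w.startswith("#")
    )


@dataclass(frozen=True)
class TopicModelConfig:
    """Settings for one topic-model fit.

    ``k`` topics × ``words_per_topic`` ranked words; ``iterations`` is
    the number of variational passes; ``alpha``/``beta`` default to the
    conventional symmetric priors 50/K and 0.01.
    """

    k: int
    words_per_topic: int
    seed: int = 0
    iterations: int = 50
    stopwords: frozenset[str] = frozenset()
    alpha: float | None = None
    beta: float = 0.01
    min_token_len: int = 2

    def __post_init__(self) -> None:
        if self.k < 1 or self.words_per_topic < 1:
            raise ConfigurationError("k and words_per_topic must be >= 1")


@dataclass(frozen=True)
class Topic:
    """One ranked topic: word list (best fit first) and corpus weight."""

    rank: int
    words: tuple[str, ...]
    weight: float
    noise_flagged: bool = False


def _filtered_docs(corpus: Corpus, stopwords, min_token_len: int):
    docs = []
    for t in corpus:
        toks = [
            tok
            for tok in tokenize(t.text)
            if tok not in stopwords and len(tok) >= min_token_len
        ]
        docs.append(toks)
    return docs


def fit_topics(corpus: Corpus, cfg: TopicModelConfig) -> list[Topic]:
    """Fit a K-topic LDA model; deterministic under ``cfg.seed``."""
    docs = [d for d in _filtered_docs(corpus, cfg.stopwords, cfg.min_token_len) if d]
    if not docs:
        raise ConfigurationError("corpus empty after stopword filtering")
    vocab = sorted(set(tok for d in docs for tok in d))
    if len(vocab) < cfg.words_per_topic:
        raise ConfigurationError(
            f"vocabulary ({len(vocab)} terms) smaller than words_per_topic "
            f"({cfg.words_per_topic})"
        )
    vectorizer = CountVectorizer(analyzer=lambda d: d, vocabulary=vocab)
    X = vectorizer.fit_transform(docs)

    # the classic symmetric prior 50/K, capped at 1.0 (the variational
    # implementation requires doc_topic_prior <= 1); for K >= 50 the two
    # coincide
    alpha = cfg.alpha if cfg.alpha is not None else min(1.0, 50.0 / cfg.k)
    lda = LatentDirichletAllocation(
        n_components=cfg.k,
        doc_topic_prior=alpha,
        topic_word_prior=cfg.beta,
        max_iter=cfg.iterations,
        learning_method="batch",
        random_state=cfg.seed,
    )
    theta = lda.fit_transform(X)  # rows sum to 1
    phi = lda.components_ / lda.components_.sum(axis=1, keepdims=True)

    # weight = expected share of corpus tokens explained by the topic
    doc_len = np.asarray(X.sum(axis=1)).ravel()
    weights = (theta * doc_len[:, None]).sum(axis=0) / doc_len.sum()

    # flag topics whose top words are mostly corpus-wide high-frequency terms
    term_freq = np.asarray(X.sum(axis=0)).ravel()
    common = {vocab[i] for i in np.argsort(-term_freq)[: max(10, len(vocab) // 20)]}

    order = np.argsort(-weights, kind="stable")
    topics: list[Topic] = []
    for rank, k in enumerate(order, start=1):
        word_order = sorted(
            range(len(vocab)), key=lambda i: (-phi[k, i], vocab[i])
        )[: cfg.words_per_topic]
        words = tuple(vocab[i] for i in word_order)
        n_common = sum(1 for w in words[:5] if w in common)
        topics.append(
            Topic(
                rank=rank,
                words=words,
                weight=float(weights[k]),
                noise_flagged=n_common >= 4,
            )
        )
    return topics


def topics_to_frame(topics: list[Topic]) -> pd.DataFrame:
    """Tabular topic output: rank, weight, word_1..word_a, noise flag."""
    a = len(topics[0].words) if topics else 0
    rows = []
    for t in topics:
        row = {"rank": t.rank, "weight": round(t.weight, 6),
               "noise_flagged": t.noise_flagged}
        row.update({f"word_{i + 1}": w for i, w in enumerate(t.words)})
        rows.append(row)
    cols = ["rank", "weight"] + [f"word_{i + 1}" for i in range(a)] + ["noise_flagged"]
    return pd.DataFrame(rows, columns=cols)


def extract_bigrams(
    corpus: Corpus,
    top_n: int = 50,
    stopwords: frozenset[str] = frozenset(),
    min_token_len: int = 1,
) -> pd.DataFrame:
    """Count adjacent token pairs within tweets (after stopword removal).

    Returns columns ``bigram`` and ``count``, sorted by descending count
    with lexicographic tie-break, limited to ``top_n`` rows.
    """
    counts: Counter = Counter()
    for toks in _filtered_docs(corpus, stopwords, min_token_len):
        for first, second in zip(toks, toks[1:]):
            counts[f"{first} {second}"] += 1
    items = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))[:top_n]
    return pd.DataFrame(items, columns=["bigram", "count"])


def corpus_statistics(
    corpus: Corpus,
    top_n: int = 50,
    stopwords: frozenset[str] = frozenset(),
    min_token_len: int = 1,
) -> pd.DataFrame:
    """Prominent-term table: total occurrences and tweets containing.

    Columns ``term``, ``occurrences``, ``tweets``; sorted by descending
    occurrences, ties lexicographic; at most ``top_n`` rows.
    """
    occurrences: Counter = Counter()
    tweet_counts: Counter = Counter()
    for toks in _filtered_docs(corpus, stopwords, min_token_len):
        occurrences.update(toks)
        tweet_counts.update(set(toks))
    items = sorted(
        occurrences.items(), key=lambda kv: (-kv[1], kv[0])
    )[:top_n]
    return pd.DataFrame(
        [(term, count, tweet_counts[term]) for term, count in items],
        columns=["term", "occurrences", "tweets"],
    )


def occurrence_rate(count: int, n_tweets: int) -> float:
    """Occurrences as a percentage of tweets, half-up to one decimal.

    ``occurrence_rate(346, 26107)`` → 1.3 (assuming one mention per
    tweet).  Exact rational arithmetic, so ties round away from zero
    deterministically.
    """
    if n_tweets < 1:
        raise ConfigurationError("n_tweets must be >= 1")
    if count < 0:
        raise ConfigurationError("count must be >= 0")
    # half-up on the exact rational 1000*count/n_tweets
    scaled, rem = divmod(1000 * count, n_tweets)
    if 2 * rem >= n_tweets:
        scaled += 1
    return scaled / 10.0
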