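"""End-to-end pipeline: clean → phase → score → stats → topics (→ eval).

A single declarative configuration drives every stage; all outputs are
UTF-8 delimited files plus a JSON manifest recording files written, row
counts, seeds, and the package version, sufficient to rerun the
deterministic stages bit-identically.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from datetime import date
from pathlib import Path

import yaml

from . import __version__
from .corpus import Corpus, read_corpus, write_corpus
from .errors import ConfigurationError, InputError
from .lexicon import load_lexicon
from .phase_stats import build_sentiment_table, table_to_markdown
from .preprocess import PhaseCalendar, assign_phases, clean_corpus
from .scorer import DEFAULT_WINDOW, score_corpus
from .topics import (
    TopicModelConfig,
    corpus_statistics,
    extract_bigrams,
    fit_topics,
    load_stopwords,
    topics_to_frame,
)

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Everything needed for one full run.

    Every choice the method leaves open (modifier window, t-test
    variant, cleaning thresholds, topic-model priors) is surfaced here
    with the package defaults.
    """

    corpus_path: str
    lexicon_dir: str
    out_dir: str
    country: str = "DK"
    language: str = "da"
    # cleaning
    min_user_tweets: int = 5
    share_threshold: float = 0.8
    # scoring
    window: int = DEFAULT_WINDOW
    use_wildcards: bool = True
    # stats
    equal_var: bool = False
    # topics
    k: int = 10
    words_per_topic: int = 10
    topic_seed: int = 0
    topic_iterations: int = 50
    top_n_terms: int = 50
    # phase calendar overrides: country -> ISO date of phase-1 start
    phase1_start: dict[str, str] = field(default_factory=dict)
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text(encoding="utf-8"))
        if not isinstance(raw, dict):
            raise ConfigurationError(f"{path}: config must be a mapping")
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ConfigurationError(f"{path}: unknown keys {sorted(unknown)}")
        return cls(**raw)

    def calendar(self) -> PhaseCalendar:
        cal = PhaseCalendar()
        if self.phase1_start:
            starts = dict(cal.phase1_start)
            starts.update(
                {c: date.fromisoformat(d) for c, d in self.phase1_start.items()}
            )
            cal = PhaseCalendar(phase1_start=starts)
        return cal

    def validate(self) -> None:
        if not Path(self.corpus_path).exists():
            raise ConfigurationError(f"corpus not found: {self.corpus_path}")
        if not Path(self.lexicon_dir).is_dir():
            raise ConfigurationError(
                f"lexicon directory not found: {self.lexicon_dir}"
            )


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Run every stage, write all outputs, and return the manifest."""
    cfg.validate()  # fail before any stage runs
    logging.basicConfig(level=cfg.log_level)
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "config": {k: str(v) for k, v in vars(cfg).items()},
        "seeds": {"topics": cfg.topic_seed},
        "files": {},
        "rows": {},
    }

    stage = "load"

    def _stage(name):
        nonlocal stage
        stage = name
        log.info("stage: %s", name)

    try:
        _stage("load")
        corpus = read_corpus(cfg.corpus_path)
        manifest["rows"]["input"] = len(corpus)
        manifest["rows"]["dropped_unparseable"] = corpus.n_dropped

        _stage("clean")
        cleaned, report = clean_corpus(
            corpus, cfg.min_user_tweets, cfg.share_threshold
        )
        manifest["cleaning"] = {
            k: v for k, v in report.items() if k != "removals"
        }
        manifest["cleaning"]["n_patterns_removed"] = len(report["removals"])

        _stage("phase")
        phased = assign_phases(cleaned, cfg.calendar())
        cleaned_path = out / "corpus_clean.csv"
        write_corpus(phased, cleaned_path)
        manifest["files"]["corpus_clean"] = str(cleaned_path)
        manifest["rows"]["clean"] = len(phased)

        _stage("score")
        lex = load_lexicon(cfg.lexicon_dir, cfg.language)
        lex.use_wildcards = cfg.use_wildcards
        scores = score_corpus(phased, lex, cfg.window)
        scored_path = out / "scores.csv"
        scores.to_csv(scored_path, index=False)
        manifest["files"]["scores"] = str(scored_path)
        manifest["rows"]["scores"] = len(scores)

        _stage("stats")
        table = build_sentiment_table(scores, cfg.country, cfg.equal_var)
        stats_path = out / "sentiment_table.csv"
        table.to_csv(stats_path)
        (out / "sentiment_table.md").write_text(
            table_to_markdown(table) + "\n", encoding="utf-8"
        )
        manifest["files"]["sentiment_table"] = str(stats_path)
        manifest["files"]["sentiment_table_md"] = str(out / "sentiment_table.md")

        _stage("topics")
        try:
            stopwords = load_stopwords(cfg.language)
        except ConfigurationError:
            stopwords = frozenset()
        analysed = phased.filter(lambda t: t.phase != "none")
        topic_cfg = TopicModelConfig(
            k=cfg.k,
            words_per_topic=cfg.words_per_topic,
            seed=cfg.topic_seed,
            iterations=cfg.topic_iterations,
            stopwords=stopwords,
        )
        topics = fit_topics(analysed, topic_cfg)
        topics_path = out / "topics.csv"
        topics_to_frame(topics).to_csv(topics_path, index=False)
        manifest["files"]["topics"] = str(topics_path)

        bigrams = extract_bigrams(analysed, cfg.top_n_terms, stopwords)
        bigrams_path = out / "bigrams.csv"
        bigrams.to_csv(bigrams_path, index=False)
        manifest["files"]["bigrams"] = str(bigrams_path)

        stats = corpus_statistics(analysed, cfg.top_n_terms, stopwords)
        terms_path = out / "corpus_stats.csv"
        stats.to_csv(terms_path, index=False)
        manifest["files"]["corpus_stats"] = str(terms_path)
    except Exception as exc:
        from .errors import CrisisPulseError

        raise CrisisPulseError(f"stage {stage!r} failed: {exc}") from exc

    manifest_path = out / "manifest.json"
    manifest_path.write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n", encoding="utf-8"
    )
    manifest["files"]["manifest"] = str(manifest_path)
    return manifest
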