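"""Topic modeling, bigrams, and term statistics on a synthetic corpus.

The generator plants three topics whose mixture drifts across the
collection phases; LDA should recover them, and the bigram/term tables
show the prominent vocabulary with per-term occurrence rates.
"""

from crisispulse import (
    SyntheticConfig,
    TopicModelConfig,
    corpus_statistics,
    extract_bigrams,
    fit_topics,
    generate_corpus,
    occurrence_rate,
)

config = SyntheticConfig(
    seed=9,
    tweets_per_phase={"base": 500, "1": 500, "2": 500, "3": 500},
    p_sentiment_word=0.0,   # isolate the topical structure
    p_repetitive_user=0.0,
    nonascii_rate=0.0,
    tweet_len=10,
)
corpus, truth = generate_corpus(config)

topics = fit_topics(corpus, TopicModelConfig(k=3, words_per_topic=5, seed=3))
print("fitted topics (rank, weight, top words):")
for topic in topics:
    print(f"  {topic.rank}  {topic.weight:.3f}  {' '.join(topic.words)}")

spec = config.resolved_topic_spec()
print("planted topics (first 5 words each):")
for i, (terms, _) in enumerate(spec.topics):
    print(f"  {i + 1}         {' '.join(terms[:5])}")

bigrams = extract_bigrams(corpus, top_n=3)
print("\ntop bigrams:")
print(bigrams.to_string(index=False))

stats = corpus_statistics(corpus, top_n=3)
term, count = stats.iloc[0]["term"], int(stats.iloc[0]["occurrences"])
rate = occurrence_rate(int(stats.iloc[0]["tweets"]), len(corpus))
print(f"\nmost prominent term: {term!r}, {count} occurrences, "
      f"in {rate}% of {len(corpus)} tweets")

# Each fitted topic's top words should come from exactly one planted
# topic; the weight is the topic's expected share of corpus tokens, and
# the occurrence rate expresses a term's reach as a percentage of
# tweets (one mention per tweet).
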