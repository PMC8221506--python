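"""Score single sentences with negation and booster rules.

Builds a minimal English lexicon and scores four sentences on the dual
0..4 / 0..-4 scale, printing each token's applied valence.
"""

from crisispulse import (
    BoosterEntry,
    LexiconEntry,
    SentimentLexicon,
    score_tweet,
    tokenize,
)

lexicon = SentimentLexicon(
    language="en",
    entries={
        "competent": LexiconEntry("competent", 1),
        "incompetent": LexiconEntry("incompetent", -1),
    },
    boosters={"extremely": BoosterEntry("extremely", 2)},
    negators={"not"},
)

sentences = [
    "Merkel is a competent leader",
    "Merkel is not a competent leader",
    "Merkel is an extremely incompetent leader",
    "Merkel is holding a speech now",
]

for sentence in sentences:
    score, annotations = score_tweet(tokenize(sentence), lexicon)
    detail = " ".join(
        f"{a.token}[{a.applied_valence}]" if a.role == "sentiment"
        else (f"{a.token}*" if a.role in ("booster", "negator") else a.token)
        for a in annotations
    )
    print(f"[{score.pos};{score.neg}]  {detail}")

# The pair [pos;neg] is the tweet's dual-polarity sentiment: a lone
# positive word gives [1;0], negating it flips the sign, a booster
# raises the magnitude before negation, and a sentence with no lexicon
# words stays [0;0] (still counted in every average downstream).
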