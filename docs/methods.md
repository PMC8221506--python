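# Methods

This note records the modelling choices behind `crisispulse`: the rules
the scorer applies, the statistics reported, what the synthetic
generator does and does not emulate, and the decisions taken where the
method leaves details open.

## Scoring semantics

Scores live on the dual scale: a positive component in 0..4 and a
negative component in 0..−4, with (0, 0) meaning "no sentiment". A
tweet is tokenized by lowercasing, whitespace splitting, and stripping
edge punctuation (keeping `#`/`@` prefixes); text is transliterated
first so lexicon terms can be stored in ASCII.

Open details of the rule set were fixed as follows:

- **Aggregation.** With several sentiment words in a tweet, the tweet's
  components are the per-polarity extremes (maximum positive, minimum
  negative applied valence), not sums. This keeps scores on the bounded
  scale and matches how dual-polarity lexicon scorers conventionally
  behave; single-word examples are unaffected.
- **Modifier window.** A booster or negator reaches the next sentiment
  word up to 3 tokens ahead. The window must exceed 1 because an
  article may sit between negator and target ("not a competent"); 3 is
  the smallest value that also tolerates a booster in between
  ("not very good"-type constructions).
- **Order of application.** Boost first, then negate: a −1 word with a
  +2 booster becomes −3, and negating it yields +3. Magnitudes clip to
  4 and floor at 1 — a diminisher weakens a word, it never erases it or
  flips its sign.
- **Consumption.** Each modifier applies to at most one sentiment word
  (nearest-first), and each sentiment word takes at most one booster
  and one negation; a second negator in the window is ignored for that
  word (no double-negation algebra) but stays available for a later
  word.
- **Boosters modify sentiment words only**, not negators; "not very
  good" negates the boosted value.

Wildcard lexicon stems (trailing `*`, longest match wins) are supported
and can be disabled per lexicon; matching is case-insensitive
throughout, since tweets are noisy.

## Cleaning and phases

Transliteration maps æ→ae, ø→oe, å→aa, ä→ae, ö→oe, ü→ue, ï→i, ë→e
(uppercase analogously) and is idempotent. `ß` has no entry in this
table; it is left unchanged and flagged in the cleaning log rather than
guessed at.

Repetitive-pattern removal is prefix-based: for each author with at
least `min_user_tweets` (default 5) non-retweet tweets, the longest
leading token run (≥ 2 tokens) shared by at least `share_threshold`
(default 0.8) of their tweets is stripped; retweets are never modified,
and tweets emptied by stripping are dropped. The thresholds are
deliberately conservative and configurable, since boilerplate detection
has no canonical setting.

The phase calendar uses inclusive interval endpoints: phase 1 from a
country-specific first-case date (2020-01-27 for DE, 2020-02-27 for DK,
NL, SE) to 2020-03-10; phase 2 2020-03-11–25; phase 3 2020-04-11–25;
the base period is calendar year 2019. Records that cannot be parsed on
load are dropped and counted, mirroring the stray unprocessable rows
real collection pipelines produce.

## Phase statistics

APS/ANS are plain means over *all* tweets of a period, neutral ones
included; ANS is reported as a negative number. The eight category
percentages follow the standard definitions (see README); in the
dominance categories, "pos > neg" compares the positive component with
the magnitude of the negative one, since the raw components live on
opposite signs. The two-sample test defaults to Welch's
unequal-variance form (a `equal_var` flag restores the pooled variant);
two samples with equal means and zero variance are defined to give
t = 0, p = 1. Printed precision: APS/ANS to 3 decimals, percentages
to 2. Marker thresholds are strict inequalities at 0.05/0.01/0.001.

## Topics, bigrams, terms

The topic model is LDA fit by batch variational inference
(scikit-learn). Priors are symmetric: topic–word β = 0.01 and
document–topic α = min(1, 50/K) — the classic 50/K heuristic, capped
because the variational implementation requires α ≤ 1; for K ≥ 50 the
two coincide. Words within a topic are ranked by per-topic word
probability (ties broken lexicographically); a topic's **weight** is
its expected share of corpus tokens, Σ_d ℓ_d θ_dk / Σ_d ℓ_d — one
concrete reading of "average fit of the topic to the corpus", stated
here rather than asserted to match any particular tool's unpublished
formula. Topics are returned best-weight first, deterministically under
the seed. Noise topics are only flagged (top words dominated by
corpus-wide high-frequency terms), never removed: short-text topic
models are noisy and inspection stays with the analyst.

Bigrams are adjacent token pairs within a tweet, counted after
stopword removal; term statistics report both total occurrences and the
number of tweets containing the term. Occurrence rates are
100·count/n_tweets rounded half-up to one decimal on the exact
rational, so e.g. 55/7270 → 0.8 (0.756 rounds up; a printed source
giving 0.7 for this quotient is an arithmetic slip, not a different
convention). Stopword lists for da/de/en/nl/sv ship as editable data
files, stored transliterated to match cleaned corpora.

## Dictionary validation

Deviation between human and machine scores is the maximum over the two
components — "one point of deviation" is read per score, not summed.
The presence-mismatch rule (one assessment (0, 0), the other not →
incorrect) takes precedence over the deviation bands because it is the
more specific rule; the corner case human (0, 0) vs machine (1, 0) is
therefore *incorrect*, not correct. This precedence is switchable
(`presence_rule=False`) for sensitivity analyses. Identification rates
from several test sets combine by a plain mean.

## The synthetic generator

The generator emulates the corpus features the pipeline must survive:
four collection periods with timestamps drawn inside the calendar
windows; a pool of users, a designated fraction of whom prepend a fixed
hashtag boilerplate to everything they post; retweets (flagged, exempt
from cleaning); tweets whose body is drawn from per-phase mixtures of K
planted topics (one topic per tweet); sentiment planted as a short
template `<filler> <negator?> <booster?> <sentiment-word>` spliced into
the body, exercising the scorer's window logic; and non-ASCII letters
injected *invertibly* (a transliteration digraph in a vocabulary word
is replaced by the corresponding letter), so cleaning restores the
canonical token exactly.

Defaults are desk-scale but shaped like real crisis collections: an
8,000-tweet base year and 3,000/5,000/2,000 tweets in phases 1–3
(collection volumes peak at lockdown onset), 50 users, 5% of them
boilerplate posters, 15% retweets, 70% of tweets carrying a sentiment
word (real no-sentiment shares run roughly 15–50%), negation and
booster probabilities of 0.15 each, 10% of tweets carrying a non-ASCII
letter, 8 body tokens per tweet. Property tests use the sample sizes
their statements call for (e.g. 10,000/phase for mean recovery; 100
seeds at 5,000/phase for the power property, run on score vectors drawn
from the generator's exact sentiment law rather than rendered text —
the distribution is identical and the full text path is exercised by
the end-to-end recovery test).

Because the construction is explicit, the per-phase score distribution
is enumerable in closed form; `GroundTruth.expected` carries exact
APS/ANS and variances, and annotation noise (`generate_annotations`)
reports exact expected correct/partial/incorrect fractions, including
the distortions from scale clipping and from neutral tweets (any
deviation applied to a true (0, 0) is necessarily a presence flip and
lands in "incorrect").

What the generator does **not** emulate: real grammar or word order,
multilingual code-switching, sarcasm and idiom, emoji, bursty user
activity, or topic drift within a phase. Passing tests therefore show
that the pipeline's mechanics are correct on corpora whose structure is
known — not that any particular lexicon captures real-world sentiment;
that remains what the human-annotation validation protocol is for.

## Degenerate inputs and numerics

Empty phase selections, missing periods, sub-2-observation samples,
empty annotation sets, vocabulary smaller than the words-per-topic
request, and corpora emptied by stopword filtering all raise typed
errors naming the problem. Ties in bigram/term counts break
lexicographically so all tabular outputs are deterministic. Topic-model
determinism holds under a fixed seed on a fixed platform (floating-point
reductions may differ across BLAS builds).

## Known limitations

- Emoticon/emoji handling, spell correction, and idiom lists are out of
  scope; the scorer is a faithful implementation of the word-level rule
  set only.
- The repetitive-pattern cleaner only strips *leading* boilerplate;
  mid-tweet templates are untouched.
- The LDA weight definition is one reasonable reading of "average
  topic fit"; alternative definitions (e.g. unweighted mean of θ·k)
  would rank near-identically but are not exposed.
- Whether boosters should also strengthen negators is unspecified in
  the rule set; here they never do.
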