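# Methods

## The surveillance procedure

`vapescope` formalizes a lexicon-based surveillance design for
location mentions in vaping-related social-media posts. The unit of
analysis is the *post*; the estimand is, for each of 11 location
categories, the proportion of analytic-sample posts containing at least
one keyword of that category. The analytic sample is the subset of the raw
stream that (a) survives a six-stage hygiene cascade and (b) contains at
least one vaping term *and* at least one location keyword after
normalization. Assignment is multi-label: a post mentioning both a school
and a workplace counts once in each category, so the percent column may
sum above 100%. A `first_match_by_table_order` mode is provided for
single-label reporting (percentages then sum to ≤ 100%); multi-label is
the default because real category tables of this kind have columns summing
above 100%.

The method has no learned parameters. All behavior comes from three
inputs: the vaping-term gate (26 surface forms of the vape / e-cigarette /
juul families; the published gates name only a few terms and defer the
rest to prior literature, so the bundled list is a reconstruction and
fully overridable), the location dictionary (11 categories; all commonly
printed illustrative keywords under their rows, plus documented expansions
such as *house*, *classroom*, *campus*, *office*, *cafe*), and the filter
thresholds below.

## Exclusion cascade

Stages run in the fixed order **retweets → language → bots →
high-frequency → duplicates → promotional**; each emits a
`StageReport` and the chain telescopes (`n_in` of the first stage equals
final `n_out` plus all removals). Each stage is a contraction and
idempotent.

- **Retweets**: `is_retweet` flag, or a leading `RT @` when streams omit
  the flag.
- **Language**: the stream's language tag against `allowed_langs`
  (default `{"en"}`); untagged posts go to a stopword-profile fallback
  identifier (en/es/fr/de/pt). Tag-first was chosen because stream
  metadata is nearly always present and far more reliable than detection
  on 140-character text.
- **Bots**: published bot classifiers for this task are proprietary, so
  the default is a transparent posting-rate rule — flag accounts at
  ≥ `bot_rate_threshold` posts/day (default 50). The scorer is pluggable
  (`scorer(AccountStats) -> bool`) so a richer classifier can be injected.
- **High-frequency**: "higher than normal frequency" is not quantified in
  the designs this mirrors; the rule used is rate ≥ mean + k·SD
  (population SD, default k = 2) over per-account daily rates computed
  *after* bot removal. An account's daily rate is posts divided by its
  active span in calendar days (inclusive; minimum 1). The comparison is
  inclusive (≥) with a zero-SD guard: when all accounts post at the same
  rate nothing is abnormal and nothing is flagged. The inclusive form is
  deliberate — for a population of equal-rate accounts plus one outlier,
  the outlier sits exactly at mean + 2·SD, and an exclusive rule would
  never flag it.
- **Duplicates**: exact text match after whitespace normalization,
  keeping the earliest copy (timestamp, then post-id, so results are
  input-order independent). Near-duplicate hashing was considered and
  rejected: "duplicate posts" without qualification reads as exact, and
  exact matching is auditable.
- **Promotional**: a configurable commerce vocabulary (sale, discount,
  coupon, promo, off, …) matched at word boundaries on the lowercased raw
  text, by default only together with a URL. Word-boundary matching keeps
  "off" from firing inside "coffee"; the URL requirement keeps ordinary
  speech ("day off") out.

## Normalization

NFKC-normalize; remove URLs (http/https, `www.`, `t.co` shortlinks);
remove hashtags wholly (marker + tag word; `keep_hashtag_words=True`
retains the word, since either reading of "hashtags were removed" is
defensible); remove @-mentions; map remaining non-alphanumerics (including
emoji) to spaces; lowercase; split; lemmatize. The lemmatizer is a
deterministic rule engine (plural `-s/-es/-ies`, gerund `-ing`, past
`-ed`, doubled-consonant undoubling) with a bundled exception TSV
(vaping→vape, drove→drive, buses→bus, …). A suffix rule's result is
accepted only if it is itself rule-stable; otherwise the token is left
unchanged. This makes every output a fixed point, so normalization is
idempotent — a property the matcher relies on, since lexicon keywords are
passed through the same pipeline. The trade-off is that a rare token whose
stripped form would expose a second spurious suffix is not reduced at all;
no dictionary keyword is affected. No stemming, stop-word removal, or
spelling correction: matching is dictionary-driven and whole-token, so
recall engineering belongs in the lexicon, not the normalizer.

## Matching

A keyword fires iff its lemmatized token sequence occurs in the post's
lemmatized tokens — exactly (single word) or contiguously (phrase).
Whole-token matching prevents "car" firing in "care"/"carpet"; it is the
reason normalization and the lexicon share one lemmatizer. The production
matcher indexes keywords by head token (O(tokens · candidates)); tests
hold it equal to an exhaustive every-keyword-every-position scan.
Ambiguity is not disambiguated by design ("court" counts as Correctional
facility regardless of sense); Miscellaneous is an ordinary category with
its own keywords, not a fallback.

## Prevalence

Percentages are per post over the analytic sample (not per user, not per
keyword firing). Wilson 95% score intervals accompany each row; published
tables of this kind print none, so rendered output marks them as an
addition. Rendered percentages round half-even to one decimal. Rows sort
by descending percent with Miscellaneous last, the usual convention.

## Synthetic corpora

The generator emulates the populations the cascade must remove, with
exact labels. Design choices that matter:

- **Exclusive contaminant kinds** (priority retweet > non-English > bot >
  high-frequency > duplicate > promotional), allocated deterministically
  as `round(frac·n)`. Real posts can be several things at once; exclusive
  kinds make per-stage recovery exact and order-invariance testable.
- **Default conditions**: 10% retweets, 10% non-English, 5% each
  bot/high-frequency/duplicate/promotional (no published contaminant
  prevalences exist for such streams, so these are illustrative and
  configurable); category mixture proportional to the published 11-category
  prevalence profile (social venues most common at 17.9/110.6, religious
  institutions rarest at 0.4/110.6); `multi_label_rate = 0.106`, the
  excess of that profile's percent column over 100. Default account sizing
  draws 1–3 posts per normal account (mean ≈ 1.4 posts/account, matching
  the ≈ 1.42 posts/user of large real analytic samples).
- **Rate structure**: normal accounts post on consecutive distinct days
  within a 10-day window (rate exactly ≤ 1/day); bot accounts burst
  ~60 posts in a single day; high-frequency accounts sustain ~12/day over
  several days. Consequently bot accounts exceed the 50/day threshold,
  high-frequency accounts exceed mean + 2·SD but not the bot threshold,
  and no normal account can be falsely flagged. Recovery degrades only
  for corpora so small that a bot account's allocation falls below the
  bot threshold (≲ 1,000 posts at the default 5% bot fraction).
- **Text structure**: clean posts are filler words plus one vaping term
  plus one keyword per planted category (a second category is planted
  with probability `multi_label_rate`). The 130-word filler vocabulary
  shares no lemma with either lexicon or the promotional terms (enforced
  by test), so matched categories equal planted categories exactly. All
  texts are globally unique except planted duplicates, which copy a clean
  source verbatim with a later timestamp. Non-English posts come from a
  small tagged phrase bank.
- **Determinism**: one `numpy` generator seeded from `spec.seed` drives
  everything; identical specs give byte-identical corpora.

What passing on synthetic corpora does **not** show: robustness to
linguistic realism (slang, misspellings, sarcasm, emoji-encoded meaning),
overlapping contaminant populations, bot behavior beyond posting rate,
near-duplicate spam, or the actual 2018 category percentages — real raw
streams are not redistributable, so real-data prevalences are out of reach
by construction. The pipeline's correctness claims are mechanical
(filters, matching, counting), not semantic.

## Problem sizes and numerics

The validation suite uses corpora of 300–20,000 posts (10 seeds of 10,000
for filter recovery; 100 corpora of 1,000 for matcher equivalence; 20,000
for exact mixture recovery) — large enough that every category including
0.4%-prevalence ones is populated, small enough for a laptop-class single
CPU in minutes. Mixture-recovery checks compare estimates against the
*planted* (realized) proportions from `mixture_truth`, which is exact
under zero contamination and a Wilson-interval comparison under
contamination. Percent arithmetic is float64 throughout; rounding happens
only at rendering.

## Known limitations

- The high-frequency threshold is a population-level heuristic; with very
  few accounts the SD estimate is unstable (flagging requires ≥ 2
  accounts by contract).
- The fallback language identifier is a stopword profile over five
  languages — adequate for tagged streams with occasional gaps, not a
  general-purpose detector.
- The lemmatizer is intentionally tiny; out-of-dictionary irregular forms
  (e.g. unusual ablaut plurals) pass through unchanged unless added to
  the exception TSV.
- Multi-label and first-match modes bracket, but cannot resolve, how a
  real study with a >100% category column handled multi-matching posts.
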