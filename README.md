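# vapescope

Infodemiology tooling for location surveillance of vaping discussions on
social media. Public-health researchers use keyword dictionaries over
Twitter-style post streams to find out *where* people say they vape —
social venues, living spaces, schools, workplaces — because secondhand and
thirdhand e-cigarette aerosol exposure makes those locations candidates for
smoke-free-air policy. `vapescope` implements that workflow end to end as a
tested, deterministic pipeline:

1. **Stream hygiene** — a six-stage exclusion cascade removes retweets,
   non-English posts, bot accounts, abnormally high-frequency accounts,
   exact-duplicate posts, and promotional posts, with per-stage attrition
   reports.
2. **Normalization** — lowercase; URLs, hashtags, mentions, punctuation and
   special characters stripped; tokens lemmatized (cars → car, vaping →
   vape) by a deterministic rule+exception lemmatizer.
3. **Rule-based classification** — posts are gated on a 26-term vaping
   dictionary, then assigned every location category (of 11) for which at
   least one dictionary keyword occurs as a whole lemmatized token
   (multi-word phrases must occur contiguously). Assignment is multi-label
   by default, so category percentages may sum above 100%.
4. **Prevalence reporting** — per-category counts and percentages over the
   analytic sample with Wilson 95% intervals, rendered as CSV/Markdown/JSON.

Because real post streams cannot be redistributed, the package ships a
**synthetic corpus generator** that plants labeled contamination and a known
category mixture, giving exact ground truth for every stage: each filter's
removed set, each post's true categories, and the true mixture are all
recoverable from `truth_labels`.

For a category with `k` matching posts out of an analytic sample of `n`
posts, the reported prevalence is `100·k/n` with the Wilson score interval
`(p̂ + z²/2n ± z·√(p̂(1−p̂)/n + z²/4n²)) / (1 + z²/n)` at `z = 1.96`.
High-frequency accounts are flagged at posting rates ≥ mean + k·SD
(population SD, default k = 2) over per-account daily rates after bot
removal; bot accounts at a fixed rate threshold (default 50 posts/day,
pluggable scorer).

The core stages are also exposed as sklearn-style estimators
(`TextNormalizer`, `TweetStreamFilter`, `KeywordLocationClassifier`) with
`fit`/`transform`/`predict` and `get_params`/`clone` support.

## Worked example

```bash
vapescope generate --n-posts 2000 --seed 3 --out corpus.jsonl
vapescope run --input corpus.jsonl --output-dir out/
```

prints the attrition chain and report (abridged):

```
retweets: in=2000 removed=200 out=1800
language: in=1800 removed=200 out=1600
bots: in=1600 removed=100 out=1500
high_frequency: in=1500 removed=100 out=1400
duplicates: in=1400 removed=100 out=1300
promotional: in=1300 removed=100 out=1200

| No. | Locations | Illustrative Keywords | % | Wilson 95% CI | n |
|---|---|---|---|---|---|
| 1 | Social venues | game, party, concert, beach | 19.3 | 17.2-21.7 | 232 |
| 2 | Living space | house, home, bedroom, apartment | 16.8 | 14.8-19.1 | 202 |
| 3 | Modes of transportation | bus, drive, car, airplane | 15.8 | 13.9-18.0 | 190 |
...
| 11 | Miscellaneous | place, town, downtown, neighborhood | 13.6 | 11.8-15.6 | 163 |

Analytic sample: 1200 posts from 934 users.
```

Reading it: of 2,000 raw posts, 800 were removed by the hygiene cascade
(each count equals the number of planted contaminants of that kind — the
generator's sidecar `corpus.jsonl.meta.yaml` records the ground truth); all
1,200 clean posts contain a vaping term and ≥1 location keyword, so the
analytic sample is 1,200 posts; 19.3% of them mention a social venue, with
a Wilson interval covering the generator's planted mixture value. The same
pipeline is available programmatically:

```python
from vapescope import (CorpusSpec, generate_corpus, run_filter_cascade,
                       classify_corpus, compute_prevalence)

records = generate_corpus(CorpusSpec(n_posts=2000, seed=3))
survivors, reports = run_filter_cascade(records)
classified = classify_corpus(survivors)          # vaping gate + 11 categories
table = compute_prevalence(classified, {r.post_id: r.account_id for r in survivors})
```

## Layout

- `src/vapescope/corpus.py` — record/lexicon types, JSONL + lexicon IO
- `src/vapescope/synthetic.py` — ground-truth corpus generator
- `src/vapescope/filtering.py` — six-stage exclusion cascade
- `src/vapescope/normalization.py` — stripping + lemmatization
- `src/vapescope/classifier.py` — vaping gate + keyword classification
- `src/vapescope/prevalence.py` — prevalence tables, Wilson CIs, rendering
- `src/vapescope/pipeline.py`, `cli.py` — orchestration and the `vapescope` CLI
- `docs/methods.md` — models, defaults, and design rationale
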