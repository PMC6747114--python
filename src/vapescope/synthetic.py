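"""Synthetic tweet-corpus generator with planted, labeled contamination.

Every record carries ``truth_labels`` naming its contaminant kind (or
``"clean"``) and, for clean posts, the planted location categories — so
every pipeline stage can be scored exactly.  Contaminant kinds are
mutually exclusive per post, resolved in the fixed priority retweet >
non-English > bot > high-frequency > duplicate > promotional; real streams
overlap, but exclusive kinds make stage-wise recovery testing exact.

The generator controls posting-rate structure so the account-level filters
are exactly recoverable: normal accounts post on consecutive distinct days
(rate ≤ 1 post/day, and exactly 1 before any removals), bot accounts burst
all their posts within single days at ``bot_posts_per_day``, and
high-frequency accounts sustain ``high_freq_posts_per_day`` over several
days — above any mean + k·SD threshold over normal accounts yet below the
bot rate.  Clean text is built from a filler vocabulary sharing no lemma
with either lexicon or the promotional term list, so a clean post's
matched categories equal exactly its planted categories.

No linguistic realism is attempted; only the statistical structure the
pipeline's tests require.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from datetime import datetime, timedelta, timezone
from typing import Mapping, Sequence

import numpy as np

from .corpus import Lexicon, TweetRecord, default_location_lexicon, default_vaping_lexicon
from .prevalence import PrevalenceTable, build_table

__all__ = [
    "CorpusSpec",
    "generate_corpus",
    "mixture_truth",
    "FILLER_VOCAB",
    "STAGE_TO_KIND",
    "DEFAULT_CATEGORY_MIXTURE",
    "CONTAMINANT_KINDS",
]

#: cascade stage name → the planted contaminant kind it should remove
STAGE_TO_KIND = {
    "retweets": "retweet",
    "language": "non_english",
    "bots": "bot",
    "high_frequency": "high_frequency",
    "duplicates": "duplicate",
    "promotional": "promotional",
}

CONTAMINANT_KINDS = (
    "retweet",
    "non_english",
    "bot",
    "high_frequency",
    "duplicate",
    "promotional",
)

# Keyword-free filler vocabulary: shares no lemma with the bundled location
# or vaping lexicons, nor with the default promotional terms.  Enforced by
# a test against the lemmatizer.
FILLER_VOCAB: tuple[str, ...] = (
    "really", "honestly", "quietly", "slowly", "gently", "almost", "always",
    "never", "often", "maybe", "probably", "certainly", "today", "tonight",
    "yesterday", "morning", "evening", "afternoon", "weekend", "moment",
    "minute", "hour", "friend", "buddy", "crew", "folks", "people",
    "everyone", "somebody", "nobody", "thing", "stuff", "idea", "thought",
    "feeling", "mood", "vibe", "weather", "rain", "wind", "cloud", "sun",
    "moon", "star", "sky", "river", "hill", "tree", "leaf", "grass",
    "flower", "bird", "dog", "cat", "tea", "water", "snack", "music",
    "song", "tune", "beat", "story", "book", "page", "chapter", "letter",
    "word", "phrase", "sentence", "question", "answer", "reason", "laugh",
    "smile", "grin", "wink", "nod", "shrug", "wander", "stroll", "linger",
    "pause", "breathe", "relax", "unwind", "chill", "rest", "nap", "dream",
    "wish", "hope", "goal", "task", "chore", "errand", "ticket", "wallet",
    "pocket", "jacket", "scarf", "glove", "boot", "sneaker", "lace",
    "button", "zipper", "umbrella", "backpack", "notebook", "pencil",
    "marker", "crayon", "sticker", "magnet", "candle", "lantern", "blanket",
    "pillow", "cushion", "carpet", "curtain", "mirror", "clock", "calendar",
    "journal", "diary", "puzzle", "riddle", "joke", "prank", "hobby",
    "craft", "sketch", "doodle", "melody", "rhythm", "harmony", "verse",
    "poem", "novel", "essay",
)

# Small non-English phrase bank with true language tags; language filtering
# is tag-driven, so linguistic fidelity is irrelevant.
_NON_ENGLISH_BANK: tuple[tuple[str, str], ...] = (
    ("es", "me gusta mucho caminar por la ciudad"),
    ("es", "hoy es un buen dia para descansar"),
    ("es", "no tengo ganas de hacer nada hoy"),
    ("fr", "je suis tres fatigue ce soir"),
    ("fr", "nous allons voir un film ce soir"),
    ("fr", "il pleut encore dans la ville"),
    ("de", "ich habe heute viel zu tun"),
    ("de", "das wetter ist heute wirklich gut"),
    ("de", "wir gehen morgen ins kino"),
    ("pt", "eu gosto de musica brasileira"),
    ("pt", "hoje o dia esta muito bonito"),
)

_PROMO_PLANT_TERMS = ("sale", "discount", "coupon", "promo", "deal", "giveaway")

# Default planted category mixture: the relative prevalence profile of the
# 11 location categories reported in published 2018 vaping-location
# surveillance (social venues most common, religious institutions rarest),
# normalized to sum to 1.
_PROFILE_PERCENT = {
    "Social venues": 17.9,
    "Living space": 16.7,
    "Stores": 15.9,
    "Modes of transportation": 15.5,
    "School": 14.9,
    "Workplace": 11.9,
    "Healthcare offices": 2.0,
    "Eateries": 1.2,
    "Correctional facility": 0.7,
    "Religious institutions": 0.4,
    "Miscellaneous": 13.5,
}
_PROFILE_TOTAL = sum(_PROFILE_PERCENT.values())
DEFAULT_CATEGORY_MIXTURE: Mapping[str, float] = {
    cat: pct / _PROFILE_TOTAL for cat, pct in _PROFILE_PERCENT.items()
}

#: Multi-label rate implied by the same profile (percent column sums to
#: 110.6, i.e. ~10.6% of posts carry a second category).
_DEFAULT_MULTI_LABEL_RATE = (_PROFILE_TOTAL - 100.0) / 100.0

_WINDOW_START = datetime(2018, 6, 1, tzinfo=timezone.utc)
_SECONDS_PER_DAY = 86400


@dataclass(frozen=True)
class CorpusSpec:
    """Full description of a synthetic corpus; the seed determines output.

    Contamination fractions are proportions of ``n_posts``; defaults mirror
    a moderately noisy stream (20% retweets+non-English, 5% each of the
    other contaminant kinds).  ``n_accounts``, when given, is the number of
    accounts hosting the normal post pool (clean, retweet, non-English,
    promotional); bot, high-frequency and duplicate posts always live on
    dedicated accounts so rate structure stays exact.
    """

    n_posts: int = 10_000
    frac_retweet: float = 0.10
    frac_non_english: float = 0.10
    frac_bot: float = 0.05
    frac_high_freq: float = 0.05
    frac_duplicate: float = 0.05
    frac_promotional: float = 0.05
    category_mixture: Mapping[str, float] | None = None
    multi_label_rate: float = _DEFAULT_MULTI_LABEL_RATE
    n_accounts: int | None = None
    seed: int = 0
    window_days: int = 10
    bot_posts_per_day: int = 60
    high_freq_posts_per_day: int = 12

    def resolved_mixture(self) -> dict[str, float]:
        mix = dict(self.category_mixture or DEFAULT_CATEGORY_MIXTURE)
        return mix

    def validate(self) -> None:
        if self.n_posts < 0:
            raise ValueError("n_posts must be >= 0")
        fracs = {
            "frac_retweet": self.frac_retweet,
            "frac_non_english": self.frac_non_english,
            "frac_bot": self.frac_bot,
            "frac_high_freq": self.frac_high_freq,
            "frac_duplicate": self.frac_duplicate,
            "frac_promotional": self.frac_promotional,
            "multi_label_rate": self.multi_label_rate,
        }
        for name, v in fracs.items():
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        mix = self.resolved_mixture()
        if any(p < 0 for p in mix.values()):
            raise ValueError("category_mixture probabilities must be >= 0")
        if abs(sum(mix.values()) - 1.0) > 1e-9:
            raise ValueError("category_mixture must sum to 1 within 1e-9")
        if self.n_accounts is not None and self.n_accounts < 1:
            raise ValueError("n_accounts must be >= 1")
        if self.window_days < 1:
            raise ValueError("window_days must be >= 1")

    def kind_counts(self) -> dict[str, int]:
        """Deterministic per-kind allocation, resolved in priority order."""
        n = self.n_posts
        counts = {
            "retweet": int(round(self.frac_retweet * n)),
            "non_english": int(round(self.frac_non_english * n)),
            "bot": int(round(self.frac_bot * n)),
            "high_frequency": int(round(self.frac_high_freq * n)),
            "duplicate": int(round(self.frac_duplicate * n)),
            "promotional": int(round(self.frac_promotional * n)),
        }
        n_clean = n - sum(counts.values())
        if n_clean < 0:
            raise ValueError("contamination fractions allocate more posts than n_posts")
        if counts["duplicate"] > 0 and n_clean == 0:
            raise ValueError("duplicates require at least one clean post to copy")
        counts["clean"] = n_clean
        return counts


class _TextFactory:
    """Builds globally unique post texts from filler plus planted units."""

    def __init__(self, rng: np.random.Generator):
        self.rng = rng
        self.seen: set[str] = set()

    def filler(self, k: int) -> list[str]:
        idx = self.rng.integers(0, len(FILLER_VOCAB), size=k)
        return [FILLER_VOCAB[i] for i in idx]

    def build(self, units: list[str]) -> str:
        units = list(units)
        self.rng.shuffle(units)
        text = " ".join(units)
        while text in self.seen:
            units.append(FILLER_VOCAB[int(self.rng.integers(0, len(FILLER_VOCAB)))])
            self.rng.shuffle(units)
            text = " ".join(units)
        self.seen.add(text)
        return text


def _balanced_partition(total: int, n_parts: int) -> list[int]:
    base, rem = divmod(total, n_parts)
    return [base + (1 if i < rem else 0) for i in range(n_parts)]


def generate_corpus(
    spec: CorpusSpec,
    vaping_lexicon: Lexicon | None = None,
    location_lexicon: Lexicon | None = None,
) -> list[TweetRecord]:
    """Generate exactly ``spec.n_posts`` labeled records (see module docs)."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    counts = spec.kind_counts()
    vap = vaping_lexicon or default_vaping_lexicon()
    loc = location_lexicon or default_location_lexicon()
    vap_terms = [kw for kws in vap.entries.values() for kw in kws]
    mix = spec.resolved_mixture()
    cats = [c for c, p in mix.items() if p > 0]
    probs = np.array([mix[c] for c in cats], dtype=float)
    probs = probs / probs.sum()
    factory = _TextFactory(rng)
    acct_counter = iter(range(10**9))

    def next_account() -> str:
        return f"a{next(acct_counter):07d}"

    def pick(seq: Sequence[str]) -> str:
        return seq[int(rng.integers(0, len(seq)))]

    def vaping_body(extra_units: list[str] | None = None) -> str:
        units = factory.filler(int(rng.integers(5, 11))) + [pick(vap_terms)]
        units.extend(extra_units or [])
        return factory.build(units)

    # --- clean posts -------------------------------------------------------
    clean: list[TweetRecord] = []
    for _ in range(counts["clean"]):
        planted = [cats[int(rng.choice(len(cats), p=probs))]]
        double = False
        if len(cats) >= 2 and rng.random() < spec.multi_label_rate:
            second = planted[0]
            while second == planted[0]:
                second = cats[int(rng.choice(len(cats), p=probs))]
            planted.append(second)
            double = True
        kw_units = [pick(loc.entries[c]) for c in planted]
        text = vaping_body(kw_units)
        clean.append(
            TweetRecord(
                post_id="",
                account_id="",
                text=text,
                lang="en",
                is_retweet=False,
                truth_labels={
                    "kind": "clean",
                    "categories": sorted(planted),
                    "double_label": double,
                },
            )
        )

    # --- record-level contaminants (normal-account pool) -------------------
    normal_pool: list[TweetRecord] = list(clean)
    for _ in range(counts["retweet"]):
        handle = f"user{int(rng.integers(0, 10**6))}"
        text = f"RT @{handle}: " + vaping_body()
        normal_pool.append(
            TweetRecord("", "", text, lang="en", is_retweet=True,
                        truth_labels={"kind": "retweet"})
        )
    for _ in range(counts["non_english"]):
        lang, phrase = _NON_ENGLISH_BANK[int(rng.integers(0, len(_NON_ENGLISH_BANK)))]
        text = factory.build([phrase] + factory.filler(2))
        normal_pool.append(
            TweetRecord("", "", text, lang=lang, is_retweet=False,
                        truth_labels={"kind": "non_english"})
        )
    for _ in range(counts["promotional"]):
        url = "https://t.co/" + "".join(
            "abcdefghij"[d] for d in rng.integers(0, 10, size=8)
        )
        units = factory.filler(int(rng.integers(4, 9)))
        units += [pick(vap_terms), pick(_PROMO_PLANT_TERMS), url]
        text = factory.build(units)
        normal_pool.append(
            TweetRecord("", "", text, lang="en", is_retweet=False,
                        truth_labels={"kind": "promotional"})
        )

    # --- normal accounts: consecutive distinct days, rate exactly <= 1/day -
    order = rng.permutation(len(normal_pool))
    if spec.n_accounts is not None and normal_pool:
        sizes = _balanced_partition(len(normal_pool), spec.n_accounts)
        sizes = [s for s in sizes if s > 0]
        if max(sizes) > spec.window_days:
            raise ValueError(
                "n_accounts too small: an account would need more posts than "
                "window_days, breaking the 1-post/day rate structure"
            )
    else:
        sizes = []
        remaining = len(normal_pool)
        while remaining > 0:
            k = int(rng.choice([1, 2, 3], p=[0.7, 0.2, 0.1]))
            k = min(k, remaining)
            sizes.append(k)
            remaining -= k
    pos = 0
    for size in sizes:
        acct = next_account()
        start_day = int(rng.integers(0, spec.window_days - size + 1))
        for j in range(size):
            rec = normal_pool[order[pos]]
            rec.account_id = acct
            rec.created_at = _WINDOW_START + timedelta(
                days=start_day + j, seconds=int(rng.integers(0, _SECONDS_PER_DAY))
            )
            pos += 1

    # --- bot accounts: one-day bursts at bot_posts_per_day -----------------
    records: list[TweetRecord] = list(normal_pool)
    n_bot = counts["bot"]
    if n_bot:
        n_acc = max(1, int(round(n_bot / spec.bot_posts_per_day)))
        for size in _balanced_partition(n_bot, n_acc):
            if size == 0:
                continue
            acct = next_account()
            day = int(rng.integers(0, spec.window_days))
            for _ in range(size):
                records.append(
                    TweetRecord(
                        "", acct, vaping_body(), lang="en", is_retweet=False,
                        created_at=_WINDOW_START + timedelta(
                            days=day, seconds=int(rng.integers(0, _SECONDS_PER_DAY))
                        ),
                        truth_labels={"kind": "bot"},
                    )
                )

    # --- high-frequency accounts: sustained elevated daily rate ------------
    n_high = counts["high_frequency"]
    if n_high:
        target = spec.high_freq_posts_per_day * min(spec.window_days, 5)
        n_acc = max(1, int(round(n_high / target)))
        for size in _balanced_partition(n_high, n_acc):
            if size == 0:
                continue
            acct = next_account()
            n_days = max(1, min(spec.window_days,
                                int(round(size / spec.high_freq_posts_per_day))))
            start_day = int(rng.integers(0, spec.window_days - n_days + 1))
            per_day = _balanced_partition(size, n_days)
            for d, m in enumerate(per_day):
                for _ in range(m):
                    records.append(
                        TweetRecord(
                            "", acct, vaping_body(), lang="en", is_retweet=False,
                            created_at=_WINDOW_START + timedelta(
                                days=start_day + d,
                                seconds=int(rng.integers(0, _SECONDS_PER_DAY)),
                            ),
                            truth_labels={"kind": "high_frequency"},
                        )
                    )

    # --- assign ids to everything generated so far -------------------------
    for i, rec in enumerate(records):
        rec.post_id = f"p{i:07d}"

    # --- duplicates: exact text copies of clean posts, later timestamps ----
    n_dup = counts["duplicate"]
    for i in range(n_dup):
        src = clean[int(rng.integers(0, len(clean)))]
        records.append(
            TweetRecord(
                post_id=f"p{len(records) + 0:07d}",
                account_id=next_account(),
                text=src.text,
                lang="en",
                is_retweet=False,
                created_at=src.created_at + timedelta(
                    seconds=int(rng.integers(60, _SECONDS_PER_DAY))
                ),
                truth_labels={"kind": "duplicate", "source_post_id": src.post_id},
            )
        )

    records.sort(key=lambda r: (r.created_at, r.post_id))
    return records


def mixture_truth(records: Sequence[TweetRecord]) -> PrevalenceTable:
    """Ground-truth category prevalence among clean posts, from labels only."""
    counts: dict[str, int] = {}
    accounts: set[str] = set()
    n_clean = 0
    for rec in records:
        if rec.truth_labels is None:
            raise ValueError(f"record {rec.post_id} has no truth_labels")
        if rec.truth_labels["kind"] != "clean":
            continue
        n_clean += 1
        accounts.add(rec.account_id)
        for cat in rec.truth_labels["categories"]:
            counts[cat] = counts.get(cat, 0) + 1
    return build_table(counts, n_total=n_clean, n_users=len(accounts))
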