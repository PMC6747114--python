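"""Stream-hygiene exclusion cascade.

Six filters applied in a fixed order — retweets, non-English posts, bot
accounts, abnormally high-frequency accounts, exact-duplicate posts,
promotional posts — each returning the surviving records plus a
:class:`~vapescope.corpus.StageReport` so attrition telescopes from the raw
stream to the analytic sample.

Thresholds for the two account-level filters are heuristics, surfaced in
:class:`FilterConfig`: a bot account is one posting at or above a fixed
daily rate (default 50 posts/day), and a high-frequency account is one
whose daily rate is at or above mean + k·SD (population SD, default k = 2)
of the per-account rates remaining after bot removal.  The bot rule is
pluggable: pass any ``scorer(AccountStats) -> bool``.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Callable, Iterable, Sequence

import numpy as np
from sklearn.base import BaseEstimator

from .corpus import StageReport, TweetRecord

__all__ = [
    "AccountStats",
    "FilterConfig",
    "TweetStreamFilter",
    "DEFAULT_PROMO_TERMS",
    "STAGE_ORDER",
    "filter_retweets",
    "filter_language",
    "compute_account_stats",
    "flag_bot_accounts",
    "flag_high_frequency_accounts",
    "filter_duplicates",
    "filter_promotional",
    "run_filter_cascade",
    "detect_language",
]

DEFAULT_PROMO_TERMS: frozenset[str] = frozenset(
    {
        "sale",
        "discount",
        "coupon",
        "promo",
        "promo code",
        "off",
        "deal",
        "free shipping",
        "buy now",
        "order now",
        "giveaway",
    }
)

STAGE_ORDER = (
    "retweets",
    "language",
    "bots",
    "high_frequency",
    "duplicates",
    "promotional",
)

_URL_RE = re.compile(r"(?:https?://\S+|\bwww\.\S+|\bt\.co/\S+)", re.IGNORECASE)

# Small stopword profiles for the tag-fallback language identifier.  The
# primary signal is always the stream's own language tag; this only breaks
# ties for untagged posts.
_STOPWORDS = {
    "en": {"the", "and", "is", "in", "at", "of", "to", "it", "that", "for", "my", "was"},
    "es": {"el", "la", "de", "que", "y", "en", "los", "se", "las", "por", "un", "para", "con", "una", "no", "es"},
    "fr": {"le", "les", "des", "et", "une", "dans", "est", "pour", "qui", "sur", "je", "ce", "il", "nous"},
    "de": {"der", "die", "und", "das", "ist", "nicht", "mit", "ein", "eine", "den", "von", "zu", "im", "ich", "wir"},
    "pt": {"o", "os", "da", "do", "em", "um", "uma", "eu", "ele", "com", "para", "muito"},
}
_LANG_PRIORITY = ("en", "es", "fr", "de", "pt")


def detect_language(text: str) -> str:
    """Cheap stopword-profile language guess; ``"und"`` when no evidence."""
    tokens = set(re.findall(r"[^\W\d_]+", text.lower()))
    best, best_score = "und", 0
    for lang in _LANG_PRIORITY:
        score = len(tokens & _STOPWORDS[lang])
        if score > best_score:
            best, best_score = lang, score
    return best


@dataclass(frozen=True)
class AccountStats:
    """Per-account posting-frequency summary."""

    account_id: str
    n_posts: int
    active_days: int

    def __post_init__(self) -> None:
        if self.n_posts < 1:
            raise ValueError("n_posts must be >= 1")

    @property
    def posts_per_day(self) -> float:
        return self.n_posts / max(self.active_days, 1)


@dataclass(frozen=True)
class FilterConfig:
    """Tunable thresholds for the cascade."""

    allowed_langs: frozenset[str] = frozenset({"en"})
    bot_rate_threshold: float = 50.0
    high_freq_multiplier: float = 2.0
    promo_terms: frozenset[str] = DEFAULT_PROMO_TERMS
    promo_requires_url: bool = True

    def __post_init__(self) -> None:
        if not self.allowed_langs:
            raise ValueError("allowed_langs must be nonempty")
        if not self.high_freq_multiplier > 0:
            raise ValueError("high_freq_multiplier must be > 0")
        if not np.isfinite(self.bot_rate_threshold):
            raise ValueError("bot_rate_threshold must be finite")
        object.__setattr__(self, "allowed_langs", frozenset(self.allowed_langs))
        object.__setattr__(self, "promo_terms", frozenset(self.promo_terms))


# ---------------------------------------------------------------------------
# Record-level filters

def filter_retweets(
    records: Sequence[TweetRecord],
) -> tuple[list[TweetRecord], StageReport]:
    """Drop retweets (flagged, or text starting with "RT @")."""
    kept = [r for r in records if not r.retweet]
    return kept, StageReport("retweets", len(records), len(records) - len(kept))


def filter_language(
    records: Sequence[TweetRecord],
    config: FilterConfig = FilterConfig(),
    detector: Callable[[str], str] = detect_language,
) -> tuple[list[TweetRecord], StageReport]:
    """Keep allowed-language posts; untagged posts go to the fallback detector."""
    kept = []
    for r in records:
        lang = r.lang if r.lang and r.lang != "und" else detector(r.text)
        if lang in config.allowed_langs:
            kept.append(r)
    return kept, StageReport("language", len(records), len(records) - len(kept))


# ---------------------------------------------------------------------------
# Account-level filters

def compute_account_stats(records: Sequence[TweetRecord]) -> list[AccountStats]:
    """One :class:`AccountStats` per distinct account.

    ``active_days`` spans the account's first to last post, inclusive, in
    calendar days (all posts on one day → 1 day).
    """
    spans: dict[str, list] = {}
    for r in records:
        day = r.created_at.date()
        entry = spans.setdefault(r.account_id, [0, day, day])
        entry[0] += 1
        if day < entry[1]:
            entry[1] = day
        if day > entry[2]:
            entry[2] = day
    return [
        AccountStats(acct, n, (last - first).days + 1)
        for acct, (n, first, last) in spans.items()
    ]


def flag_bot_accounts(
    stats: Sequence[AccountStats],
    config: FilterConfig = FilterConfig(),
    scorer: Callable[[AccountStats], bool] | None = None,
) -> set[str]:
    """Accounts posting at/above the bot rate threshold (or per a custom scorer)."""
    if not stats:
        raise ValueError("flag_bot_accounts requires nonempty stats")
    if scorer is None:
        scorer = lambda s: s.posts_per_day >= config.bot_rate_threshold
    return {s.account_id for s in stats if scorer(s)}


def flag_high_frequency_accounts(
    stats: Sequence[AccountStats],
    config: FilterConfig = FilterConfig(),
) -> set[str]:
    """Accounts at/above mean + k·SD of per-account daily rates.

    Population SD over the supplied accounts (callers pass post-bot-removal
    stats).  When the rates are all equal (SD = 0) nobody is abnormal and
    nothing is flagged.
    """
    if len(stats) < 2:
        raise ValueError("high-frequency flagging needs >= 2 accounts")
    rates = np.array([s.posts_per_day for s in stats], dtype=float)
    sd = float(rates.std(ddof=0))
    if sd == 0.0:
        return set()
    threshold = float(rates.mean()) + config.high_freq_multiplier * sd
    return {s.account_id for s in stats if s.posts_per_day >= threshold}


def _drop_accounts(
    records: Sequence[TweetRecord], flagged: set[str], stage: str
) -> tuple[list[TweetRecord], StageReport]:
    kept = [r for r in records if r.account_id not in flagged]
    return kept, StageReport(stage, len(records), len(records) - len(kept))


# ---------------------------------------------------------------------------
# Content filters

def filter_duplicates(
    records: Sequence[TweetRecord],
) -> tuple[list[TweetRecord], StageReport]:
    """Keep the earliest copy of each whitespace-normalized text.

    Ties on timestamp break by post_id order, so the result is independent
    of input order.
    """
    best: dict[str, TweetRecord] = {}
    for r in records:
        key = " ".join(r.text.split())
        cur = best.get(key)
        if cur is None or (r.created_at, r.post_id) < (cur.created_at, cur.post_id):
            best[key] = r
    keep_ids = {r.post_id for r in best.values()}
    kept = [r for r in records if r.post_id in keep_ids]
    return kept, StageReport("duplicates", len(records), len(records) - len(kept))


def _promo_patterns(terms: Iterable[str]) -> list[re.Pattern]:
    pats = []
    for term in sorted(terms):
        escaped = re.escape(term).replace(r"\ ", r"\s+")
        pats.append(re.compile(rf"\b{escaped}\b"))
    return pats


def filter_promotional(
    records: Sequence[TweetRecord],
    config: FilterConfig = FilterConfig(),
) -> tuple[list[TweetRecord], StageReport]:
    """Drop posts whose lowercased text contains a promo term (word-boundary
    match) and, if configured, a URL."""
    pats = _promo_patterns(config.promo_terms)
    kept = []
    for r in records:
        low = r.text.lower()
        promo = any(p.search(low) for p in pats)
        if promo and config.promo_requires_url:
            promo = bool(_URL_RE.search(low))
        if not promo:
            kept.append(r)
    return kept, StageReport("promotional", len(records), len(records) - len(kept))


# ---------------------------------------------------------------------------
# Cascade

def run_filter_cascade(
    records: Sequence[TweetRecord],
    config: FilterConfig = FilterConfig(),
    bot_scorer: Callable[[AccountStats], bool] | None = None,
) -> tuple[list[TweetRecord], list[StageReport]]:
    """Apply all six filters in the canonical order.

    Order: retweets → language → bots → high-frequency → duplicates →
    promotional.  Each report's ``n_in`` equals the previous ``n_out``.
    """
    reports: list[StageReport] = []
    kept, rep = filter_retweets(records)
    reports.append(rep)
    kept, rep = filter_language(kept, config)
    reports.append(rep)

    if kept:
        stats = compute_account_stats(kept)
        bots = flag_bot_accounts(stats, config, scorer=bot_scorer)
    else:
        bots = set()
    kept, rep = _drop_accounts(kept, bots, "bots")
    reports.append(rep)

    stats = compute_account_stats(kept)
    high = flag_high_frequency_accounts(stats, config) if len(stats) >= 2 else set()
    kept, rep = _drop_accounts(kept, high, "high_frequency")
    reports.append(rep)

    kept, rep = filter_duplicates(kept)
    reports.append(rep)
    kept, rep = filter_promotional(kept, config)
    reports.append(rep)
    return kept, reports


class TweetStreamFilter(BaseEstimator):
    """Estimator wrapper around the exclusion cascade.

    ``fit`` runs the cascade on the fit corpus and stores the learned
    account-level artifacts (per-account stats, flagged bot and
    high-frequency account sets) plus the stage attrition reports;
    ``transform`` filters a corpus using those fitted account flags and the
    corpus-local record-level rules.  ``fit_transform(X)`` is exactly the
    canonical cascade on ``X``.
    """

    def __init__(
        self,
        allowed_langs: tuple[str, ...] = ("en",),
        bot_rate_threshold: float = 50.0,
        high_freq_multiplier: float = 2.0,
        promo_terms: tuple[str, ...] | None = None,
        promo_requires_url: bool = True,
        bot_scorer: Callable[[AccountStats], bool] | None = None,
    ):
        self.allowed_langs = allowed_langs
        self.bot_rate_threshold = bot_rate_threshold
        self.high_freq_multiplier = high_freq_multiplier
        self.promo_terms = promo_terms
        self.bot_scorer = bot_scorer
        self.promo_requires_url = promo_requires_url

    def _config(self) -> FilterConfig:
        return FilterConfig(
            allowed_langs=frozenset(self.allowed_langs),
            bot_rate_threshold=self.bot_rate_threshold,
            high_freq_multiplier=self.high_freq_multiplier,
            promo_terms=(
                DEFAULT_PROMO_TERMS if self.promo_terms is None else frozenset(self.promo_terms)
            ),
            promo_requires_url=self.promo_requires_url,
        )

    def fit(self, X: Sequence[TweetRecord], y=None) -> "TweetStreamFilter":
        config = self._config()
        survivors, reports = run_filter_cascade(X, config, bot_scorer=self.bot_scorer)
        self.reports_ = reports
        self.survivor_ids_ = {r.post_id for r in survivors}
        after_lang, _ = filter_language(*filter_retweets(X)[:1], config)
        self.account_stats_ = compute_account_stats(after_lang) if after_lang else []
        self.bot_accounts_ = (
            flag_bot_accounts(self.account_stats_, config, scorer=self.bot_scorer)
            if self.account_stats_
            else set()
        )
        post_bot = [r for r in after_lang if r.account_id not in self.bot_accounts_]
        stats = compute_account_stats(post_bot)
        self.high_freq_accounts_ = (
            flag_high_frequency_accounts(stats, config) if len(stats) >= 2 else set()
        )
        return self

    def transform(self, X: Sequence[TweetRecord]) -> list[TweetRecord]:
        if not hasattr(self, "bot_accounts_"):
            raise RuntimeError("TweetStreamFilter is not fitted")
        config = self._config()
        kept, _ = filter_retweets(X)
        kept, _ = filter_language(kept, config)
        flagged = self.bot_accounts_ | self.high_freq_accounts_
        kept = [r for r in kept if r.account_id not in flagged]
        kept, _ = filter_duplicates(kept)
        kept, _ = filter_promotional(kept, config)
        return kept

    def fit_transform(self, X: Sequence[TweetRecord], y=None) -> list[TweetRecord]:
        self.fit(X)
        return [r for r in self.transform(X) if r.post_id in self.survivor_ids_]
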