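"""Exclusion cascade: per-stage contracts, exact recovery, order invariance."""

from __future__ import annotations

from datetime import datetime, timedelta, timezone

import numpy as np
import pytest

from conftest import clean_ids, kind_ids
from vapescope.corpus import TweetRecord
from vapescope.filtering import (
    AccountStats,
    FilterConfig,
    TweetStreamFilter,
    compute_account_stats,
    detect_language,
    filter_duplicates,
    filter_language,
    filter_promotional,
    filter_retweets,
    flag_bot_accounts,
    flag_high_frequency_accounts,
    run_filter_cascade,
)
from vapescope.synthetic import STAGE_TO_KIND, CorpusSpec, generate_corpus

UTC = timezone.utc


def rec(pid, text="hello vape", acct="a1", lang="en", rt=False, ts=None):
    return TweetRecord(pid, acct, text, lang=lang, is_retweet=rt,
                       created_at=ts or datetime(2018, 6, 1, tzinfo=UTC))


class TestRetweets:
    def test_flag_and_prefix_both_count(self):
        records = [rec(f"p{i}") for i in range(7)]
        records += [rec("r1", rt=True), rec("r2", text="RT @x: hi"), rec("r3", rt=True)]
        kept, rep = filter_retweets(records)
        assert len(kept) == 7 and rep.n_removed == 3 and rep.n_in == 10

    def test_all_retweets_removed(self):
        records = [rec(f"p{i}", rt=True) for i in range(4)]
        kept, rep = filter_retweets(records)
        assert kept == [] and rep.n_removed == rep.n_in == 4


class TestLanguage:
    def test_tagged_records(self):
        kept, rep = filter_language([rec("p1", lang="en"), rec("p2", lang="es")])
        assert [r.post_id for r in kept] == ["p1"] and rep.n_removed == 1

    def test_untagged_fallback_detection(self):
        english = rec("p1", text="this is the story of my day and it was good", lang="und")
        spanish = rec("p2", text="el dia es muy bueno y no tengo que trabajar", lang="und")
        kept, _ = filter_language([english, spanish])
        assert [r.post_id for r in kept] == ["p1"]

    @pytest.mark.parametrize(
        "text,lang",
        [
            ("the cat is in the house and it is mine", "en"),
            ("el perro y la casa de los amigos", "es"),
            ("je suis dans la maison pour la nuit", "fr"),
            ("ich bin mit der katze im haus", "de"),
        ],
    )
    def test_detector_on_clear_cases(self, text, lang):
        assert detect_language(text) == lang

    def test_detector_unknown_on_no_evidence(self):
        assert detect_language("zzz qqq xxx") == "und"


class TestAccountStats:
    def test_rate_arithmetic(self):
        records = [
            rec(f"p{i}", ts=datetime(2018, 6, 1, tzinfo=UTC) + timedelta(days=i % 5, hours=i))
            for i in range(10)
        ]
        (stats,) = compute_account_stats(records)
        assert stats.n_posts == 10 and stats.active_days == 5
        assert stats.posts_per_day == 2.0

    def test_same_timestamp_clamps_to_one_day(self):
        ts = datetime(2018, 6, 1, 12, tzinfo=UTC)
        (stats,) = compute_account_stats([rec("p1", ts=ts), rec("p2", ts=ts)])
        assert stats.active_days == 1 and stats.posts_per_day == 2.0

    def test_post_conservation_over_accounts(self, small_corpus):
        stats = compute_account_stats(small_corpus)
        assert sum(s.n_posts for s in stats) == len(small_corpus)
        assert len(stats) == len({r.account_id for r in small_corpus})


class TestBotFlagging:
    def make(self, rate):
        return AccountStats(f"a{rate}", int(rate), 1)

    def test_threshold_rule(self):
        flagged = flag_bot_accounts([self.make(60), self.make(10)],
                                    FilterConfig(bot_rate_threshold=50))
        assert flagged == {"a60"}

    def test_pluggable_scorer(self):
        scorer = lambda s: s.account_id.endswith("0")
        flagged = flag_bot_accounts([self.make(60), self.make(10)], scorer=scorer)
        assert flagged == {"a60", "a10"}

    def test_empty_stats_rejected(self):
        with pytest.raises(ValueError):
            flag_bot_accounts([])


class TestHighFrequencyFlagging:
    def test_outlier_at_mean_plus_two_sd(self):
        # rates {1,1,1,1,100}: mean 20.8, population SD 39.6 → threshold 100.0
        stats = [AccountStats(f"a{i}", 1, 1) for i in range(4)]
        stats.append(AccountStats("hot", 100, 1))
        rates = np.array([1, 1, 1, 1, 100], float)
        assert np.isclose(rates.mean() + 2 * rates.std(), 100.0)
        assert flag_high_frequency_accounts(stats, FilterConfig(high_freq_multiplier=2)) == {"hot"}

    def test_equal_rates_flag_nothing(self):
        stats = [AccountStats(f"a{i}", 3, 1) for i in range(5)]
        assert flag_high_frequency_accounts(stats) == set()

    def test_fewer_than_two_accounts_rejected(self):
        with pytest.raises(ValueError):
            flag_high_frequency_accounts([AccountStats("a", 1, 1)])


class TestDuplicates:
    def test_earliest_kept_whitespace_normalized(self):
        base = datetime(2018, 6, 1, tzinfo=UTC)
        records = [
            rec("p3", text="same  text here", ts=base + timedelta(hours=2)),
            rec("p1", text="same text here", ts=base),
            rec("p2", text="same text\there", ts=base + timedelta(hours=1)),
        ]
        kept, rep = filter_duplicates(records)
        assert [r.post_id for r in kept] == ["p1"] and rep.n_removed == 2

    def test_timestamp_tie_breaks_by_post_id(self):
        records = [rec("pB", text="x"), rec("pA", text="x")]
        kept, _ = filter_duplicates(records)
        assert [r.post_id for r in kept] == ["pA"]

    def test_no_duplicates_identity(self):
        records = [rec("p1", text="one"), rec("p2", text="two")]
        kept, rep = filter_duplicates(records)
        assert kept == records and rep.n_removed == 0


class TestPromotional:
    def test_promo_term_plus_url_removed(self):
        records = [rec("p1", text="20% off juul pods today http://x.co")]
        kept, rep = filter_promotional(records)
        assert kept == [] and rep.n_removed == 1

    def test_promo_term_without_url_kept_by_default(self):
        records = [rec("p1", text="day off tomorrow")]
        kept, _ = filter_promotional(records)
        assert len(kept) == 1
        kept, _ = filter_promotional(records, FilterConfig(promo_requires_url=False))
        assert kept == []

    def test_word_boundary_matching(self):
        # "off" must not fire inside "coffee"
        records = [rec("p1", text="coffee and vape http://x.co")]
        kept, _ = filter_promotional(records)
        assert len(kept) == 1


class TestCascade:
    def test_zero_contamination_is_identity(self):
        spec = CorpusSpec(n_posts=200, frac_retweet=0, frac_non_english=0,
                          frac_bot=0, frac_high_freq=0, frac_duplicate=0,
                          frac_promotional=0, seed=9)
        records = generate_corpus(spec)
        kept, reports = run_filter_cascade(records)
        assert kept == records
        assert all(r.n_removed == 0 for r in reports)

    def test_report_chain_telescopes(self, small_corpus):
        kept, reports = run_filter_cascade(small_corpus)
        for prev, nxt in zip(reports, reports[1:]):
            assert prev.n_out == nxt.n_in
        assert reports[0].n_in - sum(r.n_removed for r in reports) == len(kept)
        assert reports[-1].n_out == len(kept)

    def test_each_stage_removes_exactly_its_planted_kind(self, small_corpus):
        before = list(small_corpus)
        _, reports = run_filter_cascade(before)
        survivors = before
        for rep in reports:
            next_survivors, stage_rep = _apply_stage(rep.stage_name, survivors)
            removed = {r.post_id for r in survivors} - {r.post_id for r in next_survivors}
            planted = kind_ids(small_corpus, STAGE_TO_KIND[rep.stage_name])
            assert removed == planted, rep.stage_name
            survivors = next_survivors
        assert {r.post_id for r in survivors} == clean_ids(small_corpus)

    def test_cascade_idempotent(self, small_corpus):
        kept, _ = run_filter_cascade(small_corpus)
        again, reports = run_filter_cascade(kept)
        assert again == kept
        assert all(r.n_removed == 0 for r in reports)

    def test_order_invariance_for_exclusive_contaminants(self, small_corpus):
        rng = np.random.default_rng(0)
        canonical, _ = run_filter_cascade(small_corpus)
        names = ["retweets", "language", "bots", "high_frequency",
                 "duplicates", "promotional"]
        for _ in range(5):
            order = list(rng.permutation(names))
            survivors = list(small_corpus)
            for stage in order:
                survivors, _ = _apply_stage(stage, survivors)
            assert {r.post_id for r in survivors} == {r.post_id for r in canonical}, order


def _apply_stage(stage, records, config=FilterConfig()):
    """Apply one named stage the way the cascade would at that point."""
    if stage == "retweets":
        return filter_retweets(records)
    if stage == "language":
        return filter_language(records, config)
    if stage == "bots":
        stats = compute_account_stats(records)
        flagged = flag_bot_accounts(stats, config) if stats else set()
    elif stage == "high_frequency":
        stats = compute_account_stats(records)
        flagged = flag_high_frequency_accounts(stats, config) if len(stats) >= 2 else set()
    elif stage == "duplicates":
        return filter_duplicates(records)
    elif stage == "promotional":
        return filter_promotional(records, config)
    else:
        raise ValueError(stage)
    kept = [r for r in records if r.account_id not in flagged]
    from vapescope.corpus import StageReport

    return kept, StageReport(stage, len(records), len(records) - len(kept))


class TestTweetStreamFilterEstimator:
    def test_fit_transform_matches_cascade(self, small_corpus):
        est = TweetStreamFilter()
        survivors = est.fit_transform(small_corpus)
        expected, reports = run_filter_cascade(small_corpus)
        assert survivors == expected
        assert [r.stage_name for r in est.reports_] == [r.stage_name for r in reports]
        assert est.bot_accounts_ == {
            r.account_id for r in small_corpus if r.truth_labels["kind"] == "bot"
        }

    def test_transform_uses_fitted_account_flags(self, small_corpus):
        est = TweetStreamFilter().fit(small_corpus)
        bot_acct = next(iter(est.bot_accounts_))
        held_out = [rec("new1", acct=bot_acct), rec("new2", acct="fresh")]
        kept = est.transform(held_out)
        assert [r.post_id for r in kept] == ["new2"]

    def test_sklearn_param_interface(self):
        from sklearn.base import clone

        est = TweetStreamFilter(bot_rate_threshold=10.0)
        cloned = clone(est)
        assert cloned.get_params()["bot_rate_threshold"] == 10.0
        cloned.set_params(high_freq_multiplier=3.0)
        assert cloned._config().high_freq_multiplier == 3.0
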