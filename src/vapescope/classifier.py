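"""Rule-based location classification.

A post enters the analytic sample only if it contains at least one vaping
term; it is then assigned every location category with at least one
matching dictionary keyword.  Matching is on whole lemmatized tokens —
"car" never fires inside "care" or "carpet" — and multi-word phrases must
occur contiguously after lemmatization.

Two assignment modes are provided: ``multi_label`` (default; a post counts
in every matched category, so category percentages may sum above 100%) and
``first_match_by_table_order`` (a post counts only in the first matching
category in lexicon order).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from sklearn.base import BaseEstimator

from .corpus import Lexicon, TweetRecord, default_location_lexicon, default_vaping_lexicon
from .normalization import NormalizedPost, normalize_post, normalize_text

__all__ = [
    "ClassifiedPost",
    "KeywordMatcher",
    "KeywordLocationClassifier",
    "match_keywords",
    "classify_corpus",
]


@dataclass(frozen=True)
class ClassifiedPost:
    """A post's assigned categories and the keywords that fired."""

    post_id: str
    categories: frozenset[str]
    matched_keywords: Mapping[str, frozenset[str]]

    def __post_init__(self) -> None:
        nonempty = {c for c, kws in self.matched_keywords.items() if kws}
        if nonempty != set(self.categories):
            raise ValueError("categories must equal keys of nonempty matched_keywords")


class KeywordMatcher:
    """Token-indexed matcher for one lexicon.

    Each keyword is normalized with the same pipeline as post text, then
    indexed by its first lemma token; matching scans each token position
    once and checks only candidates sharing that head token.
    """

    def __init__(self, lexicon: Lexicon, exceptions: dict[str, str] | None = None):
        self.lexicon = lexicon
        self._index: dict[str, list[tuple[str, str, tuple[str, ...]]]] = {}
        for cat, kws in lexicon.entries.items():
            for kw in kws:
                seq = tuple(normalize_text(kw, exceptions=exceptions))
                if not seq:
                    continue
                self._index.setdefault(seq[0], []).append((cat, kw, seq))

    def match(self, tokens: Sequence[str]) -> dict[str, set[str]]:
        """Map category → set of keywords firing in the token sequence."""
        hits: dict[str, set[str]] = {}
        n = len(tokens)
        for i, tok in enumerate(tokens):
            for cat, kw, seq in self._index.get(tok, ()):
                if i + len(seq) <= n and tuple(tokens[i : i + len(seq)]) == seq:
                    hits.setdefault(cat, set()).add(kw)
        return hits

    def matches_any(self, tokens: Sequence[str]) -> bool:
        n = len(tokens)
        for i, tok in enumerate(tokens):
            for _, _, seq in self._index.get(tok, ()):
                if i + len(seq) <= n and tuple(tokens[i : i + len(seq)]) == seq:
                    return True
        return False


def match_keywords(post: NormalizedPost, lexicon: Lexicon) -> ClassifiedPost:
    """Classify one normalized post against a lexicon (multi-label)."""
    hits = KeywordMatcher(lexicon).match(post.tokens)
    return ClassifiedPost(
        post_id=post.post_id,
        categories=frozenset(hits),
        matched_keywords={c: frozenset(kws) for c, kws in hits.items()},
    )


def _first_match_reduce(cp: ClassifiedPost, lexicon: Lexicon) -> ClassifiedPost:
    for cat in lexicon.categories:
        if cat in cp.categories:
            return ClassifiedPost(
                post_id=cp.post_id,
                categories=frozenset({cat}),
                matched_keywords={cat: cp.matched_keywords[cat]},
            )
    raise ValueError("post has no categories to reduce")


def classify_corpus(
    records: Iterable[TweetRecord],
    vaping_terms: Lexicon | None = None,
    location_lexicon: Lexicon | None = None,
    mode: str = "multi_label",
    keep_hashtag_words: bool = False,
) -> list[ClassifiedPost]:
    """Gate on vaping terms, then classify; returns the analytic sample.

    Records with no vaping term, or with a vaping term but no location
    keyword, are excluded.  ``mode`` is ``multi_label`` or
    ``first_match_by_table_order``.
    """
    clf = KeywordLocationClassifier(
        vaping_lexicon=vaping_terms,
        location_lexicon=location_lexicon,
        mode=mode,
        keep_hashtag_words=keep_hashtag_words,
    ).fit()
    return clf.predict(records)


class KeywordLocationClassifier(BaseEstimator):
    """Estimator form of the gate-then-classify rule.

    ``fit`` builds the lemmatized keyword indices from the configured
    lexicons (bundled defaults when ``None``); ``predict`` returns the
    :class:`ClassifiedPost` list for the analytic sample.
    """

    def __init__(
        self,
        vaping_lexicon: Lexicon | None = None,
        location_lexicon: Lexicon | None = None,
        mode: str = "multi_label",
        keep_hashtag_words: bool = False,
    ):
        self.vaping_lexicon = vaping_lexicon
        self.location_lexicon = location_lexicon
        self.mode = mode
        self.keep_hashtag_words = keep_hashtag_words

    def fit(self, X: Iterable[TweetRecord] = (), y=None) -> "KeywordLocationClassifier":
        if self.mode not in ("multi_label", "first_match_by_table_order"):
            raise ValueError(f"unknown mode {self.mode!r}")
        vap = self.vaping_lexicon or default_vaping_lexicon()
        loc = self.location_lexicon or default_location_lexicon()
        if not vap.entries or not loc.entries:
            raise ValueError("lexicons must be nonempty")
        self.vaping_matcher_ = KeywordMatcher(vap)
        self.location_matcher_ = KeywordMatcher(loc)
        self.location_lexicon_ = loc
        return self

    def predict(self, X: Iterable[TweetRecord]) -> list[ClassifiedPost]:
        if not hasattr(self, "location_matcher_"):
            self.fit()
        out: list[ClassifiedPost] = []
        for rec in X:
            post = normalize_post(rec, keep_hashtag_words=self.keep_hashtag_words)
            if not self.vaping_matcher_.matches_any(post.tokens):
                continue
            hits = self.location_matcher_.match(post.tokens)
            if not hits:
                continue
            cp = ClassifiedPost(
                post_id=post.post_id,
                categories=frozenset(hits),
                matched_keywords={c: frozenset(k) for c, k in hits.items()},
            )
            if self.mode == "first_match_by_table_order":
                cp = _first_match_reduce(cp, self.location_lexicon_)
            out.append(cp)
        return out
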