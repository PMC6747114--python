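"""Text normalization for keyword matching.

Pipeline: NFKC-normalize, strip URLs / hashtags / @-mentions, replace
punctuation and other non-alphanumeric symbols with spaces, lowercase,
whitespace-tokenize, lemmatize each token (regular plurals to singular,
common inflections to base form via suffix rules plus a bundled exception
table).  Everything is deterministic: no models, no downloads.

Hashtags are dropped whole (marker plus tag word) by default; set
``keep_hashtag_words=True`` to keep the tag word, since streams differ in
whether hashtag words carry content.
"""

from __future__ import annotations

import re
import unicodedata
from dataclasses import dataclass, field
from functools import lru_cache
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

from sklearn.base import BaseEstimator, TransformerMixin

from .corpus import TweetRecord

__all__ = [
    "NormalizedPost",
    "TextNormalizer",
    "strip_artifacts",
    "normalize_text",
    "normalize_post",
    "lemmatize",
    "load_lemma_exceptions",
]

_URL_RE = re.compile(r"(?:https?://\S+|\bwww\.\S+|\bt\.co/\S+)", re.IGNORECASE)
_HASHTAG_RE = re.compile(r"#\w+")
_MENTION_RE = re.compile(r"@\w+")
# \w minus underscore, i.e. unicode letters and digits, survive; all else → space
_NON_WORD_RE = re.compile(r"[^\w]|_")
_WS_RE = re.compile(r"\s+")

# doubled final consonants undoubled after -ing/-ed stripping (shopping→shop);
# ss/ll/ff stay (passing→pass, telling→tell)
_DEDOUBLE = {"bb", "dd", "gg", "mm", "nn", "pp", "rr", "tt"}


def load_lemma_exceptions(path: str | Path | None = None) -> dict[str, str]:
    """Load the surface→lemma exception table (TSV, ``#`` comments)."""
    if path is None:
        path = Path(str(resources.files("vapescope.data").joinpath("lemma_exceptions.tsv")))
    table: dict[str, str] = {}
    for raw in Path(path).read_text(encoding="utf-8").splitlines():
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        surface, lemma = line.split("\t")
        table[surface.strip().lower()] = lemma.strip().lower()
    return table


@lru_cache(maxsize=1)
def _default_exceptions() -> dict[str, str]:
    return load_lemma_exceptions()


def lemmatize(token: str, exceptions: dict[str, str] | None = None) -> str:
    """Reduce one lowercase token to its base form.

    Exception table first, then suffix rules.  A rule result is accepted
    only if it is itself rule-stable, so every output is a fixed point of
    the function (required for normalization idempotence); e.g. an
    arbitrary token whose ``-s`` stripping would expose a spurious ``-ed``
    suffix is left unchanged.
    """
    exc = _default_exceptions() if exceptions is None else exceptions
    if token in exc:
        return exc[token]
    out = _suffix_rules(token)
    if out != token and _suffix_rules(out) != out:
        return token
    return out


def _suffix_rules(token: str) -> str:
    n = len(token)
    if token.endswith("ies") and n >= 5:
        return token[:-3] + "y"
    if token.endswith("sses") and n >= 5:
        return token[:-2]
    if n >= 4 and token.endswith("es") and token[-3] in "xz" or (
        n >= 5 and (token.endswith("ches") or token.endswith("shes"))
    ):
        return token[:-2]
    if (
        n >= 4
        and token.endswith("s")
        and not token.endswith(("ss", "us", "is"))
    ):
        return token[:-1]
    if token.endswith("ing") and n >= 6:
        stem = token[:-3]
        if stem[-2:] in _DEDOUBLE:
            stem = stem[:-1]
        return stem
    if token.endswith("ed") and n >= 5 and not token.endswith("eed"):
        stem = token[:-2]
        if stem[-2:] in _DEDOUBLE:
            stem = stem[:-1]
        return stem
    return token


def strip_artifacts(text: str, keep_hashtag_words: bool = False) -> str:
    """Remove URLs, hashtags and mentions; map symbols to spaces.

    Case is preserved; lowercasing happens in :func:`normalize_text`.
    """
    text = unicodedata.normalize("NFKC", text)
    text = _URL_RE.sub(" ", text)
    if keep_hashtag_words:
        text = text.replace("#", " ")
    else:
        text = _HASHTAG_RE.sub(" ", text)
    text = _MENTION_RE.sub(" ", text)
    text = _NON_WORD_RE.sub(" ", text)
    return _WS_RE.sub(" ", text).strip()


def normalize_text(
    text: str,
    exceptions: dict[str, str] | None = None,
    keep_hashtag_words: bool = False,
) -> list[str]:
    """Full normalization of one string to lemma tokens."""
    stripped = strip_artifacts(text, keep_hashtag_words=keep_hashtag_words).lower()
    return [lemmatize(tok, exceptions) for tok in stripped.split() if tok]


@dataclass(frozen=True)
class NormalizedPost:
    """A post reduced to its lemma token sequence, raw text kept for audit."""

    post_id: str
    tokens: tuple[str, ...]
    raw_text: str


def normalize_post(
    record: TweetRecord,
    exceptions: dict[str, str] | None = None,
    keep_hashtag_words: bool = False,
) -> NormalizedPost:
    """Normalize one record (see module docstring for the pipeline)."""
    tokens = normalize_text(
        record.text, exceptions=exceptions, keep_hashtag_words=keep_hashtag_words
    )
    return NormalizedPost(post_id=record.post_id, tokens=tuple(tokens), raw_text=record.text)


class TextNormalizer(BaseEstimator, TransformerMixin):
    """Stateless transformer: raw strings or records → lemma token lists.

    Parameters
    ----------
    keep_hashtag_words:
        Keep the word of a hashtag (dropping only ``#``) instead of the
        default of removing the whole hashtag token.
    exceptions_path:
        Optional path to a user lemma-exception TSV replacing the bundled
        table.
    """

    def __init__(self, keep_hashtag_words: bool = False, exceptions_path: str | None = None):
        self.keep_hashtag_words = keep_hashtag_words
        self.exceptions_path = exceptions_path

    def fit(self, X: Iterable = (), y=None) -> "TextNormalizer":
        self.exceptions_ = (
            _default_exceptions()
            if self.exceptions_path is None
            else load_lemma_exceptions(self.exceptions_path)
        )
        return self

    def transform(self, X: Sequence) -> list[list[str]]:
        if not hasattr(self, "exceptions_"):
            self.fit()
        out = []
        for item in X:
            text = item.text if isinstance(item, TweetRecord) else item
            out.append(
                normalize_text(
                    text,
                    exceptions=self.exceptions_,
                    keep_hashtag_words=self.keep_hashtag_words,
                )
            )
        return out
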