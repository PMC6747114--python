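"""Core domain types and corpus/lexicon IO.

A corpus is a JSON-lines file (UTF-8, one post per line) with keys
``post_id``, ``account_id``, ``text``, ``lang``, ``created_at`` (ISO-8601),
``is_retweet`` and, on synthetic corpora only, ``truth_labels``.  Unknown
keys are preserved opaquely on round-trip, since real stream exports carry
many fields the pipeline does not use.

A lexicon is a plain-text file: ``[Category Name]`` opens a category, each
following non-blank line is one keyword or phrase, ``#`` starts a comment.
Plain text was chosen over JSON because location dictionaries are hand
curated.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from datetime import datetime, timezone
from importlib import resources
from pathlib import Path
from typing import Iterable, Iterator, Mapping

logger = logging.getLogger(__name__)

__all__ = [
    "TweetRecord",
    "Lexicon",
    "StageReport",
    "CorpusFormatError",
    "LexiconFormatError",
    "read_corpus",
    "write_corpus",
    "load_lexicon",
    "save_lexicon",
    "default_location_lexicon",
    "default_vaping_lexicon",
]

#: JSONL keys owned by the record schema (everything else is ``extra``).
_CORE_KEYS = ("post_id", "account_id", "text", "lang", "created_at", "is_retweet")

_RETWEET_PREFIX = "RT @"


class CorpusFormatError(ValueError):
    """A corpus line is malformed or missing a required field."""


class LexiconFormatError(ValueError):
    """A lexicon file violates the documented format."""


@dataclass
class TweetRecord:
    """One raw stream item: text plus the account metadata filters need.

    ``truth_labels`` is present only on synthetic corpora, where it records
    the post's planted contaminant kind (or ``"clean"``) and, for clean
    posts, the planted location categories.
    """

    post_id: str
    account_id: str
    text: str
    lang: str = "und"
    created_at: datetime = field(
        default_factory=lambda: datetime(2018, 1, 1, tzinfo=timezone.utc)
    )
    is_retweet: bool = False
    truth_labels: dict | None = None
    extra: dict = field(default_factory=dict)

    @property
    def retweet(self) -> bool:
        """Retweet status: the flag when set, else inferred from "RT @"."""
        return self.is_retweet or self.text.startswith(_RETWEET_PREFIX)

    def to_json_dict(self) -> dict:
        d = {
            "post_id": self.post_id,
            "account_id": self.account_id,
            "text": self.text,
            "lang": self.lang,
            "created_at": self.created_at.isoformat(),
            "is_retweet": self.is_retweet,
        }
        if self.truth_labels is not None:
            d["truth_labels"] = self.truth_labels
        d.update(self.extra)
        return d

    @classmethod
    def from_json_dict(cls, d: Mapping) -> "TweetRecord":
        missing = [k for k in ("post_id", "account_id", "text", "created_at") if k not in d]
        if missing:
            raise CorpusFormatError(f"record missing required field(s): {missing}")
        extra = {k: v for k, v in d.items() if k not in _CORE_KEYS and k != "truth_labels"}
        created = d["created_at"]
        if isinstance(created, str):
            created = datetime.fromisoformat(created.replace("Z", "+00:00"))
        return cls(
            post_id=str(d["post_id"]),
            account_id=str(d["account_id"]),
            text=d["text"],
            lang=d.get("lang", "und") or "und",
            created_at=created,
            is_retweet=bool(d.get("is_retweet", False)),
            truth_labels=d.get("truth_labels"),
            extra=extra,
        )


@dataclass(frozen=True)
class StageReport:
    """Attrition accounting for one filter stage."""

    stage_name: str
    n_in: int
    n_removed: int

    def __post_init__(self) -> None:
        if self.n_in < 0 or self.n_removed < 0 or self.n_removed > self.n_in:
            raise ValueError(
                f"invalid stage counts: n_in={self.n_in}, n_removed={self.n_removed}"
            )

    @property
    def n_out(self) -> int:
        return self.n_in - self.n_removed


@dataclass(frozen=True)
class Lexicon:
    """A named keyword dictionary mapping categories to keyword sets.

    ``entries`` preserves category order as listed in the source file;
    keywords are lowercase, stripped, deduplicated, in first-seen order.
    """

    name: str
    entries: Mapping[str, tuple[str, ...]]
    version: str = "1"

    def __post_init__(self) -> None:
        for cat, kws in self.entries.items():
            if not kws:
                raise LexiconFormatError(f"category {cat!r} has no keywords")
            for kw in kws:
                if not kw or kw != kw.strip() or kw != kw.lower():
                    raise LexiconFormatError(
                        f"keyword {kw!r} in {cat!r} must be lowercase, "
                        "stripped and nonempty"
                    )

    @property
    def categories(self) -> tuple[str, ...]:
        return tuple(self.entries)

    def all_keywords(self) -> set[str]:
        return {kw for kws in self.entries.values() for kw in kws}


# ---------------------------------------------------------------------------
# JSON-lines corpus IO

def iter_corpus(path: str | Path, strict: bool = False) -> Iterator[TweetRecord]:
    """Stream records from a JSONL corpus file.

    In strict mode a malformed line raises :class:`CorpusFormatError`;
    otherwise it is skipped and counted in the log.
    """
    path = Path(path)
    n_skipped = 0
    with path.open("r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            try:
                obj = json.loads(line)
                if not isinstance(obj, dict):
                    raise CorpusFormatError("line is not a JSON object")
                yield TweetRecord.from_json_dict(obj)
            except (json.JSONDecodeError, CorpusFormatError, ValueError) as exc:
                if strict:
                    raise CorpusFormatError(f"{path}:{lineno}: {exc}") from exc
                n_skipped += 1
    if n_skipped:
        logger.warning("read_corpus(%s): skipped %d malformed line(s)", path, n_skipped)


def read_corpus(path: str | Path, strict: bool = False) -> list[TweetRecord]:
    """Read a JSONL corpus into a list, in file order."""
    return list(iter_corpus(path, strict=strict))


def write_corpus(records: Iterable[TweetRecord], path: str | Path) -> int:
    """Write records as JSONL (one object per line); returns the count."""
    path = Path(path)
    n = 0
    with path.open("w", encoding="utf-8") as fh:
        for rec in records:
            fh.write(json.dumps(rec.to_json_dict(), ensure_ascii=False))
            fh.write("\n")
            n += 1
    return n


# ---------------------------------------------------------------------------
# Lexicon IO

def load_lexicon(path: str | Path, name: str | None = None) -> Lexicon:
    """Parse a plain-text lexicon file (see module docstring for format)."""
    path = Path(path)
    entries: dict[str, list[str]] = {}
    current: str | None = None
    with path.open("r", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            if line.startswith("[") and line.endswith("]"):
                cat = line[1:-1].strip()
                if not cat:
                    raise LexiconFormatError(f"{path}:{lineno}: empty category name")
                if cat in entries:
                    raise LexiconFormatError(f"{path}:{lineno}: duplicate category {cat!r}")
                entries[cat] = []
                current = cat
            else:
                if current is None:
                    raise LexiconFormatError(
                        f"{path}:{lineno}: keyword {line!r} before any category header"
                    )
                kw = " ".join(line.lower().split())
                if kw not in entries[current]:
                    entries[current].append(kw)
    frozen = {cat: tuple(kws) for cat, kws in entries.items()}
    return Lexicon(name=name or path.stem, entries=frozen)


def save_lexicon(lexicon: Lexicon, path: str | Path) -> None:
    """Serialize a lexicon back to the plain-text format (load inverts it)."""
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        for cat, kws in lexicon.entries.items():
            fh.write(f"[{cat}]\n")
            for kw in kws:
                fh.write(f"{kw}\n")
            fh.write("\n")


def _bundled(fname: str) -> Path:
    return Path(str(resources.files("vapescope.data").joinpath(fname)))


def default_location_lexicon() -> Lexicon:
    """The bundled 11-category location dictionary."""
    return load_lexicon(_bundled("locations.lex"), name="locations")


def default_vaping_lexicon() -> Lexicon:
    """The bundled 26-term vaping gate."""
    return load_lexicon(_bundled("vaping_terms.lex"), name="vaping")
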