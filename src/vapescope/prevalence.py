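"""Category-prevalence tables over the analytic sample.

Percentages are per post (a multi-labeled post counts once in each of its
categories, so the percent column may sum above 100).  A Wilson 95%
interval accompanies each row; it is an addition of this package beyond
the plain percentages such tables usually print, and is marked as such in
rendered output.  Rows sort by descending percent with Miscellaneous
listed last, matching the reporting convention for this kind of table.
"""

from __future__ import annotations

import json
from collections import Counter
from dataclasses import dataclass
from decimal import ROUND_HALF_EVEN, Decimal
from typing import Iterable, Mapping, Sequence

from statsmodels.stats.proportion import proportion_confint

from .classifier import ClassifiedPost

__all__ = [
    "PrevalenceRow",
    "PrevalenceTable",
    "compute_prevalence",
    "render_report",
    "table_from_json",
    "round_percent",
]

MISC_CATEGORY = "Miscellaneous"


def round_percent(value: float, ndigits: int = 1) -> float:
    """Round-half-even to ``ndigits`` decimals (17.94 → 17.9, 17.85 → 17.8)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_EVEN))


@dataclass(frozen=True)
class PrevalenceRow:
    category: str
    n_posts_matched: int
    percent: float
    ci_low: float
    ci_high: float


@dataclass(frozen=True)
class PrevalenceTable:
    """Per-category counts/percentages plus sample-level totals.

    ``top_keywords`` lists, per category, the most frequently fired
    keywords (for the illustrative-keywords column of rendered reports).
    """

    rows: tuple[PrevalenceRow, ...]
    n_total: int
    n_users: int
    top_keywords: Mapping[str, tuple[str, ...]] | None = None

    def counts(self) -> dict[str, int]:
        return {r.category: r.n_posts_matched for r in self.rows}

    def percents(self) -> dict[str, float]:
        return {r.category: r.percent for r in self.rows}


def _sort_rows(rows: list[PrevalenceRow]) -> tuple[PrevalenceRow, ...]:
    main = [r for r in rows if r.category != MISC_CATEGORY]
    misc = [r for r in rows if r.category == MISC_CATEGORY]
    main.sort(key=lambda r: -r.percent)
    return tuple(main + misc)


def build_table(
    counts: Mapping[str, int],
    n_total: int,
    n_users: int,
    top_keywords: Mapping[str, tuple[str, ...]] | None = None,
    alpha: float = 0.05,
) -> PrevalenceTable:
    """Assemble a table from per-category post counts."""
    rows = []
    for cat, n in counts.items():
        if n_total > 0:
            lo, hi = proportion_confint(n, n_total, alpha=alpha, method="wilson")
            pct = 100.0 * n / n_total
        else:
            lo = hi = pct = 0.0
        rows.append(PrevalenceRow(cat, n, pct, 100.0 * lo, 100.0 * hi))
    return PrevalenceTable(
        rows=_sort_rows(rows), n_total=n_total, n_users=n_users, top_keywords=top_keywords
    )


def compute_prevalence(
    classified: Sequence[ClassifiedPost],
    account_map: Mapping[str, str],
    categories: Iterable[str] | None = None,
    top_k: int = 4,
) -> PrevalenceTable:
    """Prevalence of each category over the analytic sample.

    ``account_map`` maps post_id → account_id (for the distinct-user
    count).  ``categories``, when given, fixes the set of reported rows
    (zero-count rows included); otherwise only observed categories appear.
    """
    if not classified:
        raise ValueError("compute_prevalence requires a nonempty analytic sample")
    counts: Counter[str] = Counter()
    kw_counts: dict[str, Counter[str]] = {}
    for cp in classified:
        if not cp.categories:
            raise ValueError(f"post {cp.post_id} has no categories")
        for cat in cp.categories:
            counts[cat] += 1
            kw_counts.setdefault(cat, Counter()).update(cp.matched_keywords[cat])
    if categories is not None:
        counts = Counter({c: counts.get(c, 0) for c in categories})
    n_total = len(classified)
    n_users = len({account_map[cp.post_id] for cp in classified})
    top = {
        cat: tuple(kw for kw, _ in kw_counts.get(cat, Counter()).most_common(top_k))
        for cat in counts
    }
    return build_table(counts, n_total, n_users, top_keywords=top)


# ---------------------------------------------------------------------------
# Rendering

def _row_dicts(table: PrevalenceTable) -> list[dict]:
    out = []
    for i, r in enumerate(table.rows, start=1):
        kws = (table.top_keywords or {}).get(r.category, ())
        out.append(
            {
                "No.": i,
                "Locations": r.category,
                "Illustrative Keywords": ", ".join(kws),
                "%": f"{round_percent(r.percent):.1f}",
                "Wilson 95% CI": (
                    f"{round_percent(r.ci_low):.1f}-{round_percent(r.ci_high):.1f}"
                ),
                "n": r.n_posts_matched,
            }
        )
    return out


def render_report(table: PrevalenceTable, format: str = "markdown") -> str:
    """Render the table as ``csv``, ``markdown`` or ``json`` text."""
    if format == "json":
        payload = {
            "n_total": table.n_total,
            "n_users": table.n_users,
            "rows": [
                {
                    "category": r.category,
                    "n_posts_matched": r.n_posts_matched,
                    "percent": r.percent,
                    "ci_low": r.ci_low,
                    "ci_high": r.ci_high,
                    "top_keywords": list((table.top_keywords or {}).get(r.category, ())),
                }
                for r in table.rows
            ],
        }
        return json.dumps(payload, indent=2, ensure_ascii=False)
    rows = _row_dicts(table)
    header = ["No.", "Locations", "Illustrative Keywords", "%", "Wilson 95% CI", "n"]
    if format == "csv":
        lines = [",".join(header)]
        for row in rows:
            lines.append(
                ",".join(
                    f'"{row[h]}"' if ("," in str(row[h])) else str(row[h]) for h in header
                )
            )
        lines.append(f'"Total posts",{table.n_total}')
        lines.append(f'"Distinct users",{table.n_users}')
        return "\n".join(lines) + "\n"
    if format == "markdown":
        lines = ["| " + " | ".join(header) + " |", "|" + "---|" * len(header)]
        for row in rows:
            lines.append("| " + " | ".join(str(row[h]) for h in header) + " |")
        lines.append("")
        lines.append(f"Analytic sample: {table.n_total} posts from {table.n_users} users.")
        lines.append("(Wilson 95% intervals are an addition of this implementation.)")
        return "\n".join(lines) + "\n"
    raise ValueError(f"unknown report format {format!r}")


def table_from_json(text: str) -> PrevalenceTable:
    """Inverse of ``render_report(..., format='json')``."""
    d = json.loads(text)
    rows = tuple(
        PrevalenceRow(
            r["category"], r["n_posts_matched"], r["percent"], r["ci_low"], r["ci_high"]
        )
        for r in d["rows"]
    )
    top = {r["category"]: tuple(r.get("top_keywords", ())) for r in d["rows"]}
    return PrevalenceTable(rows=rows, n_total=d["n_total"], n_users=d["n_users"], top_keywords=top)
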