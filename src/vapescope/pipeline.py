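"""End-to-end orchestration: read → filter cascade → gate → classify → report.

Given one :class:`PipelineConfig`, :func:`run_pipeline` produces the
attrition CSV, the classified-post JSONL, prevalence reports in the
configured formats, and a run manifest with a config hash.  All outputs
are deterministic for a given config and input (no wall-clock content), so
reruns are byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from .classifier import ClassifiedPost, classify_corpus
from .corpus import (
    CorpusFormatError,
    StageReport,
    load_lexicon,
    read_corpus,
)
from .filtering import DEFAULT_PROMO_TERMS, FilterConfig, run_filter_cascade
from .prevalence import PrevalenceTable, compute_prevalence, render_report

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline", "write_attrition_csv"]

_FORMAT_EXT = {"markdown": "md", "csv": "csv", "json": "json"}


class PipelineConfigError(ValueError):
    """The pipeline configuration is invalid or unresolvable."""


@dataclass
class PipelineConfig:
    """Everything one pipeline run needs, serializable losslessly to YAML."""

    input_path: str
    output_dir: str
    vaping_lexicon_path: str | None = None
    location_lexicon_path: str | None = None
    classifier_mode: str = "multi_label"
    keep_hashtag_words: bool = False
    report_formats: tuple[str, ...] = ("markdown", "csv", "json")
    strict_read: bool = False
    allowed_langs: tuple[str, ...] = ("en",)
    bot_rate_threshold: float = 50.0
    high_freq_multiplier: float = 2.0
    promo_terms: tuple[str, ...] = tuple(sorted(DEFAULT_PROMO_TERMS))
    promo_requires_url: bool = True

    def filter_config(self) -> FilterConfig:
        return FilterConfig(
            allowed_langs=frozenset(self.allowed_langs),
            bot_rate_threshold=self.bot_rate_threshold,
            high_freq_multiplier=self.high_freq_multiplier,
            promo_terms=frozenset(self.promo_terms),
            promo_requires_url=self.promo_requires_url,
        )

    def to_yaml(self) -> str:
        return yaml.safe_dump(
            {k: list(v) if isinstance(v, tuple) else v for k, v in asdict(self).items()},
            sort_keys=True,
        )

    @classmethod
    def from_yaml(cls, text: str) -> "PipelineConfig":
        try:
            raw = yaml.safe_load(text) or {}
            known = {f for f in cls.__dataclass_fields__}
            unknown = set(raw) - known
            if unknown:
                raise PipelineConfigError(f"unknown config key(s): {sorted(unknown)}")
            for key in ("report_formats", "allowed_langs", "promo_terms"):
                if key in raw:
                    raw[key] = tuple(raw[key])
            return cls(**raw)
        except (TypeError, yaml.YAMLError) as exc:
            raise PipelineConfigError(str(exc)) from exc

    def validate(self) -> None:
        if not Path(self.input_path).exists():
            raise PipelineConfigError(f"input corpus not found: {self.input_path}")
        for p in (self.vaping_lexicon_path, self.location_lexicon_path):
            if p is not None and not Path(p).exists():
                raise PipelineConfigError(f"lexicon not found: {p}")
        if self.classifier_mode not in ("multi_label", "first_match_by_table_order"):
            raise PipelineConfigError(f"unknown classifier_mode {self.classifier_mode!r}")
        bad = [f for f in self.report_formats if f not in _FORMAT_EXT]
        if bad:
            raise PipelineConfigError(f"unknown report format(s): {bad}")


def write_attrition_csv(reports: list[StageReport], path: Path) -> None:
    df = pd.DataFrame(
        [
            {"stage": r.stage_name, "n_in": r.n_in, "n_removed": r.n_removed, "n_out": r.n_out}
            for r in reports
        ]
    )
    df.to_csv(path, index=False)


def _classified_jsonl(classified: list[ClassifiedPost]) -> str:
    lines = []
    for cp in classified:
        lines.append(
            json.dumps(
                {
                    "post_id": cp.post_id,
                    "categories": sorted(cp.categories),
                    "matched_keywords": {
                        c: sorted(cp.matched_keywords[c]) for c in sorted(cp.categories)
                    },
                },
                ensure_ascii=False,
                sort_keys=True,
            )
        )
    return "\n".join(lines) + ("\n" if lines else "")


def run_pipeline(
    config: PipelineConfig,
) -> tuple[PrevalenceTable, list[StageReport], dict[str, Path]]:
    """Execute the full pipeline; returns (table, stage reports, output paths)."""
    config.validate()
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)

    records = read_corpus(config.input_path, strict=config.strict_read)
    logger.info("read %d records from %s", len(records), config.input_path)

    survivors, reports = run_filter_cascade(records, config.filter_config())
    for rep in reports:
        logger.info("stage %-14s in=%d removed=%d out=%d",
                    rep.stage_name, rep.n_in, rep.n_removed, rep.n_out)

    vap = load_lexicon(config.vaping_lexicon_path) if config.vaping_lexicon_path else None
    loc = load_lexicon(config.location_lexicon_path) if config.location_lexicon_path else None
    classified = classify_corpus(
        survivors,
        vaping_terms=vap,
        location_lexicon=loc,
        mode=config.classifier_mode,
        keep_hashtag_words=config.keep_hashtag_words,
    )
    if not classified:
        raise CorpusFormatError(
            "analytic sample is empty: no surviving post passed the vaping gate "
            "with a location keyword"
        )
    account_map = {r.post_id: r.account_id for r in survivors}
    table = compute_prevalence(classified, account_map)

    outputs: dict[str, Path] = {}
    attrition = outdir / "attrition.csv"
    write_attrition_csv(reports, attrition)
    outputs["attrition"] = attrition

    classified_path = outdir / "classified.jsonl"
    classified_path.write_text(_classified_jsonl(classified), encoding="utf-8")
    outputs["classified"] = classified_path

    for fmt in config.report_formats:
        path = outdir / f"report.{_FORMAT_EXT[fmt]}"
        path.write_text(render_report(table, fmt), encoding="utf-8")
        outputs[f"report_{fmt}"] = path

    config_yaml = config.to_yaml()
    manifest = {
        "config": yaml.safe_load(config_yaml),
        "config_sha256": hashlib.sha256(config_yaml.encode()).hexdigest(),
        "stages": [
            {"stage": r.stage_name, "n_in": r.n_in, "n_removed": r.n_removed, "n_out": r.n_out}
            for r in reports
        ],
        "n_analytic": table.n_total,
        "n_users": table.n_users,
    }
    manifest_path = outdir / "run.json"
    manifest_path.write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n", encoding="utf-8"
    )
    outputs["manifest"] = manifest_path
    return table, reports, outputs
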