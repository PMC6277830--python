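"""End-to-end orchestration: filter -> normalize -> ngrams -> expand -> classify.

One YAML config drives a run; every stage writes its artifact under the output
directory and the run ends with a machine-readable manifest whose per-stage
counts chain consistently (each stage's input count equals the previous
stage's output count).
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Optional

import yaml

import hookahscope
from hookahscope.classify import classify_corpus, overlap_matrix, prevalence_report, report_to_files, write_assignments
from hookahscope.embedding import EmbeddingConfig, train_embeddings
from hookahscope.expansion import propose_candidates, write_worksheet
from hookahscope.filtering import BotPolicy, run_filter_chain
from hookahscope.lexicon import load_default_lexicons, read_lexicons
from hookahscope.ngrams import count_ngrams, export_wordcloud_data
from hookahscope.normalize import NormalizationConfig, normalize_corpus
from hookahscope.records import Corpus, read_corpus, write_corpus

logger = logging.getLogger("hookahscope.pipeline")

STAGES = ("filter", "normalize", "ngrams", "expand", "classify")


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunConfig:
    """Configuration of one full pipeline run."""

    input_path: Path
    output_dir: Path
    bot_policy: BotPolicy = field(default_factory=BotPolicy)
    normalization: NormalizationConfig = field(default_factory=NormalizationConfig)
    embedding: EmbeddingConfig = field(default_factory=EmbeddingConfig)
    lexicon_path: Optional[Path] = None  # None -> packaged default set
    stages: tuple[str, ...] = STAGES
    top_k: int = 20
    min_cosine: float = 0.5

    def __post_init__(self) -> None:
        bad = set(self.stages) - set(STAGES)
        if bad:
            raise ValueError(f"unknown stage(s): {sorted(bad)}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw: dict[str, Any] = yaml.safe_load(Path(path).read_text("utf-8")) or {}
        kwargs: dict[str, Any] = {
            "input_path": Path(raw["input"]),
            "output_dir": Path(raw["output_dir"]),
        }
        if "bot_policy" in raw:
            kwargs["bot_policy"] = BotPolicy(**raw["bot_policy"])
        if "embedding" in raw:
            kwargs["embedding"] = EmbeddingConfig(**raw["embedding"])
        if "lexicons" in raw and raw["lexicons"]:
            kwargs["lexicon_path"] = Path(raw["lexicons"])
        if "stages" in raw:
            kwargs["stages"] = tuple(raw["stages"])
        for key in ("top_k", "min_cosine"):
            if key in raw:
                kwargs[key] = raw[key]
        return cls(**kwargs)


@dataclass
class RunManifest:
    """Audit trail of one run: configuration snapshot plus per-stage counts."""

    config: dict
    stage_counts: dict[str, dict] = field(default_factory=dict)
    skipped_stages: list[str] = field(default_factory=list)
    outputs: dict[str, str] = field(default_factory=dict)
    package_version: str = hookahscope.__version__
    started_at: str = ""
    finished_at: str = ""

    def to_json(self) -> str:
        return json.dumps(self.__dict__, indent=2, default=str)


def _now() -> str:
    return time.strftime("%Y-%m-%dT%H:%M:%SZ", time.gmtime())


def run_pipeline(config: RunConfig) -> RunManifest:
    """Execute the enabled stages in fixed order and write the manifest.

    Any stage failure aborts with :class:`StageError` naming the stage;
    artifacts of completed stages are left in place for debugging.
    """
    out = config.output_dir
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(
        config={
            "input": str(config.input_path),
            "output_dir": str(out),
            "bot_policy": {"threshold": config.bot_policy.threshold,
                           "missing_score_action": config.bot_policy.missing_score_action},
            "embedding": config.embedding.__dict__,
            "lexicons": str(config.lexicon_path) if config.lexicon_path else "packaged-default",
            "stages": list(config.stages),
        },
        started_at=_now(),
    )
    manifest.skipped_stages = [s for s in STAGES if s not in config.stages]

    corpus = read_corpus(config.input_path)
    logger.info("loaded %d records from %s", len(corpus), config.input_path)
    lexicons = read_lexicons(config.lexicon_path) if config.lexicon_path else load_default_lexicons()

    filtered: Corpus = corpus
    if "filter" in config.stages:
        try:
            filtered, report = run_filter_chain(corpus, policy=config.bot_policy)
        except Exception as exc:  # pragma: no cover - defensive
            raise StageError("filter", exc) from exc
        manifest.stage_counts["filter"] = {"n_in": len(corpus), **report.to_dict(),
                                           "n_out": len(filtered)}
        path = write_corpus(filtered, out / "filtered.jsonl")
        manifest.outputs["filter"] = str(path)
        (out / "filter_report.json").write_text(json.dumps(report.to_dict(), indent=2), "utf-8")
        logger.info("filter: %d -> %d", len(corpus), len(filtered))

    normalized = None
    if "normalize" in config.stages:
        try:
            normalized = normalize_corpus(filtered, config.normalization)
        except Exception as exc:  # pragma: no cover - defensive
            raise StageError("normalize", exc) from exc
        path = out / "normalized.jsonl"
        with path.open("w", encoding="utf-8") as fh:
            for tw in normalized:
                fh.write(json.dumps({"tweet_id": tw.tweet_id, "tokens": list(tw.tokens),
                                     "mention_count": tw.mention_count}) + "\n")
        manifest.stage_counts["normalize"] = {"n_in": len(filtered), "n_out": len(normalized)}
        manifest.outputs["normalize"] = str(path)
        logger.info("normalize: %d tweets tokenized", len(normalized))

    if normalized is not None and "ngrams" in config.stages:
        try:
            for n, name in ((1, "unigrams.tsv"), (2, "bigrams.tsv")):
                table = count_ngrams(normalized, n=n)
                export_wordcloud_data(table, out / name)
                manifest.stage_counts.setdefault("ngrams", {})[f"n{n}_distinct"] = len(table)
                manifest.outputs[f"ngrams_n{n}"] = str(out / name)
        except Exception as exc:  # pragma: no cover - defensive
            raise StageError("ngrams", exc) from exc
        manifest.stage_counts["ngrams"]["n_in"] = len(normalized)

    if normalized is not None and "expand" in config.stages:
        try:
            model = train_embeddings(normalized, config.embedding)
            candidates = propose_candidates(model, lexicons,
                                            top_k=config.top_k, min_cosine=config.min_cosine)
        except Exception as exc:
            raise StageError("expand", exc) from exc
        path = write_worksheet(candidates, out / "expansion_worksheet.tsv")
        manifest.stage_counts["expand"] = {
            "n_in": len(normalized),
            "vocabulary": len(model),
            "n_candidates": sum(len(c.rows) for c in candidates),
        }
        manifest.outputs["expand"] = str(path)
        logger.info("expand: %d candidates proposed", manifest.stage_counts["expand"]["n_candidates"])

    if normalized is not None and "classify" in config.stages:
        try:
            assignments = classify_corpus(normalized, lexicons)
            report = prevalence_report(assignments, corpus_size=len(normalized),
                                       topic_names=lexicons.topic_names)
            matrix = overlap_matrix(assignments, topic_names=lexicons.topic_names)
        except Exception as exc:  # pragma: no cover - defensive
            raise StageError("classify", exc) from exc
        write_assignments(assignments, out / "assignments.jsonl")
        paths = report_to_files(report, matrix, out / "topics")
        manifest.stage_counts["classify"] = {
            "n_in": len(normalized),
            "n_covered": report.coverage_count,
            "coverage_percent": report.coverage_percent,
        }
        manifest.outputs["classify"] = ", ".join(str(p) for p in paths)
        logger.info("classify: coverage %.2f%%", report.coverage_percent)

    manifest.finished_at = _now()
    (out / "manifest.json").write_text(manifest.to_json() + "\n", "utf-8")
    return manifest
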