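"""End-to-end discriminator-report pipeline.

``run_pipeline`` chains the stages: read counts -> normalize -> bootstrap
coefficient inference -> alpha-level selection -> optional structural-level
filter -> cognitive-domain report -> cross-validated classifier metrics.
Every artifact embeds the full parameterization (seed, B, penalty, alpha,
package version), so any output file can be regenerated from its own
config stanza; identical configs produce byte-identical CSV/JSON.
"""

from __future__ import annotations

import json
import logging
import sys
from dataclasses import asdict, dataclass, field
from pathlib import Path

from . import __version__
from .bootstrap import (
    BootstrapResult,
    DEFAULT_ALPHA,
    DEFAULT_B,
    LevelFilterResult,
    SelectedTag,
    bootstrap_coefficients,
    filter_structural_level,
    select_discriminators,
    write_results_table,
)
from .corpus import map_to_domains, normalize_features, read_counts_table
from .model import ClassifierMetrics, cross_validate
from .scheme import TagScheme, default_scheme

logger = logging.getLogger("tagdisc")


@dataclass(frozen=True)
class PipelineConfig:
    """Serializable parameterization of one pipeline run."""

    counts: str
    out_dir: str
    scheme: str | None = None  # None -> packaged default scheme
    B: int = DEFAULT_B
    penalty: float = 1.0
    alpha: float = DEFAULT_ALPHA
    k: int = 5
    seed: int = 0
    level: str = "all"

    def __post_init__(self) -> None:
        if self.B < 1:
            raise ValueError("B must be >= 1")
        if self.penalty < 0:
            raise ValueError("penalty must be >= 0")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if self.k < 2:
            raise ValueError("k must be >= 2")
        if self.level not in ("all", "clause_phrase"):
            raise ValueError(f"unknown level {self.level!r}")

    @classmethod
    def from_json(cls, path: str | Path, **overrides) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            payload = json.load(fh)
        payload.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**payload)

    def stamp(self) -> dict:
        meta = asdict(self)
        meta.pop("out_dir")  # output location is not part of the analysis
        meta["version"] = __version__
        return meta


@dataclass(frozen=True)
class ReportBundle:
    """In-memory results plus the paths of the written artifacts."""

    result: BootstrapResult
    selected: tuple[SelectedTag, ...]
    level_filtered: LevelFilterResult
    domain_report: dict[str, list[str]]
    metrics: ClassifierMetrics
    paths: dict[str, Path]


def _setup_logging(log_path: Path) -> logging.Handler:
    handler = logging.FileHandler(log_path, mode="w", encoding="utf-8")
    handler.setFormatter(logging.Formatter("%(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    if not any(isinstance(h, logging.StreamHandler) for h in logger.handlers):
        logger.addHandler(logging.StreamHandler(sys.stderr))
    return handler


def run_pipeline(config: PipelineConfig) -> ReportBundle:
    """Execute all stages and write the report bundle to ``config.out_dir``."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = _setup_logging(out / "run.log")
    try:
        scheme = (
            default_scheme() if config.scheme is None
            else TagScheme.from_json(config.scheme)
        )
        stage = "read_counts"
        try:
            records = read_counts_table(config.counts, scheme)
            logger.info("read %d speakers, %d tags", len(records), scheme.n_tags)

            stage = "normalize"
            features = normalize_features(records, scheme)

            stage = "bootstrap"
            result = bootstrap_coefficients(
                features,
                B=config.B,
                penalty=config.penalty,
                seed=config.seed,
                alpha=config.alpha,
                progress=lambda done, total: logger.info(
                    "bootstrap %d/%d resamples", done, total
                ),
            )
            logger.info("bootstrap done; %d degenerate resamples redrawn",
                        result.n_failed)

            stage = "select"
            selected = select_discriminators(result, config.alpha)
            logger.info("%d discriminators at alpha=%g", len(selected), config.alpha)

            stage = "level_filter"
            filtered = filter_structural_level(selected, scheme, config.level)

            stage = "domain_report"
            domains = map_to_domains([s.tag for s in filtered.selected], scheme)

            stage = "cross_validate"
            metrics = cross_validate(
                features, k=config.k, penalty=config.penalty, seed=config.seed
            )
            logger.info(
                "pooled %d-fold CV: accuracy=%.3f precision=%.3f "
                "sensitivity=%.3f specificity=%.3f",
                config.k, metrics.accuracy, metrics.precision,
                metrics.sensitivity, metrics.specificity,
            )
        except Exception as exc:
            raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc

        paths = {
            "results": out / "results.csv",
            "metrics": out / "metrics.json",
            "domains": out / "domain_report.json",
            "log": out / "run.log",
        }
        write_results_table(result, paths["results"])
        _dump_json(
            paths["metrics"],
            {"config": config.stamp(), "metrics": metrics.to_dict()},
        )
        _dump_json(
            paths["domains"],
            {
                "config": config.stamp(),
                "n_selected": len(selected),
                "selected": [s._asdict() for s in selected],
                "level": config.level,
                "unclassified": [s.tag for s in filtered.unclassified],
                "domains": domains,
            },
        )
        return ReportBundle(
            result=result,
            selected=tuple(selected),
            level_filtered=filtered,
            domain_report=domains,
            metrics=metrics,
            paths=paths,
        )
    finally:
        logger.removeHandler(handler)
        handler.close()


def _dump_json(path: Path, payload: dict) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(payload, fh, indent=1, ensure_ascii=False, allow_nan=True)
        fh.write("\n")
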