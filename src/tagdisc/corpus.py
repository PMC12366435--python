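"""Speaker-by-tag count tables and per-word frequency normalization.

The pipeline's input is a tab-separated table with one row per speaker:
``speaker_id``, ``group`` (diagnostic label), ``word_count`` (total
words/morphemes produced), then one integer count column per tag in scheme
order. Normalization divides each tag count by the speaker's word count,
giving the proportional use of each linguistic resource independent of
speech quantity.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .scheme import COGNITIVE_DOMAINS, TagScheme

#: Default diagnostic-group vocabulary; the first label is the positive class.
POSITIVE_LABEL = "ASD"
NEGATIVE_LABEL = "non-ASD"

_META_COLUMNS = ("speaker_id", "group", "word_count")


@dataclass(frozen=True)
class SpeakerRecord:
    """One participant: group label, words produced, per-tag counts."""

    speaker_id: str
    group: str
    word_count: int
    counts: np.ndarray  # int64, length == scheme.n_tags

    def __post_init__(self) -> None:
        if self.word_count < 1:
            raise ValueError(
                f"speaker {self.speaker_id!r}: word_count must be >= 1, "
                f"got {self.word_count}"
            )
        counts = np.asarray(self.counts, dtype=np.int64)
        if counts.ndim != 1:
            raise ValueError("counts must be a 1-D integer vector")
        if (counts < 0).any():
            raise ValueError(f"speaker {self.speaker_id!r}: negative tag count")
        object.__setattr__(self, "counts", counts)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, SpeakerRecord):
            return NotImplemented
        return (
            self.speaker_id == other.speaker_id
            and self.group == other.group
            and self.word_count == other.word_count
            and np.array_equal(self.counts, other.counts)
        )


@dataclass(frozen=True)
class FeatureMatrix:
    """Normalized per-word tag frequencies ``x`` with binary labels ``y``."""

    x: np.ndarray  # (n, m) float64, x[i, j] = counts[i, j] / word_count[i]
    y: np.ndarray  # (n,) int8, 1 = positive class
    tag_names: tuple[str, ...]
    speaker_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        x = np.asarray(self.x, dtype=np.float64)
        y = np.asarray(self.y, dtype=np.int8)
        if x.shape != (len(self.speaker_ids), len(self.tag_names)):
            raise ValueError(
                f"x has shape {x.shape}, expected "
                f"({len(self.speaker_ids)}, {len(self.tag_names)})"
            )
        if y.shape != (x.shape[0],):
            raise ValueError("y length does not match number of rows")
        if not set(np.unique(y)) <= {0, 1}:
            raise ValueError("y must be binary 0/1")
        if (x < 0).any():
            raise ValueError("normalized frequencies must be non-negative")
        object.__setattr__(self, "x", x)
        object.__setattr__(self, "y", y)

    @property
    def n_speakers(self) -> int:
        return self.x.shape[0]

    @property
    def n_tags(self) -> int:
        return self.x.shape[1]


# ---------------------------------------------------------------------------
# counts-table I/O


def read_counts_table(
    path: str | Path,
    scheme: TagScheme,
    *,
    group_labels: tuple[str, str] = (POSITIVE_LABEL, NEGATIVE_LABEL),
) -> list[SpeakerRecord]:
    """Read a tab-separated speaker-by-tag count table.

    The header must be ``speaker_id  group  word_count  <tag...>`` with the
    tag columns exactly matching ``scheme.tags`` (extra or missing tag
    columns are rejected). ``group`` values must come from ``group_labels``.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if list(df.columns[:3]) != list(_META_COLUMNS):
        raise ValueError(
            f"counts table must start with columns {_META_COLUMNS}, "
            f"got {tuple(df.columns[:3])}"
        )
    file_tags = list(df.columns[3:])
    missing = [t for t in scheme.tags if t not in file_tags]
    if missing:
        raise ValueError(f"counts table is missing tag column(s): {missing[:5]}")
    unknown = [t for t in file_tags if t not in scheme.tags]
    if unknown:
        raise ValueError(f"counts table has unknown tag column(s): {unknown[:5]}")

    def _to_int(value: str, row: str, column: str) -> int:
        try:
            return int(value)
        except ValueError:
            raise ValueError(
                f"malformed numeric cell {value!r} at row {row!r}, "
                f"column {column!r}"
            ) from None

    records: list[SpeakerRecord] = []
    seen: set[str] = set()
    for _, row in df.iterrows():
        sid = row["speaker_id"]
        if sid in seen:
            raise ValueError(f"duplicate speaker_id: {sid!r}")
        seen.add(sid)
        group = row["group"]
        if group not in group_labels:
            raise ValueError(
                f"speaker {sid!r}: group {group!r} not in vocabulary {group_labels}"
            )
        w = _to_int(row["word_count"], sid, "word_count")
        counts = np.array(
            [_to_int(row[t], sid, t) for t in scheme.tags], dtype=np.int64
        )
        records.append(SpeakerRecord(sid, group, w, counts))
    return records


def write_counts_table(
    records: Sequence[SpeakerRecord], scheme: TagScheme, path: str | Path
) -> None:
    """Write records as the tab-separated table `read_counts_table` accepts."""
    _check_records(records, scheme)
    df = pd.DataFrame(
        {
            "speaker_id": [r.speaker_id for r in records],
            "group": [r.group for r in records],
            "word_count": [r.word_count for r in records],
            **{
                tag: [int(r.counts[j]) for r in records]
                for j, tag in enumerate(scheme.tags)
            },
        }
    )
    df.to_csv(path, sep="\t", index=False)


def _check_records(records: Sequence[SpeakerRecord], scheme: TagScheme) -> None:
    if len(records) == 0:
        raise ValueError("record list is empty")
    for r in records:
        if len(r.counts) != scheme.n_tags:
            raise ValueError(
                f"speaker {r.speaker_id!r} has {len(r.counts)} counts but the "
                f"scheme defines {scheme.n_tags} tags (mixed schemes?)"
            )


# ---------------------------------------------------------------------------
# normalization


def normalize_features(
    records: Sequence[SpeakerRecord],
    scheme: TagScheme,
    *,
    positive_label: str = POSITIVE_LABEL,
) -> FeatureMatrix:
    """Per-word frequency normalization: ``x[i, j] = counts[i, j] / w[i]``.

    Labels are 1 for ``positive_label`` speakers, 0 otherwise. Row order
    follows the record order; column order follows the scheme.
    """
    _check_records(records, scheme)
    counts = np.stack([r.counts for r in records]).astype(np.float64)
    w = np.array([r.word_count for r in records], dtype=np.float64)
    x = counts / w[:, None]
    y = np.array([1 if r.group == positive_label else 0 for r in records], dtype=np.int8)
    return FeatureMatrix(
        x=x,
        y=y,
        tag_names=scheme.tags,
        speaker_ids=tuple(r.speaker_id for r in records),
    )


# ---------------------------------------------------------------------------
# domain report


def map_to_domains(
    selected_tags: Iterable[str], scheme: TagScheme
) -> dict[str, list[str]]:
    """Group selected tags by cognitive-functional domain.

    Returns a dict with one key per domain (fixed order, always present,
    possibly empty) plus ``"unmapped"`` for selected tags the scheme maps
    to no domain. A multi-domain tag appears under each of its domains;
    within a domain, tags keep scheme order.
    """
    selected = list(selected_tags)
    for t in selected:
        if t not in scheme.category_of:
            raise KeyError(f"tag not in scheme: {t!r}")
    in_scheme_order = sorted(set(selected), key=scheme.index_of)
    report: dict[str, list[str]] = {d: [] for d in COGNITIVE_DOMAINS}
    report["unmapped"] = []
    for tag in in_scheme_order:
        doms = scheme.domains(tag)
        if not doms:
            report["unmapped"].append(tag)
        else:
            for d in COGNITIVE_DOMAINS:
                if d in doms:
                    report[d].append(tag)
    return report
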