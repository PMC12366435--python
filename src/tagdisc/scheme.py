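"""Tag inventory: categories, cognitive-domain map, structural levels.

A :class:`TagScheme` fixes the feature space of the whole analysis: the
ordered list of lexicogrammatical tags, the (single) major category of each
tag, an optional set of cognitive-functional domains the tag is taken to
reflect, and an optional structural-level annotation (clause/phrase level
vs. everything else) used when narrowing a discriminator list to syntactic
patterning.

Schemes are plain data, serialized as JSON, so the packaged default can be
replaced wholesale by the user.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources as _ir
from pathlib import Path
from typing import Iterable, Mapping

#: The seven cognitive-functional domains, in fixed report order.
COGNITIVE_DOMAINS: tuple[str, ...] = (
    "working memory",
    "inferential ability",
    "mental space construction",
    "joint attention",
    "weak central coherence",
    "self/other differentiation and agency",
    "restricted and repetitive behaviors",
)

#: Structural-level annotations a scheme may carry per tag.
LEVEL_CLAUSE_PHRASE = "clause_phrase"
LEVEL_OTHER = "other"

_MAX_CATEGORIES = 15


@dataclass(frozen=True)
class TagScheme:
    """Ordered tag inventory with category, domain and level annotations.

    Parameters
    ----------
    tags
        Unique tag identifiers; their order defines column order everywhere.
    category_of
        Tag -> major category (every tag must have exactly one).
    domain_of
        Tag -> set of cognitive-domain names; tags without an entry are
        treated as unmapped. Keys must be a subset of ``tags``.
    level_of
        Tag -> structural level (``"clause_phrase"`` / ``"other"``).
        Tags without an entry are "unclassified" under a level filter.
    """

    tags: tuple[str, ...]
    category_of: Mapping[str, str]
    domain_of: Mapping[str, frozenset[str]] = field(default_factory=dict)
    level_of: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.tags) == 0:
            raise ValueError("scheme must contain at least one tag")
        if len(set(self.tags)) != len(self.tags):
            dupes = sorted({t for t in self.tags if list(self.tags).count(t) > 1})
            raise ValueError(f"duplicate tag identifiers: {dupes}")
        missing = [t for t in self.tags if t not in self.category_of]
        if missing:
            raise ValueError(f"tags without a category: {missing[:5]}")
        if len(self.categories) > _MAX_CATEGORIES:
            raise ValueError(
                f"scheme has {len(self.categories)} categories; "
                f"at most {_MAX_CATEGORIES} are allowed"
            )
        unknown = set(self.domain_of) - set(self.tags)
        if unknown:
            raise ValueError(f"domain map refers to unknown tags: {sorted(unknown)[:5]}")
        for tag, doms in self.domain_of.items():
            bad = set(doms) - set(COGNITIVE_DOMAINS)
            if bad:
                raise ValueError(f"unknown cognitive domain(s) {sorted(bad)} for tag {tag!r}")
        unknown = set(self.level_of) - set(self.tags)
        if unknown:
            raise ValueError(f"level map refers to unknown tags: {sorted(unknown)[:5]}")

    # -- derived views -------------------------------------------------

    @property
    def n_tags(self) -> int:
        return len(self.tags)

    @property
    def categories(self) -> tuple[str, ...]:
        """Category names in order of first appearance."""
        seen: dict[str, None] = {}
        for t in self.tags:
            seen.setdefault(self.category_of[t], None)
        return tuple(seen)

    def index_of(self, tag: str) -> int:
        try:
            return self.tags.index(tag)
        except ValueError:
            raise KeyError(f"tag not in scheme: {tag!r}") from None

    def domains(self, tag: str) -> frozenset[str]:
        if tag not in self.category_of:
            raise KeyError(f"tag not in scheme: {tag!r}")
        return frozenset(self.domain_of.get(tag, frozenset()))

    def level(self, tag: str) -> str | None:
        if tag not in self.category_of:
            raise KeyError(f"tag not in scheme: {tag!r}")
        return self.level_of.get(tag)

    # -- (de)serialization ---------------------------------------------

    @classmethod
    def from_mapping(cls, payload: Mapping) -> "TagScheme":
        """Build a scheme from the JSON layout ``{"tags": [{id, category, domains, level}]}``."""
        entries = payload.get("tags")
        if not isinstance(entries, list) or not entries:
            raise ValueError('scheme JSON must contain a non-empty "tags" list')
        tags: list[str] = []
        category: dict[str, str] = {}
        domain: dict[str, frozenset[str]] = {}
        level: dict[str, str] = {}
        for e in entries:
            tid = e["id"]
            tags.append(tid)
            category[tid] = e["category"]
            if e.get("domains"):
                domain[tid] = frozenset(e["domains"])
            if e.get("level") is not None:
                level[tid] = e["level"]
        return cls(tuple(tags), category, domain, level)

    @classmethod
    def from_json(cls, path: str | Path) -> "TagScheme":
        with open(path, encoding="utf-8") as fh:
            return cls.from_mapping(json.load(fh))

    def to_mapping(self) -> dict:
        return {
            "tags": [
                {
                    "id": t,
                    "category": self.category_of[t],
                    "domains": sorted(self.domain_of.get(t, frozenset()),
                                      key=COGNITIVE_DOMAINS.index),
                    "level": self.level_of.get(t),
                }
                for t in self.tags
            ]
        }

    def to_json(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.to_mapping(), fh, indent=1, ensure_ascii=False)
            fh.write("\n")

    def subset_by_level(self, level: str) -> tuple[str, ...]:
        return tuple(t for t in self.tags if self.level_of.get(t) == level)


def default_scheme() -> TagScheme:
    """The packaged 135-tag scheme.

    Contains the 46 significant discriminator items with their category,
    domain and structural-level annotations, padded with synthetic
    placeholder tags (the full source inventory is not published) to the
    135 analyzed items in 15 categories.
    """
    ref = _ir.files("tagdisc") / "resources" / "default_scheme.json"
    return TagScheme.from_mapping(json.loads(ref.read_text(encoding="utf-8")))
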