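"""Dictionary-based tagging of app descriptions.

A tag corpus is a many-to-one mapping from surface strings (single words
or multi-word phrases such as "medication", "pharmaceutical", "heart
rate") to normalized tag labels. Descriptions are scanned for every
corpus string; an app's tags are the labels of all matched strings,
deduplicated at the tag level. Apps matched by fewer than ``k_min``
distinct tags (default 4) are excluded from clustering — listings
without an English, health-related description accumulate too few tags
to pass.

Matching semantics (fixed for determinism):

* case-insensitive via ``str.casefold``; non-ASCII text is preserved;
* exact matching on word boundaries — "drug" does not match inside
  "drugstore"; any run of non-word characters separates words;
* multi-word phrases match a consecutive token run;
* overlapping matches all count ("heart rate" and "heart" can both
  fire); deduplication happens at the tag level.

No stemming and no fuzzy matching are applied.
"""

from __future__ import annotations

import csv
import dataclasses
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Mapping

from .records import AppRecord

__all__ = [
    "TagCorpus",
    "TagCorpusError",
    "TagAssignment",
    "load_corpus",
    "write_corpus",
    "auto_tag",
    "tag_records",
    "filter_min_tags",
    "write_assignments",
    "read_assignments",
]

#: default minimum number of distinct tags required for inclusion
DEFAULT_MIN_TAGS = 4

_TOKEN_RE = re.compile(r"\w+", re.UNICODE)


class TagCorpusError(ValueError):
    """Raised for malformed or inconsistent tag-corpus input."""


def _tokens(text: str) -> tuple[str, ...]:
    """Case-folded word tokens; any non-word character run separates words."""
    return tuple(m.group(0) for m in _TOKEN_RE.finditer(text.casefold()))


@dataclass(frozen=True)
class TagCorpus:
    """Validated surface-string -> tag-label mapping with a token index.

    Surface strings are unique after case-folding; many strings may map
    to one tag, but no string maps to two tags.
    """

    surface_to_tag: Mapping[str, str]

    def __post_init__(self) -> None:
        # token index: first token -> [(token tuple, surface, tag), ...]
        index: dict[str, list[tuple[tuple[str, ...], str, str]]] = {}
        for surface, tag in sorted(self.surface_to_tag.items()):
            toks = _tokens(surface)
            if not toks:
                raise TagCorpusError(f"surface string {surface!r} has no word tokens")
            index.setdefault(toks[0], []).append((toks, surface, tag))
        object.__setattr__(self, "_index", index)

    @classmethod
    def from_pairs(
        cls, pairs: Iterable[tuple[str, str]], *, source: str | None = None
    ) -> "TagCorpus":
        """Build a corpus from (surface, tag) pairs.

        Identical duplicates are idempotently collapsed; the same surface
        with two different tags is a format error.
        """
        mapping: dict[str, str] = {}
        origin: dict[str, int] = {}
        for lineno, (surface, tag) in enumerate(pairs, start=1):
            surface_cf = surface.strip().casefold()
            tag = tag.strip()
            where = f"{source or '<pairs>'}:{lineno}"
            if not surface_cf or not tag:
                raise TagCorpusError(f"{where}: empty surface string or tag label")
            if surface_cf in mapping and mapping[surface_cf] != tag:
                raise TagCorpusError(
                    f"{where}: surface {surface_cf!r} maps to both "
                    f"{mapping[surface_cf]!r} (line {origin[surface_cf]}) and {tag!r}"
                )
            mapping.setdefault(surface_cf, tag)
            origin.setdefault(surface_cf, lineno)
        if not mapping:
            raise TagCorpusError(f"{source or '<pairs>'}: empty tag corpus")
        return cls(surface_to_tag=mapping)

    @property
    def tags(self) -> frozenset[str]:
        return frozenset(self.surface_to_tag.values())

    def surfaces_for(self, tag: str) -> tuple[str, ...]:
        return tuple(
            s for s, t in sorted(self.surface_to_tag.items()) if t == tag
        )

    def __len__(self) -> int:
        return len(self.surface_to_tag)

    def __iter__(self) -> Iterator[tuple[str, str]]:
        return iter(sorted(self.surface_to_tag.items()))


@dataclass(frozen=True)
class TagAssignment:
    """Result of auto-tagging one app."""

    app_id: str
    tags: frozenset[str]
    matched_strings: frozenset[str]
    included: bool

    @property
    def tag_count(self) -> int:
        return len(self.tags)


def load_corpus(path: str | Path) -> TagCorpus:
    """Load a two-column TSV (surface_string TAB tag_label)."""
    path = Path(path)
    pairs: list[tuple[str, str]] = []
    with path.open("r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            cols = line.split("\t")
            if len(cols) != 2:
                raise TagCorpusError(
                    f"{path}:{lineno}: expected 2 tab-separated columns, got {len(cols)}"
                )
            pairs.append((cols[0], cols[1]))
    return TagCorpus.from_pairs(pairs, source=str(path))


def write_corpus(corpus: TagCorpus, path: str | Path) -> None:
    with Path(path).open("w", encoding="utf-8") as fh:
        for surface, tag in corpus:
            fh.write(f"{surface}\t{tag}\n")


def auto_tag(
    app: AppRecord, corpus: TagCorpus, k_min: int = DEFAULT_MIN_TAGS
) -> TagAssignment:
    """Match every corpus string against the app description.

    A surface string matches iff its token sequence occurs consecutively
    in the case-folded token sequence of the description. An empty
    description yields the empty tag set.
    """
    if len(corpus) == 0:
        raise TagCorpusError("cannot tag with an empty corpus")
    toks = _tokens(app.description)
    index = corpus._index  # type: ignore[attr-defined]
    matched: set[str] = set()
    tags: set[str] = set()
    for i, tok in enumerate(toks):
        for pat, surface, tag in index.get(tok, ()):
            if len(pat) == 1 or toks[i : i + len(pat)] == pat:
                matched.add(surface)
                tags.add(tag)
    return TagAssignment(
        app_id=app.app_id,
        tags=frozenset(tags),
        matched_strings=frozenset(matched),
        included=len(tags) >= k_min,
    )


def tag_records(
    records: Iterable[AppRecord], corpus: TagCorpus, k_min: int = DEFAULT_MIN_TAGS
) -> list[TagAssignment]:
    return [auto_tag(rec, corpus, k_min=k_min) for rec in records]


def filter_min_tags(
    assignments: Iterable[TagAssignment], k_min: int = DEFAULT_MIN_TAGS
) -> tuple[list[TagAssignment], list[TagAssignment]]:
    """Partition assignments into (included, excluded) by distinct-tag count."""
    if k_min < 0:
        raise ValueError(f"k_min must be non-negative, got {k_min}")
    included: list[TagAssignment] = []
    excluded: list[TagAssignment] = []
    for a in assignments:
        target = included if a.tag_count >= k_min else excluded
        target.append(dataclasses.replace(a, included=a.tag_count >= k_min))
    return included, excluded


def write_assignments(assignments: Iterable[TagAssignment], path: str | Path) -> None:
    with Path(path).open("w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["app_id", "included", "tag_count", "tags"])
        for a in assignments:
            writer.writerow(
                [a.app_id, str(a.included).lower(), a.tag_count, ";".join(sorted(a.tags))]
            )


def read_assignments(path: str | Path) -> list[TagAssignment]:
    out: list[TagAssignment] = []
    with Path(path).open("r", encoding="utf-8", newline="") as fh:
        for row in csv.DictReader(fh):
            tags = frozenset(t for t in row["tags"].split(";") if t)
            out.append(
                TagAssignment(
                    app_id=row["app_id"],
                    tags=tags,
                    matched_strings=frozenset(),
                    included=row["included"] == "true",
                )
            )
    return out
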