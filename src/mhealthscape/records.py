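"""App-store listing records and their on-disk serialization.

The unit of analysis is a single store listing: identifiers, store,
category, the free-text description (the input to dictionary tagging),
and the rating metadata that feeds the descriptive statistics. Corpora
are exchanged as JSON Lines (one record per line, UTF-8); planted
ground truth as CSV.
"""

from __future__ import annotations

import csv
import json
from pathlib import Path
from typing import Iterable, Literal, Optional

from pydantic import BaseModel, Field, model_validator

Store = Literal["ios", "android"]
Category = Literal["medical", "health_fitness"]

STORES: tuple[Store, ...] = ("ios", "android")

#: archetype code used in ground-truth tables for apps planted without
#: archetype structure (non-health "noise" listings)
NOISE_ARCHETYPE = 0


class AppRecord(BaseModel):
    """One app-store listing.

    ``rating_mean`` lives on the 5-star scale and is present exactly when
    the app has at least one rating. ``download_band`` is the ordered
    Google-Play-style download bracket and only exists for Android apps.
    """

    app_id: str
    store: Store
    category: Category
    title: str = ""
    description: str = ""
    rating_count: int = Field(default=0, ge=0)
    rating_mean: Optional[float] = None
    download_band: Optional[str] = None

    @model_validator(mode="after")
    def _rating_consistency(self) -> "AppRecord":
        if self.rating_count > 0:
            if self.rating_mean is None:
                raise ValueError(f"{self.app_id}: rated app must carry rating_mean")
            if not 1.0 <= self.rating_mean <= 5.0:
                raise ValueError(f"{self.app_id}: rating_mean outside the 5-star scale")
        elif self.rating_mean is not None:
            raise ValueError(f"{self.app_id}: unrated app cannot carry rating_mean")
        return self

    @property
    def rated(self) -> bool:
        return self.rating_count > 0


class GroundTruth(BaseModel):
    """Planted structure of one synthetic app: archetype and tag set."""

    app_id: str
    planted_archetype: int = Field(ge=0)
    planted_tags: frozenset[str] = frozenset()

    @property
    def is_noise(self) -> bool:
        return self.planted_archetype == NOISE_ARCHETYPE


def write_records(records: Iterable[AppRecord], path: str | Path) -> None:
    """Write app records as JSON Lines (sorted keys, one object per line)."""
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        for rec in records:
            payload = rec.model_dump(exclude_none=True)
            fh.write(json.dumps(payload, sort_keys=True, ensure_ascii=False) + "\n")


def read_records(path: str | Path) -> list[AppRecord]:
    """Read a JSON Lines corpus, validating every record."""
    records: list[AppRecord] = []
    seen: set[str] = set()
    with Path(path).open("r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            try:
                rec = AppRecord.model_validate(json.loads(line))
            except (json.JSONDecodeError, ValueError) as exc:
                raise ValueError(f"{path}:{lineno}: invalid app record: {exc}") from exc
            if rec.app_id in seen:
                raise ValueError(f"{path}:{lineno}: duplicate app_id {rec.app_id!r}")
            seen.add(rec.app_id)
            records.append(rec)
    return records


def write_ground_truth(truths: Iterable[GroundTruth], path: str | Path) -> None:
    with Path(path).open("w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["app_id", "planted_archetype", "planted_tags"])
        for gt in truths:
            writer.writerow(
                [gt.app_id, gt.planted_archetype, ";".join(sorted(gt.planted_tags))]
            )


def read_ground_truth(path: str | Path) -> list[GroundTruth]:
    truths: list[GroundTruth] = []
    with Path(path).open("r", encoding="utf-8", newline="") as fh:
        for row in csv.DictReader(fh):
            tags = frozenset(t for t in row["planted_tags"].split(";") if t)
            truths.append(
                GroundTruth(
                    app_id=row["app_id"],
                    planted_archetype=int(row["planted_archetype"]),
                    planted_tags=tags,
                )
            )
    return truths
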