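"""Descriptive outputs: selection flow, rating statistics, aggregations.

Covers the landscape-survey style outputs: the app-selection flow
(discovered -> tag-filtered -> clustered -> assessed), per-store rating
summaries, the rank-sum comparison of store ratings with an effect
size, the rating-count/download-band rank correlation, and the
characteristic-level aggregation of archetype tables.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .assessment import CHARACTERISTICS, _LEVELS, Archetype
from .records import AppRecord
from .synthetic_corpus import band_rank

__all__ = [
    "FlowError",
    "FlowReport",
    "build_flow",
    "characteristic_table",
    "rating_summary",
    "RatingComparison",
    "compare_ratings",
]


class FlowError(ValueError):
    """Raised when selection-flow counts violate their identities."""


def _round_half_up(x: float, digits: int) -> float:
    """Half-up decimal rounding at the rendered precision."""
    q = Decimal(1).scaleb(-digits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class FlowReport:
    """App-selection flow counts with derived percentages.

    Identities: discovered - excluded_by_tagging = clustered, and
    clustered - uninformative_apps = assessed (when the assessment
    stages are present).
    """

    discovered: int
    excluded_by_tagging: int
    clustered: int
    uninformative_apps: Optional[int] = None
    assessed: Optional[int] = None
    by_store: Optional[Mapping[str, Mapping[str, int]]] = None

    @property
    def excluded_pct(self) -> float:
        return _round_half_up(100.0 * self.excluded_by_tagging / self.discovered, 2)

    @property
    def uninformative_pct(self) -> Optional[float]:
        if self.uninformative_apps is None:
            return None
        return _round_half_up(100.0 * self.uninformative_apps / self.clustered, 2)


def build_flow(
    *,
    discovered: Optional[int] = None,
    excluded_by_tagging: Optional[int] = None,
    clustered: Optional[int] = None,
    uninformative_apps: Optional[int] = None,
    assessed: Optional[int] = None,
    by_store: Optional[Mapping[str, Mapping[str, int]]] = None,
) -> FlowReport:
    """Assemble and invariant-check the selection-flow report.

    Any one member of each identity may be omitted and is derived from
    the other two; fully specified but inconsistent counts raise a
    ``FlowError`` stating the failed identity.
    """
    known = [v for v in (discovered, excluded_by_tagging, clustered) if v is not None]
    if len(known) < 2:
        raise FlowError(
            "need at least two of discovered / excluded_by_tagging / clustered"
        )
    if discovered is None:
        discovered = clustered + excluded_by_tagging  # type: ignore[operator]
    elif excluded_by_tagging is None:
        excluded_by_tagging = discovered - clustered  # type: ignore[operator]
    elif clustered is None:
        clustered = discovered - excluded_by_tagging
    if discovered - excluded_by_tagging != clustered:
        raise FlowError(
            f"discovered - excluded_by_tagging != clustered "
            f"({discovered} - {excluded_by_tagging} != {clustered})"
        )
    for name, v in (
        ("discovered", discovered),
        ("excluded_by_tagging", excluded_by_tagging),
        ("clustered", clustered),
    ):
        if v < 0:
            raise FlowError(f"{name} is negative: {v}")

    if uninformative_apps is not None or assessed is not None:
        if assessed is None:
            if uninformative_apps is None:
                raise FlowError("cannot derive assessed without uninformative_apps")
            assessed = clustered - uninformative_apps
        elif uninformative_apps is None:
            uninformative_apps = clustered - assessed
        if clustered - uninformative_apps != assessed:
            raise FlowError(
                f"clustered - uninformative_apps != assessed "
                f"({clustered} - {uninformative_apps} != {assessed})"
            )
        if uninformative_apps < 0 or assessed < 0:
            raise FlowError("assessment-stage counts are negative")

    return FlowReport(
        discovered=discovered,
        excluded_by_tagging=excluded_by_tagging,
        clustered=clustered,
        uninformative_apps=uninformative_apps,
        assessed=assessed,
        by_store=by_store,
    )


def characteristic_table(archetypes: Sequence[Archetype]) -> pd.DataFrame:
    """Per-characteristic, per-level cluster and app aggregation.

    Sums cluster and app counts over all archetypes whose signature
    carries the level; percentages are computed on the informative
    totals and rendered half-up to 1 decimal (clusters) and 2 decimals
    (apps). Returns a tidy frame indexed by (characteristic, level).
    """
    if not archetypes:
        raise ValueError("no archetypes supplied")
    total_clusters = sum(a.cluster_count for a in archetypes)
    total_apps = sum(a.app_count for a in archetypes)
    rows = []
    for char in CHARACTERISTICS:
        for level in _LEVELS[char]:
            members = [
                a for a in archetypes if getattr(a.signature, char) == level
            ]
            clusters = sum(a.cluster_count for a in members)
            apps = sum(a.app_count for a in members)
            rows.append(
                {
                    "characteristic": char,
                    "level": level,
                    "clusters": clusters,
                    "cluster_pct": _round_half_up(
                        100.0 * clusters / total_clusters, 1
                    ),
                    "apps": apps,
                    "app_pct": _round_half_up(100.0 * apps / total_apps, 2),
                }
            )
    return pd.DataFrame(rows).set_index(["characteristic", "level"])


def rating_summary(records: Iterable[AppRecord]) -> pd.DataFrame:
    """Per-store rating statistics.

    For each store: app counts, mean/median/SD of the 5-star mean over
    rated apps, and the fractions unrated, rated fewer than 10 times,
    rated more than 1000 times, and (among rated apps) rated >= 4 or
    <= 2 stars. Invariant to record order.
    """
    rows = {}
    records = list(records)
    for store in sorted({r.store for r in records}):
        sub = [r for r in records if r.store == store]
        rated = [r for r in sub if r.rated]
        means = np.array([r.rating_mean for r in rated], dtype=float)
        n = len(sub)
        rows[store] = {
            "n_apps": n,
            "n_rated": len(rated),
            "rating_mean": float(means.mean()) if len(rated) else np.nan,
            "rating_median": float(np.median(means)) if len(rated) else np.nan,
            "rating_sd": float(means.std(ddof=1)) if len(rated) > 1 else np.nan,
            "frac_unrated": sum(1 for r in sub if not r.rated) / n,
            "frac_lt10_ratings": sum(1 for r in sub if r.rating_count < 10) / n,
            "frac_gt1000_ratings": sum(1 for r in sub if r.rating_count > 1000) / n,
            "frac_rated_ge4": (
                float((means >= 4.0).mean()) if len(rated) else np.nan
            ),
            "frac_rated_le2": (
                float((means <= 2.0).mean()) if len(rated) else np.nan
            ),
        }
    return pd.DataFrame.from_dict(rows, orient="index").rename_axis("store")


@dataclass(frozen=True)
class RatingComparison:
    """Rank-sum comparison of per-store ratings plus the count/band rank
    correlation for Android.

    ``u`` is the Mann–Whitney statistic oriented toward the first-named
    group; ``z`` uses the tie-corrected normal approximation (no
    continuity correction) and ``effect_size_r = |z| / sqrt(n)``.
    """

    group_a: str
    group_b: str
    n_a: int
    n_b: int
    u: float
    z: float
    p: float
    effect_size_r: float
    spearman_rho: Optional[float] = None
    spearman_p: Optional[float] = None
    spearman_n: Optional[int] = None


def compare_ratings(
    records: Iterable[AppRecord],
    groups: tuple[str, str] = ("android", "ios"),
) -> RatingComparison:
    """Mann–Whitney comparison of rated 5-star means between two stores.

    Also reports the Spearman rank correlation between rating count and
    download-band rank over all apps of the first group that carry a
    band (the band fields exist only for Android).
    """
    records = list(records)
    ga, gb = groups
    x = np.array([r.rating_mean for r in records if r.store == ga and r.rated])
    y = np.array([r.rating_mean for r in records if r.store == gb and r.rated])
    if len(x) == 0 or len(y) == 0:
        raise ValueError(f"both groups need rated apps (got {len(x)} vs {len(y)})")

    n_a, n_b = len(x), len(y)
    n = n_a + n_b
    combined = np.concatenate([x, y])
    ranks = stats.rankdata(combined)
    r_a = ranks[:n_a].sum()
    u_a = r_a - n_a * (n_a + 1) / 2.0

    # tie-corrected variance of U
    _, tie_counts = np.unique(combined, return_counts=True)
    tie_term = ((tie_counts**3 - tie_counts).sum()) / (n * (n - 1))
    sigma2 = n_a * n_b / 12.0 * ((n + 1) - tie_term)
    if sigma2 <= 0:
        z = 0.0
    else:
        z = (u_a - n_a * n_b / 2.0) / np.sqrt(sigma2)
    p = float(2.0 * stats.norm.sf(abs(z)))
    p = min(p, 1.0)

    banded = [
        r for r in records if r.store == ga and r.download_band is not None
    ]
    rho = rho_p = rho_n = None
    if len(banded) >= 2:
        counts = [r.rating_count for r in banded]
        band_ranks = [band_rank(r.download_band) for r in banded]
        res = stats.spearmanr(counts, band_ranks)
        rho, rho_p, rho_n = float(res.statistic), float(res.pvalue), len(banded)

    return RatingComparison(
        group_a=ga,
        group_b=gb,
        n_a=n_a,
        n_b=n_b,
        u=float(u_a),
        z=float(z),
        p=p,
        effect_size_r=float(abs(z) / np.sqrt(n)),
        spearman_rho=rho,
        spearman_p=rho_p,
        spearman_n=rho_n,
    )
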