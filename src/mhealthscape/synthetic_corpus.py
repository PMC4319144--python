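"""Seeded generator of app-store-like corpora with planted structure.

Every downstream stage (tagging, graph building, clustering, reporting)
is exercised on corpora produced here, so the generator plants known
structure and emulates the marginal statistics of the 2013 iOS/Android
health-app landscape this pipeline was designed around:

* ~9:1 iOS:Android imbalance (store weights 0.8995 / 0.1005);
* a noise fraction of 34.48% — listings without health-related English
  descriptions that the 4-distinct-tag inclusion filter later removes;
* zero-inflated rating counts (75.76% of iOS and 42.37% of Android apps
  unrated) with a log-normal heavy tail calibrated so that roughly
  1.4–1.6% of apps collect more than 1000 ratings;
* 5-star rating means drawn from a Beta distribution rescaled to
  [1, 5] and moment-matched to the per-store targets (iOS mean 3.1,
  SD 1.01; Android mean 3.7, SD 1.08);
* Android download brackets derived from a latent download count that is
  strongly positively coupled to the rating count (Spearman ~0.9).

Non-noise apps draw their tags from archetype-specific tag pools; pools
overlap slightly so the shared-tag graph is connected and clustering is
non-trivial. Tag surface strings are synthetic tokens (two single-word
synonyms and one three-word phrase per tag) that are disjoint from the
bundled filler vocabulary, which makes planted tags exactly recoverable
by the tagger. Identical configurations (including the seed) regenerate
byte-identical corpora.
"""

from __future__ import annotations

import bisect
import math
from importlib import resources
from functools import lru_cache
from typing import Optional

import numpy as np
from pydantic import BaseModel, ConfigDict, Field, model_validator

from .records import NOISE_ARCHETYPE, AppRecord, GroundTruth, Store
from .tagging import TagCorpus

__all__ = [
    "GeneratorConfig",
    "generate_corpus",
    "sample_rating_block",
    "build_tag_pools",
    "build_tag_corpus",
    "DOWNLOAD_BANDS",
    "band_for_downloads",
    "band_rank",
    "filler_words",
]

# Google-Play-style ordered download brackets. The survey this emulates
# did not publish its observed bracket boundaries; these edges are a
# fixture convention, not an observed fact.
_BAND_EDGES = [
    5, 10, 50, 100, 500, 1_000, 5_000, 10_000,
    50_000, 100_000, 500_000, 1_000_000, 5_000_000,
]

DOWNLOAD_BANDS: tuple[str, ...] = tuple(
    f"{lo:,}-{hi:,}" for lo, hi in zip([1] + _BAND_EDGES[:-1], _BAND_EDGES)
) + (f">{_BAND_EDGES[-1]:,}",)

_BAND_RANK = {label: i for i, label in enumerate(DOWNLOAD_BANDS)}


def band_for_downloads(downloads: float) -> str:
    """Deterministic banding of a latent download count."""
    if downloads < 0:
        raise ValueError("download count cannot be negative")
    return DOWNLOAD_BANDS[bisect.bisect_left(_BAND_EDGES, downloads)]


def band_rank(label: str) -> int:
    """Ordinal rank of a download band label (0 = smallest bracket)."""
    try:
        return _BAND_RANK[label]
    except KeyError:
        raise ValueError(f"unknown download band {label!r}") from None


@lru_cache(maxsize=1)
def filler_words() -> tuple[str, ...]:
    """Fixed non-health filler vocabulary shipped with the package."""
    text = (
        resources.files("mhealthscape").joinpath("data/filler_words.txt").read_text()
    )
    return tuple(w for w in text.split() if w)


class GeneratorConfig(BaseModel):
    """All knobs of the corpus generator, with landscape-matched defaults."""

    model_config = ConfigDict(frozen=True)

    n_apps: int = Field(default=2000, gt=0)
    store_weights: dict[Store, float] = Field(
        default={"ios": 0.8995, "android": 0.1005}
    )
    noise_fraction: float = Field(default=0.3448, ge=0.0, le=1.0)
    archetype_count: int = Field(default=8, gt=0)
    tags_per_archetype_pool: int = Field(default=12, gt=0)
    tags_per_app_min: int = Field(default=4, ge=1)
    tags_per_app_max: int = Field(default=8, ge=1)
    pool_overlap_fraction: float = Field(default=0.1, ge=0.0, le=1.0)
    unrated_probability_by_store: dict[Store, float] = Field(
        default={"ios": 0.7576, "android": 0.4237}
    )
    # per-store (location, scale) = target mean and SD of the 5-star
    # rating mean, realised by a moment-matched Beta rescaled to [1, 5]
    rating_mean_params_by_store: dict[Store, tuple[float, float]] = Field(
        default={"ios": (3.1, 1.01), "android": (3.7, 1.08)}
    )
    # per-store (mu, sigma) of the log-normal rating-count tail, solved
    # from the published fractions of apps rated <10 and >1000 times
    rating_count_tail_params: dict[Store, tuple[float, float]] = Field(
        default={"ios": (3.77, 1.99), "android": (1.72, 2.69)}
    )
    # latent downloads-per-rating multiplier: log-normal(log_mean, log_sd)
    download_ratio_log_mean: float = math.log(50.0)
    download_ratio_log_sd: float = 0.5
    seed: int = 0

    @model_validator(mode="after")
    def _check(self) -> "GeneratorConfig":
        total = sum(self.store_weights.values())
        if not math.isclose(total, 1.0, abs_tol=1e-9):
            raise ValueError(f"store_weights must sum to 1, got {total}")
        for name, probs in (
            ("store_weights", self.store_weights),
            ("unrated_probability_by_store", self.unrated_probability_by_store),
        ):
            for store, p in probs.items():
                if not 0.0 <= p <= 1.0:
                    raise ValueError(f"{name}[{store}] = {p} outside [0, 1]")
        if self.tags_per_app_max < self.tags_per_app_min:
            raise ValueError(
                "tags_per_app_max must be >= tags_per_app_min "
                f"({self.tags_per_app_max} < {self.tags_per_app_min})"
            )
        pool_size = self.tags_per_archetype_pool + self._overlap_count
        if self.tags_per_app_max > pool_size:
            raise ValueError(
                f"tags_per_app_max = {self.tags_per_app_max} exceeds the "
                f"archetype pool size {pool_size}"
            )
        for store, (loc, scale) in self.rating_mean_params_by_store.items():
            if not 1.0 < loc < 5.0:
                raise ValueError(
                    f"rating_mean_params_by_store[{store}] location {loc} "
                    "outside (1, 5)"
                )
            if scale <= 0:
                raise ValueError(f"rating_mean_params_by_store[{store}] scale <= 0")
            m01, v01 = (loc - 1.0) / 4.0, (scale / 4.0) ** 2
            if v01 >= m01 * (1.0 - m01):
                raise ValueError(
                    f"rating_mean_params_by_store[{store}] scale {scale} "
                    "infeasible for a distribution on [1, 5] with that mean"
                )
        return self

    @property
    def _overlap_count(self) -> int:
        if self.archetype_count < 2:
            return 0
        return int(round(self.pool_overlap_fraction * self.tags_per_archetype_pool))


def build_tag_pools(config: GeneratorConfig) -> list[list[str]]:
    """Archetype tag pools: own tags plus a slice borrowed from the next pool.

    The borrowed slice (``pool_overlap_fraction`` of the pool size,
    cyclically from the neighbouring archetype) connects the shared-tag
    graph across archetypes, as real clusters shared tags.
    """
    a_count, p = config.archetype_count, config.tags_per_archetype_pool
    base = [[f"t{a:02d}x{i:02d}" for i in range(p)] for a in range(1, a_count + 1)]
    k = config._overlap_count
    pools = []
    for a in range(a_count):
        pool = list(base[a])
        if k and a_count > 1:
            pool += base[(a + 1) % a_count][:k]
        pools.append(pool)
    return pools


def build_tag_corpus(config: GeneratorConfig) -> TagCorpus:
    """Corpus with three synonym surface strings per planted tag.

    Each tag gets two single-word synonyms and one multi-word phrase
    ("sanoNNN", "vitaNNN", "salus NNN modus"), mirroring real corpora in
    which several wordings map to one tag. Surfaces are unique, contain
    digits, and can therefore never collide with filler vocabulary.
    """
    pools = build_tag_pools(config)
    all_tags = sorted({tag for pool in pools for tag in pool})
    pairs: list[tuple[str, str]] = []
    for gid, tag in enumerate(all_tags):
        pairs.append((f"sano{gid:03d}", tag))
        pairs.append((f"vita{gid:03d}", tag))
        pairs.append((f"salus {gid:03d} modus", tag))
    return TagCorpus.from_pairs(pairs)


def sample_rating_block(
    config: GeneratorConfig,
    store: str,
    rng: Optional[np.random.Generator] = None,
) -> tuple[int, Optional[float], Optional[str]]:
    """Draw (rating_count, rating_mean, download_band) for one app.

    Unrated apps (probability per store) have count 0 and no mean. Rated
    apps draw a log-normal count (rounded, >= 1) and a 5-star mean from
    a Beta rescaled to [1, 5] whose first two moments match the
    configured per-store mean/SD. Android apps additionally receive a
    download band:
    a deterministic banding of ``(count + 1) * ratio`` where ``ratio``
    is a log-normal downloads-per-rating multiplier, which induces the
    strong positive count/band association seen in real stores.
    """
    if store not in config.store_weights:
        raise ValueError(f"unknown store {store!r}")
    if rng is None:
        rng = np.random.default_rng(config.seed)

    count = 0
    mean: Optional[float] = None
    if rng.random() >= config.unrated_probability_by_store[store]:
        mu, sigma = config.rating_count_tail_params[store]
        count = max(1, int(round(rng.lognormal(mu, sigma))))
        loc, scale = config.rating_mean_params_by_store[store]
        m01, v01 = (loc - 1.0) / 4.0, (scale / 4.0) ** 2
        concentration = m01 * (1.0 - m01) / v01 - 1.0
        alpha, beta = m01 * concentration, (1.0 - m01) * concentration
        mean = float(1.0 + 4.0 * rng.beta(alpha, beta))

    band: Optional[str] = None
    if store == "android":
        ratio = rng.lognormal(config.download_ratio_log_mean, config.download_ratio_log_sd)
        band = band_for_downloads((count + 1) * ratio)
    return count, mean, band


def _compose_description(
    rng: np.random.Generator,
    surfaces: list[str],
    fillers: tuple[str, ...],
) -> str:
    words: list[str] = list(rng.choice(fillers, size=int(rng.integers(3, 9))))
    order = list(rng.permutation(len(surfaces)))
    for idx in order:
        words.append(surfaces[idx])
        words.extend(rng.choice(fillers, size=int(rng.integers(2, 6))))
    return " ".join(words)


def generate_corpus(
    config: GeneratorConfig,
) -> tuple[list[AppRecord], list[GroundTruth], TagCorpus]:
    """Generate a full synthetic corpus with planted ground truth.

    Returns app records, the planted archetype/tag assignments, and the
    tag corpus whose surface strings are embedded in the descriptions.
    Noise apps carry fewer than four planted tags (drawn from the whole
    tag universe) and are therefore excluded later by the default
    inclusion filter; non-noise apps carry 4..``tags_per_app_max`` tags
    from their archetype's pool.
    """
    rng = np.random.default_rng(config.seed)
    pools = build_tag_pools(config)
    corpus = build_tag_corpus(config)
    all_tags = sorted({tag for pool in pools for tag in pool})
    surfaces_by_tag = {tag: corpus.surfaces_for(tag) for tag in all_tags}
    fillers = filler_words()

    stores = sorted(config.store_weights)
    weights = np.array([config.store_weights[s] for s in stores])
    categories = ("health_fitness", "medical")

    records: list[AppRecord] = []
    truths: list[GroundTruth] = []
    n_noise_tags_max = 4  # strictly below the default inclusion threshold
    for i in range(config.n_apps):
        app_id = f"app{i:06d}"
        store = stores[int(rng.choice(len(stores), p=weights))]
        category = categories[int(rng.integers(0, 2))]
        is_noise = rng.random() < config.noise_fraction

        if is_noise:
            archetype = NOISE_ARCHETYPE
            k = int(rng.integers(0, n_noise_tags_max))
            tags = sorted(rng.choice(all_tags, size=k, replace=False)) if k else []
        else:
            archetype = int(rng.integers(1, config.archetype_count + 1))
            pool = pools[archetype - 1]
            k = int(rng.integers(config.tags_per_app_min, config.tags_per_app_max + 1))
            tags = sorted(rng.choice(pool, size=k, replace=False))

        chosen_surfaces = [
            surfaces_by_tag[t][int(rng.integers(0, len(surfaces_by_tag[t])))]
            for t in tags
        ]
        if is_noise and not tags and rng.random() < 0.25:
            description = ""  # some noise listings ship no description at all
        else:
            description = _compose_description(rng, chosen_surfaces, fillers)
        title = " ".join(rng.choice(fillers, size=2)) + f" {i}"

        count, mean, band = sample_rating_block(config, store, rng)
        records.append(
            AppRecord(
                app_id=app_id,
                store=store,  # type: ignore[arg-type]
                category=category,  # type: ignore[arg-type]
                title=title,
                description=description,
                rating_count=count,
                rating_mean=mean,
                download_band=band,
            )
        )
        truths.append(
            GroundTruth(
                app_id=app_id,
                planted_archetype=archetype,
                planted_tags=frozenset(tags),
            )
        )
    return records, truths, corpus
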