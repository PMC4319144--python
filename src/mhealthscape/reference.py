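"""Bundled reference summary tables of the 2013 store-snapshot survey.

The May-2013 iOS/Android health-app snapshot this pipeline's design is
anchored to is no longer retrievable, but its published summary tables
are: the selection-flow totals, the per-store rating statistics, and
the twelve-archetype taxonomy with cluster and app counts. They are
shipped here as plain data and used as worked-example inputs for the
aggregation operations (the characteristic table and selection-flow
reports are exactly recomputable from them).
"""

from __future__ import annotations

import csv
from importlib import resources

from .assessment import CHARACTERISTICS, Archetype, Signature

__all__ = ["REFERENCE_FLOW", "REFERENCE_RATINGS", "load_reference_archetypes"]

#: selection-flow totals of the reference snapshot
REFERENCE_FLOW = {
    "discovered": 37_246,
    "discovered_ios": 32_614,
    "discovered_android": 4_632,
    "excluded_by_tagging": 12_841,
    "clustered": 24_405,
    "clustered_ios": 21_953,
    "clustered_android": 2_452,
    "total_clusters": 245,
    "uninformative_clusters": 70,
    "uninformative_apps": 6_426,
    "informative_clusters": 175,
    "assessed_apps": 17_979,
}

#: per-store rating statistics of the reference snapshot
REFERENCE_RATINGS = {
    "ios": {
        "mean": 3.1,
        "median": 3.0,
        "sd": 1.01,
        "unrated_fraction": 0.7576,
        "lt10_fraction": 0.8136,
        "gt1000_fraction": 0.0138,
    },
    "android": {
        "mean": 3.7,
        "median": 3.92,
        "sd": 1.08,
        "unrated_fraction": 0.4237,
        "lt10_fraction": 0.7614,
        "gt1000_fraction": 0.0155,
    },
    "ios_to_android_ratio": 8.95,
    "count_download_spearman": 0.89,
}


def load_reference_archetypes() -> list[Archetype]:
    """The twelve reference archetypes with signatures and counts."""
    text = (
        resources.files("mhealthscape")
        .joinpath("data/reference_archetypes.csv")
        .read_text()
    )
    archetypes = []
    for row in csv.DictReader(text.splitlines()):
        archetypes.append(
            Archetype(
                archetype_id=int(row["archetype_id"]),
                signature=Signature(*(row[c] for c in CHARACTERISTICS)),
                cluster_count=int(row["clusters"]),
                app_count=int(row["apps"]),
            )
        )
    return archetypes
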