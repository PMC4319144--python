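"""Cluster assessments, inter-rater agreement, and archetype consolidation.

Each informative cluster is assessed by two or more raters on five
nominal security/privacy characteristics:

1. specificity — health specificity of information available to the
   apps (standard / nonstandard / medical);
2. leaks — potential damage through information leaks (none/low/high);
3. change — potential damage through information manipulation;
4. loss — potential damage through information loss;
5. value — value of the information to third parties.

Agreement between raters is quantified with Janson–Olsson iota, a
multivariate extension of Cohen's kappa for multiple judges on the same
(here nominal) scales:

    iota = 1 - D_obs / D_exp

where the cell distance d(r, s) is the fraction of the K = 5 variables
on which two ratings differ, D_obs averages d over all objects and
unordered pairs of distinct judges rating the same object, and D_exp
averages d over all ordered pairs of distinct objects combined with all
ordered pairs of distinct judges. This estimator variant is fixed here
and oracle-tested; levels are treated as nominal, with no ordinal
weighting.

After disagreements are resolved (adjudication enters as data), clusters
with identical five-characteristic vectors are consolidated into
archetypes, ordered by ascending severity of the signature.
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, NamedTuple, Optional, Sequence

import numpy as np

__all__ = [
    "CHARACTERISTICS",
    "SPECIFICITY_LEVELS",
    "DAMAGE_LEVELS",
    "Signature",
    "severity_key",
    "ClusterAssessment",
    "Archetype",
    "RatingMatrix",
    "AssessmentError",
    "iota",
    "resolve_disagreements",
    "exclude_uninformative",
    "UninformativeSplit",
    "consolidate",
    "read_assessments",
    "write_assessments",
    "write_archetypes",
    "archetypes_to_markdown",
]

CHARACTERISTICS = ("specificity", "leaks", "change", "loss", "value")
SPECIFICITY_LEVELS = ("standard", "nonstandard", "medical")
DAMAGE_LEVELS = ("none", "low", "high")

_LEVELS: dict[str, tuple[str, ...]] = {
    "specificity": SPECIFICITY_LEVELS,
    "leaks": DAMAGE_LEVELS,
    "change": DAMAGE_LEVELS,
    "loss": DAMAGE_LEVELS,
    "value": DAMAGE_LEVELS,
}


class AssessmentError(ValueError):
    """Raised for incomplete, invalid, or unresolved assessment data."""


class Signature(NamedTuple):
    """The five-characteristic vector defining an archetype."""

    specificity: str
    leaks: str
    change: str
    loss: str
    value: str


def severity_key(signature: Signature) -> tuple[int, ...]:
    """Ascending severity rank: standard<nonstandard<medical, none<low<high."""
    return tuple(
        _LEVELS[char].index(value)
        for char, value in zip(CHARACTERISTICS, signature)
    )


@dataclass(frozen=True)
class ClusterAssessment:
    """One rater's assessment of one cluster.

    Uninformative clusters (tags conveying no interpretable
    security/privacy content) carry no characteristic values.
    """

    cluster_id: str
    rater_id: str
    informative: bool
    specificity: Optional[str] = None
    leaks: Optional[str] = None
    change: Optional[str] = None
    loss: Optional[str] = None
    value: Optional[str] = None
    annotation: str = ""

    def __post_init__(self) -> None:
        values = [getattr(self, c) for c in CHARACTERISTICS]
        if self.informative:
            for char, val in zip(CHARACTERISTICS, values):
                if val not in _LEVELS[char]:
                    raise AssessmentError(
                        f"cluster {self.cluster_id}, rater {self.rater_id}: "
                        f"{char}={val!r} not in {_LEVELS[char]}"
                    )
        elif any(v is not None for v in values):
            raise AssessmentError(
                f"cluster {self.cluster_id}, rater {self.rater_id}: "
                "uninformative assessment must carry no characteristic values"
            )

    @property
    def signature(self) -> Signature:
        if not self.informative:
            raise AssessmentError(
                f"cluster {self.cluster_id}: uninformative assessment has no signature"
            )
        return Signature(*(getattr(self, c) for c in CHARACTERISTICS))


@dataclass(frozen=True)
class Archetype:
    """An equivalence class of clusters sharing one assessment signature."""

    archetype_id: int
    signature: Signature
    cluster_count: int
    app_count: int
    member_clusters: tuple[str, ...] = ()
    descriptor: Optional[str] = None


class RatingMatrix:
    """Complete objects x judges x variables block of nominal ratings.

    The cluster-assessment use case has K = 5 variables (the five
    characteristics), but the agreement coefficient is defined for any
    number of nominal variables.
    """

    def __init__(
        self,
        objects: Sequence[str],
        judges: Sequence[str],
        values: np.ndarray,
    ) -> None:
        values = np.asarray(values, dtype=object)
        if values.ndim != 3 or values.shape[:2] != (len(objects), len(judges)):
            raise AssessmentError(
                f"rating matrix shape {values.shape} does not match "
                f"{len(objects)} objects x {len(judges)} judges x K variables"
            )
        if any(v is None for v in values.ravel()):
            raise AssessmentError("rating matrix has missing cells")
        self.objects = tuple(objects)
        self.judges = tuple(judges)
        self.values = values

    @classmethod
    def from_assessments(
        cls, assessments: Iterable[ClusterAssessment]
    ) -> "RatingMatrix":
        """Assemble the matrix from informative per-cluster assessments.

        Every judge must have rated every cluster that any judge rated
        as informative; anything else is an incomplete matrix.
        """
        cells: dict[tuple[str, str], ClusterAssessment] = {}
        for a in assessments:
            if not a.informative:
                continue
            key = (a.cluster_id, a.rater_id)
            if key in cells:
                raise AssessmentError(
                    f"duplicate assessment for cluster {a.cluster_id} "
                    f"by rater {a.rater_id}"
                )
            cells[key] = a
        if not cells:
            raise AssessmentError("no informative assessments supplied")
        objects = sorted({c for c, _ in cells})
        judges = sorted({r for _, r in cells})
        missing = [
            (c, r) for c in objects for r in judges if (c, r) not in cells
        ]
        if missing:
            raise AssessmentError(f"missing rating cells: {missing[:5]}")
        values = np.empty((len(objects), len(judges), len(CHARACTERISTICS)), object)
        for oi, c in enumerate(objects):
            for ji, r in enumerate(judges):
                values[oi, ji, :] = list(cells[(c, r)].signature)
        return cls(objects, judges, values)


def iota(matrix: RatingMatrix) -> float:
    """Janson–Olsson iota for multivariate nominal ratings.

    Perfect agreement gives 1. If the expected disagreement is zero
    (every rating identical everywhere) the coefficient is undefined and
    reported as 1 with a warning.
    """
    n_obj, n_judges, n_vars = matrix.values.shape
    if n_judges < 2:
        raise AssessmentError("iota needs at least 2 judges")
    if n_obj < 2:
        raise AssessmentError("iota needs at least 2 objects")

    flat = matrix.values.reshape(n_obj * n_judges, n_vars)
    # pairwise mismatch fraction between every pair of rating cells
    dist = (flat[:, None, :] != flat[None, :, :]).mean(axis=2).astype(float)
    dist = dist.reshape(n_obj, n_judges, n_obj, n_judges)

    obs_terms = [
        dist[o, j1, o, j2]
        for o in range(n_obj)
        for j1 in range(n_judges)
        for j2 in range(j1 + 1, n_judges)
    ]
    d_obs = float(np.mean(obs_terms))

    obj_mask = ~np.eye(n_obj, dtype=bool)  # ordered pairs of distinct objects
    judge_mask = ~np.eye(n_judges, dtype=bool)  # ordered pairs of distinct judges
    d_exp = float(dist.transpose(0, 2, 1, 3)[obj_mask][:, judge_mask].mean())

    if d_exp == 0.0:
        warnings.warn(
            "expected disagreement is zero (degenerate ratings); iota reported as 1",
            stacklevel=2,
        )
        return 1.0
    return 1.0 - d_obs / d_exp


def resolve_disagreements(
    matrix: RatingMatrix,
    adjudication: Optional[Mapping[tuple[str, str], str]] = None,
) -> dict[str, ClusterAssessment]:
    """Collapse a multi-judge matrix into one resolved assessment per cluster.

    Cells on which all judges agree take the agreed value. Disagreeing
    cells take the adjudicated override keyed by (cluster_id,
    characteristic); the adjudication outcome enters as data. Unresolved
    disagreements and overrides referencing unknown cells are errors.
    """
    adjudication = dict(adjudication or {})
    for (cluster_id, char), value in adjudication.items():
        if cluster_id not in matrix.objects:
            raise AssessmentError(f"override references unknown cluster {cluster_id!r}")
        if char not in CHARACTERISTICS:
            raise AssessmentError(f"override references unknown characteristic {char!r}")
        if value not in _LEVELS[char]:
            raise AssessmentError(
                f"override value {value!r} invalid for {char} (allowed {_LEVELS[char]})"
            )

    resolved: dict[str, ClusterAssessment] = {}
    unresolved: list[tuple[str, str]] = []
    for oi, cluster_id in enumerate(matrix.objects):
        out: dict[str, str] = {}
        for ki, char in enumerate(CHARACTERISTICS):
            cell_values = {matrix.values[oi, ji, ki] for ji in range(len(matrix.judges))}
            override = adjudication.get((cluster_id, char))
            if override is not None:
                out[char] = override
            elif len(cell_values) == 1:
                out[char] = next(iter(cell_values))
            else:
                unresolved.append((cluster_id, char))
        if cluster_id not in {c for c, _ in unresolved}:
            resolved[cluster_id] = ClusterAssessment(
                cluster_id=cluster_id, rater_id="resolved", informative=True, **out
            )
    if unresolved:
        raise AssessmentError(f"unresolved disagreements: {sorted(unresolved)}")
    return resolved


class UninformativeSplit(NamedTuple):
    informative: list[ClusterAssessment]
    uninformative: list[ClusterAssessment]
    informative_apps: Optional[int]
    uninformative_apps: Optional[int]


def exclude_uninformative(
    assessments: Iterable[ClusterAssessment],
    cluster_sizes: Optional[Mapping[str, int]] = None,
) -> UninformativeSplit:
    """Partition assessments by the informative flag.

    When cluster sizes are supplied, the app totals of both parts are
    reported alongside (for the selection-flow bookkeeping).
    """
    informative: list[ClusterAssessment] = []
    uninformative: list[ClusterAssessment] = []
    for a in assessments:
        (informative if a.informative else uninformative).append(a)
    inf_apps = unin_apps = None
    if cluster_sizes is not None:
        try:
            inf_apps = sum(cluster_sizes[a.cluster_id] for a in informative)
            unin_apps = sum(cluster_sizes[a.cluster_id] for a in uninformative)
        except KeyError as exc:
            raise AssessmentError(f"no size for cluster {exc.args[0]!r}") from exc
    return UninformativeSplit(informative, uninformative, inf_apps, unin_apps)


def consolidate(
    resolved: Mapping[str, ClusterAssessment] | Iterable[ClusterAssessment],
    cluster_sizes: Mapping[str, int],
    descriptors: Optional[Mapping[Signature, str]] = None,
) -> list[Archetype]:
    """Group informative clusters with identical signatures into archetypes.

    Archetypes are numbered 1..A in ascending severity order of their
    signatures (specificity first, then leaks, change, loss, value);
    app counts aggregate member cluster sizes. Optional descriptors are
    human-supplied labels keyed by signature, never computed.
    """
    if isinstance(resolved, Mapping):
        assessments = list(resolved.values())
    else:
        assessments = list(resolved)
    assessments = [a for a in assessments if a.informative]
    if not assessments:
        raise AssessmentError("no informative resolved assessments to consolidate")
    missing = sorted(
        a.cluster_id for a in assessments if a.cluster_id not in cluster_sizes
    )
    if missing:
        raise AssessmentError(f"clusters without sizes: {missing}")

    groups: dict[Signature, list[str]] = {}
    for a in assessments:
        groups.setdefault(a.signature, []).append(a.cluster_id)

    archetypes = []
    for i, sig in enumerate(sorted(groups, key=severity_key), start=1):
        members = tuple(sorted(groups[sig]))
        archetypes.append(
            Archetype(
                archetype_id=i,
                signature=sig,
                cluster_count=len(members),
                app_count=sum(cluster_sizes[c] for c in members),
                member_clusters=members,
                descriptor=(descriptors or {}).get(sig),
            )
        )
    return archetypes


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------

_CSV_FIELDS = ["cluster_id", "rater_id", "informative", *CHARACTERISTICS, "annotation"]


def write_assessments(
    assessments: Iterable[ClusterAssessment], path: str | Path
) -> None:
    with Path(path).open("w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(_CSV_FIELDS)
        for a in assessments:
            writer.writerow(
                [
                    a.cluster_id,
                    a.rater_id,
                    str(a.informative).lower(),
                    *(getattr(a, c) or "" for c in CHARACTERISTICS),
                    a.annotation,
                ]
            )


def read_assessments(path: str | Path) -> list[ClusterAssessment]:
    out: list[ClusterAssessment] = []
    with Path(path).open("r", encoding="utf-8", newline="") as fh:
        reader = csv.DictReader(fh)
        for lineno, row in enumerate(reader, start=2):
            if row.get("informative") not in ("true", "false"):
                raise AssessmentError(
                    f"{path}:{lineno}: informative flag must be true/false"
                )
            informative = row["informative"] == "true"
            out.append(
                ClusterAssessment(
                    cluster_id=row["cluster_id"],
                    rater_id=row["rater_id"],
                    informative=informative,
                    annotation=row.get("annotation", ""),
                    **{
                        c: (row[c] or None) if informative else None
                        for c in CHARACTERISTICS
                    },
                )
            )
    return out


def write_archetypes(archetypes: Iterable[Archetype], path: str | Path) -> None:
    with Path(path).open("w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(
            ["archetype_id", *CHARACTERISTICS, "clusters", "apps", "descriptor"]
        )
        for at in archetypes:
            writer.writerow(
                [
                    at.archetype_id,
                    *at.signature,
                    at.cluster_count,
                    at.app_count,
                    at.descriptor or "",
                ]
            )


def archetypes_to_markdown(archetypes: Sequence[Archetype]) -> str:
    """Markdown archetype table (id, signature, cluster and app counts)."""
    total_clusters = sum(a.cluster_count for a in archetypes)
    total_apps = sum(a.app_count for a in archetypes)
    lines = [
        "| AT | Specificity | Leaks | Change | Loss | Value | Clusters n (%) | Apps n (%) |",
        "|---:|---|---|---|---|---|---:|---:|",
    ]
    for at in archetypes:
        c_pct = 100.0 * at.cluster_count / total_clusters if total_clusters else 0.0
        a_pct = 100.0 * at.app_count / total_apps if total_apps else 0.0
        lines.append(
            f"| {at.archetype_id} | "
            + " | ".join(at.signature)
            + f" | {at.cluster_count} ({c_pct:.1f}) | {at.app_count} ({a_pct:.2f}) |"
        )
    return "\n".join(lines)
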