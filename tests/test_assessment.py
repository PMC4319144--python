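"""Assessments: iota agreement, disagreement resolution, consolidation."""

import itertools

import numpy as np
import pytest

from mhealthscape.assessment import (
    CHARACTERISTICS,
    Archetype,
    AssessmentError,
    ClusterAssessment,
    RatingMatrix,
    Signature,
    archetypes_to_markdown,
    consolidate,
    exclude_uninformative,
    iota,
    read_assessments,
    resolve_disagreements,
    severity_key,
    write_archetypes,
    write_assessments,
)
from mhealthscape.reference import load_reference_archetypes


def matrix_from_arrays(*judge_columns, n_vars=1):
    """Build a RatingMatrix from per-judge lists of per-object tuples."""
    n_obj = len(judge_columns[0])
    values = np.empty((n_obj, len(judge_columns), n_vars), object)
    for ji, col in enumerate(judge_columns):
        for oi, cell in enumerate(col):
            cell = (cell,) if isinstance(cell, str) else tuple(cell)
            values[oi, ji, :] = cell
    return RatingMatrix(
        [f"o{i}" for i in range(n_obj)],
        [f"j{i}" for i in range(len(judge_columns))],
        values,
    )


def iota_oracle(matrix):
    """Brute-force double-loop evaluation of the agreement coefficient."""
    vals = matrix.values
    n, j, k = vals.shape

    def d(a, b):
        return sum(x != y for x, y in zip(a, b)) / k

    obs = [
        d(vals[o, j1], vals[o, j2])
        for o in range(n)
        for j1, j2 in itertools.combinations(range(j), 2)
    ]
    exp = [
        d(vals[o1, j1], vals[o2, j2])
        for o1 in range(n)
        for o2 in range(n)
        if o1 != o2
        for j1 in range(j)
        for j2 in range(j)
        if j1 != j2
    ]
    d_obs, d_exp = np.mean(obs), np.mean(exp)
    return 1.0 if d_exp == 0 else 1.0 - d_obs / d_exp


def informative(cluster_id, rater_id, sig, annotation=""):
    return ClusterAssessment(
        cluster_id=cluster_id,
        rater_id=rater_id,
        informative=True,
        annotation=annotation,
        **dict(zip(CHARACTERISTICS, sig)),
    )


SIG_A = ("medical", "high", "high", "high", "high")
SIG_B = ("standard", "none", "low", "none", "none")
SIG_C = ("nonstandard", "low", "low", "low", "low")


class TestIota:
    def test_perfect_agreement(self):
        m = matrix_from_arrays(["a", "b", "c"], ["a", "b", "c"])
        assert iota(m) == pytest.approx(1.0)

    def test_constant_total_disagreement_is_zero(self):
        m = matrix_from_arrays(["a", "a", "a"], ["b", "b", "b"])
        assert iota(m) == pytest.approx(0.0)

    def test_worked_single_variable_example(self):
        m = matrix_from_arrays(list("aabb"), list("abbb"))
        assert iota(m) == pytest.approx(1 - 0.25 / (14 / 24))

    def test_degenerate_identical_everything_warns(self):
        m = matrix_from_arrays(["a", "a"], ["a", "a"])
        with pytest.warns(UserWarning, match="degenerate"):
            assert iota(m) == 1.0

    def test_requires_two_judges_and_objects(self):
        with pytest.raises(AssessmentError):
            iota(matrix_from_arrays(["a", "b"]))
        with pytest.raises(AssessmentError):
            iota(matrix_from_arrays(["a"], ["b"]))

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n_obj = int(rng.integers(2, 21))
        n_judges = int(rng.integers(2, 5))
        n_vars = int(rng.integers(1, 6))
        alphabet = ["u", "v", "w"]
        values = rng.choice(alphabet, size=(n_obj, n_judges, n_vars)).astype(object)
        m = RatingMatrix(
            [f"o{i}" for i in range(n_obj)],
            [f"j{i}" for i in range(n_judges)],
            values,
        )
        assert iota(m) == pytest.approx(iota_oracle(m), abs=1e-12)

    def test_invariant_to_relabeling_and_reordering(self):
        rng = np.random.default_rng(99)
        values = rng.choice(["x", "y", "z"], size=(8, 3, 2)).astype(object)
        m = RatingMatrix([f"o{i}" for i in range(8)], list("abc"), values)
        base = iota(m)
        relabeled = np.vectorize({"x": "q", "y": "r", "z": "s"}.get)(values).astype(object)
        perm_obj = rng.permutation(8)
        perm_judge = rng.permutation(3)
        shuffled = relabeled[perm_obj][:, perm_judge]
        m2 = RatingMatrix([f"o{i}" for i in range(8)], list("abc"), shuffled)
        assert iota(m2) == pytest.approx(base, abs=1e-12)


class TestRatingMatrixAssembly:
    def test_incomplete_matrix_rejected(self):
        a = [
            informative("c1", "r1", SIG_A),
            informative("c2", "r1", SIG_B),
            informative("c1", "r2", SIG_A),
        ]
        with pytest.raises(AssessmentError, match="missing"):
            RatingMatrix.from_assessments(a)

    def test_duplicate_cell_rejected(self):
        a = [informative("c1", "r1", SIG_A), informative("c1", "r1", SIG_A)]
        with pytest.raises(AssessmentError, match="duplicate"):
            RatingMatrix.from_assessments(a)

    def test_assembly_and_iota_end_to_end(self):
        a = [
            informative("c1", "r1", SIG_A),
            informative("c2", "r1", SIG_B),
            informative("c1", "r2", SIG_A),
            informative("c2", "r2", SIG_B),
        ]
        assert iota(RatingMatrix.from_assessments(a)) == pytest.approx(1.0)


class TestResolveDisagreements:
    def test_full_agreement_needs_no_overrides(self):
        m = RatingMatrix.from_assessments(
            [
                informative("c1", "r1", SIG_A),
                informative("c1", "r2", SIG_A),
                informative("c2", "r1", SIG_B),
                informative("c2", "r2", SIG_B),
            ]
        )
        resolved = resolve_disagreements(m)
        assert resolved["c1"].signature == Signature(*SIG_A)
        assert resolved["c2"].signature == Signature(*SIG_B)

    def test_override_applied_to_disagreeing_cell(self):
        sig_disagree = ("medical", "high", "high", "high", "low")
        m = RatingMatrix.from_assessments(
            [
                informative("c1", "r1", SIG_A),
                informative("c1", "r2", sig_disagree),
                informative("c2", "r1", SIG_B),
                informative("c2", "r2", SIG_B),
            ]
        )
        resolved = resolve_disagreements(m, {("c1", "value"): "high"})
        assert resolved["c1"].signature == Signature(*SIG_A)

    def test_unresolved_disagreement_names_cell(self):
        sig_disagree = ("medical", "high", "high", "high", "low")
        m = RatingMatrix.from_assessments(
            [
                informative("c1", "r1", SIG_A),
                informative("c1", "r2", sig_disagree),
                informative("c2", "r1", SIG_B),
                informative("c2", "r2", SIG_B),
            ]
        )
        with pytest.raises(AssessmentError, match=r"c1.*value"):
            resolve_disagreements(m)

    def test_override_for_unknown_cell_rejected(self):
        m = RatingMatrix.from_assessments(
            [
                informative("c1", "r1", SIG_A),
                informative("c1", "r2", SIG_A),
                informative("c2", "r1", SIG_B),
                informative("c2", "r2", SIG_B),
            ]
        )
        with pytest.raises(AssessmentError, match="unknown cluster"):
            resolve_disagreements(m, {("nope", "value"): "high"})
        with pytest.raises(AssessmentError, match="invalid"):
            resolve_disagreements(m, {("c1", "value"): "medical"})


class TestExcludeUninformative:
    def test_all_informative(self):
        a = [informative("c1", "r", SIG_A)]
        split = exclude_uninformative(a)
        assert len(split.informative) == 1 and split.uninformative == []

    def test_mixed_flags_with_app_totals(self):
        assessments = [informative(f"c{i}", "r", SIG_A) for i in range(3)] + [
            ClusterAssessment(cluster_id=f"u{i}", rater_id="r", informative=False)
            for i in range(2)
        ]
        sizes = {"c0": 10, "c1": 20, "c2": 30, "u0": 5, "u1": 7}
        split = exclude_uninformative(assessments, sizes)
        assert len(split.informative) == 3 and len(split.uninformative) == 2
        assert split.informative_apps == 60 and split.uninformative_apps == 12

    def test_missing_size_rejected(self):
        with pytest.raises(AssessmentError, match="size"):
            exclude_uninformative([informative("c1", "r", SIG_A)], {})

    def test_uninformative_with_values_rejected(self):
        with pytest.raises(AssessmentError):
            ClusterAssessment(
                cluster_id="c", rater_id="r", informative=False, leaks="high"
            )


class TestConsolidate:
    def test_single_signature_single_archetype(self):
        resolved = {f"c{i}": informative(f"c{i}", "resolved", SIG_A) for i in range(4)}
        sizes = {f"c{i}": 10 for i in range(4)}
        (at,) = consolidate(resolved, sizes)
        assert at.cluster_count == 4 and at.app_count == 40
        assert at.signature == Signature(*SIG_A)

    def test_distinct_signature_count(self):
        rng = np.random.default_rng(3)
        sigs = []
        for _ in range(20):
            sigs.append(
                (
                    rng.choice(["standard", "nonstandard", "medical"]),
                    *rng.choice(["none", "low", "high"], size=4),
                )
            )
        resolved = {f"c{i}": informative(f"c{i}", "r", s) for i, s in enumerate(sigs)}
        sizes = {f"c{i}": 1 for i in range(20)}
        archetypes = consolidate(resolved, sizes)
        assert len(archetypes) == len({tuple(s) for s in sigs})
        assert sum(a.app_count for a in archetypes) == 20

    def test_permutation_invariance(self):
        sigs = [SIG_A, SIG_B, SIG_A, SIG_C]
        resolved = [informative(f"c{i}", "r", s) for i, s in enumerate(sigs)]
        sizes = {f"c{i}": i + 1 for i in range(4)}
        fwd = consolidate(resolved, sizes)
        rev = consolidate(list(reversed(resolved)), sizes)
        assert fwd == rev

    def test_severity_ordering_matches_reference_taxonomy(self):
        reference = load_reference_archetypes()
        clusters = {}
        sizes = {}
        cid = 0
        for at in reference:
            for _ in range(at.cluster_count):
                name = f"c{cid:03d}"
                clusters[name] = informative(name, "r", at.signature)
                sizes[name] = at.app_count // at.cluster_count
                cid += 1
        archetypes = consolidate(clusters, sizes)
        assert len(archetypes) == 12
        assert [a.signature for a in archetypes] == [a.signature for a in reference]
        assert [a.cluster_count for a in archetypes] == [
            a.cluster_count for a in reference
        ]

    def test_missing_cluster_size_listed(self):
        resolved = {"c1": informative("c1", "r", SIG_A)}
        with pytest.raises(AssessmentError, match="c1"):
            consolidate(resolved, {})

    def test_severity_key_orders_levels(self):
        low = Signature("standard", "none", "none", "none", "none")
        high = Signature("medical", "high", "high", "high", "high")
        assert severity_key(low) < severity_key(high)


def test_assessment_csv_roundtrip(tmp_path):
    assessments = [
        informative("c1", "r1", SIG_A, annotation="records"),
        ClusterAssessment(cluster_id="c2", rater_id="r1", informative=False),
    ]
    write_assessments(assessments, tmp_path / "a.csv")
    assert read_assessments(tmp_path / "a.csv") == assessments


def test_archetype_outputs(tmp_path):
    archetypes = load_reference_archetypes()
    write_archetypes(archetypes, tmp_path / "at.csv")
    text = (tmp_path / "at.csv").read_text()
    assert "medical,high,high,high,high,25,2098" in text
    md = archetypes_to_markdown(archetypes)
    assert "| 12 | medical | high | high | high | high | 25 (14.3) | 2098 (11.67) |" in md
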