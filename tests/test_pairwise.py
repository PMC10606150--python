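import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from snptree.matrix_io import AllelicState, GenotypeMatrix
from snptree.pairwise import (
    Candidate,
    Relation,
    build_relation_table,
    classify_pair,
    downstream_table,
    one_way_assessment,
    remove_contradictory,
)
from snptree.simulate import SimulationConfig, simulate

A, D, X = AllelicState.ANCESTRAL, AllelicState.DERIVED, AllelicState.MISSING

EDU = Candidate.EQUAL | Candidate.DOWNSTREAM | Candidate.UPSTREAM
PU = Candidate.PARALLEL | Candidate.UPSTREAM
ALL = EDU | Candidate.PARALLEL


def _mat(rows: dict[str, str]) -> GenotypeMatrix:
    code = {"A": 0, "D": 1, "X": 2}
    names = list(rows)
    n = len(next(iter(rows.values())))
    grid = np.array([[code[c] for c in rows[v]] for v in names], dtype=np.int8)
    return GenotypeMatrix(names, [f"S{i}" for i in range(1, n + 1)], grid)


class TestOneWayAssessment:
    @pytest.mark.parametrize(
        "observed, expected",
        [
            ([D], EDU),
            ([D, A], Candidate.UPSTREAM),
            ([A], PU),
            ([X], ALL),
            ([D, X], EDU),
            ([A, X], PU),
            ([A, D, X], Candidate.UPSTREAM),
        ],
        ids=["D", "D+A", "A", "X", "D+X", "A+X", "A+D+X"],
    )
    def test_rule_table(self, observed, expected):
        assert one_way_assessment(observed) == expected

    def test_multiplicities_are_irrelevant(self):
        assert one_way_assessment([D, D, D]) == EDU
        assert one_way_assessment([A, A, X, X]) == PU

    def test_empty_restriction_is_an_error(self):
        with pytest.raises(ValueError):
            one_way_assessment([])

    @given(
        st.lists(st.sampled_from([A, D, X]), min_size=2, max_size=8),
        st.data(),
    )
    @settings(max_examples=200, derandomize=True)
    def test_masking_one_observation_never_shrinks_the_candidate_set(
        self, states, data
    ):
        idx = data.draw(st.integers(0, len(states) - 1))
        masked = list(states)
        masked[idx] = X
        before = one_way_assessment(states)
        after = one_way_assessment(masked)
        assert before & after == before  # after is a superset


class TestClassifyPair:
    def test_worked_consensus_is_upstream(self, demo):
        assert classify_pair(demo, "M1", "M3") is Relation.UPSTREAM
        assert classify_pair(demo, "M3", "M1") is Relation.DOWNSTREAM

    def test_recurrent_variant_is_contradictory(self, demo):
        assert classify_pair(demo, "M9", "M16") is Relation.CONTRADICTORY

    def test_identical_columns_are_equal_unresolved(self):
        m = _mat({"a": "DDAA", "b": "DDAA"})
        assert classify_pair(m, "a", "b") is Relation.EQUAL_UNRESOLVED

    def test_disjoint_carriers_are_parallel(self):
        m = _mat({"a": "DDAA", "b": "AADD"})
        assert classify_pair(m, "a", "b") is Relation.PARALLEL

    def test_derived_only_under_missing_is_uninformative(self):
        # b is derived only where a is missing: the {X}-row gives the full
        # candidate set, which intersects {parallel, upstream} to nothing usable
        m = _mat({"a": "DAXA", "b": "AADA"})
        assert classify_pair(m, "a", "b") is Relation.UNINFORMATIVE

    @pytest.mark.parametrize("seed", range(3))
    def test_mirror_symmetry_everywhere(self, seed, demo):
        _, sim = simulate(
            SimulationConfig(
                n_branches=5, n_variants=12, n_individuals=10,
                missing_rate=0.4, homoplasy_count=1, seed=seed,
            )
        )
        mirror = {
            Relation.UPSTREAM: Relation.DOWNSTREAM,
            Relation.DOWNSTREAM: Relation.UPSTREAM,
        }
        for m in (demo, sim):
            for i, v in enumerate(m.variant_names):
                for w in m.variant_names[i + 1 :]:
                    fwd = classify_pair(m, v, w)
                    rev = classify_pair(m, w, v)
                    assert rev is mirror.get(fwd, fwd)


class TestRelationTable:
    def test_matches_classify_pair_and_known_relations(self, demo):
        table = build_relation_table(demo)
        for v, w in [("M1", "M2"), ("M5", "M6"), ("M9", "M11")]:
            assert table.label(v, w) is Relation.UPSTREAM
        for v, w, lab in table.pairs():
            assert classify_pair(demo, v, w) is lab


class TestRemoveContradictory:
    def test_demo_removes_only_the_recurrent_variant(self, demo):
        table = build_relation_table(demo)
        cleaned, records = remove_contradictory(table)
        assert [(r.variant, r.n_contradictions, r.removal_round) for r in records] == [
            ("M16", 4, 1)
        ]
        assert "M16" not in cleaned.variants
        assert all(lab is not Relation.CONTRADICTORY for *_, lab in cleaned.pairs())

    def test_contradiction_free_table_is_a_fixpoint(self, demo):
        table = build_relation_table(demo)
        cleaned, _ = remove_contradictory(table)
        again, records = remove_contradictory(cleaned)
        assert records == [] and again.variants == cleaned.variants

    def test_max_count_variant_goes_first(self):
        # c carries a recurrent mutation: derived with a's carriers and with
        # b's carriers, so it contradicts both while a and b are clean
        m = _mat({"a": "DDAAAA", "b": "AAADDA", "c": "DAADAA"})
        table = build_relation_table(m)
        counts = table.contradiction_counts()
        assert counts["c"] == 2
        cleaned, records = remove_contradictory(table)
        assert [r.variant for r in records] == ["c"]
        assert records[0].removal_round == 1
        assert set(cleaned.variants) == {"a", "b"}


class TestDownstreamTable:
    def test_worked_example_rows(self, demo):
        table, _ = remove_contradictory(build_relation_table(demo))
        down = downstream_table(table)
        assert {v: set(ws) for v, ws in down.items()} == {
            "M1": {"M2", "M3"},
            "M4": {"M2", "M3"},
            "M5": {"M6", "M7"},
            "M8": {"M6"},
            "M9": {"M10", "M11", "M12", "M15"},
            "M10": {"M12"},
            "M13": {"M11", "M14"},
        }

    def test_no_upstream_labels_means_empty_mapping(self):
        m = _mat({"a": "DDAA", "b": "AADD"})
        assert downstream_table(build_relation_table(m)) == {}

    @pytest.mark.parametrize("seed", range(5))
    def test_upstream_digraph_is_acyclic_after_pruning(self, seed):
        _, m = simulate(
            SimulationConfig(
                n_branches=6, n_variants=15, n_individuals=12,
                missing_rate=0.5, homoplasy_count=2, seed=seed,
            )
        )
        table, _ = remove_contradictory(build_relation_table(m))
        down = downstream_table(table)  # raises CycleError on failure
        for v, ws in down.items():
            assert v not in ws
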