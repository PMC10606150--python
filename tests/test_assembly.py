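import numpy as np
import pytest

from snptree import build_tree
from snptree.assembly import (
    GroupedDownstream,
    assemble_tree,
    compute_certainty,
    merge_equal,
    resolve_ambiguities,
    resolve_shared_downstream,
)
from snptree.matrix_io import AllelicState, GenotypeMatrix
from snptree.pairwise import (
    build_relation_table,
    downstream_table,
    remove_contradictory,
)
from snptree.simulate import SimulationConfig, simulate


def _mat(rows: dict[str, str]) -> GenotypeMatrix:
    code = {"A": 0, "D": 1, "X": 2}
    names = list(rows)
    n = len(next(iter(rows.values())))
    grid = np.array([[code[c] for c in rows[v]] for v in names], dtype=np.int8)
    return GenotypeMatrix(names, [f"S{i}" for i in range(1, n + 1)], grid)


def _state(matrix) -> GroupedDownstream:
    table, _ = remove_contradictory(build_relation_table(matrix))
    return GroupedDownstream(matrix, table, downstream_table(table))


class TestMergeEqual:
    def test_demo_upstream_and_tip_merges(self, demo_result):
        groups = {frozenset(n.group) for n in demo_result.tree.nodes()}
        assert {"M1", "M4"} in groups
        assert {"M2", "M3"} in groups
        assert {"M6", "M7"} in groups  # co-derived tips under M5

    def test_complete_data_chain_has_no_merges(self):
        # a -> b -> c with an individual on every level: all orders strict
        m = _mat({"a": "DDDA", "b": "ADDA", "c": "AADA"})
        state = _state(m)
        assert merge_equal(state) is False
        assert all(len(g) == 1 for g in state.groups())


class TestSharedDownstreamRemoval:
    def test_demo_removes_the_smaller_nested_group(self, demo_result):
        by_scenario = {
            r.variant: r.scenario for r in demo_result.ambiguity_records
        }
        assert by_scenario["M8"] == "shared-downstream-subset"

    def test_known_relationship_prevents_removal(self):
        # b nests under a (a upstream of b is resolved), so sharing x is fine
        m = _mat({"a": "DDDA", "b": "DDAA", "x": "DAAA", "y": "AADA"})
        # a -> {b, x, y}? construct: a carriers S1,S2,S3; b S1,S2; x S1; y S3
        state = _state(m)
        resolve_shared_downstream(state)
        assert state.removals == []
        assert state.retained == {"a", "b", "x", "y"}

    def test_disjoint_downstream_sets_untouched(self, demo_result):
        # M5 and M9 both survive with disjoint subtrees
        assert {"M5", "M9"} <= set(demo_result.retained_variants)


class TestRemoveAmbiguous:
    def test_demo_scenario_outcomes(self, demo_result):
        by_scenario = {
            r.variant: r.scenario for r in demo_result.ambiguity_records
        }
        assert by_scenario == {
            "M8": "shared-downstream-subset",
            "M13": "unconnected-subtrees",
            "M15": "no-informative-placement",
            "M14": "orphaned-cascade",
        }


class TestAssembleTree:
    def test_demo_tree_topology(self, demo_result):
        tree = demo_result.tree
        assert [n.name for n in tree.root.children] == ["M1, M4", "M5", "M9"]
        main1 = (("M1", "M4"), ((("M2", "M3"), ()),))
        main2 = (("M5",), ((("M6", "M7"), ()),))
        main3 = (
            ("M9",),
            (
                (("M10",), ((("M12",), ()),)),
                (("M11",), ()),
            ),
        )
        assert tree.canonical() == ((), (main1, main2, main3))

    def test_single_variant_becomes_sole_root_child(self):
        m = _mat({"a": "DA"})
        tree = build_tree(m).tree
        assert [n.name for n in tree.root.children] == ["a"]
        assert tree.certainty["a"] is None

    def test_partition_and_single_occurrence(self, demo, demo_result):
        retained = set(demo_result.retained_variants)
        contradictory = set(demo_result.removed_contradictory)
        ambiguous = set(demo_result.removed_ambiguous)
        assert retained | contradictory | ambiguous == set(demo.variant_names)
        assert not retained & contradictory
        assert not retained & ambiguous
        assert not contradictory & ambiguous
        seen = [v for n in demo_result.tree.nodes() for v in n.group]
        assert len(seen) == len(set(seen))

    @pytest.mark.parametrize("seed", range(6))
    def test_individual_path_consistency_holds(self, seed):
        _, m = simulate(
            SimulationConfig(
                n_branches=7, n_variants=18, n_individuals=14,
                missing_rate=0.5, homoplasy_count=1, seed=seed,
            )
        )
        result = build_tree(m, drop_invalid=True)
        tree = result.tree
        present = set(tree.variants())
        for indiv in m.individual_names:
            nodes = {
                id(tree.node_of(v)): tree.node_of(v)
                for v in present
                if m.state(v, indiv) is AllelicState.DERIVED
            }
            nodes = list(nodes.values())
            for i, a in enumerate(nodes):
                for b in nodes[i + 1 :]:
                    assert (
                        a is b
                        or tree.is_ancestor(a, b)
                        or tree.is_ancestor(b, a)
                    )


class TestCertainty:
    def test_demo_certainties_are_all_consistent(self, demo_result):
        assert demo_result.tree.certainty["M5"] == 1.0
        assert all(c == 1.0 for c in demo_result.tree.certainty.values())

    def test_complete_data_simulation_gives_unit_certainty(self):
        truth, m = simulate(
            SimulationConfig(n_branches=6, n_variants=14, n_individuals=12, seed=3)
        )
        result = build_tree(m)
        assert all(c == 1.0 for c in result.tree.certainty.values())

    def test_equal_only_variant_has_no_certainty(self):
        # two indistinguishable variants merge; no informative partner remains
        m = _mat({"a": "DDA", "b": "DDA"})
        result = build_tree(m)
        assert result.tree.certainty == {"a": None, "b": None}
        assert [n.name for n in result.tree.root.children] == ["a, b"]

    @pytest.mark.parametrize("seed", range(4))
    def test_certainty_values_in_unit_interval_or_none(self, seed):
        _, m = simulate(
            SimulationConfig(
                n_branches=6, n_variants=16, n_individuals=12,
                missing_rate=0.6, seed=seed,
            )
        )
        result = build_tree(m, drop_invalid=True)
        for c in result.tree.certainty.values():
            assert c is None or 0 < c <= 1
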