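"""Two-way pairwise variant comparison, contradiction pruning, downstream table.

The core primitive: for an ordered pair (v1, v2), restrict v2's states to
the individuals in which v1 is observed derived.  The *set* of distinct
states seen there (multiplicities are irrelevant) pins v1's relationship
to v2 down to a candidate set:

    observed in v2   v1 compared to v2 is ...
    D                equal, downstream, or upstream
    D + A            upstream
    A                parallel or upstream
    X                parallel, upstream, downstream, or equal
    D + X            equal, downstream, or upstream
    A + X            parallel or upstream
    A + D + X        upstream

The same assessment run the other way round is mirrored into v1's frame
(upstream <-> downstream) and intersected with the first.  A singleton
intersection is a resolved relation; an empty intersection is a
contradiction (recurrent mutation, backmutation, or sequencing error);
an intersection containing "equal" leaves the pair unresolved; the
residual intersections {parallel, upstream} / {parallel, downstream}
carry no usable ordering information.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Iterable, Mapping

import networkx as nx
import numpy as np

from snptree.matrix_io import AllelicState, GenotypeMatrix

__all__ = [
    "Candidate",
    "Relation",
    "RelationTable",
    "ContradictionRecord",
    "one_way_assessment",
    "classify_pair",
    "build_relation_table",
    "remove_contradictory",
    "downstream_table",
    "CycleError",
]


class Candidate(enum.Flag):
    """Elementary relationship candidates produced by a one-way assessment."""

    EQUAL = enum.auto()
    UPSTREAM = enum.auto()
    DOWNSTREAM = enum.auto()
    PARALLEL = enum.auto()


_ALL = Candidate.EQUAL | Candidate.UPSTREAM | Candidate.DOWNSTREAM | Candidate.PARALLEL
_EDU = Candidate.EQUAL | Candidate.DOWNSTREAM | Candidate.UPSTREAM
_PU = Candidate.PARALLEL | Candidate.UPSTREAM
_PD = Candidate.PARALLEL | Candidate.DOWNSTREAM


class Relation(enum.Enum):
    """Final consensus relationship of an ordered variant pair."""

    UPSTREAM = "upstream"
    DOWNSTREAM = "downstream"
    PARALLEL = "parallel"
    EQUAL_UNRESOLVED = "equal"
    UNINFORMATIVE = "uninformative"
    CONTRADICTORY = "contradictory"


INFORMATIVE = frozenset({Relation.UPSTREAM, Relation.DOWNSTREAM, Relation.PARALLEL})

_MIRROR = {
    Relation.UPSTREAM: Relation.DOWNSTREAM,
    Relation.DOWNSTREAM: Relation.UPSTREAM,
    Relation.PARALLEL: Relation.PARALLEL,
    Relation.EQUAL_UNRESOLVED: Relation.EQUAL_UNRESOLVED,
    Relation.UNINFORMATIVE: Relation.UNINFORMATIVE,
    Relation.CONTRADICTORY: Relation.CONTRADICTORY,
}


def mirror(relation: Relation) -> Relation:
    """The same relation seen from the other variant's frame."""
    return _MIRROR[relation]


def one_way_assessment(observed_states: Iterable[AllelicState]) -> Candidate:
    """Candidate set for v1 vs v2 from v2's states where v1 is derived.

    Only the set of distinct states matters.  Raises ``ValueError`` on an
    empty restriction, which would violate the polymorphic-site contract
    (every variant must be observed derived somewhere).
    """
    states = set(observed_states)
    if not states:
        raise ValueError("empty restricted sequence set (non-polymorphic variant?)")
    return _candidates_from_flags(
        AllelicState.DERIVED in states,
        AllelicState.ANCESTRAL in states,
        AllelicState.MISSING in states,
    )


def _candidates_from_flags(has_d: bool, has_a: bool, has_x: bool) -> Candidate:
    if has_d and has_a:
        return Candidate.UPSTREAM
    if has_d:  # D alone or D+X
        return _EDU
    if has_a:  # A alone or A+X
        return _PU
    return _ALL  # X only


def _mirror_set(c: Candidate) -> Candidate:
    out = c & ~(Candidate.UPSTREAM | Candidate.DOWNSTREAM)
    if c & Candidate.UPSTREAM:
        out |= Candidate.DOWNSTREAM
    if c & Candidate.DOWNSTREAM:
        out |= Candidate.UPSTREAM
    return out


def _label_from_intersection(c: Candidate) -> Relation:
    if not c:
        return Relation.CONTRADICTORY
    if c == Candidate.UPSTREAM:
        return Relation.UPSTREAM
    if c == Candidate.DOWNSTREAM:
        return Relation.DOWNSTREAM
    if c == Candidate.PARALLEL:
        return Relation.PARALLEL
    if c & Candidate.EQUAL:
        return Relation.EQUAL_UNRESOLVED
    if c in (_PU, _PD):
        return Relation.UNINFORMATIVE
    raise AssertionError(f"unreachable candidate intersection {c!r}")


def classify_pair(matrix: GenotypeMatrix, v1: str, v2: str) -> Relation:
    """Consensus relationship of v1 relative to v2 via two-way comparison."""
    r1, r2 = matrix.row(v1), matrix.row(v2)
    c1 = one_way_assessment(AllelicState(s) for s in r2[r1 == AllelicState.DERIVED])
    c2 = one_way_assessment(AllelicState(s) for s in r1[r2 == AllelicState.DERIVED])
    return _label_from_intersection(c1 & _mirror_set(c2))


class RelationTable:
    """Consensus relations for every unordered pair of retained variants.

    Internally stores the label of the ordered pair (v1, v2) with
    v1 < v2 by matrix order; lookups mirror automatically, so
    ``label(a, b)`` is always expressed in ``a``'s frame.
    """

    def __init__(self, variants: list[str], labels: dict[tuple[str, str], Relation]):
        self.variants = list(variants)
        self._order = {v: i for i, v in enumerate(self.variants)}
        self._labels = labels

    def label(self, v1: str, v2: str) -> Relation:
        if v1 == v2:
            raise KeyError("self-pairs are excluded from the relation table")
        if self._order[v1] < self._order[v2]:
            return self._labels[(v1, v2)]
        return mirror(self._labels[(v2, v1)])

    def pairs(self):
        """Iterate (v1, v2, label) over canonical (matrix-ordered) pairs."""
        for (a, b), lab in self._labels.items():
            yield a, b, lab

    def restrict(self, keep: Iterable[str]) -> "RelationTable":
        keep_set = set(keep)
        variants = [v for v in self.variants if v in keep_set]
        labels = {
            (a, b): lab
            for (a, b), lab in self._labels.items()
            if a in keep_set and b in keep_set
        }
        return RelationTable(variants, labels)

    def contradiction_counts(self) -> dict[str, int]:
        counts = {v: 0 for v in self.variants}
        for a, b, lab in self.pairs():
            if lab is Relation.CONTRADICTORY:
                counts[a] += 1
                counts[b] += 1
        return counts


def build_relation_table(matrix: GenotypeMatrix) -> RelationTable:
    """Classify all unordered variant pairs (vectorised two-way comparison)."""
    S = matrix.states
    D = (S == AllelicState.DERIVED).astype(np.int32)
    A = (S == AllelicState.ANCESTRAL).astype(np.int32)
    X = (S == AllelicState.MISSING).astype(np.int32)
    # entry [i, j]: number of individuals where i is derived and j is A/D/X
    n_dd = D @ D.T
    n_da = D @ A.T
    n_dx = D @ X.T
    names = matrix.variant_names
    labels: dict[tuple[str, str], Relation] = {}
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            c1 = _candidates_from_flags(n_dd[i, j] > 0, n_da[i, j] > 0, n_dx[i, j] > 0)
            c2 = _candidates_from_flags(n_dd[j, i] > 0, n_da[j, i] > 0, n_dx[j, i] > 0)
            labels[(names[i], names[j])] = _label_from_intersection(c1 & _mirror_set(c2))
    return RelationTable(list(names), labels)


@dataclass(frozen=True)
class ContradictionRecord:
    """Audit entry for one variant removed during contradiction pruning."""

    variant: str
    n_contradictions: int
    removal_round: int


def remove_contradictory(
    table: RelationTable,
    missing_counts: Mapping[str, int] | None = None,
) -> tuple[RelationTable, list[ContradictionRecord]]:
    """Greedily remove maximally contradictory variants until none remain.

    One variant per round; counts are recomputed after every removal.
    Ties on the contradiction count are broken towards the variant with
    more missing cells (``missing_counts``), then the lexicographically
    smallest name — prefer discarding the least-observed variant, and
    stay deterministic.
    """
    missing_counts = missing_counts or {}
    records: list[ContradictionRecord] = []
    current = table
    rnd = 0
    while True:
        counts = current.contradiction_counts()
        worst = max(counts.values(), default=0)
        if worst == 0:
            return current, records
        rnd += 1
        tied = [v for v, c in counts.items() if c == worst]
        victim = min(tied, key=lambda v: (-missing_counts.get(v, 0), v))
        records.append(ContradictionRecord(victim, worst, rnd))
        current = current.restrict(v for v in current.variants if v != victim)


class CycleError(RuntimeError):
    """Internal-consistency failure: a cycle among upstream relations."""


def downstream_table(table: RelationTable) -> dict[str, frozenset[str]]:
    """Each variant's strictly downstream variants (preliminary branches).

    Only variants with a non-empty downstream set appear as keys.  The
    upstream digraph is checked to be acyclic; a cycle should be
    impossible after contradiction removal and raises :class:`CycleError`.
    """
    down: dict[str, set[str]] = {}
    g = nx.DiGraph()
    g.add_nodes_from(table.variants)
    for a, b, lab in table.pairs():
        if lab is Relation.UPSTREAM:
            down.setdefault(a, set()).add(b)
            g.add_edge(a, b)
        elif lab is Relation.DOWNSTREAM:
            down.setdefault(b, set()).add(a)
            g.add_edge(b, a)
    if not nx.is_directed_acyclic_graph(g):
        raise CycleError("cycle detected among upstream relations")
    return {v: frozenset(ws) for v, ws in down.items()}
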