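"""Equal-variant merging, ambiguity pruning, tree assembly, certainty values.

After contradiction pruning, the downstream table holds one preliminary
branch per variant.  Connecting those branches into a single rooted tree
requires (1) merging variants whose order the data cannot resolve into
"equal" groups sharing one tree position, and (2) removing variants whose
position is ambiguous — they could sit at several places without
contradicting any pairwise relation.  Four pruning scenarios are applied
in order and iterated to a fixpoint:

1. *merge*: upstream variants with mutually unresolved order, compatible
   observed states and identical downstream sets become one group; branch
   tips sharing the same immediate upstream group merge when they are
   observed co-derived in at least one individual.
2. *shared-downstream-subset*: of two unmerged groups with unresolved
   mutual order whose downstream sets are nested, the smaller is removed.
3. *unconnected-subtrees*: two groups sharing some but not all downstream
   variants, each with unique downstream variants and unresolved mutual
   order — the less resolved group is removed.
4. *no-informative-placement*: a branch tip whose relation to an entire
   sibling subtree is unresolved is removed in favour of the deeper branch.

A cascade step removes groups left with no informative relation to any
retained variant.  Finally, assembly nests groups by immediacy of the
upstream relation and enforces that the variants derived in any one
individual lie on a single root-to-tip path, removing offending single
groups parallel to the most resolved branch.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator

from snptree.matrix_io import AllelicState, GenotypeMatrix
from snptree.pairwise import INFORMATIVE, Relation, RelationTable

__all__ = [
    "EqualGroup",
    "CladeNode",
    "PhyloTree",
    "AmbiguityRemovalRecord",
    "GroupedDownstream",
    "AssemblyError",
    "merge_equal",
    "resolve_shared_downstream",
    "remove_ambiguous",
    "resolve_ambiguities",
    "assemble_tree",
    "compute_certainty",
]

EqualGroup = frozenset  # of variant names; canonical key is min(group)

SCENARIO_SHARED = "shared-downstream-subset"
SCENARIO_UNCONNECTED = "unconnected-subtrees"
SCENARIO_NO_INFO = "no-informative-placement"
SCENARIO_CASCADE = "orphaned-cascade"


@dataclass(frozen=True)
class AmbiguityRemovalRecord:
    """Audit entry for one variant removed as ambiguously placed."""

    variant: str
    scenario: str
    detail: str


class AssemblyError(RuntimeError):
    """Parent candidates could not be ordered; should be prevented upstream."""


def _gname(group: EqualGroup) -> str:
    return min(group)


class GroupedDownstream:
    """Mutable working state: retained variants partitioned into equal groups
    plus the variant-level downstream mapping, against a fixed relation table."""

    def __init__(
        self,
        matrix: GenotypeMatrix,
        rtable: RelationTable,
        down: dict[str, frozenset[str]],
    ):
        self.matrix = matrix
        self.rtable = rtable
        self.retained: set[str] = set(rtable.variants)
        self._down: dict[str, set[str]] = {
            v: set(ws) for v, ws in down.items() if v in self.retained
        }
        self.group_of: dict[str, EqualGroup] = {
            v: frozenset({v}) for v in self.retained
        }
        self.removals: list[AmbiguityRemovalRecord] = []

    # -- queries ---------------------------------------------------------

    def groups(self) -> list[EqualGroup]:
        return sorted(set(self.group_of.values()), key=_gname)

    def gdown(self, group: EqualGroup) -> frozenset[str]:
        """Variants strictly downstream of any member of ``group``."""
        out: set[str] = set()
        for m in group:
            out |= self._down.get(m, set())
        return frozenset((out & self.retained) - group)

    def keys(self) -> list[EqualGroup]:
        return [g for g in self.groups() if self.gdown(g)]

    def ups(self, group: EqualGroup) -> frozenset[EqualGroup]:
        """Groups with at least one member of ``group`` downstream of them."""
        return frozenset(
            g for g in self.groups() if g is not group and group & self.gdown(g)
        )

    def unresolved(self, g: EqualGroup, h: EqualGroup) -> bool:
        """True when no cross-pair between the groups has an informative label."""
        return all(
            self.rtable.label(a, b) not in INFORMATIVE for a in g for b in h
        )

    def states_compatible(self, g: EqualGroup, h: EqualGroup) -> bool:
        for a in g:
            ra = self.matrix.row(a)
            for b in h:
                rb = self.matrix.row(b)
                typed = (ra != AllelicState.MISSING) & (rb != AllelicState.MISSING)
                if (ra[typed] != rb[typed]).any():
                    return False
        return True

    def co_derived(self, g: EqualGroup, h: EqualGroup) -> bool:
        """Some individual is observed derived for a member of each group."""
        for a in g:
            ra = self.matrix.row(a)
            for b in h:
                rb = self.matrix.row(b)
                if ((ra == AllelicState.DERIVED) & (rb == AllelicState.DERIVED)).any():
                    return True
        return False

    def missing_load(self, group: EqualGroup) -> int:
        return sum(self.matrix.missing_count(v) for v in group)

    # -- mutations -------------------------------------------------------

    def merge(self, g: EqualGroup, h: EqualGroup) -> EqualGroup:
        merged = g | h
        for v in merged:
            self.group_of[v] = merged
        return merged

    def remove_group(self, group: EqualGroup, scenario: str, detail: str) -> None:
        for v in sorted(group):
            self.removals.append(AmbiguityRemovalRecord(v, scenario, detail))
        self.retained -= group
        for v in group:
            self._down.pop(v, None)
            self.group_of.pop(v, None)
        for ws in self._down.values():
            ws -= group


def merge_equal(state: GroupedDownstream) -> bool:
    """Scenario 1: merge equal upstream variants and co-derived sibling tips.

    Returns True when at least one merge happened.
    """
    changed = False
    # (a) upstream groups: mutually "equal", state-compatible, same downstream set
    while True:
        merged_once = False
        keys = state.keys()
        for i, g in enumerate(keys):
            for h in keys[i + 1 :]:
                if state.gdown(g) - h != state.gdown(h) - g:
                    continue
                if not state.unresolved(g, h):
                    continue
                if any(
                    state.rtable.label(a, b) is not Relation.EQUAL_UNRESOLVED
                    for a in g
                    for b in h
                ):
                    continue
                if not state.states_compatible(g, h):
                    continue
                state.merge(g, h)
                merged_once = changed = True
                break
            if merged_once:
                break
        if not merged_once:
            break
    # (b) branch tips with identical immediate upstream groups, co-derived
    tips = [g for g in state.groups() if not state.gdown(g)]
    by_ups: dict[frozenset, list[EqualGroup]] = {}
    for t in tips:
        by_ups.setdefault(state.ups(t), []).append(t)
    for cls in by_ups.values():
        cls = sorted(cls, key=_gname)
        # merge connected components of the co-derivation relation
        for i, t1 in enumerate(cls):
            for t2 in cls[i + 1 :]:
                g1, g2 = state.group_of[_gname(t1)], state.group_of[_gname(t2)]
                if g1 == g2:
                    continue
                if state.co_derived(g1, g2):
                    state.merge(g1, g2)
                    changed = True
    return changed


def _tie_victim(state: GroupedDownstream, g: EqualGroup, h: EqualGroup) -> EqualGroup:
    """Same-size ambiguous pair: drop the more missing-laden, then lex-smallest."""
    mg, mh = state.missing_load(g), state.missing_load(h)
    if mg != mh:
        return g if mg > mh else h
    return min(g, h, key=_gname)


def resolve_shared_downstream(state: GroupedDownstream) -> bool:
    """Scenario 2: nested downstream sets with unresolved mutual order."""
    changed = False
    while True:
        removed = False
        keys = state.keys()
        for g in keys:
            for h in keys:
                if g == h:
                    continue
                dg, dh = state.gdown(g), state.gdown(h)
                if not dh <= dg:
                    continue
                if not state.unresolved(g, h):
                    continue
                victim = h if dh < dg else _tie_victim(state, g, h)
                other = g if victim is h else h
                state.remove_group(
                    victim,
                    SCENARIO_SHARED,
                    f"downstream set nested in that of {_gname(other)} "
                    "with unresolved mutual order",
                )
                removed = changed = True
                break
            if removed:
                break
        if not removed:
            return changed


def remove_ambiguous(state: GroupedDownstream) -> bool:
    """Scenarios 3 and 4 plus the no-informative-relation cascade."""
    changed = False
    # scenario 3: partially overlapping subtrees, unresolved connection
    while True:
        removed = False
        keys = state.keys()
        for i, g in enumerate(keys):
            for h in keys[i + 1 :]:
                dg, dh = state.gdown(g), state.gdown(h)
                if not (dg & dh) or dg <= dh or dh <= dg:
                    continue
                if not state.unresolved(g, h):
                    continue
                if len(dg) != len(dh):
                    victim = g if len(dg) < len(dh) else h
                else:
                    victim = _tie_victim(state, g, h)
                other = g if victim is h else h
                state.remove_group(
                    victim,
                    SCENARIO_UNCONNECTED,
                    f"shares downstream variants with {_gname(other)} but the "
                    "subtrees cannot be connected",
                )
                removed = changed = True
                break
            if removed:
                break
        if not removed:
            break
    # scenario 4: tip unresolved against an entire deeper sibling subtree
    while True:
        removed = False
        tips = [g for g in state.groups() if not state.gdown(g)]
        for t in tips:
            ups_t = state.ups(t)
            if not ups_t:
                continue
            for s in state.keys():
                if s == t or not (state.ups(s) & ups_t):
                    continue
                ds = state.gdown(s)
                if t & ds:
                    continue
                subtree = [s] + sorted(
                    {state.group_of[u] for u in ds}, key=_gname
                )
                if all(state.unresolved(t, x) for x in subtree):
                    state.remove_group(
                        t,
                        SCENARIO_NO_INFO,
                        f"unresolved against the deeper sibling branch of "
                        f"{_gname(s)}",
                    )
                    removed = changed = True
                    break
            if removed:
                break
        if not removed:
            break
    # cascade: nothing informative ties the group to the rest of the tree
    while True:
        removed = False
        for g in state.groups():
            others = state.retained - g
            if not others:
                continue
            if all(
                state.rtable.label(a, b) not in INFORMATIVE
                for a in g
                for b in sorted(others)
            ):
                state.remove_group(
                    g, SCENARIO_CASCADE,
                    "no informative relation to any retained variant",
                )
                removed = changed = True
                break
        if not removed:
            break
    return changed


def resolve_ambiguities(state: GroupedDownstream) -> None:
    """Iterate merge -> scenario 2 -> scenarios 3/4/cascade to a fixpoint."""
    while True:
        changed = merge_equal(state)
        changed |= resolve_shared_downstream(state)
        changed |= remove_ambiguous(state)
        if not changed:
            return


@dataclass
class CladeNode:
    """One tree position: a group of equal variants (or the synthetic root)."""

    group: EqualGroup | None
    children: list["CladeNode"] = field(default_factory=list)
    parent: "CladeNode | None" = field(default=None, repr=False)

    @property
    def name(self) -> str:
        return "" if self.group is None else ", ".join(sorted(self.group))

    def walk(self) -> Iterator["CladeNode"]:
        yield self
        for c in self.children:
            yield from c.walk()

    def subtree_group_count(self) -> int:
        return sum(1 for n in self.walk() if n.group is not None)


class PhyloTree:
    """Rooted tree of equal-variant groups with per-variant certainty values."""

    def __init__(self, root: CladeNode):
        self.root = root
        self.certainty: dict[str, float | None] = {}
        self._node_of: dict[str, CladeNode] = {}
        for node in root.walk():
            if node.group is not None:
                for v in node.group:
                    self._node_of[v] = node

    def nodes(self) -> list[CladeNode]:
        """Depth-first pre-order, excluding the synthetic root."""
        return [n for n in self.root.walk() if n.group is not None]

    def variants(self) -> list[str]:
        return sorted(self._node_of)

    def node_of(self, variant: str) -> CladeNode:
        return self._node_of[variant]

    def is_ancestor(self, a: CladeNode, b: CladeNode) -> bool:
        """True when ``a`` is a proper ancestor of ``b``."""
        cur = b.parent
        while cur is not None:
            if cur is a:
                return True
            cur = cur.parent
        return False

    def canonical(self):
        """Order-independent canonical form, for tree-equality comparisons."""

        def canon(node: CladeNode):
            kids = tuple(sorted(canon(c) for c in node.children))
            label = tuple(sorted(node.group)) if node.group is not None else ()
            return (label, kids)

        return canon(self.root)


def _build_tree(state: GroupedDownstream) -> PhyloTree:
    groups = state.groups()
    parent: dict[EqualGroup, EqualGroup | None] = {}
    for h in groups:
        candidates = sorted(state.ups(h), key=_gname)
        if not candidates:
            parent[h] = None
        elif len(candidates) == 1:
            parent[h] = candidates[0]
        else:
            # the immediate parent is downstream of every other candidate
            immediate = [
                p
                for p in candidates
                if all(q is p or (p & state.gdown(q)) for q in candidates)
            ]
            if len(immediate) != 1:
                raise AssemblyError(
                    f"cannot order upstream candidates {[_gname(c) for c in candidates]} "
                    f"of group {_gname(h)}"
                )
            parent[h] = immediate[0]
    root = CladeNode(None)
    node_map: dict[EqualGroup, CladeNode] = {g: CladeNode(g) for g in groups}
    for g in groups:
        p = parent[g]
        pnode = root if p is None else node_map[p]
        node_map[g].parent = pnode
        pnode.children.append(node_map[g])
    for node in root.walk():
        node.children.sort(key=lambda n: _gname(n.group))
    return PhyloTree(root)


def _consistency_victims(tree: PhyloTree, matrix: GenotypeMatrix) -> list[EqualGroup]:
    """Groups violating the one-path-per-individual contract, to remove.

    For every individual, the tree positions of its observed-derived
    variants must form a chain under ancestry.  For each incomparable
    pair the node in the less resolved branch below their deepest common
    ancestor loses (ties: lexicographically larger branch root loses).
    """
    victims: set[EqualGroup] = set()
    present = set(tree.variants())
    for j, indiv in enumerate(matrix.individual_names):
        nodes: list[CladeNode] = []
        seen: set[int] = set()
        for v in matrix.variant_names:
            if v in present and matrix.state(v, indiv) is AllelicState.DERIVED:
                n = tree.node_of(v)
                if id(n) not in seen:
                    seen.add(id(n))
                    nodes.append(n)
        for a_i in range(len(nodes)):
            for b_i in range(a_i + 1, len(nodes)):
                a, b = nodes[a_i], nodes[b_i]
                if tree.is_ancestor(a, b) or tree.is_ancestor(b, a):
                    continue
                branch_a = _branch_below_lca(tree, a, b)
                branch_b = _branch_below_lca(tree, b, a)
                sa, sb = branch_a.subtree_group_count(), branch_b.subtree_group_count()
                if sa != sb:
                    loser = a if sa < sb else b
                else:
                    loser = (
                        a
                        if _gname(branch_a.group) > _gname(branch_b.group)
                        else b
                    )
                victims.add(loser.group)
    return sorted(victims, key=_gname)


def _branch_below_lca(tree: PhyloTree, node: CladeNode, other: CladeNode) -> CladeNode:
    """The child of lca(node, other) on the path towards ``node``."""
    ancestors_other = set()
    cur: CladeNode | None = other
    while cur is not None:
        ancestors_other.add(id(cur))
        cur = cur.parent
    cur = node
    while cur.parent is not None and id(cur.parent) not in ancestors_other:
        cur = cur.parent
    return cur


def assemble_tree(state: GroupedDownstream) -> PhyloTree:
    """Nest groups into the rooted tree and enforce per-individual paths.

    Mutates ``state`` when the one-path-per-individual contract forces
    further removals (recorded in ``state.removals``); the ambiguity
    scenarios are re-run after every such removal.
    """
    while True:
        tree = _build_tree(state)
        victims = _consistency_victims(tree, state.matrix)
        if not victims:
            return tree
        for group in victims:
            state.remove_group(
                group,
                SCENARIO_CASCADE,
                "parallel to a more resolved branch carrying variants "
                "derived in the same individual",
            )
        resolve_ambiguities(state)


def compute_certainty(
    tree: PhyloTree, rtable: RelationTable
) -> dict[str, float | None]:
    """Fraction of informative pairwise relations consistent with the tree.

    For each retained variant the denominator counts retained partners
    with an informative (upstream/downstream/parallel) relation; the
    numerator counts those whose relation matches the final topology.
    ``None`` when no informative partner exists.
    """
    retained = tree.variants()
    out: dict[str, float | None] = {}
    for v in retained:
        nv = tree.node_of(v)
        num = den = 0
        for w in retained:
            if w == v:
                continue
            lab = rtable.label(v, w)
            if lab not in INFORMATIVE:
                continue
            den += 1
            nw = tree.node_of(w)
            if lab is Relation.UPSTREAM:
                ok = tree.is_ancestor(nv, nw)
            elif lab is Relation.DOWNSTREAM:
                ok = tree.is_ancestor(nw, nv)
            else:  # PARALLEL
                ok = (
                    nv is not nw
                    and not tree.is_ancestor(nv, nw)
                    and not tree.is_ancestor(nw, nv)
                )
            num += ok
        out[v] = None if den == 0 else num / den
    return out
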