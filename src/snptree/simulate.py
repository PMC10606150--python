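"""Synthetic perfect-phylogeny matrices with controlled missingness/homoplasy.

The generator draws a random rooted branch tree, distributes variants
over its branches, and assigns each individual to a branch: the
individual is derived for every variant on its root path and ancestral
elsewhere.  Cells are then independently masked to missing, and an
optional number of variants is flipped to derived in one off-path
individual to plant recurrent mutations (which the pipeline should
detect as contradictions).

The true phylogeny is kept alongside the matrix and serves as the oracle
for recovery and precision tests: with no masking and no homoplasy the
pipeline must reconstruct it exactly, and under masking no informative
relation the pipeline reports may contradict it.

Every branch receives at least one variant and at least one individual,
so every branch is identifiable from complete data (an unsampled
single-child branch would be indistinguishable from its child).  No
coalescent or mutation-rate realism is attempted; the generator targets
the combinatorial contract of the method.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from snptree.assembly import CladeNode, PhyloTree
from snptree.matrix_io import AllelicState, GenotypeMatrix
from snptree.pairwise import INFORMATIVE, Relation

__all__ = [
    "TruePhylogeny",
    "SimulationConfig",
    "simulate",
    "mask_more",
    "check_precision",
]

_MASK_RETRIES = 20


@dataclass
class TruePhylogeny:
    """Ground-truth branch tree: parent of each branch (None = root child)
    and the variants carried by each branch."""

    parent: dict[str, str | None]
    variants_per_branch: dict[str, list[str]]

    def branches(self) -> list[str]:
        return sorted(self.parent)

    def branch_of(self, variant: str) -> str:
        for b, vs in self.variants_per_branch.items():
            if variant in vs:
                return b
        raise KeyError(variant)

    def path(self, branch: str) -> list[str]:
        """Branches from a root child down to ``branch`` inclusive."""
        out = [branch]
        while (p := self.parent[out[-1]]) is not None:
            out.append(p)
        return out[::-1]

    def relation(self, v: str, w: str) -> str:
        """True relation of variant v to w: upstream/downstream/parallel/equal."""
        bv, bw = self.branch_of(v), self.branch_of(w)
        if bv == bw:
            return "equal"
        if bv in self.path(bw):
            return "upstream"
        if bw in self.path(bv):
            return "downstream"
        return "parallel"

    def expected_tree(self) -> PhyloTree:
        """The tree the pipeline should reconstruct from complete data."""
        root = CladeNode(None)
        nodes = {
            b: CladeNode(frozenset(vs))
            for b, vs in self.variants_per_branch.items()
        }
        for b in self.branches():
            p = self.parent[b]
            pnode = root if p is None else nodes[p]
            nodes[b].parent = pnode
            pnode.children.append(nodes[b])
        for node in root.walk():
            node.children.sort(key=lambda n: min(n.group))
        return PhyloTree(root)

    def drop_variants(self, variants: set[str]) -> None:
        for b in list(self.variants_per_branch):
            self.variants_per_branch[b] = [
                v for v in self.variants_per_branch[b] if v not in variants
            ]

    def to_json(self, path: str | Path) -> None:
        payload = {
            b: {"parent": self.parent[b], "variants": self.variants_per_branch[b]}
            for b in self.branches()
        }
        Path(path).write_text(json.dumps(payload, indent=1), encoding="utf-8")

    @classmethod
    def from_json(cls, path: str | Path) -> "TruePhylogeny":
        payload = json.loads(Path(path).read_text(encoding="utf-8"))
        return cls(
            parent={b: d["parent"] for b, d in payload.items()},
            variants_per_branch={b: list(d["variants"]) for b, d in payload.items()},
        )


@dataclass
class SimulationConfig:
    """Knobs of the generator; defaults give a small, fully typed dataset."""

    n_branches: int = 8
    n_variants: int = 16
    n_individuals: int = 16
    missing_rate: float = 0.0
    homoplasy_count: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.missing_rate < 1):
            raise ValueError("missing_rate must be in [0, 1)")
        if self.n_variants < self.n_branches:
            raise ValueError("need at least one variant per branch")
        if self.n_individuals < self.n_branches:
            raise ValueError("need at least one individual per branch")


def simulate(config: SimulationConfig) -> tuple[TruePhylogeny, GenotypeMatrix]:
    """Draw a true phylogeny and the matrix observed from it."""
    rng = np.random.default_rng(config.seed)
    nb = config.n_branches
    branch_ids = [f"B{i + 1}" for i in range(nb)]
    parent: dict[str, str | None] = {}
    for i, b in enumerate(branch_ids):
        if i < min(2, nb):  # the root keeps >=2 children so root-level
            parent[b] = None  # variants stay polymorphic
        else:
            choices = [None] + branch_ids[:i]
            parent[b] = choices[rng.integers(len(choices))]
    truth = TruePhylogeny(parent, {b: [] for b in branch_ids})

    variant_ids = [f"v{i + 1}" for i in range(config.n_variants)]
    for i, v in enumerate(variant_ids):
        b = branch_ids[i] if i < nb else branch_ids[rng.integers(nb)]
        truth.variants_per_branch[b].append(v)

    indiv_ids = [f"S{i + 1}" for i in range(config.n_individuals)]
    indiv_branch: dict[str, str] = {}
    for i, s in enumerate(indiv_ids):
        indiv_branch[s] = branch_ids[i] if i < nb else branch_ids[rng.integers(nb)]

    states = np.zeros((config.n_variants, config.n_individuals), dtype=np.int8)
    vindex = {v: i for i, v in enumerate(variant_ids)}
    for j, s in enumerate(indiv_ids):
        for b in truth.path(indiv_branch[s]):
            for v in truth.variants_per_branch[b]:
                states[vindex[v], j] = AllelicState.DERIVED

    if config.homoplasy_count:
        flippable = rng.permutation(config.n_variants)
        flipped = 0
        for vi in flippable:
            if flipped == config.homoplasy_count:
                break
            v = variant_ids[vi]
            own_path = set(truth.path(truth.branch_of(v)))
            off_path = [
                j
                for j, s in enumerate(indiv_ids)
                if states[vi, j] == AllelicState.ANCESTRAL
            ]
            if not off_path:
                continue

            # prefer a carrier of >=2 foreign variants that are also carried
            # by someone else: each such variant then contradicts the
            # recurrent one (which collects strictly more contradictions
            # than any partner); a variant whose only carrier is the target
            # individual would instead make the recurrence look ancestral
            def foreign_load(j: int) -> int:
                load = 0
                for b in truth.path(indiv_branch[indiv_ids[j]]):
                    if b in own_path:
                        continue
                    if any(
                        k != j and b in truth.path(indiv_branch[indiv_ids[k]])
                        for k in range(config.n_individuals)
                    ):
                        load += len(truth.variants_per_branch[b])
                return load

            rich = [j for j in off_path if foreign_load(j) >= 2]
            pool = rich or off_path
            states[vi, pool[rng.integers(len(pool))]] = AllelicState.DERIVED
            flipped += 1

    if config.missing_rate > 0:
        for vi in range(config.n_variants):
            row = states[vi].copy()
            for _ in range(_MASK_RETRIES):
                mask = rng.random(config.n_individuals) < config.missing_rate
                masked = row.copy()
                masked[mask] = AllelicState.MISSING
                if (masked == AllelicState.DERIVED).any() and (
                    masked == AllelicState.ANCESTRAL
                ).any():
                    states[vi] = masked
                    break
            else:
                states[vi] = row  # keep fully typed rather than drop

    matrix = GenotypeMatrix(variant_ids, indiv_ids, states)
    return truth, matrix


def mask_more(
    matrix: GenotypeMatrix, additional_rate: float, seed: int
) -> GenotypeMatrix:
    """Mask currently typed cells with the given probability (nested masking)."""
    if not (0 <= additional_rate < 1):
        raise ValueError("additional_rate must be in [0, 1)")
    rng = np.random.default_rng(seed)
    states = matrix.states.copy()
    typed = states != AllelicState.MISSING
    mask = (rng.random(states.shape) < additional_rate) & typed
    states[mask] = AllelicState.MISSING
    return GenotypeMatrix(
        list(matrix.variant_names), list(matrix.individual_names), states
    )


_CONSISTENT = {
    Relation.UPSTREAM: "upstream",
    Relation.DOWNSTREAM: "downstream",
    Relation.PARALLEL: "parallel",
}


def check_precision(truth: TruePhylogeny, result) -> list[str]:
    """Violations of the truth by the pipeline's asserted relationships.

    Checks every informative pairwise relation among the variants placed
    in the tree, and that merged equal groups never join truly parallel
    variants.  Returns human-readable violation messages (empty = the
    output never contradicts the truth).
    """
    violations: list[str] = []
    retained = result.tree.variants()
    for i, v in enumerate(retained):
        for w in retained[i + 1 :]:
            lab = result.relation_table.label(v, w)
            if lab in INFORMATIVE and truth.relation(v, w) != _CONSISTENT[lab]:
                violations.append(
                    f"{v} vs {w}: asserted {lab.value}, truth {truth.relation(v, w)}"
                )
    for node in result.tree.nodes():
        members = sorted(node.group)
        for i, v in enumerate(members):
            for w in members[i + 1 :]:
                if truth.relation(v, w) == "parallel":
                    violations.append(f"{v} and {w} merged but truly parallel")
    return violations
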