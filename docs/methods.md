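# Methods

## Model and assumptions

`snptree` assumes an infinite-sites-like regime on a non-recombining locus:
each variant arises once on a single lineage and never reverts, so the true
history is a rooted tree in which every variant sits on exactly one branch
and an individual is derived for precisely the variants on its root-to-tip
path. Input calls are already oriented (ancestral vs derived against an
outgroup); the method neither re-orients nor imputes. Deviations from the
model — recurrent mutations, backmutations, genotyping errors — surface as
*contradictory* pairwise relations and are pruned rather than modelled.

## Pairwise classification

For an ordered pair (v₁, v₂), the states of v₂ restricted to individuals
where v₁ is observed derived are reduced to their distinct-state set, which
maps to a candidate set over {equal, upstream, downstream, parallel} (seven
rules; multiplicities never matter). The two one-way candidate sets — the
second mirrored into v₁'s frame — are intersected:

- singleton → resolved relation (upstream / downstream / parallel);
- empty → contradictory;
- containing *equal* → equal-unresolved (the data cannot order the pair);
- {parallel, upstream} or {parallel, downstream} → uninformative.

Equal-unresolved and uninformative are distinguished internally: only the
former can justify merging two variants onto one branch, and neither counts
towards certainty denominators. Masking an observation can only grow a
one-way candidate set, so missing data moves pairs monotonically from
resolved towards unresolved — never from one resolved relation to another.
This is the formal sense in which missing data costs resolution, not
correctness.

## Contradiction pruning

Contradictions are counted per variant; the variant with the maximal count
is removed and counts are recomputed, one variant per round, until none
remain. Ties are broken towards the variant with more missing cells (prefer
discarding the least observed), then the lexicographically smallest name —
both choices are ours, made for determinism; the original procedure's
tie-break is not documented anywhere we could follow.

## Equal merging and ambiguity removal

The downstream table (variant → strictly downstream variants) gives one
preliminary branch per variant. Four scenarios are applied in order and
iterated to a fixpoint:

1. **Merge.** Upstream variants that are pairwise equal-unresolved, agree
   at every individual where both are typed, and have identical downstream
   sets become one group. Branch tips (empty downstream sets) with
   *identical* sets of immediate upstream groups merge when observed
   co-derived in at least one individual. Requiring identical upstream sets
   (not merely an overlap) is deliberate: an overlap rule would merge a tip
   into a sibling that a deeper subtree still needs to displace, and the
   fixpoint iteration lets legitimate merges happen on a later pass once
   scenario 2 has cleared the offending upstream variant. Tips with no
   upstream at all may merge with each other under the same co-derivation
   condition; otherwise two co-derived root tips would end up as sister
   clades and immediately violate the one-path-per-individual contract.
2. **Shared-downstream-subset.** Two unmerged groups with unresolved mutual
   order whose downstream sets are nested: the group with the strictly
   smaller set is removed (equal-sized sets: more missing cells loses, then
   lexicographic).
3. **Unconnected-subtrees.** Two groups sharing some downstream variants,
   each with unique ones, mutual order unresolved: the group with fewer
   downstream variants is removed (same tie-break).
4. **No-informative-placement.** A tip unresolved against a deeper sibling
   branch (the sibling and its entire downstream set) and sharing no
   downstream variant with it is removed in favour of tree depth.

A cascade removes any group left with no informative relation to any other
retained variant (unplaceable); it never fires on a matrix whose variants
all belong to one group, since there is nothing to place them against.

## Assembly and the one-path contract

Groups nest by immediacy: the parent of a group is the upstream candidate
that is itself downstream of every other candidate. Groups with no upstream
attach to a synthetic, unlabeled root. After assembly, the variants derived
in any one individual must lie on a single root-to-tip path; for each
violating incomparable pair, the group in the less resolved branch below
the deepest common ancestor (fewer groups in the subtree; lexicographic on
ties) is removed as ambiguous, the pruning scenarios are re-run, and the
tree is rebuilt. In the shipped demonstration matrix this rule — not the
cascade — is what removes `M14`: it is parallel to two main branches but
shares a carrier with a four-group branch it cannot be ordered against.

## Certainty values

For each retained variant, the denominator counts retained partners with an
informative pairwise relation (computed against the post-contradiction
relation table; removed-ambiguous variants are excluded from both sides),
the numerator those relations consistent with the final topology
(upstream ⇔ proper ancestor, parallel ⇔ disjoint positions). Variants with
no informative partner get `NA`. Values are reported with two decimals.

## Synthetic data generator

`snptree.simulate` draws a rooted branch tree by sequential random
attachment (the root keeps at least two children so root-level variants
stay polymorphic), gives every branch at least one variant and at least one
individual (hence `n_individuals ≥ n_branches`: an unsampled single-child
internal branch is mathematically indistinguishable from its child, and
exact recovery would be ill-posed), and fills the matrix by path membership.
Defaults are 8 branches, 16 variants, 16 individuals, no missing data, no
homoplasy — a small, fully identifiable regime in which the pipeline must
reproduce the generator exactly.

Missingness masks each cell independently at the configured rate; rows
rendered non-polymorphic are re-drawn up to 20 times, then kept fully typed
(dropping them would orphan true branches and break the oracle). Planted
recurrent mutations flip one off-path individual to derived, preferring an
individual carrying at least two foreign variants that also have another
carrier — exactly the configuration in which the recurrence is provably
detected and uniquely attributed (each foreign variant contradicts the
recurrent one, which therefore accumulates the strictly largest count). A
recurrence whose target individual is the sole carrier of its branch
instead masquerades as an upstream variant and is undetectable by design —
the same failure mode known from real data, where recurrent variants
present in *all* individuals of a clade pass through unflagged.

What the generator does not emulate: genotype-call noise, reference bias,
correlated (per-individual or per-region) missingness, and realistic
branch-length/frequency structure. Passing tests therefore demonstrate the
combinatorial correctness of the algorithm under its own model, not robustness
to every artefact of real sequencing data.

## Problem sizes and test design

The correctness suite runs at desk scale, chosen to keep the full suite in
seconds while covering the interesting regimes: exact recovery on 20
complete-data replicates up to 30 branches / 60 variants / 60 individuals;
precision (no asserted relation contradicts the generating tree, and no
merge joins truly parallel variants) on 7 replicates each at 20/50/70 %
missing cells; recurrence detection on replicates with one planted
homoplasy; plus property tests for mirror symmetry, monotone candidate-set
growth under masking, acyclicity, the retained/removed partition, and
bytewise determinism of all outputs. `scripts/acceptance.py` recomputes the
same quantities as rates from a user-supplied seed.

## Numerical and degenerate-input choices

- All orderings (children, rows, removal scans) are lexicographic or
  matrix-order; the pipeline has no randomness, so identical inputs give
  byte-identical outputs.
- Empty cells in input files are rejected (missingness must be explicit
  `X`); state tokens are case-insensitive on input, upper-case on output.
- Monomorphic rows are a hard error by default; `--drop-invalid` demotes
  them to logged warnings and drops the rows.
- A matrix that loses all variants to pruning yields an empty tree and
  header-only output files rather than an error.
- Parent candidates that cannot be totally ordered raise an internal
  `AssemblyError`; the pruning scenarios are designed to make this
  unreachable, and no simulated or hand-built input has triggered it.

## Known limitations

- Resolution (branch count) is *not* monotone in the missing-data rate:
  masking the one cell that witnesses co-derivation of two tips prevents
  their merge and splits a branch in two. Pair-level information loss is
  monotone; tree-level granularity is not. Tests assert the former.
- "Equal" placement is non-committal: under heavy masking two truly
  parallel variants whose separating observations are all missing can merge
  into one branch. The suite checks this never happens at the tested rates
  and sizes, but it is not a theorem at extreme missingness.
- Removed variants are gone: no attempt is made to re-inject a recurrent
  variant as two independent mutation events.
- Certainty values quantify internal consistency, not statistical support;
  there is no resampling.
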