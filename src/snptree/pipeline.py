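"""End-to-end pipeline: matrix in, rooted variant tree and reports out."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

from snptree import serializers
from snptree.assembly import (
    AmbiguityRemovalRecord,
    GroupedDownstream,
    PhyloTree,
    assemble_tree,
    compute_certainty,
    resolve_ambiguities,
)
from snptree.matrix_io import (
    GenotypeMatrix,
    ValidationIssue,
    drop_invalid_rows,
    read_matrix,
    validate_matrix,
)
from snptree.pairwise import (
    ContradictionRecord,
    RelationTable,
    build_relation_table,
    downstream_table,
    remove_contradictory,
)

__all__ = ["PipelineResult", "RunConfig", "build_tree", "run_pipeline"]

log = logging.getLogger("snptree")


@dataclass
class PipelineResult:
    """Everything the pipeline computed, for inspection and serialization."""

    matrix: GenotypeMatrix
    relation_table: RelationTable
    contradiction_records: list[ContradictionRecord]
    downstream: dict[str, frozenset[str]]
    tree: PhyloTree
    ambiguity_records: list[AmbiguityRemovalRecord]
    validation_issues: list[ValidationIssue] = field(default_factory=list)

    @property
    def retained_variants(self) -> list[str]:
        return self.tree.variants()

    @property
    def removed_contradictory(self) -> list[str]:
        return [r.variant for r in self.contradiction_records]

    @property
    def removed_ambiguous(self) -> list[str]:
        return [r.variant for r in self.ambiguity_records]


def build_tree(matrix: GenotypeMatrix, drop_invalid: bool = False) -> PipelineResult:
    """Run the full inference on an in-memory matrix.

    With ``drop_invalid`` non-polymorphic rows are dropped with a warning
    instead of raising.
    """
    issues = validate_matrix(matrix)
    if any(i.severity == "error" for i in issues):
        if drop_invalid:
            matrix, issues = drop_invalid_rows(matrix)
            for i in issues:
                log.warning("%s", i.message)
        else:
            bad = "; ".join(i.message for i in issues if i.severity == "error")
            raise ValueError(f"invalid input matrix: {bad}")
    log.info("input: %d variants x %d individuals", matrix.n_variants, matrix.n_individuals)

    rtable = build_relation_table(matrix)
    missing = {v: matrix.missing_count(v) for v in matrix.variant_names}
    rtable, contradiction_records = remove_contradictory(rtable, missing)
    log.info("contradiction pruning removed %d variant(s)", len(contradiction_records))

    down = downstream_table(rtable)
    state = GroupedDownstream(matrix, rtable, down)
    resolve_ambiguities(state)
    tree = assemble_tree(state)
    log.info(
        "ambiguity pruning removed %d variant(s); %d retained in %d branches "
        "(%d at the root)",
        len(state.removals),
        len(tree.variants()),
        len(tree.nodes()),
        len(tree.root.children),
    )
    tree.certainty = compute_certainty(tree, rtable)
    return PipelineResult(
        matrix=matrix,
        relation_table=rtable,
        contradiction_records=contradiction_records,
        downstream=down,
        tree=tree,
        ambiguity_records=state.removals,
        validation_issues=issues,
    )


@dataclass
class RunConfig:
    """Configuration of a command-line run."""

    input_path: Path
    output_dir: Path
    emit_contradictory: bool = False
    emit_ambiguous: bool = False
    emit_metadata: bool = False
    drop_invalid: bool = False
    log_level: str = "info"


def run_pipeline(config: RunConfig) -> PipelineResult:
    """Read the input file, run the inference, write all output files.

    Always writes ``tree.phyloxml``, ``tree.csv`` and
    ``certainty_values.csv``; the removal reports and the metadata matrix
    are written on request.
    """
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    matrix = read_matrix(config.input_path)
    result = build_tree(matrix, drop_invalid=config.drop_invalid)
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    serializers.write_phyloxml(result.tree, out / "tree.phyloxml")
    serializers.write_csv_tree(result.tree, out / "tree.csv")
    serializers.write_certainty(result.tree, out / "certainty_values.csv")
    if config.emit_metadata:
        serializers.write_metadata(result.tree, result.matrix, out / "metadata.csv")
    serializers.write_removals(
        result.contradiction_records,
        result.ambiguity_records,
        out,
        write_contradictory=config.emit_contradictory,
        write_ambiguous=config.emit_ambiguous,
    )
    return result
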