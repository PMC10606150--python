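"""Output artifacts: phyloXML, haplogroup-style CSV grid, metadata, reports.

All textual "csv" outputs are tab-separated, matching the input dialect.
Equal variants within a group are joined with ", " in grid cells and with
"/" in phyloXML clade names (commas in clade names confuse downstream
viewers).  Everything is emitted depth-first with children in
lexicographic order, so identical runs produce byte-identical files.
"""

from __future__ import annotations

from pathlib import Path

from Bio import Phylo
from Bio.Phylo import PhyloXML as PX

from snptree.assembly import AmbiguityRemovalRecord, CladeNode, PhyloTree
from snptree.matrix_io import GenotypeMatrix
from snptree.pairwise import ContradictionRecord

__all__ = [
    "write_phyloxml",
    "read_phyloxml",
    "write_csv_tree",
    "read_csv_tree",
    "write_metadata",
    "write_certainty",
    "write_removals",
]


def _to_px_clade(node: CladeNode) -> PX.Clade:
    clade = PX.Clade(name="/".join(sorted(node.group)) if node.group else None)
    clade.clades = [_to_px_clade(c) for c in node.children]
    return clade


def write_phyloxml(tree: PhyloTree, path: str | Path) -> None:
    """Write the tree as a rooted phyloXML document (one clade per group)."""
    root = _to_px_clade(tree.root)
    phylo = PX.Phylogeny(root=root, rooted=True)
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        Phylo.write([phylo], fh, "phyloxml")


def read_phyloxml(path: str | Path) -> PhyloTree:
    """Re-parse a phyloXML file written by :func:`write_phyloxml`."""
    phylo = Phylo.read(str(path), "phyloxml")

    def convert(px_clade) -> CladeNode:
        group = frozenset(px_clade.name.split("/")) if px_clade.name else None
        node = CladeNode(group)
        for child in px_clade.clades:
            sub = convert(child)
            sub.parent = node
            node.children.append(sub)
        return node

    root = convert(phylo.root)
    if root.group is not None:  # re-insert the synthetic unlabeled root
        outer = CladeNode(None)
        root.parent = outer
        outer.children = [root]
        root = outer
    return PhyloTree(root)


def _grid_rows(tree: PhyloTree) -> list[list[str]]:
    rows: list[list[str]] = []

    def place(node: CladeNode, row: list[str], depth: int) -> None:
        while len(row) <= depth:
            row.append("")
        row[depth] = node.name
        for k, child in enumerate(node.children):
            if k == 0:
                place(child, row, depth + 1)
            else:
                new_row: list[str] = [""] * (depth + 1)
                rows.append(new_row)
                place(child, new_row, depth + 1)

    for k, child in enumerate(tree.root.children):
        row: list[str] = []
        rows.append(row)
        place(child, row, 0)
    return rows


def write_csv_tree(tree: PhyloTree, path: str | Path) -> None:
    """Tab-separated grid: cell column = clade depth, root children left.

    The first child of a clade continues on the same row; each further
    child opens a new row below (sister clades share a column).
    """
    rows = _grid_rows(tree)
    width = max((len(r) for r in rows), default=0)
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for row in rows:
            padded = row + [""] * (width - len(row))
            fh.write("\t".join(padded) + "\n")


def read_csv_tree(path: str | Path) -> PhyloTree:
    """Re-parse a grid written by :func:`write_csv_tree`."""
    root = CladeNode(None)
    last_at_depth: dict[int, CladeNode] = {}
    for line in Path(path).read_text(encoding="utf-8").splitlines():
        cells = line.split("\t")
        for depth, cell in enumerate(cells):
            if cell == "":
                continue
            group = frozenset(v.strip() for v in cell.split(","))
            parent = root if depth == 0 else last_at_depth[depth - 1]
            node = CladeNode(group, parent=parent)
            parent.children.append(node)
            last_at_depth[depth] = node
    return PhyloTree(root)


def write_metadata(tree: PhyloTree, matrix: GenotypeMatrix, path: str | Path) -> None:
    """Branch-to-individuals matrix: one row per group, depth-first order.

    The second column lists every individual observed derived for at
    least one of the group's variants.
    """
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("branch_variants\tindividuals\n")
        for node in tree.nodes():
            carriers = matrix.carriers(node.group)
            fh.write(f"{node.name}\t{', '.join(carriers)}\n")


def write_certainty(tree: PhyloTree, path: str | Path) -> None:
    """Per-variant certainty values, two decimals, NA when undefined."""
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("variant\tcertainty\n")
        for node in tree.nodes():
            for v in sorted(node.group):
                c = tree.certainty.get(v)
                fh.write(f"{v}\t{'NA' if c is None else format(c, '.2f')}\n")


def write_removals(
    contradictory: list[ContradictionRecord],
    ambiguous: list[AmbiguityRemovalRecord],
    out_dir: str | Path,
    write_contradictory: bool = False,
    write_ambiguous: bool = False,
) -> list[Path]:
    """Optional audit files for removed variants; returns the paths written."""
    out_dir = Path(out_dir)
    written: list[Path] = []
    if write_contradictory:
        p = out_dir / "contradictory_variants.csv"
        with p.open("w", encoding="utf-8", newline="\n") as fh:
            fh.write("variant\tn_contradictions\tround\n")
            for rec in contradictory:
                fh.write(f"{rec.variant}\t{rec.n_contradictions}\t{rec.removal_round}\n")
        written.append(p)
    if write_ambiguous:
        p = out_dir / "ambiguous_variants.csv"
        with p.open("w", encoding="utf-8", newline="\n") as fh:
            fh.write("variant\tscenario\tdetail\n")
            for rec in ambiguous:
                fh.write(f"{rec.variant}\t{rec.scenario}\t{rec.detail}\n")
        written.append(p)
    return written
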