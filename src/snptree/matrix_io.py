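"""Reading, writing and validating allelic-state matrices.

The input dialect is a tab-separated text matrix ("csv" by convention of
the field, tab-separated in practice): the header row carries individual
labels, the first column carries variant names, and every cell is one of
``A`` (ancestral), ``D`` (derived) or ``X`` (missing).  Ancestral/derived
orientation is assumed to have been established beforehand against an
outgroup; only polymorphic sites (at least one observed A and one
observed D per row) are legal.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np

__all__ = [
    "AllelicState",
    "GenotypeMatrix",
    "ValidationIssue",
    "MatrixParseError",
    "read_matrix",
    "write_matrix",
    "validate_matrix",
    "drop_invalid_rows",
]


class AllelicState(enum.IntEnum):
    """One of the exactly three allelic states a matrix cell may hold."""

    ANCESTRAL = 0
    DERIVED = 1
    MISSING = 2

    @property
    def token(self) -> str:
        return _STATE_TO_TOKEN[self]


_TOKEN_TO_STATE = {
    "A": AllelicState.ANCESTRAL,
    "D": AllelicState.DERIVED,
    "X": AllelicState.MISSING,
}
_STATE_TO_TOKEN = {v: k for k, v in _TOKEN_TO_STATE.items()}


class MatrixParseError(ValueError):
    """Raised for malformed input matrices (bad tokens, duplicates, ragged rows)."""


@dataclass(frozen=True)
class ValidationIssue:
    """A problem found while validating a parsed matrix.

    ``severity`` is ``"error"`` or ``"warning"``; ``subject`` names the
    offending variant or individual when one exists.
    """

    severity: str
    subject: str | None
    message: str


@dataclass
class GenotypeMatrix:
    """Variants × individuals grid of allelic states.

    ``states`` is an int8 array with values from :class:`AllelicState`,
    indexed ``[variant, individual]`` in the order given by
    ``variant_names`` / ``individual_names``.
    """

    variant_names: list[str]
    individual_names: list[str]
    states: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.states = np.asarray(self.states, dtype=np.int8)
        nv, ni = len(self.variant_names), len(self.individual_names)
        if self.states.shape != (nv, ni):
            raise ValueError(
                f"state grid is {self.states.shape}, expected ({nv}, {ni})"
            )
        if len(set(self.variant_names)) != nv:
            raise MatrixParseError("duplicate variant names")
        if len(set(self.individual_names)) != ni:
            raise MatrixParseError("duplicate individual labels")
        self._vindex = {v: i for i, v in enumerate(self.variant_names)}
        self._iindex = {s: i for i, s in enumerate(self.individual_names)}

    @property
    def n_variants(self) -> int:
        return len(self.variant_names)

    @property
    def n_individuals(self) -> int:
        return len(self.individual_names)

    def state(self, variant: str, individual: str) -> AllelicState:
        return AllelicState(self.states[self._vindex[variant], self._iindex[individual]])

    def row(self, variant: str) -> np.ndarray:
        return self.states[self._vindex[variant]]

    def missing_count(self, variant: str) -> int:
        return int((self.row(variant) == AllelicState.MISSING).sum())

    def carriers(self, variants: Iterable[str]) -> list[str]:
        """Individuals observed DERIVED for at least one of ``variants``."""
        idx = [self._vindex[v] for v in variants]
        mask = (self.states[idx] == AllelicState.DERIVED).any(axis=0)
        return [s for s, m in zip(self.individual_names, mask) if m]

    def subset(self, variants: Iterable[str]) -> "GenotypeMatrix":
        keep = [v for v in self.variant_names if v in set(variants)]
        idx = [self._vindex[v] for v in keep]
        return GenotypeMatrix(keep, list(self.individual_names), self.states[idx])

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GenotypeMatrix):
            return NotImplemented
        return (
            self.variant_names == other.variant_names
            and self.individual_names == other.individual_names
            and np.array_equal(self.states, other.states)
        )


def read_matrix(path: str | Path) -> GenotypeMatrix:
    """Parse a tab-separated allelic-state matrix file.

    The first line is the header of individual labels (its first field —
    the corner above the variant-name column — may be empty or carry any
    label and is ignored).  Each following line is a variant name and one
    state token per individual.  Tokens are matched case-insensitively
    and normalised to upper case; LF and CRLF line endings are accepted.

    Raises :class:`MatrixParseError` on unknown tokens (naming the cell),
    duplicated names, ragged rows, or empty cells.
    """
    path = Path(path)
    text = path.read_text(encoding="utf-8")
    lines = [ln for ln in text.replace("\r\n", "\n").split("\n") if ln != ""]
    if len(lines) < 2:
        raise MatrixParseError(f"{path}: need a header row and at least one variant row")
    header = lines[0].split("\t")
    individuals = header[1:]
    if any(s == "" for s in individuals):
        raise MatrixParseError(f"{path}: empty individual label in header")
    variant_names: list[str] = []
    rows: list[list[int]] = []
    for lineno, line in enumerate(lines[1:], start=2):
        fields = line.split("\t")
        if len(fields) != len(individuals) + 1:
            raise MatrixParseError(
                f"{path}:{lineno}: row has {len(fields) - 1} cells, "
                f"expected {len(individuals)}"
            )
        name, cells = fields[0], fields[1:]
        if name == "":
            raise MatrixParseError(f"{path}:{lineno}: empty variant name")
        row = []
        for indiv, cell in zip(individuals, cells):
            state = _TOKEN_TO_STATE.get(cell.strip().upper())
            if state is None:
                raise MatrixParseError(
                    f"{path}:{lineno}: unknown state token {cell!r} "
                    f"(variant {name}, individual {indiv}); expected A, D or X"
                )
            row.append(int(state))
        variant_names.append(name)
        rows.append(row)
    if len(set(variant_names)) != len(variant_names):
        raise MatrixParseError(f"{path}: duplicated variant name")
    if len(set(individuals)) != len(individuals):
        raise MatrixParseError(f"{path}: duplicated individual label")
    return GenotypeMatrix(variant_names, individuals, np.array(rows, dtype=np.int8))


def write_matrix(matrix: GenotypeMatrix, path: str | Path) -> None:
    """Write a matrix in the tab-separated input dialect (upper-case tokens)."""
    path = Path(path)
    with path.open("w", encoding="utf-8", newline="\n") as fh:
        fh.write("\t" + "\t".join(matrix.individual_names) + "\n")
        for name, row in zip(matrix.variant_names, matrix.states):
            tokens = [_STATE_TO_TOKEN[AllelicState(c)] for c in row]
            fh.write(name + "\t" + "\t".join(tokens) + "\n")


def validate_matrix(matrix: GenotypeMatrix) -> list[ValidationIssue]:
    """Check the polymorphic-site contract.

    Returns an error issue for every variant row lacking an observed
    DERIVED or an observed ANCESTRAL state, and a warning for variants
    typed (non-missing) in fewer than two individuals.  An empty list
    means the matrix is accepted.
    """
    issues: list[ValidationIssue] = []
    for name, row in zip(matrix.variant_names, matrix.states):
        n_der = int((row == AllelicState.DERIVED).sum())
        n_anc = int((row == AllelicState.ANCESTRAL).sum())
        if n_der == 0:
            issues.append(ValidationIssue(
                "error", name, f"variant {name} has no derived observation"))
        if n_anc == 0:
            issues.append(ValidationIssue(
                "error", name, f"variant {name} has no ancestral observation"))
        if n_der + n_anc < 2:
            issues.append(ValidationIssue(
                "warning", name,
                f"variant {name} is typed in fewer than 2 individuals"))
    return issues


def drop_invalid_rows(
    matrix: GenotypeMatrix,
) -> tuple[GenotypeMatrix, list[ValidationIssue]]:
    """Remove rows violating the polymorphic-site contract.

    Returns the reduced matrix plus the (downgraded-to-warning) issues
    for the dropped rows.  Used by the ``--drop-invalid`` CLI mode.
    """
    issues = validate_matrix(matrix)
    bad = {i.subject for i in issues if i.severity == "error"}
    kept = [v for v in matrix.variant_names if v not in bad]
    downgraded = [
        ValidationIssue("warning", i.subject, i.message + " (row dropped)")
        for i in issues
        if i.severity == "error"
    ]
    return matrix.subset(kept), downgraded
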