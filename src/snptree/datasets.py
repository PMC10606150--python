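"""Small built-in worked-example dataset.

Sixteen variants typed in twelve individuals, falling into three main
branches, with enough missing data and one recurrent variant (M16) to
exercise every pruning rule: M16 is removed as contradictory; M8, M13,
M14 and M15 are removed as ambiguously placed; M1/M4, M2/M3 and M6/M7
merge into equal groups.
"""

from __future__ import annotations

import numpy as np

from snptree.matrix_io import GenotypeMatrix

_DEMO = """\
M1  D D D A A A A A A A A A
M2  D A A A A A A A A A A A
M3  D A X A A A A A A A A A
M4  D D D A A A A A A A A A
M5  A A A D D D A A A A A A
M6  A A A D A A A A A A A A
M7  A A A D A X A A A A A A
M8  A A A D X D A A A A A A
M9  A A A A A A D D D D D X
M10 A A A A A A D A A D D A
M11 A A A A A A A A D A A A
M12 A A A A A A D A A A D A
M13 A A A A A A X D D X X D
M14 A A A A A A X D X X X A
M15 A A A A A A D X A X D A
M16 D D D D D D A X A X D A
"""

_CODE = {"A": 0, "D": 1, "X": 2}


def demo_matrix() -> GenotypeMatrix:
    """The 16-variant x 12-individual worked-example matrix."""
    names, rows = [], []
    for line in _DEMO.strip().splitlines():
        parts = line.split()
        names.append(parts[0])
        rows.append([_CODE[t] for t in parts[1:]])
    individuals = [f"S{i}" for i in range(1, 13)]
    return GenotypeMatrix(names, individuals, np.array(rows, dtype=np.int8))
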