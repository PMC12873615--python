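import datetime as dt

import numpy as np
import pytest

from overlapcca.datamodel import (
    CellState,
    EvidenceMatrix,
    Inclusion,
    OverviewDataset,
    Reference,
    Review,
)


def make_matrix(rows, columns, included, sm=(), row_mode="reference"):
    """Build an EvidenceMatrix from explicit (row, col) coordinate lists."""
    idx = {r: i for i, r in enumerate(rows)}
    jdx = {c: j for j, c in enumerate(columns)}
    cells = np.zeros((len(rows), len(columns)), dtype=np.int8)
    for r, c in included:
        cells[idx[r], jdx[c]] = CellState.INCLUDED
    for r, c in sm:
        cells[idx[r], jdx[c]] = CellState.STRUCTURAL_MISSING
    return EvidenceMatrix(row_ids=rows, column_ids=columns, cells=cells, row_mode=row_mode)


def random_matrix(rng, max_rows=12, max_cols=6, p=0.4, p_sm=0.15):
    """Random valid evidence matrix: every row has >=1 inclusion; some
    of the remaining absent cells may be structural zeros."""
    r = int(rng.integers(1, max_rows + 1))
    c = int(rng.integers(2, max_cols + 1))
    cells = (rng.random((r, c)) < p).astype(np.int8)
    for i in range(r):
        if not cells[i].any():
            cells[i, rng.integers(0, c)] = 1
    absent = cells == 0
    cells[absent & (rng.random((r, c)) < p_sm)] = CellState.STRUCTURAL_MISSING
    return EvidenceMatrix(
        row_ids=[f"s{i}" for i in range(r)],
        column_ids=[f"R{j}" for j in range(c)],
        cells=cells,
        row_mode="study",
    )


@pytest.fixture
def tiny_dataset():
    """Hand-built 3-review overview exercising threads, scope, late studies.

    - review A (searched 2019, covers main outcome) includes ref1, ref2a
    - review B (searched 2020, covers main outcome) includes ref2b, ref3
    - review C (searched 2018, does NOT cover main outcome) includes ref1
    - refs 2a/2b are one publication thread (study s2)
    - ref4 (study s4) published 2021 > every search date, included nowhere
      (it is dropped from matrices, so no warning path is triggered)
    - ref3 contributes to no overview outcome (empty outcome set)
    """
    reviews = [
        Review("A", dt.date(2019, 6, 1), True, frozenset({"pain", "function"})),
        Review("B", dt.date(2020, 3, 1), True, frozenset({"pain"})),
        Review("C", dt.date(2018, 1, 1), False, frozenset({"function"})),
    ]
    references = [
        Reference("ref1", "s1", dt.date(2015, 5, 1), frozenset({"pain"})),
        Reference("ref2a", "s2", dt.date(2016, 1, 1), frozenset({"pain", "function"})),
        Reference("ref2b", "s2", dt.date(2017, 8, 1), frozenset({"pain", "function"})),
        Reference("ref3", "s3", dt.date(2019, 9, 1), frozenset()),
        Reference("ref4", "s4", dt.date(2021, 2, 1), frozenset({"pain"})),
    ]
    inclusions = [
        Inclusion("A", "ref1"),
        Inclusion("A", "ref2a"),
        Inclusion("B", "ref2b"),
        Inclusion("B", "ref3"),
        Inclusion("C", "ref1"),
    ]
    return OverviewDataset(
        reviews=tuple(reviews),
        references=tuple(references),
        inclusions=tuple(inclusions),
        main_outcome="pain",
        outcome_universe=frozenset({"pain", "function"}),
    )
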