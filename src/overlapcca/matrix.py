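"""Evidence-matrix construction and the four construction assumptions.

The raw matrix lists every reference with at least one inclusion against every
review (overview level) or against the reviews reporting a chosen outcome
(outcome level).  Three further adjustments can then be applied, always in the
fixed order scope -> publication threads -> structural missingness, so that
the missingness marking operates on exactly the rows and columns that will be
analysed:

* **scope** keeps only reviews relevant to the overview's main outcome and
  drops rows contributing to no overview outcome;
* **threads** collapses each publication thread (all references sharing a
  ``study_id``) to a single study-level row;
* **structural missingness** flags cells a review could not possibly have
  filled because the study was published strictly after the review's search.

Crossing the two analysis levels with the three binary adjustments gives the
16 canonical scenarios.
"""

from __future__ import annotations

import logging

import numpy as np

from .datamodel import CellState, EvidenceMatrix, OverviewDataset, ScenarioSpec, normalise_outcome

logger = logging.getLogger(__name__)

__all__ = [
    "build_matrix",
    "adjust_scope",
    "collapse_threads",
    "mark_structural_missingness",
    "enumerate_scenarios",
    "apply_scenario",
]


def build_matrix(
    dataset: OverviewDataset,
    level: str = "overview",
    outcome: str | None = None,
) -> EvidenceMatrix:
    """Construct the unadjusted reference-level evidence matrix.

    At overview level every review is a column.  At outcome level only
    reviews whose outcome set contains ``outcome`` are kept, and rows are
    restricted to references contributing to that outcome.  Rows with no
    inclusion among the retained columns are dropped.
    """
    if not dataset.reviews:
        raise ValueError("empty overview: dataset has zero reviews")
    if level not in ("overview", "outcome"):
        raise ValueError(f"unknown level {level!r}")

    if level == "outcome":
        if outcome is None:
            outcome = dataset.main_outcome
        outcome = normalise_outcome(outcome)
        if outcome not in dataset.outcome_universe:
            raise ValueError(f"unknown outcome label {outcome!r}")
        columns = [rv.review_id for rv in dataset.reviews if outcome in rv.outcomes]
        eligible_refs = {
            ref.reference_id for ref in dataset.references if outcome in ref.outcomes
        }
    else:
        columns = [rv.review_id for rv in dataset.reviews]
        eligible_refs = {ref.reference_id for ref in dataset.references}

    col_index = {cid: j for j, cid in enumerate(columns)}
    ref_order = [ref.reference_id for ref in dataset.references if ref.reference_id in eligible_refs]
    row_index = {rid: i for i, rid in enumerate(ref_order)}

    cells = np.zeros((len(ref_order), len(columns)), dtype=np.int8)
    for inc in dataset.inclusions:
        i = row_index.get(inc.reference_id)
        j = col_index.get(inc.review_id)
        if i is not None and j is not None:
            cells[i, j] = CellState.INCLUDED

    keep = (cells == CellState.INCLUDED).any(axis=1)
    rows = [rid for rid, k in zip(ref_order, keep) if k]
    return EvidenceMatrix(
        row_ids=rows,
        column_ids=columns,
        cells=cells[keep],
        row_mode="reference",
        provenance="raw",
    )


def _row_references(matrix: EvidenceMatrix, dataset: OverviewDataset) -> dict[str, tuple]:
    """Map each matrix row id to the Reference objects behind it."""
    by_ref = dataset.reference_by_id()
    threads = dataset.threads()
    out = {}
    for rid in matrix.row_ids:
        if matrix.row_mode == "reference":
            out[rid] = (by_ref[rid],)
        else:
            out[rid] = threads[rid]
    return out


def adjust_scope(matrix: EvidenceMatrix, dataset: OverviewDataset) -> EvidenceMatrix:
    """Restrict the matrix to the overview's declared scope.

    Columns are limited to reviews flagged as covering the main outcome;
    rows whose references contribute to no outcome of the overview are
    deleted, and rows left without any inclusion are then dropped.
    """
    reviews = dataset.review_by_id()
    keep_cols = [j for j, cid in enumerate(matrix.column_ids) if reviews[cid].covers_main_outcome]
    if not keep_cols:
        raise ValueError("scope adjustment empties matrix: no review covers the main outcome")

    refs_of_row = _row_references(matrix, dataset)
    keep_rows = []
    for i, rid in enumerate(matrix.row_ids):
        contributes = any(ref.outcomes & dataset.outcome_universe for ref in refs_of_row[rid])
        if contributes:
            keep_rows.append(i)

    cells = matrix.cells[np.ix_(keep_rows, keep_cols)]
    has_inclusion = (cells == CellState.INCLUDED).any(axis=1)
    rows = [matrix.row_ids[i] for i, k in zip(keep_rows, has_inclusion) if k]
    return EvidenceMatrix(
        row_ids=rows,
        column_ids=[matrix.column_ids[j] for j in keep_cols],
        cells=cells[has_inclusion],
        row_mode=matrix.row_mode,
        provenance=matrix.provenance,
    )


def collapse_threads(matrix: EvidenceMatrix, dataset: OverviewDataset) -> EvidenceMatrix:
    """Collapse publication threads: one row per underlying primary study.

    A study-review cell is INCLUDED if any member reference of the thread was
    included by that review; STRUCTURAL_MISSING only if every member cell was
    structurally missing; ABSENT otherwise.
    """
    if matrix.row_mode == "study":
        raise ValueError("already at study level: cannot collapse threads twice")

    by_ref = dataset.reference_by_id()
    study_order: list[str] = []
    members: dict[str, list[int]] = {}
    for i, rid in enumerate(matrix.row_ids):
        sid = by_ref[rid].study_id
        if sid not in members:
            members[sid] = []
            study_order.append(sid)
        members[sid].append(i)

    cells = np.zeros((len(study_order), matrix.n_columns), dtype=np.int8)
    for k, sid in enumerate(study_order):
        block = matrix.cells[members[sid]]
        included = (block == CellState.INCLUDED).any(axis=0)
        all_sm = (block == CellState.STRUCTURAL_MISSING).all(axis=0)
        cells[k, included] = CellState.INCLUDED
        cells[k, ~included & all_sm] = CellState.STRUCTURAL_MISSING

    return EvidenceMatrix(
        row_ids=study_order,
        column_ids=matrix.column_ids,
        cells=cells,
        row_mode="study",
        provenance=matrix.provenance,
    )


def mark_structural_missingness(matrix: EvidenceMatrix, dataset: OverviewDataset) -> EvidenceMatrix:
    """Flag cells a review could not have filled given its search date.

    An ABSENT cell becomes STRUCTURAL_MISSING when the row's publication date
    is strictly later than the column's search date (equal dates count as
    reachable).  For study-level rows the thread's earliest member publication
    date is used.  INCLUDED cells are never altered; an inclusion that
    postdates the review's search is kept but logged as a data-quality
    warning.
    """
    reviews = dataset.review_by_id()
    refs_of_row = _row_references(matrix, dataset)

    missing_dates = [
        rid
        for rid in matrix.row_ids
        if any(ref.publication_date is None for ref in refs_of_row[rid])
    ]
    missing_dates += [cid for cid in matrix.column_ids if reviews[cid].search_date is None]
    if missing_dates:
        raise ValueError(f"entities lacking dates: {missing_dates}")

    pub_dates = [min(ref.publication_date for ref in refs_of_row[rid]) for rid in matrix.row_ids]
    search_dates = [reviews[cid].search_date for cid in matrix.column_ids]

    cells = np.array(matrix.cells, dtype=np.int8)
    for i, pub in enumerate(pub_dates):
        for j, search in enumerate(search_dates):
            if pub > search:
                if cells[i, j] == CellState.ABSENT:
                    cells[i, j] = CellState.STRUCTURAL_MISSING
                elif cells[i, j] == CellState.INCLUDED:
                    logger.warning(
                        "row %s (published %s) included by review %s searched %s: "
                        "inclusion kept, check source data",
                        matrix.row_ids[i], pub, matrix.column_ids[j], search,
                    )
    return matrix.with_cells(cells)


#: Canonical flag order shared by the overview-level block (scenarios 1-8)
#: and the outcome-level block (9-16): none; scope; threads; missingness;
#: scope+threads; scope+missingness; threads+missingness; all three.
_FLAG_ORDER: tuple[tuple[bool, bool, bool], ...] = (
    (False, False, False),
    (True, False, False),
    (False, True, False),
    (False, False, True),
    (True, True, False),
    (True, False, True),
    (False, True, True),
    (True, True, True),
)


def enumerate_scenarios() -> list[ScenarioSpec]:
    """The 16 canonical scenarios: 1-8 overview level, 9-16 outcome level."""
    specs = []
    for block, level in enumerate(("overview", "outcome")):
        for k, (scope, threads, missing) in enumerate(_FLAG_ORDER):
            specs.append(
                ScenarioSpec(
                    index=8 * block + k + 1,
                    level=level,
                    adjust_scope=scope,
                    adjust_threads=threads,
                    adjust_missingness=missing,
                )
            )
    return specs


def apply_scenario(
    dataset: OverviewDataset,
    spec: ScenarioSpec,
    outcome: str | None = None,
) -> EvidenceMatrix:
    """Build the evidence matrix for one scenario.

    Composition is fixed: build, then scope, threads and missingness in that
    order when flagged.  Outcome-level scenarios default to the dataset's
    main outcome.
    """
    matrix = build_matrix(dataset, level=spec.level, outcome=outcome)
    if spec.adjust_scope:
        matrix = adjust_scope(matrix, dataset)
    if spec.adjust_threads:
        matrix = collapse_threads(matrix, dataset)
    if spec.adjust_missingness:
        matrix = mark_structural_missingness(matrix, dataset)
    return EvidenceMatrix(
        row_ids=matrix.row_ids,
        column_ids=matrix.column_ids,
        cells=matrix.cells,
        row_mode=matrix.row_mode,
        provenance=spec,
    )
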