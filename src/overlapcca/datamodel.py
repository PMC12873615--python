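"""Core data structures for overlap analysis in overviews of systematic reviews.

An *overview dataset* bundles the systematic reviews included in an overview,
the references of their primary studies (grouped into publication threads via
a shared ``study_id``), and the review-to-reference inclusion links.  An
*evidence matrix* is the two-dimensional table derived from such a dataset:
rows are primary-study references (or collapsed studies), columns are reviews,
and each cell records whether the review included the row, or whether the cell
is a structural zero (the study was published after the review's search date).
"""

from __future__ import annotations

import datetime as _dt
import enum
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "CellState",
    "Review",
    "Reference",
    "Inclusion",
    "OverviewDataset",
    "EvidenceMatrix",
    "ScenarioSpec",
    "parse_date",
    "normalise_outcome",
    "validate_dataset",
]


class CellState(enum.IntEnum):
    """State of one study-by-review cell of an evidence matrix."""

    ABSENT = 0
    INCLUDED = 1
    STRUCTURAL_MISSING = 2


def normalise_outcome(label: str) -> str:
    """Canonical form of an outcome label: trimmed, case-folded."""
    return str(label).strip().casefold()


def parse_date(value, *, bare_year_to: str = "start") -> _dt.date:
    """Parse an ISO-8601 date or a bare year into a :class:`datetime.date`.

    Bare years are canonicalised conservatively: review search dates resolve
    to 31 December (``bare_year_to="end"``) and publication dates to
    1 January (``bare_year_to="start"``), which minimises false structural
    zeros when only year precision is available.
    """
    if isinstance(value, _dt.datetime):
        return value.date()
    if isinstance(value, _dt.date):
        return value
    text = str(value).strip()
    if text.isdigit() and len(text) == 4:
        year = int(text)
        return _dt.date(year, 12, 31) if bare_year_to == "end" else _dt.date(year, 1, 1)
    try:
        return _dt.date.fromisoformat(text)
    except ValueError as exc:
        raise ValueError(f"unparseable date {value!r}: expected ISO-8601 or bare year") from exc


@dataclass(frozen=True)
class Review:
    """One systematic review: a column of the evidence matrix."""

    review_id: str
    search_date: _dt.date
    covers_main_outcome: bool
    outcomes: frozenset[str] = frozenset()

    def __post_init__(self):
        object.__setattr__(self, "outcomes", frozenset(normalise_outcome(o) for o in self.outcomes))


@dataclass(frozen=True)
class Reference:
    """One published report of a primary study.

    References sharing a ``study_id`` form a publication thread: distinct
    reports of the same underlying study population.
    """

    reference_id: str
    study_id: str
    publication_date: _dt.date
    outcomes: frozenset[str] = frozenset()

    def __post_init__(self):
        object.__setattr__(self, "outcomes", frozenset(normalise_outcome(o) for o in self.outcomes))


@dataclass(frozen=True)
class Inclusion:
    """A review-cites-reference link."""

    review_id: str
    reference_id: str


@dataclass(frozen=True)
class OverviewDataset:
    reviews: tuple[Review, ...]
    references: tuple[Reference, ...]
    inclusions: tuple[Inclusion, ...]
    main_outcome: str
    outcome_universe: frozenset[str]

    def __post_init__(self):
        object.__setattr__(self, "reviews", tuple(self.reviews))
        object.__setattr__(self, "references", tuple(self.references))
        object.__setattr__(self, "inclusions", tuple(self.inclusions))
        object.__setattr__(self, "main_outcome", normalise_outcome(self.main_outcome))
        object.__setattr__(
            self, "outcome_universe", frozenset(normalise_outcome(o) for o in self.outcome_universe)
        )

    def review_by_id(self) -> dict[str, Review]:
        return {r.review_id: r for r in self.reviews}

    def reference_by_id(self) -> dict[str, Reference]:
        return {r.reference_id: r for r in self.references}

    def threads(self) -> dict[str, tuple[Reference, ...]]:
        """Publication threads: study_id -> member references."""
        out: dict[str, list[Reference]] = {}
        for ref in self.references:
            out.setdefault(ref.study_id, []).append(ref)
        return {k: tuple(v) for k, v in out.items()}


@dataclass(frozen=True)
class ScenarioSpec:
    """One of the 16 matrix-construction scenarios.

    ``level`` chooses the unit of analysis (whole overview vs a single
    outcome); the three boolean flags switch the scope, publication-thread
    and structural-missingness adjustments on or off.
    """

    index: int
    level: str  # "overview" | "outcome"
    adjust_scope: bool
    adjust_threads: bool
    adjust_missingness: bool

    def __post_init__(self):
        if self.level not in ("overview", "outcome"):
            raise ValueError(f"unknown level {self.level!r}")
        if not 1 <= self.index <= 16:
            raise ValueError(f"scenario index {self.index} outside 1..16")

    @property
    def label(self) -> str:
        flags = "".join(
            ch if on else "-"
            for ch, on in zip("STM", (self.adjust_scope, self.adjust_threads, self.adjust_missingness))
        )
        return f"{self.index:02d}:{self.level}:{flags}"


@dataclass(frozen=True)
class EvidenceMatrix:
    """Rows (references or collapsed studies) by columns (reviews).

    ``cells`` is an integer array of :class:`CellState` codes with shape
    ``(len(row_ids), len(column_ids))``.  Rows without a single INCLUDED cell
    are never admitted.
    """

    row_ids: tuple[str, ...]
    column_ids: tuple[str, ...]
    cells: np.ndarray
    row_mode: str  # "reference" | "study"
    provenance: ScenarioSpec | str = "raw"

    def __post_init__(self):
        object.__setattr__(self, "row_ids", tuple(self.row_ids))
        object.__setattr__(self, "column_ids", tuple(self.column_ids))
        cells = np.asarray(self.cells, dtype=np.int8)
        cells.setflags(write=False)
        object.__setattr__(self, "cells", cells)
        if cells.shape != (len(self.row_ids), len(self.column_ids)):
            raise ValueError("cells shape does not match row/column ids")
        if self.row_mode not in ("reference", "study"):
            raise ValueError(f"unknown row_mode {self.row_mode!r}")
        if len(set(self.row_ids)) != len(self.row_ids):
            raise ValueError("duplicate row ids")
        if len(set(self.column_ids)) != len(self.column_ids):
            raise ValueError("duplicate column ids")
        if len(self.row_ids) and not ((cells == CellState.INCLUDED).any(axis=1)).all():
            bad = [rid for rid, ok in zip(self.row_ids, (cells == CellState.INCLUDED).any(axis=1)) if not ok]
            raise ValueError(f"rows without any inclusion: {bad}")

    # -- counts used by the CCA formula ------------------------------------
    @property
    def n_included(self) -> int:
        """N: total number of inclusion occurrences."""
        return int((self.cells == CellState.INCLUDED).sum())

    @property
    def n_rows(self) -> int:
        """r: number of distinct rows (references or studies)."""
        return len(self.row_ids)

    @property
    def n_columns(self) -> int:
        """c: number of reviews."""
        return len(self.column_ids)

    @property
    def n_structural_missing(self) -> int:
        """SZ: number of structural zeros."""
        return int((self.cells == CellState.STRUCTURAL_MISSING).sum())

    def to_frame(self) -> pd.DataFrame:
        """Matrix as a DataFrame of CellState codes (rows x reviews)."""
        return pd.DataFrame(self.cells, index=list(self.row_ids), columns=list(self.column_ids))

    def with_cells(self, cells: np.ndarray, **changes) -> "EvidenceMatrix":
        return replace(self, cells=np.array(cells, dtype=np.int8), **changes)


def validate_dataset(dataset: OverviewDataset) -> list[str]:
    """Check every dataset invariant; return human-readable violations.

    Returns an empty list for a well-formed dataset.  Validation never
    raises: every broken rule is reported, naming the offending entity.
    """
    violations: list[str] = []

    seen_reviews: set[str] = set()
    for rv in dataset.reviews:
        if rv.review_id in seen_reviews:
            violations.append(f"duplicate review_id {rv.review_id!r}")
        seen_reviews.add(rv.review_id)

    seen_refs: set[str] = set()
    for ref in dataset.references:
        if ref.reference_id in seen_refs:
            violations.append(f"duplicate reference_id {ref.reference_id!r}")
        seen_refs.add(ref.reference_id)
        if not ref.study_id:
            violations.append(f"reference {ref.reference_id!r} has empty study_id")

    seen_pairs: set[tuple[str, str]] = set()
    for inc in dataset.inclusions:
        pair = (inc.review_id, inc.reference_id)
        if pair in seen_pairs:
            violations.append(f"duplicate inclusion {pair!r}")
        seen_pairs.add(pair)
        if inc.review_id not in seen_reviews:
            violations.append(f"inclusion references unknown review_id {inc.review_id!r}")
        if inc.reference_id not in seen_refs:
            violations.append(f"inclusion references unknown reference_id {inc.reference_id!r}")

    if dataset.main_outcome not in dataset.outcome_universe:
        violations.append(f"main_outcome {dataset.main_outcome!r} not in outcome universe")
    for rv in dataset.reviews:
        extra = rv.outcomes - dataset.outcome_universe
        if extra:
            violations.append(f"review {rv.review_id!r} has outcomes outside universe: {sorted(extra)}")
    for ref in dataset.references:
        extra = ref.outcomes - dataset.outcome_universe
        if extra:
            violations.append(
                f"reference {ref.reference_id!r} has outcomes outside universe: {sorted(extra)}"
            )

    return violations
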