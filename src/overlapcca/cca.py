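"""Corrected covered area (CCA) computation and overlap classification.

For an evidence matrix with N inclusion occurrences, r distinct rows, c
reviews and SZ structural zeros, the corrected covered area is

    CCA = 100 * (N - r) / (r*c - r - SZ)

i.e. the share of *duplicate* study entries among the cells a review could
actually have filled.  SZ = 0 on matrices without the structural-missingness
adjustment, recovering the classical definition.  The pairwise CCA of two
reviews restricts the matrix to their two columns (dropping rows neither
includes) and applies the same formula with c = 2; on unadjusted matrices it
reduces algebraically to the Jaccard index |A∩B| / |A∪B| of the two study
sets, expressed as a percentage.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .datamodel import CellState, EvidenceMatrix

__all__ = [
    "PairwiseValue",
    "CCAResult",
    "overall_cca",
    "pairwise_cca",
    "compute_cca",
    "classify_overlap",
    "OVERLAP_BANDS",
]

#: Published interpretation bands.  The printed bands "<5", "5-10", "10-15",
#: ">15" are ambiguous at the joints; the convention here follows the strict
#: outer inequalities and closes the high band at both ends:
#: slight [0,5), moderate [5,10), high [10,15], very high (15,100].
OVERLAP_BANDS = "slight [0,5) | moderate [5,10) | high [10,15] | very high (15,100]"


def classify_overlap(cca: float) -> str:
    """Map a CCA percentage onto the published overlap categories."""
    if cca is None or not np.isfinite(cca):
        raise ValueError("cannot classify undefined CCA")
    if not 0.0 <= cca <= 100.0:
        raise ValueError(f"CCA {cca} outside [0, 100]")
    if cca < 5.0:
        return "slight"
    if cca < 10.0:
        return "moderate"
    if cca <= 15.0:
        return "high"
    return "very high"


@dataclass(frozen=True)
class PairwiseValue:
    """Pairwise CCA for one unordered review pair; NA when undefined."""

    review_i: str
    review_j: str
    cca: float | None
    reason: str | None = None  # set when cca is None

    @property
    def defined(self) -> bool:
        return self.cca is not None


@dataclass(frozen=True)
class CCAResult:
    """Overall and pairwise CCA for one evidence matrix."""

    overall: float | None
    overall_reason: str | None
    N: int
    r: int
    c: int
    SZ: int
    pairwise: tuple[PairwiseValue, ...] = ()
    pairwise_summary: dict = field(default_factory=dict)

    @property
    def overall_defined(self) -> bool:
        return self.overall is not None

    @property
    def overall_category(self) -> str | None:
        return classify_overlap(self.overall) if self.overall_defined else None


def _cca_value(N: int, r: int, c: int, SZ: int) -> tuple[float | None, str | None]:
    if c < 2:
        return None, "CCA requires >=2 reviews"
    denom = r * c - r - SZ
    if denom <= 0:
        return None, "fully saturated/empty denominator"
    return 100.0 * (N - r) / denom, None


def overall_cca(matrix: EvidenceMatrix) -> CCAResult:
    """Overall CCA of the whole matrix.

    Structural zeros shrink the denominator, so a missingness-adjusted matrix
    can only report equal or higher overlap than its unadjusted counterpart.
    Undefined cases (fewer than two reviews, saturated or empty denominator)
    are reported via an explicit NA flag with a reason, never as zero.
    """
    N, r, c, SZ = matrix.n_included, matrix.n_rows, matrix.n_columns, matrix.n_structural_missing
    value, reason = _cca_value(N, r, c, SZ)
    return CCAResult(overall=value, overall_reason=reason, N=N, r=r, c=c, SZ=SZ)


def _summary(values: list[float], n_pairs: int) -> dict:
    defined = np.asarray(values, dtype=float)
    out = {"n_pairs": n_pairs, "n_defined": len(values), "n_undefined": n_pairs - len(values)}
    if len(values) == 0:
        out.update({"median": None, "q1": None, "q3": None, "min": None, "max": None})
        return out
    # linear-interpolation quartiles, so boxplots are exactly reproducible
    q1, med, q3 = np.percentile(defined, [25, 50, 75], method="linear")
    out.update(
        {
            "median": float(med),
            "q1": float(q1),
            "q3": float(q3),
            "min": float(defined.min()),
            "max": float(defined.max()),
        }
    )
    return out


def pairwise_cca(matrix: EvidenceMatrix, *, global_sz: bool = False) -> CCAResult:
    """CCA for every unordered pair of reviews, plus summary statistics.

    Each pair's sub-matrix keeps only rows with at least one INCLUDED cell in
    either column; its own structural zeros form the pair's SZ.  With
    ``global_sz=True`` the whole-matrix SZ is reused instead (an alternative
    reading of denominator adjustment; the sub-matrix restriction is the
    default).  Undefined pairs carry an NA marker and are excluded from the
    summary statistics — treating them as 0 would conflate "no comparable
    evidence" with "no overlap".
    """
    if matrix.n_columns < 2:
        raise ValueError("pairwise CCA requires >=2 reviews")

    inc = matrix.cells == CellState.INCLUDED
    sm = matrix.cells == CellState.STRUCTURAL_MISSING
    pairs: list[PairwiseValue] = []
    defined_values: list[float] = []
    for a in range(matrix.n_columns):
        for b in range(a + 1, matrix.n_columns):
            keep = inc[:, a] | inc[:, b]
            r = int(keep.sum())
            if r == 0:
                pairs.append(
                    PairwiseValue(matrix.column_ids[a], matrix.column_ids[b], None, "empty sub-matrix")
                )
                continue
            N = int(inc[keep][:, [a, b]].sum())
            SZ = matrix.n_structural_missing if global_sz else int(sm[keep][:, [a, b]].sum())
            value, reason = _cca_value(N, r, 2, SZ)
            pairs.append(PairwiseValue(matrix.column_ids[a], matrix.column_ids[b], value, reason))
            if value is not None:
                defined_values.append(value)

    n_pairs = matrix.n_columns * (matrix.n_columns - 1) // 2
    return CCAResult(
        overall=None,
        overall_reason="pairwise-only result",
        N=matrix.n_included,
        r=matrix.n_rows,
        c=matrix.n_columns,
        SZ=matrix.n_structural_missing,
        pairwise=tuple(pairs),
        pairwise_summary=_summary(defined_values, n_pairs),
    )


def compute_cca(matrix: EvidenceMatrix, *, global_sz: bool = False) -> CCAResult:
    """Overall and pairwise CCA in a single result."""
    base = overall_cca(matrix)
    if matrix.n_columns < 2:
        return base
    pw = pairwise_cca(matrix, global_sz=global_sz)
    return CCAResult(
        overall=base.overall,
        overall_reason=base.overall_reason,
        N=base.N,
        r=base.r,
        c=base.c,
        SZ=base.SZ,
        pairwise=pw.pairwise,
        pairwise_summary=pw.pairwise_summary,
    )
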