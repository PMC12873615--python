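"""Readers, writers and report rendering.

A dataset on disk is three CSV tables — ``reviews.csv``
(review_id,search_date,covers_main_outcome,outcomes), ``references.csv``
(reference_id,study_id,publication_date,outcomes) and ``inclusions.csv``
(review_id,reference_id) — plus a small ``dataset.json`` naming the main
outcome and the outcome universe.  Outcome labels within a cell are separated
by ``|``.  A single JSON document with the same structure is also accepted.
"""

from __future__ import annotations

import datetime as _dt
import json
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd

from . import __version__
from .cca import OVERLAP_BANDS, classify_overlap
from .datamodel import (
    CellState,
    EvidenceMatrix,
    Inclusion,
    OverviewDataset,
    Reference,
    Review,
    ScenarioSpec,
    parse_date,
    validate_dataset,
)
from .sweep import SweepResult, classify_change, impact_range

__all__ = [
    "load_dataset",
    "write_dataset",
    "write_matrix",
    "write_sweep",
    "render_figure",
    "sweep_to_frame",
]

_OUTCOME_SEP = "|"


def _split_outcomes(cell) -> frozenset[str]:
    if cell is None or (isinstance(cell, float) and pd.isna(cell)) or str(cell).strip() == "":
        return frozenset()
    return frozenset(part.strip() for part in str(cell).split(_OUTCOME_SEP) if part.strip())


def _parse_bool(value) -> bool:
    text = str(value).strip().lower()
    if text in ("true", "1", "yes", "y"):
        return True
    if text in ("false", "0", "no", "n"):
        return False
    raise ValueError(f"not a boolean: {value!r}")


def _dataset_from_tables(reviews_df, references_df, inclusions_df, meta) -> OverviewDataset:
    reviews = [
        Review(
            review_id=str(row.review_id),
            search_date=parse_date(row.search_date, bare_year_to="end"),
            covers_main_outcome=_parse_bool(row.covers_main_outcome),
            outcomes=_split_outcomes(row.outcomes),
        )
        for row in reviews_df.itertuples(index=False)
    ]
    references = [
        Reference(
            reference_id=str(row.reference_id),
            study_id=str(row.study_id),
            publication_date=parse_date(row.publication_date, bare_year_to="start"),
            outcomes=_split_outcomes(row.outcomes),
        )
        for row in references_df.itertuples(index=False)
    ]
    inclusions = [
        Inclusion(review_id=str(row.review_id), reference_id=str(row.reference_id))
        for row in inclusions_df.itertuples(index=False)
    ]
    universe = meta.get("outcome_universe")
    if universe is None:
        universe = set()
        for entity in (*reviews, *references):
            universe |= entity.outcomes
    return OverviewDataset(
        reviews=tuple(reviews),
        references=tuple(references),
        inclusions=tuple(inclusions),
        main_outcome=meta["main_outcome"],
        outcome_universe=frozenset(universe),
    )


def load_dataset(path: str | Path) -> OverviewDataset:
    """Load a dataset from a directory of CSVs or a single JSON document.

    The loaded dataset is validated; any violation aborts the load with an
    aggregated report.
    """
    path = Path(path)
    if path.is_dir():
        required = ["reviews.csv", "references.csv", "inclusions.csv"]
        missing = [name for name in required if not (path / name).exists()]
        if missing:
            raise FileNotFoundError(f"dataset directory {path} lacks: {missing}")
        reviews_df = pd.read_csv(path / "reviews.csv", dtype=str)
        references_df = pd.read_csv(path / "references.csv", dtype=str)
        inclusions_df = pd.read_csv(path / "inclusions.csv", dtype=str)
        meta_path = path / "dataset.json"
        meta = json.loads(meta_path.read_text()) if meta_path.exists() else {}
        if "main_outcome" not in meta:
            raise ValueError(f"{meta_path} must name the overview's main_outcome")
    else:
        doc = json.loads(Path(path).read_text())
        reviews_df = pd.DataFrame(doc["reviews"])
        references_df = pd.DataFrame(doc["references"])
        inclusions_df = pd.DataFrame(doc["inclusions"])
        meta = {
            "main_outcome": doc["main_outcome"],
            "outcome_universe": doc.get("outcome_universe"),
        }

    for name, df, cols in (
        ("reviews", reviews_df, ["review_id", "search_date", "covers_main_outcome", "outcomes"]),
        ("references", references_df, ["reference_id", "study_id", "publication_date", "outcomes"]),
        ("inclusions", inclusions_df, ["review_id", "reference_id"]),
    ):
        lacking = [c for c in cols if c not in df.columns]
        if lacking:
            raise ValueError(f"{name} table lacks columns {lacking}")

    dataset = _dataset_from_tables(reviews_df, references_df, inclusions_df, meta)
    violations = validate_dataset(dataset)
    if violations:
        raise ValueError("invalid dataset:\n  " + "\n  ".join(violations))
    return dataset


def write_dataset(dataset: OverviewDataset, outdir: str | Path) -> dict[str, Path]:
    """Write the three CSV tables plus the JSON metadata sidecar."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}

    reviews = pd.DataFrame(
        {
            "review_id": [r.review_id for r in dataset.reviews],
            "search_date": [r.search_date.isoformat() for r in dataset.reviews],
            "covers_main_outcome": [r.covers_main_outcome for r in dataset.reviews],
            "outcomes": [_OUTCOME_SEP.join(sorted(r.outcomes)) for r in dataset.reviews],
        }
    )
    references = pd.DataFrame(
        {
            "reference_id": [r.reference_id for r in dataset.references],
            "study_id": [r.study_id for r in dataset.references],
            "publication_date": [r.publication_date.isoformat() for r in dataset.references],
            "outcomes": [_OUTCOME_SEP.join(sorted(r.outcomes)) for r in dataset.references],
        }
    )
    inclusions = pd.DataFrame(
        {
            "review_id": [i.review_id for i in dataset.inclusions],
            "reference_id": [i.reference_id for i in dataset.inclusions],
        }
    )
    for name, df in (("reviews", reviews), ("references", references), ("inclusions", inclusions)):
        paths[name] = outdir / f"{name}.csv"
        df.to_csv(paths[name], index=False)

    paths["meta"] = outdir / "dataset.json"
    paths["meta"].write_text(
        json.dumps(
            {
                "main_outcome": dataset.main_outcome,
                "outcome_universe": sorted(dataset.outcome_universe),
                "tool_version": __version__,
            },
            indent=2,
        )
    )
    return paths


_CELL_TOKENS = {CellState.ABSENT: "0", CellState.INCLUDED: "1", CellState.STRUCTURAL_MISSING: "SM"}


def write_matrix(matrix: EvidenceMatrix, path: str | Path) -> Path:
    """Export a matrix as wide CSV (1/0/SM) with a provenance JSON sidecar."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    frame = matrix.to_frame().map(lambda v: _CELL_TOKENS[CellState(v)])
    frame.index.name = "row_id"
    frame.to_csv(path)

    prov = matrix.provenance
    sidecar = {
        "tool_version": __version__,
        "row_mode": matrix.row_mode,
        "N": matrix.n_included,
        "r": matrix.n_rows,
        "c": matrix.n_columns,
        "SZ": matrix.n_structural_missing,
    }
    if isinstance(prov, ScenarioSpec):
        sidecar["scenario"] = {
            "index": prov.index,
            "level": prov.level,
            "adjust_scope": prov.adjust_scope,
            "adjust_threads": prov.adjust_threads,
            "adjust_missingness": prov.adjust_missingness,
        }
    else:
        sidecar["scenario"] = str(prov)
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))
    return path


def sweep_to_frame(sweep: SweepResult) -> pd.DataFrame:
    """Long-format table: one row per scenario with counts and CCA summaries."""
    rows = []
    for rec in sweep.records:
        spec = rec.spec
        res = rec.result
        summary = res.pairwise_summary if res is not None else {}
        rows.append(
            {
                "scenario": spec.index,
                "level": spec.level,
                "adjust_scope": spec.adjust_scope,
                "adjust_threads": spec.adjust_threads,
                "adjust_missingness": spec.adjust_missingness,
                "outcome": rec.outcome,
                "N": res.N if res else None,
                "r": res.r if res else None,
                "c": res.c if res else None,
                "SZ": res.SZ if res else None,
                "overall_cca": rec.overall,
                "overall_category": (
                    classify_overlap(rec.overall) if rec.overall is not None else None
                ),
                "pairwise_median": summary.get("median"),
                "pairwise_q1": summary.get("q1"),
                "pairwise_q3": summary.get("q3"),
                "pairwise_min": summary.get("min"),
                "pairwise_max": summary.get("max"),
                "n_pairs": summary.get("n_pairs"),
                "n_undefined_pairs": summary.get("n_undefined"),
                "error": rec.error,
            }
        )
    return pd.DataFrame(rows)


def _metadata_header(extra: dict | None = None) -> str:
    meta = {
        "tool": f"overlapcca {__version__}",
        "generated": _dt.date.today().isoformat(),
        "scenario_order": "1-8 overview level, 9-16 outcome level; flag order "
        "none, scope, threads, missingness, scope+threads, scope+missingness, "
        "threads+missingness, all",
        "overlap_bands": OVERLAP_BANDS,
    }
    if extra:
        meta.update(extra)
    return "".join(f"# {k}: {v}\n" for k, v in meta.items())


def write_sweep(sweep: SweepResult, outdir: str | Path, *, seed=None) -> dict[str, Path]:
    """Write the per-scenario long CSV and the JSON summary with impacts."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    frame = sweep_to_frame(sweep)

    csv_path = outdir / "scenario_cca.csv"
    with open(csv_path, "w") as fh:
        fh.write(_metadata_header({"seed": seed} if seed is not None else None))
        frame.to_csv(fh, index=False)

    summary: dict = {"tool_version": __version__, "outcome": sweep.outcome}
    if seed is not None:
        summary["seed"] = seed
    for method in ("overall", "pairwise-median"):
        try:
            delta = impact_range(sweep, method)
            summary[method.replace("-", "_")] = {
                "impact_range": delta,
                "change_category": classify_change(delta),
                "n_defined": len(sweep.defined(method)),
            }
        except ValueError as exc:
            summary[method.replace("-", "_")] = {"impact_range": None, "reason": str(exc)}
    json_path = outdir / "sweep_summary.json"
    json_path.write_text(json.dumps(summary, indent=2))
    return {"csv": csv_path, "json": json_path}


def render_figure(sweep: SweepResult, path: str | Path, *, title: str | None = None) -> Path:
    """Boxplot of pairwise CCA per scenario with the overall CCA as a point.

    Scenarios run down the vertical axis, CCA along the horizontal one; a
    dashed line divides the overview-level block (1-8) from the outcome-level
    block (9-16).  NA scenarios appear as gaps.
    """
    path = Path(path)
    if path.suffix.lower() not in (".svg", ".png"):
        raise ValueError(f"unknown figure format {path.suffix!r}: use .svg or .png")
    path.parent.mkdir(parents=True, exist_ok=True)

    fig, ax = plt.subplots(figsize=(7, 6))
    for rec in sweep.records:
        y = rec.spec.index
        if rec.result is not None and rec.result.pairwise:
            vals = [pv.cca for pv in rec.result.pairwise if pv.defined]
            if vals:
                ax.boxplot(
                    [vals], positions=[y], orientation="horizontal", widths=0.6,
                    flierprops={"markersize": 3},
                )
        if rec.overall is not None:
            ax.plot(rec.overall, y, "ko", markersize=5, zorder=5)
            ax.annotate(
                f"{rec.overall:.1f}", (rec.overall, y),
                textcoords="offset points", xytext=(6, 4), fontsize=7,
            )
    ax.axhline(8.5, linestyle="--", color="grey", linewidth=1)
    ax.set_yticks(range(1, 17))
    ax.set_ylabel("scenario")
    ax.set_xlabel("CCA (%)")
    ax.set_ylim(16.8, 0.2)  # scenario 1 on top
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
    return path
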