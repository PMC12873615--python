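"""Synthetic overview datasets with controlled overlap structure.

The generator emulates the features of real overviews that drive CCA:

* per-study inclusion propensities (some studies are "popular" and picked up
  by many reviews, others by few) drawn from a Beta distribution whose mean is
  ``inclusion_prob`` and whose dispersion is set by
  ``popularity_concentration`` — large values give near-identical
  propensities, small values a long popularity tail;
* publication threads: each study carries 1 + Poisson(``thread_mean_extra_refs``)
  references, and a review citing the study cites one or more of them;
* structural missingness: a ``late_fraction`` share of studies is published
  after the earliest review search date, so older reviews cannot possibly
  include them (a review never includes a study postdating its search);
* outcome structure: reviews and studies carry outcome labels so scope and
  outcome-level analyses are exercised; thread members share their study's
  outcomes.

Everything is reproducible from ``seed``; independent sub-streams per entity
class keep, e.g., review search dates stable when only study parameters change.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, replace

import numpy as np

from .datamodel import Inclusion, OverviewDataset, Reference, Review

__all__ = ["GeneratorConfig", "generate_overview", "expected_pairwise_cca"]

# Review searches span these six years; study publications may fall before or
# (for the late fraction) after the earliest search.
_SEARCH_WINDOW = (_dt.date(2016, 1, 1), _dt.date(2021, 12, 31))
_EARLIEST_PUBLICATION = _dt.date(2000, 1, 1)
_LATEST_PUBLICATION = _dt.date(2023, 12, 31)


@dataclass(frozen=True)
class GeneratorConfig:
    """Tunable structure of a synthetic overview.

    Defaults describe a mid-sized overview: 6 reviews over ~40 candidate
    studies with moderate (30%) inclusion propensity, occasional companion
    reports, a tenth of studies postdating the earliest search, and three
    outcomes with the main outcome widely covered.
    """

    n_reviews: int = 6
    n_studies: int = 40
    inclusion_prob: float = 0.3
    popularity_concentration: float = 10.0
    thread_mean_extra_refs: float = 0.3
    late_fraction: float = 0.1
    n_outcomes: int = 3
    review_outcome_prob: float = 0.6
    study_outcome_prob: float = 0.6
    main_outcome_review_prob: float = 0.8
    seed: int = 0

    def __post_init__(self):
        for name in ("inclusion_prob", "late_fraction", "review_outcome_prob",
                     "study_outcome_prob", "main_outcome_review_prob"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.n_reviews < 2:
            raise ValueError("n_reviews must be >= 2")
        if self.n_studies < 1 or self.n_outcomes < 1:
            raise ValueError("counts must be >= 1")
        if self.popularity_concentration <= 0:
            raise ValueError("popularity_concentration must be positive")
        if self.thread_mean_extra_refs < 0:
            raise ValueError("thread_mean_extra_refs must be non-negative")


def expected_pairwise_cca(p: float) -> float:
    """Expected pairwise CCA of two reviews with i.i.d. inclusion prob ``p``.

    Conditional on a study appearing in at least one of the two reviews, it
    appears in both with probability p^2 / (2p - p^2) = p / (2 - p); the
    pairwise CCA (a Jaccard index) therefore converges to 100*p/(2-p).
    """
    if not 0.0 < p <= 1.0:
        raise ValueError("p must be in (0, 1]: no studies can appear in the union at p=0")
    return 100.0 * p / (2.0 - p)


def _random_date(rng: np.random.Generator, lo: _dt.date, hi: _dt.date) -> _dt.date:
    span = (hi - lo).days
    return lo + _dt.timedelta(days=int(rng.integers(0, span + 1)))


def _outcome_set(rng, labels, main, p_main, p_other) -> set[str]:
    out = {o for o in labels if rng.random() < (p_main if o == main else p_other)}
    if not out:
        out.add(labels[int(rng.integers(0, len(labels)))])
    return out


def generate_overview(config: GeneratorConfig) -> OverviewDataset:
    """Draw one synthetic overview dataset; retries degenerate draws.

    Raises if 100 consecutive draws produce zero eligible inclusions (e.g.
    ``inclusion_prob`` near zero with few studies).
    """
    root = np.random.SeedSequence(config.seed)
    for attempt, child in enumerate(root.spawn(100)):
        dataset = _generate_once(config, child)
        if dataset is not None:
            return dataset
    raise ValueError(
        "generator produced zero eligible inclusions in 100 attempts: "
        f"inclusion_prob={config.inclusion_prob}, n_studies={config.n_studies}, "
        f"late_fraction={config.late_fraction} leave no review-study pair both "
        "eligible (study predates search) and selected"
    )


def _generate_once(config: GeneratorConfig, seed_seq: np.random.SeedSequence) -> OverviewDataset | None:
    # independent sub-streams per entity class
    rng_dates, rng_prop, rng_threads, rng_incl, rng_out = (
        np.random.default_rng(s) for s in seed_seq.spawn(5)
    )

    outcome_labels = [f"outcome_{k + 1}" for k in range(config.n_outcomes)]
    main = outcome_labels[0]

    # --- reviews ---------------------------------------------------------
    search_dates = sorted(
        _random_date(rng_dates, *_SEARCH_WINDOW) for _ in range(config.n_reviews)
    )
    review_outcomes = [
        _outcome_set(rng_out, outcome_labels, main,
                     config.main_outcome_review_prob, config.review_outcome_prob)
        for _ in range(config.n_reviews)
    ]
    if not any(main in o for o in review_outcomes):
        review_outcomes[int(rng_out.integers(0, config.n_reviews))].add(main)

    earliest_search = search_dates[0]

    # --- studies and their publication threads ---------------------------
    if config.inclusion_prob in (0.0, 1.0):
        propensities = np.full(config.n_studies, config.inclusion_prob)
    else:
        k = config.popularity_concentration
        propensities = rng_prop.beta(
            config.inclusion_prob * k, (1.0 - config.inclusion_prob) * k, size=config.n_studies
        )
    late = rng_dates.random(config.n_studies) < config.late_fraction
    study_dates = [
        _random_date(
            rng_dates,
            earliest_search + _dt.timedelta(days=1) if is_late else _EARLIEST_PUBLICATION,
            _LATEST_PUBLICATION if is_late else earliest_search,
        )
        for is_late in late
    ]
    study_outcomes = [
        _outcome_set(rng_out, outcome_labels, main,
                     config.study_outcome_prob, config.study_outcome_prob)
        for _ in range(config.n_studies)
    ]
    if not any(main in o for o in study_outcomes):
        study_outcomes[int(rng_out.integers(0, config.n_studies))].add(main)

    references: list[Reference] = []
    thread_members: list[list[tuple[str, _dt.date]]] = []
    for s in range(config.n_studies):
        sid = f"study_{s + 1:04d}"
        n_extra = int(rng_threads.poisson(config.thread_mean_extra_refs))
        members = []
        for k in range(1 + n_extra):
            rid = f"{sid}_ref{k + 1}"
            # companion reports appear at or after the index publication
            pub = study_dates[s] if k == 0 else _random_date(
                rng_threads, study_dates[s], _LATEST_PUBLICATION
            )
            references.append(
                Reference(reference_id=rid, study_id=sid,
                          publication_date=pub, outcomes=frozenset(study_outcomes[s]))
            )
            members.append((rid, pub))
        thread_members.append(members)

    # --- inclusions -------------------------------------------------------
    inclusions: list[Inclusion] = []
    review_ids = [f"review_{i + 1:02d}" for i in range(config.n_reviews)]
    for i, rv_id in enumerate(review_ids):
        for s in range(config.n_studies):
            if study_dates[s] > search_dates[i]:
                continue  # structurally unreachable
            if rng_incl.random() >= propensities[s]:
                continue
            # only reports already published by the search can be cited; the
            # index publication always qualifies
            citable = [rid for rid, pub in thread_members[s] if pub <= search_dates[i]]
            cited = [rid for rid in citable if rng_incl.random() < 0.5]
            if not cited:
                cited = [citable[int(rng_incl.integers(0, len(citable)))]]
            for rid in cited:
                inclusions.append(Inclusion(review_id=rv_id, reference_id=rid))

    if not inclusions:
        return None

    reviews = [
        Review(
            review_id=review_ids[i],
            search_date=search_dates[i],
            covers_main_outcome=main in review_outcomes[i],
            outcomes=frozenset(review_outcomes[i]),
        )
        for i in range(config.n_reviews)
    ]
    return OverviewDataset(
        reviews=tuple(reviews),
        references=tuple(references),
        inclusions=tuple(inclusions),
        main_outcome=main,
        outcome_universe=frozenset(outcome_labels),
    )
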