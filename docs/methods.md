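# Methods

## The statistic

`overlapcca` quantifies primary-study overlap in an overview of systematic
reviews. The input is an *evidence matrix*: rows are primary studies (or the
individual references reporting them), columns are the included systematic
reviews, and a cell is filled when the review includes the row. With

- `N` — total number of inclusion occurrences (filled cells),
- `r` — number of distinct rows,
- `c` — number of reviews,
- `SZ` — number of *structural zeros* (cells a review could not possibly have
  filled because the study was published after the review's search date),

the corrected covered area is

```
CCA = 100 · (N − r) / (r·c − r − SZ)        [percent]
```

With `SZ = 0` this is the classical definition: of all study entries beyond
the first appearance of each study, what share of the available cells do they
fill. The structural-zero correction removes unreachable cells from the
denominator, so a missingness-adjusted CCA is never lower than the unadjusted
one (the numerator is unchanged and the denominator can only shrink); this
monotonicity is enforced by property tests and re-measured by the acceptance
script.

The **pairwise CCA** of two reviews restricts the matrix to their two columns,
drops rows included by neither, and applies the same formula with `c = 2`. On
unadjusted matrices this is algebraically the Jaccard index of the two study
sets, `100·|A∩B|/|A∪B|`; the test suite checks the exact equivalence against a
set-arithmetic oracle. For missingness-adjusted matrices the pair's own
sub-matrix structural zeros enter the denominator by default; reusing the
whole-matrix `SZ` is available via `pairwise_cca(..., global_sz=True)` but is
not the default, because a pair should only be corrected for cells *it* could
not have filled.

Undefined values — fewer than two reviews, an empty pair sub-matrix, or a
non-positive denominator — are reported as explicit NA markers with a reason.
They are excluded from medians and quartiles and counted in `n_undefined`;
treating them as 0 would conflate "no comparable evidence" with "no overlap",
so the package refuses to do it.

## Matrix construction and the 16 scenarios

Four assumptions parameterise matrix construction:

1. **Level of analysis.** Overview level uses every review; outcome level
   keeps only reviews reporting the chosen outcome and references contributing
   to it. Outcome-level runs default to the overview's main outcome; other
   outcomes are analysed one at a time via the `outcome` argument and reported
   separately, never pooled.
2. **Scope adjustment.** Columns are restricted to reviews flagged as covering
   the overview's main outcome; rows contributing to no overview outcome are
   deleted, then rows left without any inclusion are dropped.
3. **Publication-thread adjustment.** References sharing a `study_id` (e.g. a
   trial's main report plus companion publications) collapse to one study-level
   row. A study-review cell is included if any member reference was; it is
   structurally missing only if every member cell was.
4. **Structural-missingness adjustment.** Absent cells whose row publication
   date is *strictly* later than the column's search date become structural
   zeros; equal dates count as reachable. For study-level rows the thread's
   earliest publication date is used. Included cells are never altered — an
   inclusion that postdates the search is kept as given, with a data-quality
   warning logged.

Crossing the two levels with the three binary adjustments yields the 16
canonical scenarios: 1–8 at overview level, 9–16 at outcome level, each block
ordered *none, scope, threads, missingness, scope+threads, scope+missingness,
threads+missingness, all three*. Scenario 1 is therefore fully unadjusted and
scenario 16 fully adjusted at outcome level. The ordering is recorded in every
output header so results stay interpretable.

Adjustments compose in the fixed order **scope → threads → missingness**. The
order matters only for the missingness step: marking structural zeros last
guarantees the `SZ` correction refers to exactly the rows and columns that are
analysed. Scope and thread collapse commute whenever thread members share
outcome labels (the generator's default, and tested as a property).

**Dates.** ISO-8601 dates or bare years are accepted. A bare year `Y`
canonicalises to `Y-12-31` for review search dates and `Y-01-01` for
publication dates — the conservative choice that can only *under*-mark
structural zeros when precision is missing, never invent them.

**Sensitivity summary.** A sweep runs all 16 scenarios (construction failures
become NA records with a reason; the sweep never aborts) and reports the
impact range, max − min of the defined overall CCAs and of the per-scenario
median pairwise CCAs. Ranges are labelled descriptively: *minimal* ≤ 5
percentage points, *moderate* strictly between 5 and 10, *marked* ≥ 10.
Overlap itself is labelled *slight* [0, 5), *moderate* [5, 10), *high*
[10, 15], *very high* (15, 100]: the published bands are open at the printed
outer inequalities and ambiguous at the joints, so the high band is closed at
both ends and the convention is stamped into every output file.

## Synthetic data generator

`generate_overview(GeneratorConfig(...))` emulates the data-generating
features that drive CCA, so the whole pipeline is testable without real
overview data:

| parameter | default | meaning |
|---|---|---|
| `n_reviews` | 6 | systematic reviews (columns); search dates uniform over 2016–2021 |
| `n_studies` | 40 | candidate primary studies |
| `inclusion_prob` | 0.3 | mean per-study inclusion propensity |
| `popularity_concentration` | 10 | Beta concentration of propensities; small ⇒ few "popular" studies dominate |
| `thread_mean_extra_refs` | 0.3 | Poisson mean of companion reports per study |
| `late_fraction` | 0.1 | share of studies published after the earliest search date |
| `n_outcomes` | 3 | outcome labels; the first is the main outcome |
| `review_outcome_prob` | 0.6 | a review reports each non-main outcome |
| `study_outcome_prob` | 0.6 | a study contributes to each outcome |
| `main_outcome_review_prob` | 0.8 | a review covers the main outcome |
| `seed` | 0 | reproducibility; sub-streams per entity class |

Propensities are Beta(`p·k`, `(1−p)·k`) with `p = inclusion_prob` and
`k = popularity_concentration`, which reproduces both high-overlap/few-reference
and dense-reference/low-overlap regimes. Thread multiplicities are
1 + Poisson(`thread_mean_extra_refs`); no empirical multiplicity distribution
exists, so Poisson is the minimal-assumption choice. Companion reports are
dated at or after the index publication, and a review cites only thread
members already published at its search date — a review can never include a
study (or cite a report) that postdates its search, which keeps the
missingness adjustment exactly inert when `late_fraction = 0` and threads are
singletons. Outcome labels are assigned independently with the stated
probabilities; the main outcome is forced non-empty on both axes, and every
entity gets at least one label. Seeding uses `numpy.random.SeedSequence` with
independent child streams for dates, propensities, threads, inclusions and
outcomes, so changing one parameter class leaves the other draws stable.
Degenerate configurations (no eligible inclusion in 100 attempts) raise a
diagnostic error rather than returning an invalid dataset.

For two reviews with i.i.d. per-study inclusion probability `p`, a study in
the union of their study sets is in the intersection with probability
`p² / (2p − p²) = p / (2 − p)`; the expected pairwise CCA is therefore
`100·p/(2−p)`. This closed form (`expected_pairwise_cca`) is the calibration
oracle: simulated two-review datasets at `n_studies = 5000` with propensities
pinned at `p` (concentration 10⁹) recover it within 3 Monte-Carlo standard
errors over 20 replicates for `p ∈ {0.2, 0.5, 0.8}`.

**What passing tests do and do not show.** The generator produces Bernoulli
inclusion given eligibility, independent outcome labels, and uniform dates. It
does not emulate topical clustering of reviews, correlated search strategies,
reference-matching errors, or non-random missingness of outcome data — so
green tests certify the arithmetic, the adjustment semantics and the
generator's own calibration, not the behaviour of CCA on any particular real
overview. Matrices from real overviews can be analysed by converting them to
the documented CSV schema and running the same pipeline.

## Numerical and degenerate-input choices

- All CCA arithmetic is exact rational arithmetic in floating point (one
  division); the brute-force cell-enumeration oracle matches to machine
  precision on 1,000 random matrices.
- Quartiles for pairwise summaries use linear interpolation
  (`numpy.percentile(..., method="linear")`), matching default boxplot hinges.
- Human-readable output prints one decimal place; machine outputs (CSV/JSON)
  keep full precision.
- Matrices are immutable; every adjustment returns a new object, and rows
  without inclusions are rejected at construction, so `N ≥ r` holds by
  invariant and `0 ≤ CCA ≤ 100` follows wherever the value is defined.
- Problem sizes in the test and acceptance runs (matrices up to 12×6, datasets
  of 40–60 studies, convergence checks at 5,000 studies × 20 replicates) were
  chosen as the smallest sizes at which the Monte-Carlo checks are sharp.

## Known limitations

- Thread membership must be given explicitly via `study_id`; the package does
  not deduplicate citations or parse reference strings.
- Scope relevance is taken from the `covers_main_outcome` flag as recorded;
  no attempt is made to infer review scope from outcome sets.
- The change-magnitude and overlap categories are descriptive conventions, not
  validated thresholds; the documented boundary handling is one defensible
  reading of the published bands.
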