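# overlapcca

Quantitative overlap assessment for **overviews of systematic reviews**
(umbrella reviews). When several systematic reviews (SRs) on the same question
include the same primary studies, a meta-analytic summary across them double-
counts evidence and overstates precision. The standard way to measure this
redundancy is the **corrected covered area (CCA)**, computed from an *evidence
matrix* — primary studies in rows, SRs in columns, a filled cell where a review
includes a study:

```
CCA = 100 · (N − r) / (r·c − r − SZ)
```

where `N` is the number of filled cells, `r` the number of studies, `c` the
number of reviews, and `SZ` the number of *structural zeros* — cells a review
could not possibly have filled because the study was published after the
review's search date (`SZ = 0` in the classical, unadjusted form). The
**pairwise CCA** applies the formula to each pair of reviews; on unadjusted
matrices it equals `100·|A∩B|/|A∪B|`, the Jaccard index of the two study sets.

The catch is that the matrix itself depends on construction assumptions: the
level of analysis (whole overview vs a single outcome), the review scope, the
handling of *publication threads* (several reports of one study), and
structural missingness. `overlapcca` makes those assumptions explicit
parameters: it builds the evidence matrix under all **16 canonical scenarios**
(scenarios 1–8 at overview level, 9–16 at outcome level, each crossing the
three binary adjustments), computes overall and pairwise CCA for each, and
summarises sensitivity as the max−min impact range with descriptive labels
(*minimal* ≤ 5 points, *moderate* 5–10, *marked* ≥ 10). A seeded synthetic-data
generator produces overview datasets with controlled overlap so every stage is
testable end to end. It is aimed at overview authors and methodologists who
want reproducible, assumption-transparent overlap reporting.

## Worked example

Simulate an overview, validate it, and measure overlap:

```bash
$ overlapcca simulate --out demo/dataset --seed 7
wrote dataset to demo/dataset: 6 reviews, 48 references, 61 inclusions

$ overlapcca validate demo/dataset
OK: 6 reviews, 48 references, 61 inclusions, main outcome 'outcome_1'

$ overlapcca cca demo/dataset --pairwise
overall CCA: 20.7% (very high) [N=61, r=30, c=6, SZ=0]
  review_01 vs review_02: 25.0%
  review_01 vs review_03: 10.0%
  ...
```

The overall CCA of 20.7% means that of the 150 cells the 6 reviews could have
filled beyond each study's first appearance (`r·c − r = 180 − 30`), 31 hold a
duplicate entry (`N − r = 61 − 30`) — *very high* overlap on the published
bands. The pairwise values show which review pairs actually share studies.

Run the full 16-scenario sensitivity sweep with the boxplot figure:

```bash
$ overlapcca report demo/dataset --out demo/results
wrote demo/results/scenario_cca.csv, demo/results/sweep_summary.json and demo/results/scenario_cca.svg

$ cat demo/results/sweep_summary.json
{
  "tool_version": "0.1.0",
  "outcome": "outcome_1",
  "overall": {
    "impact_range": 5.649122807017541,
    "change_category": "moderate",
    "n_defined": 16
  },
  "pairwise_median": {
    "impact_range": 6.3492063492063515,
    "change_category": "moderate",
    "n_defined": 16
  }
}
```

Here the choice of matrix-construction assumptions moves the overall CCA by
5.6 percentage points across the 16 scenarios — a *moderate* change: for this
dataset the overlap verdict depends materially on how the matrix is built.
`scenario_cca.csv` holds one row per scenario (flags, `N`, `r`, `c`, `SZ`,
overall CCA and category, pairwise quartiles, NA reasons), with a metadata
header recording the scenario ordering and band conventions. The same pipeline
is available as a library:

```python
from overlapcca import GeneratorConfig, generate_overview, run_scenario_sweep, impact_range

ds = generate_overview(GeneratorConfig(seed=7))
sweep = run_scenario_sweep(ds)
print(impact_range(sweep, "overall"))   # 5.649122807017541
```

Real datasets are three CSV tables (`reviews.csv`, `references.csv`,
`inclusions.csv`) plus a `dataset.json` naming the main outcome — see
`docs/methods.md` for the schema, the model and all conventions.

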