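import datetime as dt

import numpy as np
import pytest

from overlapcca.datamodel import CellState, Inclusion, OverviewDataset, Reference, Review
from overlapcca.matrix import (
    adjust_scope,
    apply_scenario,
    build_matrix,
    collapse_threads,
    enumerate_scenarios,
    mark_structural_missingness,
)
from overlapcca.simulate import GeneratorConfig, generate_overview


class TestBuildMatrix:
    def test_overview_level_shape(self, tiny_dataset):
        m = build_matrix(tiny_dataset)
        assert m.column_ids == ("A", "B", "C")
        # ref4 has no inclusion anywhere and is dropped
        assert m.row_ids == ("ref1", "ref2a", "ref2b", "ref3")
        assert m.row_mode == "reference"
        assert m.n_included == 5

    def test_outcome_level_restricts_columns_and_rows(self, tiny_dataset):
        # 'function' is reported by reviews A and C only
        m = build_matrix(tiny_dataset, level="outcome", outcome="function")
        assert m.column_ids == ("A", "C")
        # only refs contributing to 'function' and still included somewhere
        assert m.row_ids == ("ref2a",)

    def test_reference_cited_only_outside_outcome_drops(self, tiny_dataset):
        # brute-force oracle: filter the inclusion table by hand
        outcome = "pain"
        cols = {rv.review_id for rv in tiny_dataset.reviews if outcome in rv.outcomes}
        refs = {r.reference_id for r in tiny_dataset.references if outcome in r.outcomes}
        expected_rows = {
            i.reference_id
            for i in tiny_dataset.inclusions
            if i.review_id in cols and i.reference_id in refs
        }
        m = build_matrix(tiny_dataset, level="outcome", outcome="pain")
        assert set(m.row_ids) == expected_rows
        assert set(m.column_ids) == cols

    def test_unknown_outcome_named_in_error(self, tiny_dataset):
        with pytest.raises(ValueError, match="mortality"):
            build_matrix(tiny_dataset, level="outcome", outcome="mortality")

    def test_empty_overview_rejected(self, tiny_dataset):
        empty = OverviewDataset(
            reviews=(),
            references=tiny_dataset.references,
            inclusions=(),
            main_outcome="pain",
            outcome_universe=frozenset({"pain"}),
        )
        with pytest.raises(ValueError, match="empty overview"):
            build_matrix(empty)


class TestAdjustScope:
    def test_identity_when_all_in_scope(self):
        ds = OverviewDataset(
            reviews=(
                Review("A", dt.date(2020, 1, 1), True, frozenset({"x"})),
                Review("B", dt.date(2020, 1, 1), True, frozenset({"x"})),
            ),
            references=(Reference("r1", "s1", dt.date(2018, 1, 1), frozenset({"x"})),),
            inclusions=(Inclusion("A", "r1"), Inclusion("B", "r1")),
            main_outcome="x",
            outcome_universe=frozenset({"x"}),
        )
        m = build_matrix(ds)
        adj = adjust_scope(m, ds)
        assert adj.row_ids == m.row_ids and adj.column_ids == m.column_ids
        assert np.array_equal(adj.cells, m.cells)

    def test_out_of_scope_columns_dropped(self, tiny_dataset):
        m = adjust_scope(build_matrix(tiny_dataset), tiny_dataset)
        assert m.column_ids == ("A", "B")  # C does not cover the main outcome

    def test_rows_without_outcome_contribution_dropped(self, tiny_dataset):
        m = adjust_scope(build_matrix(tiny_dataset), tiny_dataset)
        assert "ref3" not in m.row_ids  # contributes to no overview outcome

    def test_row_losing_sole_inclusion_removed(self):
        # brute-force audit: after dropping review B, row r2 has no inclusion
        ds = OverviewDataset(
            reviews=(
                Review("A", dt.date(2020, 1, 1), True, frozenset({"x"})),
                Review("B", dt.date(2020, 1, 1), False, frozenset({"x"})),
            ),
            references=(
                Reference("r1", "s1", dt.date(2018, 1, 1), frozenset({"x"})),
                Reference("r2", "s2", dt.date(2018, 1, 1), frozenset({"x"})),
            ),
            inclusions=(Inclusion("A", "r1"), Inclusion("B", "r1"), Inclusion("B", "r2")),
            main_outcome="x",
            outcome_universe=frozenset({"x"}),
        )
        adj = adjust_scope(build_matrix(ds), ds)
        assert adj.column_ids == ("A",)
        assert adj.row_ids == ("r1",)

    def test_no_review_in_scope_errors(self, tiny_dataset):
        ds = OverviewDataset(
            reviews=tuple(
                Review(r.review_id, r.search_date, False, r.outcomes) for r in tiny_dataset.reviews
            ),
            references=tiny_dataset.references,
            inclusions=tiny_dataset.inclusions,
            main_outcome="pain",
            outcome_universe=tiny_dataset.outcome_universe,
        )
        with pytest.raises(ValueError, match="scope adjustment empties matrix"):
            adjust_scope(build_matrix(ds), ds)


class TestCollapseThreads:
    def test_singleton_threads_identity_up_to_mode(self):
        ds = generate_overview(GeneratorConfig(thread_mean_extra_refs=0.0, seed=3))
        m = build_matrix(ds)
        collapsed = collapse_threads(m, ds)
        assert collapsed.row_mode == "study"
        assert collapsed.n_rows == m.n_rows
        assert np.array_equal(collapsed.cells, m.cells)

    def test_split_thread_merges_into_one_row(self, tiny_dataset):
        # s2 is cited via ref2a by A and via ref2b by B
        collapsed = collapse_threads(build_matrix(tiny_dataset), tiny_dataset)
        i = collapsed.row_ids.index("s2")
        frame = collapsed.to_frame()
        assert frame.loc["s2", "A"] == CellState.INCLUDED
        assert frame.loc["s2", "B"] == CellState.INCLUDED

    def test_same_review_thread_shrinks_counts_only(self):
        # 3 companion reports all cited by review A only: N and r each drop
        # by 2, pairwise study sets unchanged (brute-force recount)
        ds = OverviewDataset(
            reviews=(
                Review("A", dt.date(2020, 1, 1), True, frozenset({"x"})),
                Review("B", dt.date(2020, 1, 1), True, frozenset({"x"})),
            ),
            references=(
                Reference("r1a", "s1", dt.date(2015, 1, 1), frozenset({"x"})),
                Reference("r1b", "s1", dt.date(2016, 1, 1), frozenset({"x"})),
                Reference("r1c", "s1", dt.date(2017, 1, 1), frozenset({"x"})),
                Reference("r2", "s2", dt.date(2015, 1, 1), frozenset({"x"})),
            ),
            inclusions=(
                Inclusion("A", "r1a"), Inclusion("A", "r1b"), Inclusion("A", "r1c"),
                Inclusion("A", "r2"), Inclusion("B", "r2"),
            ),
            main_outcome="x",
            outcome_universe=frozenset({"x"}),
        )
        m = build_matrix(ds)
        collapsed = collapse_threads(m, ds)
        assert m.n_included - collapsed.n_included == 2
        assert m.n_rows - collapsed.n_rows == 2
        # pairwise sets at study granularity are invariant
        by_ref = ds.reference_by_id()
        for col in ("A", "B"):
            j = m.column_ids.index(col)
            before = {by_ref[m.row_ids[i]].study_id
                      for i in range(m.n_rows) if m.cells[i, j] == CellState.INCLUDED}
            jc = collapsed.column_ids.index(col)
            after = {collapsed.row_ids[i]
                     for i in range(collapsed.n_rows)
                     if collapsed.cells[i, jc] == CellState.INCLUDED}
            assert before == after

    def test_double_collapse_rejected(self, tiny_dataset):
        collapsed = collapse_threads(build_matrix(tiny_dataset), tiny_dataset)
        with pytest.raises(ValueError, match="already at study level"):
            collapse_threads(collapsed, tiny_dataset)

    def test_sm_propagates_only_when_all_members_sm(self, tiny_dataset):
        marked = mark_structural_missingness(build_matrix(tiny_dataset), tiny_dataset)
        collapsed = collapse_threads(marked, tiny_dataset)
        frame = collapsed.to_frame()
        # ref2a (2016) and ref2b (2017) both postdate C's 2018 search? no:
        # both predate nothing — C searched 2018-01-01, both published before,
        # so the s2/C cell is plain ABSENT
        assert frame.loc["s2", "C"] == CellState.ABSENT
        # ref3 (2019-09) postdates A's search (2019-06) and C's (2018):
        # its singleton thread keeps the SM marks
        assert frame.loc["s3", "A"] == CellState.STRUCTURAL_MISSING
        assert frame.loc["s3", "C"] == CellState.STRUCTURAL_MISSING


class TestStructuralMissingness:
    def test_no_late_studies_is_identity(self):
        # singleton threads: with companion reports, a late companion can
        # still be structurally unreachable at reference level
        ds = generate_overview(
            GeneratorConfig(late_fraction=0.0, thread_mean_extra_refs=0.0, seed=5)
        )
        m = build_matrix(ds)
        marked = mark_structural_missingness(m, ds)
        assert np.array_equal(marked.cells, m.cells)

    def test_late_absent_cell_marked(self, tiny_dataset):
        marked = mark_structural_missingness(build_matrix(tiny_dataset), tiny_dataset)
        frame = marked.to_frame()
        assert frame.loc["ref3", "A"] == CellState.STRUCTURAL_MISSING
        assert frame.loc["ref3", "C"] == CellState.STRUCTURAL_MISSING
        assert frame.loc["ref3", "B"] == CellState.INCLUDED  # B searched later

    def test_exhaustive_cell_state_audit(self, tiny_dataset):
        # independent oracle: recompute every expected state from dates
        m = build_matrix(tiny_dataset)
        marked = mark_structural_missingness(m, tiny_dataset)
        by_ref = tiny_dataset.reference_by_id()
        by_rev = tiny_dataset.review_by_id()
        for i, rid in enumerate(m.row_ids):
            for j, cid in enumerate(m.column_ids):
                before = m.cells[i, j]
                late = by_ref[rid].publication_date > by_rev[cid].search_date
                expected = (
                    CellState.STRUCTURAL_MISSING
                    if (before == CellState.ABSENT and late)
                    else before
                )
                assert marked.cells[i, j] == expected

    def test_implausible_inclusion_kept_and_warned(self, caplog):
        # a review "including" a study published after its search keeps the
        # inclusion (data as given wins) but logs a data-quality warning
        ds = OverviewDataset(
            reviews=(
                Review("A", dt.date(2019, 1, 1), True, frozenset({"x"})),
                Review("B", dt.date(2022, 1, 1), True, frozenset({"x"})),
            ),
            references=(Reference("r1", "s1", dt.date(2021, 1, 1), frozenset({"x"})),),
            inclusions=(Inclusion("A", "r1"), Inclusion("B", "r1")),
            main_outcome="x",
            outcome_universe=frozenset({"x"}),
        )
        m = build_matrix(ds)
        with caplog.at_level("WARNING", logger="overlapcca.matrix"):
            marked = mark_structural_missingness(m, ds)
        assert marked.to_frame().loc["r1", "A"] == CellState.INCLUDED
        assert any("inclusion kept" in rec.message for rec in caplog.records)

    def test_equal_dates_are_reachable(self):
        ds = OverviewDataset(
            reviews=(
                Review("A", dt.date(2020, 1, 1), True, frozenset({"x"})),
                Review("B", dt.date(2021, 1, 1), True, frozenset({"x"})),
            ),
            references=(Reference("r1", "s1", dt.date(2020, 1, 1), frozenset({"x"})),),
            inclusions=(Inclusion("B", "r1"),),
            main_outcome="x",
            outcome_universe=frozenset({"x"}),
        )
        marked = mark_structural_missingness(build_matrix(ds), ds)
        assert marked.to_frame().loc["r1", "A"] == CellState.ABSENT


class TestScenarios:
    def test_enumeration_is_exhaustive_and_canonical(self):
        specs = enumerate_scenarios()
        assert len(specs) == 16
        assert [s.index for s in specs] == list(range(1, 17))
        assert all(s.level == "overview" for s in specs[:8])
        assert all(s.level == "outcome" for s in specs[8:])
        combos = {(s.level, s.adjust_scope, s.adjust_threads, s.adjust_missingness) for s in specs}
        assert len(combos) == 16  # pairwise distinct, exhaustive
        s1, s2, s3, s4 = specs[0], specs[1], specs[2], specs[3]
        assert not (s1.adjust_scope or s1.adjust_threads or s1.adjust_missingness)
        assert (s2.adjust_scope, s2.adjust_threads, s2.adjust_missingness) == (True, False, False)
        assert (s3.adjust_scope, s3.adjust_threads, s3.adjust_missingness) == (False, True, False)
        assert (s4.adjust_scope, s4.adjust_threads, s4.adjust_missingness) == (False, False, True)

    def test_scenario_one_is_plain_build(self, tiny_dataset):
        spec1 = enumerate_scenarios()[0]
        m = apply_scenario(tiny_dataset, spec1)
        base = build_matrix(tiny_dataset)
        assert m.row_ids == base.row_ids and m.column_ids == base.column_ids
        assert np.array_equal(m.cells, base.cells)
        assert m.provenance == spec1

    def test_scenario_eight_equals_manual_chain(self, tiny_dataset):
        spec8 = enumerate_scenarios()[7]
        assert (spec8.adjust_scope, spec8.adjust_threads, spec8.adjust_missingness) == (
            True, True, True,
        )
        m = apply_scenario(tiny_dataset, spec8)
        manual = mark_structural_missingness(
            collapse_threads(adjust_scope(build_matrix(tiny_dataset), tiny_dataset), tiny_dataset),
            tiny_dataset,
        )
        assert m.row_ids == manual.row_ids and m.column_ids == manual.column_ids
        assert np.array_equal(m.cells, manual.cells)

    def test_outcome_scope_near_idempotent_when_all_reviews_cover_main(self):
        # every review covers the main outcome: scenario 10 (outcome+scope)
        # reduces to scenario 9 (outcome only)
        ds = generate_overview(GeneratorConfig(main_outcome_review_prob=1.0, seed=11))
        specs = enumerate_scenarios()
        m9 = apply_scenario(ds, specs[8])
        m10 = apply_scenario(ds, specs[9])
        assert m9.column_ids == m10.column_ids
        assert m9.row_ids == m10.row_ids
        assert np.array_equal(m9.cells, m10.cells)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_adjustments_never_grow_matrix(self, seed):
        ds = generate_overview(GeneratorConfig(thread_mean_extra_refs=0.5, late_fraction=0.2, seed=seed))
        base = build_matrix(ds)
        scoped = adjust_scope(base, ds)
        assert scoped.n_included <= base.n_included and scoped.n_rows <= base.n_rows
        collapsed = collapse_threads(base, ds)
        assert collapsed.n_included <= base.n_included and collapsed.n_rows <= base.n_rows
        marked = mark_structural_missingness(base, ds)
        assert marked.n_included == base.n_included and marked.n_rows == base.n_rows

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_scope_and_collapse_commute_when_threads_share_outcomes(self, seed):
        # generator gives thread members their study's outcome set, so the
        # two adjustments commute
        ds = generate_overview(GeneratorConfig(thread_mean_extra_refs=0.8, seed=seed))
        base = build_matrix(ds)
        a = collapse_threads(adjust_scope(base, ds), ds)
        b = adjust_scope(collapse_threads(base, ds), ds)
        assert a.row_ids == b.row_ids and a.column_ids == b.column_ids
        assert np.array_equal(a.cells, b.cells)
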