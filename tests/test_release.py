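"""Release semantics: override, deferred disqualification, audit, reversal."""

import datetime

import pytest

from cii import (
    CIIError,
    FunctionalTierError,
    InvalidTransitionError,
    PieceStatus,
    Query,
    ReviewConclusion,
    StudyType,
    apply_override,
    compute_escore_series,
    create_release,
    reactivate,
    requalify,
    reversal_stats,
    scenario,
)
from conftest import add_piece, make_store


def series_for(fx, end_year=2012):
    return compute_escore_series(
        Query(), fx.store, fx.hierarchy, fx.matrices["uniform"], fx.custom,
        fx.layout, fx.scoring, end_year,
    )


class TestApplyOverride:
    def test_marks_context_pieces_pending_and_nothing_else(self):
        fx = scenario("reversal")
        affected = apply_override(
            fx.store.get_piece("REV"), fx.store, fx.layout, fx.hierarchy
        )
        assert affected == ["E1", "E2", "E3"]
        for pid in affected:
            assert fx.store.get_piece(pid).status is PieceStatus.disqualified_pending
        # nothing deleted; the review itself is stored
        assert fx.store.get_piece("REV").status is PieceStatus.active

    def test_lower_tier_review_rejected(self, layout, hierarchy):
        store = make_store()
        add_piece(store, "P1", "T1", 2004)
        rct_review = add_piece(
            store, "RV", "T1", 2006, significant=False,
            review_conclusion=ReviewConclusion.insufficient_support,
        )
        with pytest.raises(FunctionalTierError, match="top functional tier"):
            apply_override(rct_review, store, layout, hierarchy)

    def test_supportive_review_does_not_override(self, layout, hierarchy):
        store = make_store()
        add_piece(store, "P1", "T1", 2004)
        review = add_piece(
            store, "RV", "T1", 2006, study_type=StudyType.meta_analysis,
            significant=False, review_conclusion=ReviewConclusion.supports,
        )
        with pytest.raises(CIIError, match="insufficient_support"):
            apply_override(review, store, layout, hierarchy)

    def test_vacuous_override_returns_empty_list(self, layout, hierarchy):
        store = make_store()
        review = add_piece(
            store, "RV", "T1", 2006, study_type=StudyType.systematic_review,
            significant=False,
            review_conclusion=ReviewConclusion.insufficient_support,
        )
        assert apply_override(review, store, layout, hierarchy) == []
        assert "RV" in store.pieces

    def test_tagged_review_restricts_to_same_tagged_pieces(self, layout, hierarchy):
        store = make_store()
        add_piece(store, "P1", "T1", 2003, subgroup_tags={"egfr-mutant"})
        add_piece(store, "P2", "T1", 2004)
        review = add_piece(
            store, "RV", "T1", 2006, study_type=StudyType.meta_analysis,
            significant=False, subgroup_tags={"egfr-mutant"},
            review_conclusion=ReviewConclusion.insufficient_support,
        )
        assert apply_override(review, store, layout, hierarchy) == ["P1"]

    def test_pieces_after_review_date_not_touched(self, layout, hierarchy):
        store = make_store()
        add_piece(store, "P1", "T1", 2004)
        add_piece(store, "P2", "T1", 2010)
        review = add_piece(
            store, "RV", "T1", 2006, study_type=StudyType.meta_analysis,
            significant=False,
            review_conclusion=ReviewConclusion.insufficient_support,
        )
        assert apply_override(review, store, layout, hierarchy) == ["P1"]
        assert store.get_piece("P2").status is PieceStatus.active


class TestCreateRelease:
    def test_pre_release_series_unchanged_by_override(self):
        fx = scenario("reversal")
        before = series_for(fx)
        apply_override(fx.store.get_piece("REV"), fx.store, fx.layout, fx.hierarchy)
        # pending pieces still score until the release is cut
        assert series_for(fx).scores == before.scores

    def test_post_release_series_pointwise_le_and_monotone(self):
        fx = scenario("reversal")
        before = series_for(fx)
        apply_override(fx.store.get_piece("REV"), fx.store, fx.layout, fx.hierarchy)
        release = create_release(fx.store)
        after = series_for(fx)
        assert all(after.scores[y] <= before.scores[y] for y in before.scores)
        values = list(after.scores.values())
        assert all(b >= a for a, b in zip(values, values[1:]))
        # snapshot still reproduces the pre-override view of disqualified rows
        assert release.snapshot.get_piece("E1").status is PieceStatus.disqualified
        assert len(release.applied_transitions) == 3

    def test_disqualified_pieces_remain_retrievable(self):
        fx = scenario("reversal")
        n_before = fx.store.total_row_count()
        apply_override(fx.store.get_piece("REV"), fx.store, fx.layout, fx.hierarchy)
        create_release(fx.store)
        assert fx.store.total_row_count() > n_before
        assert fx.store.get_piece("E2").status is PieceStatus.disqualified
        # full version history of a disqualified piece is intact
        assert [p.status for p in fx.store._pieces["E2"]] == [
            PieceStatus.active,
            PieceStatus.disqualified_pending,
            PieceStatus.disqualified,
        ]

    def test_noop_release_changes_nothing_but_metadata(self):
        fx = scenario("stepwise_accumulation")
        before = series_for(fx, 2014)
        r1 = create_release(fx.store)
        after = series_for(fx, 2014)
        assert before.scores == after.scores
        r2 = create_release(fx.store)
        assert r2.release_id == r1.release_id + 1
        assert r2.snapshot_hash == r1.snapshot_hash  # tables untouched

    def test_successive_releases_append_only(self):
        fx = scenario("reversal")
        apply_override(fx.store.get_piece("REV"), fx.store, fx.layout, fx.hierarchy)
        create_release(fx.store)
        n_rows = fx.store.total_row_count()
        n_audit = len(fx.store.audit_log)
        create_release(fx.store)
        assert fx.store.total_row_count() >= n_rows
        assert len(fx.store.audit_log) >= n_audit

    def test_frozen_snapshot_rejects_mutation(self):
        fx = scenario("reversal")
        release = create_release(fx.store)
        from cii import FrozenStoreError, Treatment

        with pytest.raises(FrozenStoreError):
            release.snapshot.add_record(Treatment(treatment_id="TX"))


class TestRequalifyAndReactivate:
    def _overridden_fixture(self):
        fx = scenario("reversal")
        apply_override(fx.store.get_piece("REV"), fx.store, fx.layout, fx.hierarchy)
        create_release(fx.store)
        return fx

    def test_new_evidence_flags_disqualified_for_review(self):
        fx = self._overridden_fixture()
        new_piece = add_piece(
            fx.store, "NEW", "T1", 2015,
        )
        flagged = requalify(new_piece, fx.store, fx.layout)
        assert flagged == ["E1", "E2", "E3"]
        for pid in flagged:
            assert fx.store.get_piece(pid).status is PieceStatus.to_review

    def test_new_piece_in_untouched_context_flags_nothing(self):
        fx = self._overridden_fixture()
        new_piece = add_piece(
            fx.store, "NEW", "T1", 2015, state="regional", goal="stop_progression",
        )
        assert requalify(new_piece, fx.store, fx.layout) == []

    def test_reactivation_restores_contributions(self):
        fx = self._overridden_fixture()
        dropped = series_for(fx, 2015)
        new_piece = add_piece(fx.store, "NEW", "T1", 2015)
        flagged = requalify(new_piece, fx.store, fx.layout)
        reactivate(flagged, fx.store, timestamp=datetime.date(2015, 12, 1))
        create_release(fx.store)
        restored = series_for(fx, 2015)
        assert all(restored.scores[y] >= dropped.scores[y] for y in dropped.scores)
        assert restored.scores[2006] == 3.0  # the three old trials count again

    def test_state_machine_rejects_illegal_edges(self):
        fx = scenario("reversal")
        with pytest.raises(InvalidTransitionError):
            fx.store.transition_status(
                "E1", PieceStatus.disqualified, timestamp=datetime.date(2008, 1, 1)
            )
        with pytest.raises(InvalidTransitionError):
            fx.store.transition_status(
                "E1", PieceStatus.to_review, timestamp=datetime.date(2008, 1, 1)
            )

    def test_every_transition_writes_exactly_one_audit_entry(self):
        fx = self._overridden_fixture()
        # 3 pending + 3 disqualified entries so far
        assert len(fx.store.audit_log) == 6
        new_piece = add_piece(fx.store, "NEW", "T1", 2015)
        requalify(new_piece, fx.store, fx.layout)
        assert len(fx.store.audit_log) == 9
        entry_ids = [e.entry_id for e in fx.store.audit_log]
        assert entry_ids == sorted(set(entry_ids))


class TestReversalStats:
    def test_single_override_counts(self):
        fx = scenario("reversal")
        apply_override(fx.store.get_piece("REV"), fx.store, fx.layout, fx.hierarchy)
        create_release(fx.store)
        stats = reversal_stats(fx.store, fx.layout)
        assert stats["totals"]["n_override_events"] == 1
        assert stats["totals"]["pieces_ever_disqualified"] == 3
        assert stats["by_context"][0]["treatment_id"] == "T1"
        assert stats["by_context"][0]["square"] == "D"

    def test_no_overrides_all_zero(self):
        fx = scenario("stepwise_accumulation")
        create_release(fx.store)
        stats = reversal_stats(fx.store, fx.layout)
        assert stats["totals"]["n_override_events"] == 0
        assert stats["totals"]["pieces_ever_disqualified"] == 0

    def test_reversed_then_restored_traced(self):
        fx = scenario("reversal")
        apply_override(fx.store.get_piece("REV"), fx.store, fx.layout, fx.hierarchy)
        create_release(fx.store)
        new_piece = add_piece(fx.store, "NEW", "T1", 2015)
        flagged = requalify(new_piece, fx.store, fx.layout)
        reactivate(flagged, fx.store, timestamp=datetime.date(2015, 12, 1))
        stats = reversal_stats(fx.store, fx.layout)
        assert stats["totals"]["reversed_then_restored"] == 1
        assert stats["totals"]["pieces_reactivated"] == 3

    def test_requires_a_release(self):
        fx = scenario("reversal")
        with pytest.raises(CIIError, match="release"):
            reversal_stats(fx.store, fx.layout)
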