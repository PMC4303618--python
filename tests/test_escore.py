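"""E-Score engine: product formula, cumulative series, strata, fingerprint."""

import datetime

import pytest

from cii import (
    CIIError,
    CorpusParams,
    CustomWeights,
    DiseaseState,
    Modality,
    Query,
    ScoringConfig,
    TherapeuticGoal,
    ValueMatrix,
    compute_escore_series,
    config_fingerprint,
    generate_corpus,
    piece_contribution,
    stratified_scores,
    uniform_matrix,
)
from conftest import add_piece, make_store
from reference_impl import brute_force_series


def curative_matrices(layout, curative=2.0, other=1.0):
    weights = {
        s: (curative if s in layout.curative_set else other) for s in layout.squares
    }
    return [ValueMatrix(effective_date=datetime.date(1990, 1, 1), weights=weights)]


class TestPieceContribution:
    def test_product_of_three_factors(self, hierarchy, layout, scoring, custom):
        store = make_store()
        piece = add_piece(
            store, "P1", "T1", 2005, state=DiseaseState.advanced,
            goal=TherapeuticGoal.become_disease_free,
        )
        matrices = curative_matrices(layout)  # square A weighted 2
        assert piece_contribution(
            piece, store, hierarchy, matrices, custom, layout, scoring
        ) == pytest.approx(2.0)

    def test_all_zero_value_matrix_annihilates(self, hierarchy, layout, scoring, custom):
        store = make_store()
        piece = add_piece(store, "P1", "T1", 2005)
        zero = [uniform_matrix(datetime.date(1990, 1, 1), value=0.0)]
        assert piece_contribution(
            piece, store, hierarchy, zero, custom, layout, scoring
        ) == 0.0

    def test_group_times_value_times_custom(self, hierarchy, layout, scoring):
        store = make_store()
        piece = add_piece(
            store, "P1", "T1", 2005, group_evidence=True, group_size=4,
            state=DiseaseState.advanced, goal=TherapeuticGoal.become_disease_free,
        )
        matrices = curative_matrices(layout, curative=3.0)
        custom = CustomWeights(per_piece_override={"P1": 0.5})
        # (1.0 / 4) * 3 * 0.5
        assert piece_contribution(
            piece, store, hierarchy, matrices, custom, layout, scoring
        ) == pytest.approx(0.375)

    def test_non_qualifying_piece_contributes_exactly_zero(
        self, hierarchy, layout, scoring, custom, matrices
    ):
        store = make_store()
        piece = add_piece(store, "P1", "T1", 2005, failed_due_to_toxicity=True)
        assert piece_contribution(
            piece, store, hierarchy, matrices, custom, layout, scoring
        ) == 0.0


class TestSeries:
    def test_empty_match_gives_zero_series(
        self, hierarchy, layout, scoring, custom, matrices
    ):
        store = make_store()
        series = compute_escore_series(
            Query(), store, hierarchy, matrices, custom, layout, scoring, 2010
        )
        assert set(series.scores.values()) == {0.0}

    def test_single_piece_is_step_function(
        self, hierarchy, layout, scoring, custom
    ):
        store = make_store()
        add_piece(
            store, "P1", "T1", 2005, state=DiseaseState.advanced,
            goal=TherapeuticGoal.become_disease_free,
        )
        matrices = curative_matrices(layout)
        series = compute_escore_series(
            Query(), store, hierarchy, matrices, custom, layout, scoring, 2007
        )
        assert series.scores == {2004: 0.0, 2005: 2.0, 2006: 2.0, 2007: 2.0}
        assert series.n_pieces[2007] == 1

    def test_end_year_before_first_piece_rejected(
        self, hierarchy, layout, scoring, custom, matrices
    ):
        store = make_store()
        add_piece(store, "P1", "T1", 2005)
        with pytest.raises(CIIError, match="end_year"):
            compute_escore_series(
                Query(), store, hierarchy, matrices, custom, layout, scoring, 2003
            )

    def test_matches_brute_force_on_synthetic_corpus(
        self, hierarchy, layout, scoring, custom, matrices
    ):
        corpus = generate_corpus(CorpusParams(n_treatments=25, seed=7))
        store = corpus.store
        assert len(store.pieces) >= 150
        series = compute_escore_series(
            Query(), store, hierarchy, matrices, custom, layout, scoring, 2016
        )
        expected = brute_force_series(
            store.pieces.values(), store, hierarchy, matrices, custom, layout,
            scoring, 2016,
        )
        assert series.scores.keys() == expected.keys()
        for year in expected:
            assert series.scores[year] == pytest.approx(expected[year], abs=1e-9)

    def test_series_monotone_non_decreasing(
        self, hierarchy, layout, scoring, custom, matrices
    ):
        corpus = generate_corpus(CorpusParams(n_treatments=10, seed=3))
        series = compute_escore_series(
            Query(), corpus.store, hierarchy, matrices, custom, layout, scoring, 2016
        )
        values = list(series.scores.values())
        assert all(b >= a for a, b in zip(values, values[1:]))

    def test_linear_in_value_matrix_scaling(
        self, hierarchy, layout, scoring, custom
    ):
        corpus = generate_corpus(CorpusParams(n_treatments=8, seed=11))
        base = [uniform_matrix(datetime.date(1990, 1, 1), value=1.0)]
        scaled = [uniform_matrix(datetime.date(1990, 1, 1), value=3.5)]
        s1 = compute_escore_series(
            Query(), corpus.store, hierarchy, base, custom, layout, scoring, 2016
        )
        s2 = compute_escore_series(
            Query(), corpus.store, hierarchy, scaled, custom, layout, scoring, 2016
        )
        for year in s1.scores:
            assert s2.scores[year] == pytest.approx(3.5 * s1.scores[year], abs=1e-9)

    def test_effect_size_rule_scales_hazard_ratio_benefit(
        self, hierarchy, layout, scoring, matrices
    ):
        store = make_store()
        add_piece(
            store, "P1", "T1", 2005,
            effect_size=0.6, effect_type="hazard_ratio",
        )
        custom = CustomWeights(effect_size_rule="linear_in_benefit", effect_slope=1.0)
        series = compute_escore_series(
            Query(), store, hierarchy, matrices, custom, layout, scoring, 2005
        )
        assert series.final() == pytest.approx(1.0 * (1 + 0.4))


class TestCountThreshold:
    def test_pending_pool_releases_when_threshold_reached(
        self, hierarchy, layout, custom, matrices
    ):
        cfg = ScoringConfig(count_threshold=2.0)
        store = make_store()
        for year, pid in [(2001, "P1"), (2004, "P2"), (2006, "P3")]:
            add_piece(store, pid, "T1", year)
        series = compute_escore_series(
            Query(), store, hierarchy, matrices, custom, layout, cfg, 2008
        )
        # pool (weight 1) pending in 2001; crosses 2.0 in 2004 -> both count
        assert series.scores[2001] == 0.0
        assert series.scores[2004] == 2.0
        assert series.scores[2006] == 3.0
        assert series.n_pieces[2004] == 2

    def test_threshold_zero_counts_immediately(
        self, hierarchy, layout, scoring, custom, matrices
    ):
        store = make_store()
        add_piece(store, "P1", "T1", 2001)
        series = compute_escore_series(
            Query(), store, hierarchy, matrices, custom, layout, scoring, 2002
        )
        assert series.scores[2001] == 1.0


class TestStratified:
    def _two_site_store(self):
        store = make_store(("T1", "T2"))
        add_piece(store, "P1", "T1", 2001, subgroup_tags={"lung"})
        add_piece(store, "P2", "T1", 2004, subgroup_tags={"lung"})
        add_piece(store, "P3", "T2", 2003, subgroup_tags={"breast"})
        return store

    def test_strata_sum_pointwise_to_total(
        self, hierarchy, layout, scoring, custom, matrices
    ):
        store = self._two_site_store()
        total = compute_escore_series(
            Query(), store, hierarchy, matrices, custom, layout, scoring, 2006
        )
        strata = stratified_scores(
            ["lung", "breast"], Query(), store, hierarchy, matrices, custom,
            layout, scoring, 2006,
        )
        for year in total.scores:
            assert sum(s.scores[year] for s in strata.values()) == pytest.approx(
                total.scores[year], abs=1e-9
            )

    def test_empty_stratum_is_zero_series(
        self, hierarchy, layout, scoring, custom, matrices
    ):
        store = make_store()
        add_piece(store, "P1", "T1", 2001, subgroup_tags={"lung"})
        strata = stratified_scores(
            ["lung", "melanoma"], Query(), store, hierarchy, matrices, custom,
            layout, scoring, 2003,
        )
        assert set(strata["melanoma"].scores.values()) == {0.0}

    def test_single_covering_stratum_equals_unstratified(
        self, hierarchy, layout, scoring, custom, matrices
    ):
        store = make_store()
        add_piece(store, "P1", "T1", 2001, subgroup_tags={"lung"})
        add_piece(store, "P2", "T1", 2003, subgroup_tags={"lung"})
        total = compute_escore_series(
            Query(), store, hierarchy, matrices, custom, layout, scoring, 2004
        )
        strata = stratified_scores(
            ["lung"], Query(), store, hierarchy, matrices, custom, layout,
            scoring, 2004,
        )
        assert strata["lung"].scores == total.scores

    def test_overlapping_strata_rejected_listing_pieces(
        self, hierarchy, layout, scoring, custom, matrices
    ):
        store = make_store()
        add_piece(store, "P1", "T1", 2001, subgroup_tags={"lung", "elderly"})
        with pytest.raises(CIIError, match="P1"):
            stratified_scores(
                ["lung", "elderly"], Query(), store, hierarchy, matrices, custom,
                layout, scoring, 2002,
            )


class TestFingerprint:
    def test_changes_iff_any_weight_input_changes(
        self, hierarchy, layout, scoring, custom, matrices
    ):
        fp = config_fingerprint(hierarchy, matrices, custom, layout, scoring)
        assert fp == config_fingerprint(hierarchy, matrices, custom, layout, scoring)
        bumped = CustomWeights(modality_multiplier={Modality.surgery: 1.5})
        assert fp != config_fingerprint(hierarchy, matrices, bumped, layout, scoring)
        other_matrix = [uniform_matrix(datetime.date(1990, 1, 1), value=2.0)]
        assert fp != config_fingerprint(hierarchy, other_matrix, custom, layout, scoring)
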