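"""Elo-rating and David's-score inference."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dominet import (
    EloConfig,
    WinLossMatrix,
    build_win_loss_matrix,
    compare_rankings,
    davids_scores,
    elo_update,
    expected_win_prob,
    randomized_elo,
    run_elo_sequence,
)

from conftest import make_record


def classic_elo_expectation(diff: float) -> float:
    """Independent oracle: the base-10 logistic used in classical Elo."""
    return 1.0 / (1.0 + 10.0 ** (-diff / 400.0))


class TestExpectedWinProb:
    def test_even_match_is_a_coin_flip(self):
        assert expected_win_prob(0.0) == 0.5

    @given(d=st.floats(min_value=-2000, max_value=2000))
    @settings(max_examples=50, deadline=None)
    def test_complement_identity(self, d):
        assert expected_win_prob(d) + expected_win_prob(-d) == pytest.approx(1.0)

    def test_monotone_and_bounded(self):
        diffs = np.linspace(-3000, 3000, 101)
        p = expected_win_prob(diffs)
        assert np.all(np.diff(p) > 0)
        assert p[0] > 0 and p[-1] < 1
        assert expected_win_prob(1e7) == pytest.approx(1.0)

    def test_matches_classic_elo_curve(self):
        # default scale reproduces the base-10 convention: 200 points ~ 0.76
        for d in (-300, -50, 0, 100, 200, 400):
            assert expected_win_prob(d) == pytest.approx(classic_elo_expectation(d))
        assert expected_win_prob(200.0) == pytest.approx(0.76, abs=0.01)


class TestEloUpdate:
    def test_even_match_transfers_half_of_k(self):
        assert elo_update(1000.0, 1000.0) == (1050.0, 950.0)

    def test_expected_win_transfers_less_than_half_of_k(self):
        w, l = elo_update(1200.0, 1000.0)
        assert w - 1200.0 < 50.0
        assert w - 1200.0 > 0.0

    @given(
        ws=st.floats(min_value=0, max_value=3000),
        ls=st.floats(min_value=0, max_value=3000),
        k=st.floats(min_value=1, max_value=400),
    )
    @settings(max_examples=50, deadline=None)
    def test_zero_sum(self, ws, ls, k):
        w, l = elo_update(ws, ls, EloConfig(k=k))
        assert w + l == pytest.approx(ws + ls)

    def test_fixed_rule_transfers_exactly_k(self):
        w, l = elo_update(1400.0, 1000.0, EloConfig(update_rule="fixed"))
        assert (w, l) == (1500.0, 900.0)


def seq(*pairs):
    """Decided agonistic records: each pair is (winner, loser)."""
    return [
        make_record(order_index=k, initiator_id=w, recipient_id=l)
        for k, (w, l) in enumerate(pairs)
    ]


class TestRunEloSequence:
    def test_single_event(self):
        traj = run_elo_sequence(seq(("A", "B")), ["A", "B", "C"])
        assert traj.final_scores.to_dict() == {"A": 1050.0, "B": 950.0, "C": 1000.0}

    def test_empty_sequence_keeps_initial_scores(self):
        traj = run_elo_sequence([], ["A", "B"], EloConfig(init_score=1234.0))
        assert (traj.final_scores == 1234.0).all()

    def test_two_step_hand_calculation(self):
        # A beats B, then B beats A; second transfer computed with the
        # classic base-10 curve as an independent oracle.
        traj = run_elo_sequence(seq(("A", "B"), ("B", "A")), ["A", "B"])
        t2 = 100.0 * (1.0 - classic_elo_expectation(950.0 - 1050.0))
        assert traj.final_scores["A"] == pytest.approx(1050.0 - t2)
        assert traj.final_scores["B"] == pytest.approx(950.0 + t2)
        # the upset transfers more than the first, even exchange
        assert t2 > 50.0
        assert traj.final_scores["A"] < 1000.0

    def test_sum_conserved_after_every_event(self):
        events = seq(("A", "B"), ("B", "C"), ("C", "A"), ("A", "B"), ("A", "C"))
        traj = run_elo_sequence(events, ["A", "B", "C"])
        sums = traj.scores_after_each_event.sum(axis=1)
        assert np.allclose(sums, 3 * 1000.0)

    def test_nonparticipants_keep_their_scores(self):
        traj = run_elo_sequence(seq(("A", "B")), ["A", "B", "C", "D"])
        assert np.all(traj.scores_after_each_event[0, 2:] == 1000.0)

    def test_translation_invariance(self):
        events = seq(("A", "B"), ("B", "C"), ("A", "C"))
        lo = run_elo_sequence(events, ["A", "B", "C"], EloConfig(init_score=1000.0))
        hi = run_elo_sequence(events, ["A", "B", "C"], EloConfig(init_score=1500.0))
        assert np.allclose(hi.final_scores.values, lo.final_scores.values + 500.0)


class TestRandomizedElo:
    def test_unbeaten_individual_ranks_first(self):
        events = seq(("A", "B"), ("A", "C"), ("A", "B"), ("B", "C"))
        result = randomized_elo(events, ["A", "B", "C"], EloConfig(n_randomizations=50))
        assert result.ranking[0] == "A"

    def test_symmetric_dyad_has_equal_mean_scores(self):
        # A and B swap roles the same number of times: any asymmetry in the
        # mean final scores is pure Monte-Carlo noise.
        events = seq(*([("A", "B"), ("B", "A")] * 10))
        result = randomized_elo(events, ["A", "B"], EloConfig(rng_seed=7))
        finals = result.per_randomization_finals
        mc_sd = finals[:, 0].std(ddof=1) / math.sqrt(finals.shape[0])
        diff = abs(result.mean_scores["A"] - result.mean_scores["B"])
        assert diff < 4 * 2 * mc_sd + 1e-9

    def test_deterministic_given_seed(self):
        events = seq(("A", "B"), ("B", "C"), ("C", "A"), ("A", "C"))
        cfg = EloConfig(rng_seed=42, n_randomizations=100)
        r1 = randomized_elo(events, ["A", "B", "C"], cfg)
        r2 = randomized_elo(events, ["A", "B", "C"], cfg)
        assert np.array_equal(r1.per_randomization_finals, r2.per_randomization_finals)
        assert r1.ranking == r2.ranking

    def test_each_randomization_is_a_valid_sequential_trajectory(self):
        # with a single event every ordering is the same: all finals equal
        # the one-step update
        result = randomized_elo(seq(("A", "B")), ["A", "B"],
                                EloConfig(n_randomizations=20))
        assert np.allclose(result.per_randomization_finals[:, 0], 1050.0)
        assert np.allclose(result.per_randomization_finals[:, 1], 950.0)

    def test_zero_sum_holds_in_every_randomization(self):
        events = seq(("A", "B"), ("B", "C"), ("C", "A"), ("B", "A"))
        result = randomized_elo(events, ["A", "B", "C"],
                                EloConfig(n_randomizations=200, rng_seed=1))
        assert np.allclose(result.per_randomization_finals.sum(axis=1), 3000.0)

    def test_no_decided_records_is_an_error(self):
        with pytest.raises(ValueError, match="skip"):
            randomized_elo([make_record(outcome="draw")], ["A", "B"])

    def test_mean_scores_are_column_means(self):
        events = seq(("A", "B"), ("B", "C"))
        result = randomized_elo(events, ["A", "B", "C"],
                                EloConfig(n_randomizations=64, rng_seed=3))
        assert np.allclose(
            result.mean_scores.values, result.per_randomization_finals.mean(axis=0)
        )


class TestDavidsScores:
    def test_two_individual_worked_example(self):
        # A beats B three times, no reversals: P=1, n=3 so D = 1 - 0.5/4
        wl = WinLossMatrix(["A", "B"], np.array([[0, 3], [0, 0]]))
        ds = davids_scores(wl)
        assert ds.D[0, 1] == pytest.approx(0.875)
        assert ds.DS["A"] == pytest.approx(0.75)
        assert ds.DS["B"] == pytest.approx(-0.75)
        assert ds.normDS["A"] == pytest.approx(0.875)
        assert ds.ranking == ["A", "B"]

    def test_all_zero_matrix_is_flat(self):
        ds = davids_scores(WinLossMatrix(["A", "B", "C"], np.zeros((3, 3), dtype=int)))
        assert np.allclose(ds.DS.values, 0.0)
        assert np.allclose(ds.normDS.values, 1.0)  # (N-1)/2 for N=3

    @given(
        cells=st.lists(st.integers(min_value=0, max_value=9),
                       min_size=12, max_size=12)
    )
    @settings(max_examples=50, deadline=None)
    def test_scores_sum_to_zero_and_p_is_complementary(self, cells):
        counts = np.zeros((4, 4), dtype=int)
        counts[~np.eye(4, dtype=bool)] = cells
        ds = davids_scores(WinLossMatrix(list("ABCD"), counts))
        assert ds.DS.sum() == pytest.approx(0.0, abs=1e-9)
        n = counts + counts.T
        interacting = n > 0
        np.fill_diagonal(interacting, False)
        assert np.allclose((ds.P + ds.P.T)[interacting], 1.0)
        assert np.all((ds.P >= 0) & (ds.P <= 1))

    def test_order_independence_under_record_permutation(self):
        rng = np.random.default_rng(0)
        pairs = [("A", "B")] * 3 + [("B", "C")] * 2 + [("C", "A"), ("B", "A")]
        forward = build_win_loss_matrix(seq(*pairs), ["A", "B", "C"])
        shuffled_pairs = [pairs[i] for i in rng.permutation(len(pairs))]
        shuffled = build_win_loss_matrix(seq(*shuffled_pairs), ["A", "B", "C"])
        d1, d2 = davids_scores(forward), davids_scores(shuffled)
        assert np.allclose(d1.DS.values, d2.DS.values)
        assert d1.ranking == d2.ranking

    def test_single_individual_rejected(self):
        with pytest.raises(ValueError, match="two individuals"):
            davids_scores(WinLossMatrix(["A"], np.zeros((1, 1), dtype=int)))


class TestCompareRankings:
    def _elo_and_ds(self, pairs, individuals):
        events = seq(*pairs)
        elo = randomized_elo(events, individuals,
                             EloConfig(n_randomizations=100, rng_seed=0))
        ds = davids_scores(build_win_loss_matrix(events, individuals))
        return elo, ds

    def test_concordant_hierarchy_gives_high_positive_correlations(self):
        pairs = [("A", "B")] * 4 + [("A", "C")] * 4 + [("B", "C")] * 4
        elo, ds = self._elo_and_ds(pairs, ["A", "B", "C"])
        cmp_ = compare_rankings(elo, ds)
        assert cmp_.spearman_rho == pytest.approx(1.0)
        assert cmp_.pearson_r > 0.9
        assert cmp_.pearson_p < 0.5  # defined, two-sided

    def test_two_individuals_reported_without_p(self):
        elo, ds = self._elo_and_ds([("A", "B")] * 3, ["A", "B"])
        cmp_ = compare_rankings(elo, ds)
        assert cmp_.n == 2
        assert math.isnan(cmp_.pearson_p)
        assert cmp_.pearson_r == pytest.approx(1.0)

    def test_mismatched_individual_sets_rejected(self):
        elo, _ = self._elo_and_ds([("A", "B")] * 3, ["A", "B"])
        _, ds = self._elo_and_ds([("A", "C")] * 3, ["A", "C"])
        with pytest.raises(ValueError, match="different individuals"):
            compare_rankings(elo, ds)
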