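"""Dominance hierarchy inference: randomized Elo-rating and David's scores.

Elo-rating treats each decided agonistic interaction as a contest: points flow
from the loser to the winner, scaled by how surprising the outcome was given
the current score gap. Because final scores depend on interaction order, and
observed orders within a session are partly arbitrary, the standard remedy is
to recompute the scores over many random permutations of the event order and
average the final scores ("randomized Elo").

David's score is the order-independent alternative: each dyad's win proportion
is corrected for chance and combined with the opponents' own win/loss profiles
(DS = w + w2 - l - l2). Both are computed per observation day and their
rankings compared.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .interactions import InteractionRecord, WinLossMatrix

__all__ = [
    "DEFAULT_SIGMOID_SCALE",
    "DavidsScores",
    "EloConfig",
    "EloResult",
    "EloTrajectory",
    "RankComparison",
    "compare_rankings",
    "davids_scores",
    "elo_update",
    "expected_win_prob",
    "randomized_elo",
    "run_elo_sequence",
]

# Classic Elo curve: a 200-point advantage wins with probability ~0.76
# (logistic in base 10 with scale 400, i.e. natural scale 400/ln 10).
DEFAULT_SIGMOID_SCALE = 400.0 / math.log(10.0)


@dataclass(frozen=True)
class EloConfig:
    """Parameters of the Elo procedure.

    ``k`` is the maximum points transferred per contest; the realised transfer
    is ``k * (1 - p_expected(winner))`` under the default expectation-weighted
    rule, or a flat ``k`` when ``update_rule="fixed"``. Draws are excluded by
    default (``draw_rule="exclude"``); ``"half"`` credits each participant a
    half outcome instead.
    """

    init_score: float = 1000.0
    k: float = 100.0
    n_randomizations: int = 1000
    sigmoid_scale: float = DEFAULT_SIGMOID_SCALE
    rng_seed: int = 0
    update_rule: str = "expected"
    draw_rule: str = "exclude"

    def __post_init__(self) -> None:
        if self.k <= 0:
            raise ValueError("k must be positive")
        if self.n_randomizations < 1:
            raise ValueError("n_randomizations must be >= 1")
        if self.sigmoid_scale <= 0:
            raise ValueError("sigmoid_scale must be positive")
        if self.update_rule not in ("expected", "fixed"):
            raise ValueError("update_rule must be 'expected' or 'fixed'")
        if self.draw_rule not in ("exclude", "half"):
            raise ValueError("draw_rule must be 'exclude' or 'half'")


@dataclass
class EloTrajectory:
    """Score trajectory under one fixed event ordering."""

    individuals: list[str]
    ordering: list[InteractionRecord]
    scores_after_each_event: np.ndarray  # (n_events, n_individuals)
    final_scores: pd.Series


@dataclass
class EloResult:
    """Randomization-averaged Elo scores for one observation day."""

    individuals: list[str]
    mean_scores: pd.Series
    per_randomization_finals: np.ndarray  # (n_randomizations, n_individuals)
    ranking: list[str]
    ties: list[tuple[str, ...]] = field(default_factory=list)


def expected_win_prob(score_diff: float, sigmoid_scale: float = DEFAULT_SIGMOID_SCALE):
    """Probability that the higher-scoring side of a ``score_diff`` gap wins.

    Logistic in the score difference: p(0) = 0.5, p(d) + p(-d) = 1.
    Accepts arrays.
    """
    return 1.0 / (1.0 + np.exp(-np.asarray(score_diff, dtype=float) / sigmoid_scale))


def elo_update(
    winner_score: float, loser_score: float, config: EloConfig = EloConfig()
) -> tuple[float, float]:
    """Post-contest scores. Zero-sum: the winner gains what the loser loses."""
    if config.update_rule == "fixed":
        transfer = config.k
    else:
        p = float(expected_win_prob(winner_score - loser_score, config.sigmoid_scale))
        transfer = config.k * (1.0 - p)
    return winner_score + transfer, loser_score - transfer


def _contest_indices(
    records: Iterable[InteractionRecord],
    index: dict[str, int],
    config: EloConfig,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Winner/loser index arrays plus a draw flag per usable event."""
    winners, losers, draws = [], [], []
    for rec in records:
        if rec.category != "agonistic":
            raise ValueError("Elo is defined on agonistic records only")
        if rec.outcome == "draw":
            if config.draw_rule == "exclude":
                continue
            a, b = rec.initiator_id, rec.recipient_id
            draws.append(True)
        else:
            a, b = rec.winner_id, rec.loser_id
            draws.append(False)
        for ind in (a, b):
            if ind not in index:
                raise ValueError(f"individual {ind!r} not in the individual list")
        winners.append(index[a])
        losers.append(index[b])
    return (
        np.asarray(winners, dtype=int),
        np.asarray(losers, dtype=int),
        np.asarray(draws, dtype=bool),
    )


def _step(scores, w, l, draw, config):
    """One vectorised update; ``scores`` has one row per parallel replicate."""
    rows = np.arange(scores.shape[0])
    sw = scores[rows, w]
    sl = scores[rows, l]
    target = np.where(draw, 0.5, 1.0)
    if config.update_rule == "fixed":
        transfer = config.k * (target - 0.5) * 2.0  # full k decided, 0 on draws
    else:
        p = expected_win_prob(sw - sl, config.sigmoid_scale)
        transfer = config.k * (target - p)
    scores[rows, w] += transfer
    scores[rows, l] -= transfer


def run_elo_sequence(
    records: Sequence[InteractionRecord],
    individuals: Sequence[str],
    config: EloConfig = EloConfig(),
) -> EloTrajectory:
    """Apply Elo updates sequentially in the given record order.

    Non-participants keep their scores; the score sum is conserved after every
    event.
    """
    individuals = list(individuals)
    index = {ind: i for i, ind in enumerate(individuals)}
    w, l, d = _contest_indices(records, index, config)
    scores = np.full((1, len(individuals)), config.init_score, dtype=float)
    history = np.empty((len(w), len(individuals)), dtype=float)
    for t in range(len(w)):
        _step(scores, w[t : t + 1], l[t : t + 1], d[t : t + 1], config)
        history[t] = scores[0]
    finals = pd.Series(scores[0], index=individuals, name="elo_score")
    return EloTrajectory(
        individuals=individuals,
        ordering=list(records),
        scores_after_each_event=history,
        final_scores=finals,
    )


def _rank_with_ties(
    scores: pd.Series, wins: pd.Series
) -> tuple[list[str], list[tuple[str, ...]]]:
    """Descending-score ranking; ties broken by total wins then identifier."""
    order = sorted(
        scores.index, key=lambda ind: (-scores[ind], -wins.get(ind, 0), ind)
    )
    ties: list[tuple[str, ...]] = []
    group: list[str] = []
    for ind in order:
        if group and np.isclose(scores[group[0]], scores[ind]):
            group.append(ind)
        else:
            if len(group) > 1:
                ties.append(tuple(group))
            group = [ind]
    if len(group) > 1:
        ties.append(tuple(group))
    return order, ties


def randomized_elo(
    records: Sequence[InteractionRecord],
    individuals: Sequence[str],
    config: EloConfig = EloConfig(),
) -> EloResult:
    """Average final Elo scores over random permutations of the event order.

    Runs ``config.n_randomizations`` independent uniform shuffles of the
    usable events (decided ones, plus draws under ``draw_rule="half"``),
    seeded by ``config.rng_seed``; deterministic for a fixed seed.
    """
    individuals = list(individuals)
    index = {ind: i for i, ind in enumerate(individuals)}
    w, l, d = _contest_indices(records, index, config)
    n_events = len(w)
    if n_events == 0:
        raise ValueError(
            "no usable agonistic contests on this day; skip it rather than "
            "inferring a hierarchy"
        )
    n_rand = config.n_randomizations
    rng = np.random.default_rng(np.random.SeedSequence(config.rng_seed))
    perms = np.argsort(rng.random((n_rand, n_events)), axis=1)
    scores = np.full((n_rand, len(individuals)), config.init_score, dtype=float)
    for t in range(n_events):
        ev = perms[:, t]
        _step(scores, w[ev], l[ev], d[ev], config)
    mean_scores = pd.Series(scores.mean(axis=0), index=individuals, name="mean_elo")
    wins = pd.Series(0, index=individuals, dtype=int)
    decided = ~d
    np.add.at(wins.values, w[decided], 1)
    ranking, ties = _rank_with_ties(mean_scores, wins)
    return EloResult(
        individuals=individuals,
        mean_scores=mean_scores,
        per_randomization_finals=scores,
        ranking=ranking,
        ties=ties,
    )


# ---------------------------------------------------------------------------
# David's scores


@dataclass
class DavidsScores:
    """David's score decomposition for one win-loss matrix.

    ``P`` holds dyadic win proportions, ``D`` the chance-corrected dyadic
    indices; non-interacting dyads contribute zero throughout. ``DS`` sums to
    zero across individuals; ``normDS`` rescales it into [0, N-1].
    """

    individuals: list[str]
    P: np.ndarray
    D: np.ndarray
    w: pd.Series
    w2: pd.Series
    l: pd.Series
    l2: pd.Series
    DS: pd.Series
    normDS: pd.Series
    ranking: list[str]


def davids_scores(win_loss: WinLossMatrix) -> DavidsScores:
    """Compute David's scores from a win-loss matrix.

    For each interacting dyad, P_ij = wins_ij / n_ij and the chance-corrected
    index D_ij = P_ij - (P_ij - 0.5) / (n_ij + 1); then
    w_i = sum_j D_ij, w2_i = sum_j D_ij w_j, l_i = sum_j D_ji,
    l2_i = sum_j D_ji l_j, DS_i = w_i + w2_i - l_i - l2_i and
    normDS_i = (DS_i + N(N-1)/2) / N.
    """
    individuals = win_loss.individuals
    n_ind = len(individuals)
    if n_ind < 2:
        raise ValueError("David's scores need at least two individuals")
    wins = win_loss.counts.astype(float)
    n = wins + wins.T
    with np.errstate(invalid="ignore", divide="ignore"):
        P = np.where(n > 0, wins / np.where(n > 0, n, 1.0), 0.0)
        D = np.where(n > 0, P - (P - 0.5) / (n + 1.0), 0.0)
    np.fill_diagonal(P, 0.0)
    np.fill_diagonal(D, 0.0)
    w = D.sum(axis=1)
    l = D.sum(axis=0)
    w2 = D @ w
    l2 = D.T @ l
    DS = w + w2 - l - l2
    normDS = (DS + n_ind * (n_ind - 1) / 2.0) / n_ind
    as_series = lambda v, name: pd.Series(v, index=individuals, name=name)
    DS_s = as_series(DS, "DS")
    total_wins = as_series(wins.sum(axis=1), "wins")
    ranking, _ = _rank_with_ties(DS_s, total_wins)
    return DavidsScores(
        individuals=list(individuals),
        P=P,
        D=D,
        w=as_series(w, "w"),
        w2=as_series(w2, "w2"),
        l=as_series(l, "l"),
        l2=as_series(l2, "l2"),
        DS=DS_s,
        normDS=as_series(normDS, "normDS"),
        ranking=ranking,
    )


# ---------------------------------------------------------------------------
# comparing the two hierarchies


@dataclass
class RankComparison:
    """Agreement between Elo and David's-score hierarchies."""

    n: int
    pearson_r: float
    pearson_p: float
    spearman_rho: float
    spearman_p: float


def compare_rankings(elo: EloResult, ds: DavidsScores) -> RankComparison:
    """Pearson correlation of the two score vectors plus Spearman rank agreement.

    With fewer than 3 paired individuals the correlations are reported without
    p-values (NaN).
    """
    if set(elo.individuals) != set(ds.individuals):
        raise ValueError("Elo and David's scores cover different individuals")
    x = elo.mean_scores.loc[elo.individuals].to_numpy()
    y = ds.DS.loc[elo.individuals].to_numpy()
    n = len(x)
    if n < 3:
        r = float(np.corrcoef(x, y)[0, 1])
        rho = float(stats.spearmanr(x, y).statistic)
        return RankComparison(n=n, pearson_r=r, pearson_p=float("nan"),
                              spearman_rho=rho, spearman_p=float("nan"))
    pr = stats.pearsonr(x, y)
    sr = stats.spearmanr(x, y)
    return RankComparison(
        n=n,
        pearson_r=float(pr.statistic),
        pearson_p=float(pr.pvalue),
        spearman_rho=float(sr.statistic),
        spearman_p=float(sr.pvalue),
    )


def pooled_rank_comparison(
    per_day: Sequence[tuple[EloResult, DavidsScores]]
) -> RankComparison:
    """Elo vs David's-score agreement pooling individual-day pairs across days."""
    xs: list[float] = []
    ys: list[float] = []
    for elo, ds in per_day:
        xs.extend(elo.mean_scores.loc[elo.individuals].tolist())
        ys.extend(ds.DS.loc[elo.individuals].tolist())
    x = np.asarray(xs)
    y = np.asarray(ys)
    if len(x) < 3:
        raise ValueError("pooled comparison needs at least 3 paired values")
    pr = stats.pearsonr(x, y)
    sr = stats.spearmanr(x, y)
    return RankComparison(
        n=len(x),
        pearson_r=float(pr.statistic),
        pearson_p=float(pr.pvalue),
        spearman_rho=float(sr.statistic),
        spearman_p=float(sr.pvalue),
    )
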