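"""Per-session interaction networks and QAP consistency tests.

Each observation session yields two directed, weighted adjacency matrices —
one agonistic, one affiliative — whose cell (i, j) counts interactions
initiated by i toward j (draws included: a draw is still an interaction).
Counts are normalised to interactions per hour to make sessions of different
recording length comparable, and nodes are ordered by dominance rank.

Consistency of interaction patterns between sessions is tested with the
quadratic assignment procedure (QAP), a Mantel-type permutation test: the
observed graph correlation (Pearson over corresponding off-diagonal cells) is
compared to the null distribution obtained by jointly permuting the rows and
columns of one matrix, which preserves its weight structure while breaking
the node-label correspondence.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .interactions import InteractionRecord, SessionInfo

__all__ = [
    "ConsistencyReport",
    "InteractionNetwork",
    "NetworkMismatchError",
    "QAPResult",
    "build_network",
    "consistency_report",
    "graph_correlation",
    "qap_test",
]

_TIE_TOL = 1e-9  # float-noise guard when counting null values >= observed


class NetworkMismatchError(ValueError):
    """Two networks cannot be compared (different individual sets)."""


@dataclass
class InteractionNetwork:
    """Directed weighted interaction network for one session.

    ``raw_counts[i, j]`` counts interactions initiated by individual i toward
    j; ``weights`` is the same matrix in interactions per hour. Node order is
    the supplied dominance ranking restricted to the session roster.
    """

    session_id: str
    network_type: str
    individuals: list[str]
    raw_counts: np.ndarray
    duration_hours: float

    def __post_init__(self) -> None:
        self.raw_counts = np.asarray(self.raw_counts, dtype=int)
        n = len(self.individuals)
        if self.raw_counts.shape != (n, n):
            raise ValueError("raw_counts must be square, one row per individual")
        if np.any(np.diag(self.raw_counts) != 0):
            raise ValueError("self-loops are not allowed")
        if self.duration_hours <= 0:
            raise ValueError("duration_hours must be positive")

    @property
    def weights(self) -> np.ndarray:
        return self.raw_counts / self.duration_hours

    def reordered(self, individuals: Sequence[str]) -> "InteractionNetwork":
        """The same network with rows/columns in the requested identifier order."""
        if set(individuals) != set(self.individuals):
            raise NetworkMismatchError(
                f"cannot reorder onto a different individual set: "
                f"{sorted(individuals)} vs {sorted(self.individuals)}"
            )
        idx = [self.individuals.index(ind) for ind in individuals]
        return InteractionNetwork(
            session_id=self.session_id,
            network_type=self.network_type,
            individuals=list(individuals),
            raw_counts=self.raw_counts[np.ix_(idx, idx)],
            duration_hours=self.duration_hours,
        )

    def to_frame(self, rates: bool = True) -> pd.DataFrame:
        data = self.weights if rates else self.raw_counts
        return pd.DataFrame(data, index=self.individuals, columns=self.individuals)

    def to_edge_list(self) -> pd.DataFrame:
        rows = []
        for i, a in enumerate(self.individuals):
            for j, b in enumerate(self.individuals):
                if i != j and self.raw_counts[i, j] > 0:
                    rows.append(
                        {
                            "from": a,
                            "to": b,
                            "count": int(self.raw_counts[i, j]),
                            "weight": float(self.weights[i, j]),
                        }
                    )
        return pd.DataFrame(rows, columns=["from", "to", "count", "weight"])

    def to_graphml(self, path: str | Path) -> None:
        g = nx.DiGraph(session_id=self.session_id, network_type=self.network_type)
        for rank, ind in enumerate(self.individuals, start=1):
            g.add_node(ind, rank=rank)
        for row in self.to_edge_list().itertuples(index=False):
            g.add_edge(row[0], row[1], count=row.count, weight=row.weight)
        nx.write_graphml(g, path)


def build_network(
    records: Sequence[InteractionRecord],
    session: SessionInfo,
    network_type: str,
    ranking: Sequence[str],
) -> InteractionNetwork:
    """Build one session's directed weighted network of a given category.

    Records are filtered to the session and category (draws included for
    agonistic networks); the node order follows ``ranking`` restricted to the
    individuals present in the session. A record involving an individual
    outside the session roster is an error.
    """
    if network_type not in ("agonistic", "affiliative"):
        raise ValueError("network_type must be 'agonistic' or 'affiliative'")
    roster = session.individuals_present
    missing = roster - set(ranking)
    if missing:
        raise ValueError(f"ranking does not cover present individuals: {sorted(missing)}")
    individuals = [ind for ind in ranking if ind in roster]
    index = {ind: i for i, ind in enumerate(individuals)}
    counts = np.zeros((len(individuals), len(individuals)), dtype=int)
    for rec in records:
        if rec.session_id != session.session_id or rec.category != network_type:
            continue
        for ind in (rec.initiator_id, rec.recipient_id):
            if ind not in roster:
                raise ValueError(
                    f"individual {ind!r} interacted in session "
                    f"{session.session_id!r} but is absent from its roster"
                )
        counts[index[rec.initiator_id], index[rec.recipient_id]] += 1
    return InteractionNetwork(
        session_id=session.session_id,
        network_type=network_type,
        individuals=individuals,
        raw_counts=counts,
        duration_hours=session.duration_hours,
    )


# ---------------------------------------------------------------------------
# graph correlation and QAP


def _offdiag(matrix: np.ndarray) -> np.ndarray:
    n = matrix.shape[0]
    return matrix[~np.eye(n, dtype=bool)]


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    xc = x - x.mean()
    yc = y - y.mean()
    denom = np.sqrt((xc @ xc) * (yc @ yc))
    if denom == 0:
        return float("nan")
    return float((xc @ yc) / denom)


def graph_correlation(net_a: InteractionNetwork, net_b: InteractionNetwork) -> float:
    """Pearson correlation over corresponding off-diagonal weight cells.

    Networks are aligned by individual identifier first; a zero-variance
    matrix yields NaN (undefined correlation).
    """
    net_b = net_b.reordered(net_a.individuals)
    return _pearson(_offdiag(net_a.weights), _offdiag(net_b.weights))


@dataclass
class QAPResult:
    """Outcome of a QAP test between two networks on the same individuals."""

    r_observed: float
    null_distribution: np.ndarray
    p_greater: float
    p_lesser: float
    n_permutations: int
    exact: bool
    n_individuals: int


def _null_correlations(a: np.ndarray, b: np.ndarray, perms: np.ndarray) -> np.ndarray:
    """Graph correlations between ``a`` and each row-permutation relabeling of ``b``.

    ``perms`` has one permutation of node indices per row; rows and columns of
    ``b`` are relabeled jointly.
    """
    n = a.shape[0]
    off = ~np.eye(n, dtype=bool)
    x = a[off]
    xc = x - x.mean()
    xnorm = np.sqrt(xc @ xc)
    # flat indices of the permuted off-diagonal cells, one row per permutation
    flat = perms[:, :, None] * n + perms[:, None, :]
    cells = b.ravel()[flat[:, off]]
    yc = cells - cells.mean(axis=1, keepdims=True)
    ynorm = np.sqrt(np.einsum("ij,ij->i", yc, yc))
    denom = xnorm * ynorm
    with np.errstate(invalid="ignore", divide="ignore"):
        return (yc @ xc) / denom


def qap_test(
    net_a: InteractionNetwork,
    net_b: InteractionNetwork,
    n_permutations: int = 1000,
    seed: int | None = None,
    mode: str = "sampled",
) -> QAPResult:
    """QAP association test between two networks on the same individuals.

    ``sampled`` mode draws ``n_permutations`` uniform node relabelings of
    ``net_b`` and reports p_greater = (#{null >= observed} + 1) / (n + 1),
    counting the identity arrangement, so p is never exactly zero. ``exact``
    mode enumerates all N! relabelings (N <= 8) and reports exact
    proportions.
    """
    if mode not in ("sampled", "exact"):
        raise ValueError("mode must be 'sampled' or 'exact'")
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    net_b = net_b.reordered(net_a.individuals)
    a = net_a.weights
    b = net_b.weights
    n = a.shape[0]
    r_obs = _pearson(_offdiag(a), _offdiag(b))
    if mode == "exact":
        if n > 8:
            raise ValueError("exact enumeration is limited to 8 individuals")
        perms = np.array(list(itertools.permutations(range(n))), dtype=int)
        null = _null_correlations(a, b, perms)
        p_greater = float(np.mean(null >= r_obs - _TIE_TOL))
        p_lesser = float(np.mean(null <= r_obs + _TIE_TOL))
        n_perm = len(perms)
    else:
        rng = np.random.default_rng(np.random.SeedSequence(seed))
        perms = np.argsort(rng.random((n_permutations, n)), axis=1)
        null = _null_correlations(a, b, perms)
        p_greater = (np.sum(null >= r_obs - _TIE_TOL) + 1.0) / (n_permutations + 1.0)
        p_lesser = (np.sum(null <= r_obs + _TIE_TOL) + 1.0) / (n_permutations + 1.0)
        n_perm = n_permutations
    return QAPResult(
        r_observed=r_obs,
        null_distribution=null,
        p_greater=float(p_greater),
        p_lesser=float(p_lesser),
        n_permutations=n_perm,
        exact=(mode == "exact"),
        n_individuals=n,
    )


@dataclass
class ConsistencyReport:
    """Pairwise QAP results across sessions plus the skipped pairs."""

    table: pd.DataFrame
    skipped: list[tuple[str, str, str]]  # (session_a, session_b, reason)


def consistency_report(
    networks: Sequence[InteractionNetwork],
    n_permutations: int = 1000,
    seed: int | None = None,
    mode: str = "sampled",
    all_pairs: bool = False,
) -> ConsistencyReport:
    """QAP tests between same-roster session pairs of one network type.

    By default only consecutive session pairs are tested; pairs whose rosters
    differ (e.g. around an individual's removal/reintroduction) are skipped
    and listed rather than failing.
    """
    if len({net.network_type for net in networks}) > 1:
        raise ValueError("consistency_report expects networks of a single type")
    if all_pairs:
        pairs = list(itertools.combinations(range(len(networks)), 2))
    else:
        pairs = [(i, i + 1) for i in range(len(networks) - 1)]
    rows = []
    skipped: list[tuple[str, str, str]] = []
    ss = np.random.SeedSequence(seed)
    pair_seeds = ss.generate_state(max(len(pairs), 1)) >> 1  # keep below 2**31
    for k, (i, j) in enumerate(pairs):
        a, b = networks[i], networks[j]
        if set(a.individuals) != set(b.individuals):
            skipped.append((a.session_id, b.session_id, "different individuals"))
            continue
        res = qap_test(a, b, n_permutations=n_permutations,
                       seed=int(pair_seeds[k]), mode=mode)
        rows.append(
            {
                "session_a": a.session_id,
                "session_b": b.session_id,
                "network_type": a.network_type,
                "n_individuals": res.n_individuals,
                "r": res.r_observed,
                "p_greater": res.p_greater,
                "p_lesser": res.p_lesser,
                "n_permutations": res.n_permutations,
                "exact": res.exact,
            }
        )
    columns = [
        "session_a", "session_b", "network_type", "n_individuals",
        "r", "p_greater", "p_lesser", "n_permutations", "exact",
    ]
    return ConsistencyReport(table=pd.DataFrame(rows, columns=columns), skipped=skipped)
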