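"""Dyadic interaction records: reading, validation, categorisation and tallies.

The observational unit is a single dyadic behavioural event — one individual
(the initiator) directs a behaviour at another (the recipient) during a
recorded observation session. Behaviours are classified by an ethogram into
``agonistic`` (conflict: pecks, jabs, chases, displacements), ``affiliative``
(allopreening, sitting close, collaborative foraging/exploring) or
``ambiguous`` (no clear intention; retained in the data but excluded from
every downstream analysis). Agonistic events carry an outcome — the initiator
won, the recipient won, or a draw — which feeds the dominance inference;
draws still count as interactions when networks are built.

Input schema (see ``docs/data_schema.md``):

* interaction table (CSV/TSV, header): ``session_id, order_index,
  initiator_id, recipient_id, behaviour_code, outcome``
* session table (CSV/TSV, header): ``session_id, date, duration_hours,
  individuals_present`` (present individuals separated by ``;``)
* ethogram (YAML/JSON): ``code -> {category, description}`` or the shorthand
  ``code -> category``.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "CATEGORIES",
    "OUTCOMES",
    "Ethogram",
    "InteractionRecord",
    "SessionInfo",
    "ValidationError",
    "WinLossMatrix",
    "build_win_loss_matrix",
    "read_interactions",
    "tally_interactions",
    "write_interactions",
    "write_sessions",
]

CATEGORIES = ("agonistic", "affiliative", "ambiguous")
OUTCOMES = ("initiator_wins", "recipient_wins", "draw", "not_applicable")
DECIDED_OUTCOMES = ("initiator_wins", "recipient_wins")


class ValidationError(ValueError):
    """An input record violates the interaction-data contract."""


@dataclass(frozen=True)
class Ethogram:
    """Catalogue mapping behaviour codes to behavioural categories.

    Every behaviour code appearing in an accepted interaction table must map
    to exactly one of :data:`CATEGORIES`.
    """

    codes: Mapping[str, str]
    descriptions: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for code, cat in self.codes.items():
            if cat not in CATEGORIES:
                raise ValidationError(
                    f"ethogram code {code!r} has unknown category {cat!r}; "
                    f"expected one of {CATEGORIES}"
                )

    def category(self, code: str) -> str:
        try:
            return self.codes[code]
        except KeyError:
            raise ValidationError(f"unknown behaviour code {code!r}") from None

    def __contains__(self, code: str) -> bool:
        return code in self.codes

    @classmethod
    def from_dict(cls, mapping: Mapping[str, object]) -> "Ethogram":
        codes: dict[str, str] = {}
        descriptions: dict[str, str] = {}
        for code, value in mapping.items():
            if isinstance(value, Mapping):
                codes[code] = str(value["category"])
                if "description" in value:
                    descriptions[code] = str(value["description"])
            else:
                codes[code] = str(value)
        return cls(codes=codes, descriptions=descriptions)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "Ethogram":
        with open(path, "r", encoding="utf-8") as fh:
            data = yaml.safe_load(fh)
        if not isinstance(data, Mapping):
            raise ValidationError(f"ethogram file {path} must contain a mapping")
        return cls.from_dict(data)

    def to_yaml(self, path: str | Path) -> None:
        data = {
            code: {"category": cat, "description": self.descriptions.get(code, "")}
            for code, cat in sorted(self.codes.items())
        }
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(data, fh, sort_keys=True)


@dataclass(frozen=True)
class InteractionRecord:
    """One dyadic behavioural event.

    ``order_index`` gives the within-session temporal order. ``outcome`` is a
    decided result or a draw for agonistic events and ``not_applicable``
    otherwise.
    """

    session_id: str
    order_index: int
    initiator_id: str
    recipient_id: str
    behaviour_code: str
    category: str
    outcome: str

    def __post_init__(self) -> None:
        if self.initiator_id == self.recipient_id:
            raise ValidationError(
                f"session {self.session_id}, event {self.order_index}: "
                f"initiator equals recipient ({self.initiator_id!r})"
            )
        if self.category not in CATEGORIES:
            raise ValidationError(f"unknown category {self.category!r}")
        if self.outcome not in OUTCOMES:
            raise ValidationError(f"unknown outcome {self.outcome!r}")
        if self.category == "agonistic":
            if self.outcome == "not_applicable":
                raise ValidationError(
                    f"session {self.session_id}, event {self.order_index}: "
                    "agonistic record needs a decided outcome or a draw"
                )
        elif self.outcome != "not_applicable":
            raise ValidationError(
                f"session {self.session_id}, event {self.order_index}: "
                f"{self.category} record cannot carry outcome {self.outcome!r}"
            )

    @property
    def decided(self) -> bool:
        return self.outcome in DECIDED_OUTCOMES

    @property
    def winner_id(self) -> str | None:
        if self.outcome == "initiator_wins":
            return self.initiator_id
        if self.outcome == "recipient_wins":
            return self.recipient_id
        return None

    @property
    def loser_id(self) -> str | None:
        if self.outcome == "initiator_wins":
            return self.recipient_id
        if self.outcome == "recipient_wins":
            return self.initiator_id
        return None


@dataclass(frozen=True)
class SessionInfo:
    """One observation session: date, recording duration and roster."""

    session_id: str
    date: _dt.date
    duration_hours: float
    individuals_present: frozenset[str]

    def __post_init__(self) -> None:
        if self.duration_hours <= 0:
            raise ValidationError(
                f"session {self.session_id}: duration_hours must be positive"
            )
        if not self.individuals_present:
            raise ValidationError(f"session {self.session_id}: empty roster")


@dataclass
class WinLossMatrix:
    """Square win count matrix: cell (i, j) = wins of i over j, draws excluded."""

    individuals: list[str]
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=int)
        n = len(self.individuals)
        if self.counts.shape != (n, n):
            raise ValueError("counts must be square with one row per individual")
        if np.any(np.diag(self.counts) != 0):
            raise ValueError("diagonal of a win-loss matrix must be zero")
        if np.any(self.counts < 0):
            raise ValueError("win counts must be non-negative")

    @property
    def total_decided(self) -> int:
        return int(self.counts.sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.individuals, columns=self.individuals)


# ---------------------------------------------------------------------------
# reading / writing

_INTERACTION_COLUMNS = [
    "session_id",
    "order_index",
    "initiator_id",
    "recipient_id",
    "behaviour_code",
    "outcome",
]
_SESSION_COLUMNS = ["session_id", "date", "duration_hours", "individuals_present"]


def _read_table(path: str | Path) -> pd.DataFrame:
    sep = "\t" if str(path).endswith((".tsv", ".tab")) else ","
    return pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)


def read_interactions(
    interaction_table: str | Path,
    session_table: str | Path,
    ethogram: Ethogram | str | Path,
) -> tuple[list[InteractionRecord], list[SessionInfo]]:
    """Read and validate interaction and session tables.

    Returns records ordered by (session, order_index) with their ethogram
    category attached, and the session metadata. Ambiguous-category records
    are retained (callers exclude them from analyses). Raises
    :class:`ValidationError` on unknown behaviour codes, self-interactions,
    sessions missing from the session table, or individuals missing from the
    session roster.
    """
    if not isinstance(ethogram, Ethogram):
        ethogram = Ethogram.from_yaml(ethogram)

    sess_df = _read_table(session_table)
    missing = set(_SESSION_COLUMNS) - set(sess_df.columns)
    if missing:
        raise ValidationError(f"session table missing columns: {sorted(missing)}")
    sessions: dict[str, SessionInfo] = {}
    for row in sess_df.itertuples(index=False):
        sid = str(row.session_id)
        if sid in sessions:
            raise ValidationError(f"duplicate session_id {sid!r}")
        present = frozenset(p for p in str(row.individuals_present).split(";") if p)
        sessions[sid] = SessionInfo(
            session_id=sid,
            date=_dt.date.fromisoformat(str(row.date)),
            duration_hours=float(row.duration_hours),
            individuals_present=present,
        )

    df = _read_table(interaction_table)
    missing = set(_INTERACTION_COLUMNS) - set(df.columns)
    if missing:
        raise ValidationError(f"interaction table missing columns: {sorted(missing)}")

    records: list[InteractionRecord] = []
    for row in df.itertuples(index=False):
        sid = str(row.session_id)
        if sid not in sessions:
            raise ValidationError(f"session {sid!r} not found in session table")
        category = ethogram.category(str(row.behaviour_code))
        outcome = str(row.outcome) or "not_applicable"
        rec = InteractionRecord(
            session_id=sid,
            order_index=int(row.order_index),
            initiator_id=str(row.initiator_id),
            recipient_id=str(row.recipient_id),
            behaviour_code=str(row.behaviour_code),
            category=category,
            outcome=outcome,
        )
        roster = sessions[sid].individuals_present
        for ind in (rec.initiator_id, rec.recipient_id):
            if ind not in roster:
                raise ValidationError(
                    f"session {sid!r}: individual {ind!r} not in session roster"
                )
        records.append(rec)

    records.sort(key=lambda r: (r.session_id, r.order_index))
    seen: dict[str, set[int]] = {}
    for rec in records:
        idx = seen.setdefault(rec.session_id, set())
        if rec.order_index in idx:
            raise ValidationError(
                f"session {rec.session_id!r}: duplicate order_index {rec.order_index}"
            )
        idx.add(rec.order_index)
    session_list = sorted(sessions.values(), key=lambda s: (s.date, s.session_id))
    return records, session_list


def write_interactions(records: Iterable[InteractionRecord], path: str | Path) -> None:
    """Write records to the CSV schema consumed by :func:`read_interactions`."""
    rows = [
        {
            "session_id": r.session_id,
            "order_index": r.order_index,
            "initiator_id": r.initiator_id,
            "recipient_id": r.recipient_id,
            "behaviour_code": r.behaviour_code,
            "outcome": "" if r.outcome == "not_applicable" else r.outcome,
        }
        for r in records
    ]
    pd.DataFrame(rows, columns=_INTERACTION_COLUMNS).to_csv(path, index=False)


def write_sessions(sessions: Iterable[SessionInfo], path: str | Path) -> None:
    rows = [
        {
            "session_id": s.session_id,
            "date": s.date.isoformat(),
            "duration_hours": s.duration_hours,
            "individuals_present": ";".join(sorted(s.individuals_present)),
        }
        for s in sessions
    ]
    pd.DataFrame(rows, columns=_SESSION_COLUMNS).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# tallies and sociomatrices


def tally_interactions(
    records: Sequence[InteractionRecord],
    sessions: Sequence[SessionInfo],
) -> pd.DataFrame:
    """Per-session and total interaction counts by category.

    Rows are sessions (in session-table order) plus ``total``, ``mean`` and
    ``sd`` rows; columns are the behavioural categories plus the number of
    draws among agonistic events. Mean and SD are taken over the provided
    sessions (sample SD, NaN for a single session).
    """
    session_ids = [s.session_id for s in sessions]
    counts = pd.DataFrame(
        0, index=session_ids, columns=list(CATEGORIES) + ["draws"], dtype=float
    )
    for rec in records:
        counts.loc[rec.session_id, rec.category] += 1
        if rec.outcome == "draw":
            counts.loc[rec.session_id, "draws"] += 1
    summary = counts.copy()
    summary.loc["total"] = counts.sum()
    summary.loc["mean"] = counts.mean()
    summary.loc["sd"] = counts.std(ddof=1)
    return summary


def build_win_loss_matrix(
    records: Iterable[InteractionRecord],
    individuals: Sequence[str],
) -> WinLossMatrix:
    """Tally decided agonistic wins into a sociomatrix.

    Draws contribute to no cell. The matrix always has one row/column per
    supplied individual, even if some never interacted. Records involving an
    individual outside ``individuals`` raise :class:`ValidationError`.
    """
    individuals = list(individuals)
    index = {ind: i for i, ind in enumerate(individuals)}
    counts = np.zeros((len(individuals), len(individuals)), dtype=int)
    for rec in records:
        if rec.category != "agonistic":
            raise ValidationError(
                "win-loss matrix is defined on agonistic records only; got "
                f"{rec.category!r}"
            )
        for ind in (rec.initiator_id, rec.recipient_id):
            if ind not in index:
                raise ValidationError(
                    f"individual {ind!r} not in the supplied individual list"
                )
        if rec.decided:
            counts[index[rec.winner_id], index[rec.loser_id]] += 1
    return WinLossMatrix(individuals=individuals, counts=counts)
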