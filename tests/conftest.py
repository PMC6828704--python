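from pathlib import Path

import pytest

from dominet import (
    Ethogram,
    InteractionRecord,
    SessionInfo,
    write_interactions,
    write_sessions,
)

import datetime as dt


@pytest.fixture
def ethogram() -> Ethogram:
    return Ethogram.from_dict(
        {
            "peck": {"category": "agonistic", "description": "peck at another bird"},
            "displace": "agonistic",
            "allopreen": "affiliative",
            "approach_unclear": "ambiguous",
        }
    )


def make_record(
    session_id="s1",
    order_index=0,
    initiator_id="A",
    recipient_id="B",
    behaviour_code="peck",
    category="agonistic",
    outcome="initiator_wins",
) -> InteractionRecord:
    return InteractionRecord(
        session_id=session_id,
        order_index=order_index,
        initiator_id=initiator_id,
        recipient_id=recipient_id,
        behaviour_code=behaviour_code,
        category=category,
        outcome=outcome,
    )


def make_session(
    session_id="s1",
    date=dt.date(2015, 7, 1),
    duration_hours=2.0,
    individuals=("A", "B", "C"),
) -> SessionInfo:
    return SessionInfo(
        session_id=session_id,
        date=date,
        duration_hours=duration_hours,
        individuals_present=frozenset(individuals),
    )


@pytest.fixture
def tiny_dataset(tmp_path: Path, ethogram: Ethogram):
    """Three-interaction dataset on disk: two agonistic, one affiliative."""
    records = [
        make_record(order_index=0, initiator_id="A", recipient_id="B"),
        make_record(
            order_index=1,
            initiator_id="B",
            recipient_id="C",
            behaviour_code="allopreen",
            category="affiliative",
            outcome="not_applicable",
        ),
        make_record(
            order_index=2,
            initiator_id="A",
            recipient_id="C",
            behaviour_code="displace",
        ),
    ]
    sessions = [make_session()]
    interactions_path = tmp_path / "interactions.csv"
    sessions_path = tmp_path / "sessions.csv"
    ethogram_path = tmp_path / "ethogram.yaml"
    write_interactions(records, interactions_path)
    write_sessions(sessions, sessions_path)
    ethogram.to_yaml(ethogram_path)
    return interactions_path, sessions_path, ethogram_path, records, sessions
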