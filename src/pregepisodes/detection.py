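"""Candidate pregnancy-outcome event detection.

Outcome presence is asserted by code *type*: deliveries from delivery
procedure claims, stillbirths and abortions from diagnosis claims.
Abortion *procedure* codes inform gestational-age estimation only and
never create an outcome event on their own.  Same-day repeats of a
qualifying claim collapse to one event.
"""

from __future__ import annotations

from typing import Iterable, Mapping

from .config import AlgorithmParams, CodeMap
from .records import CandidateEvent, ClaimRecord, Person

__all__ = ["detect_events", "filter_childbearing_age"]

#: (category, system) pairs that assert an outcome, and the outcome they assert.
_OUTCOME_RULES = {
    ("delivery_procedure", "procedure"): "delivery",
    ("stillbirth_diagnosis", "diagnosis"): "stillbirth",
    ("abortion_diagnosis", "diagnosis"): "abortion",
}


def detect_events(
    claims: Iterable[ClaimRecord], codemap: CodeMap
) -> list[CandidateEvent]:
    """Scan claims for outcome-asserting codes.

    One event per distinct (person, date, outcome type); the claims
    behind it are retained for audit.  Output order is deterministic and
    independent of claim input order.
    """
    grouped: dict[tuple[str, object, str], list[ClaimRecord]] = {}
    for claim in claims:
        categories = codemap.classify(claim.code, claim.system)
        for cat in categories:
            outcome = _OUTCOME_RULES.get((cat, claim.system))
            if outcome is None:
                continue
            grouped.setdefault(
                (claim.person_id, claim.service_date, outcome), []
            ).append(claim)
    events = []
    for (person_id, date, outcome), members in sorted(
        grouped.items(), key=lambda kv: (kv[0][0], kv[0][1], kv[0][2])
    ):
        members = sorted(set(members), key=lambda c: (c.code, c.system))
        events.append(
            CandidateEvent(
                person_id=person_id,
                event_date=date,
                outcome_type=outcome,
                source_claims=tuple(members),
            )
        )
    return events


def filter_childbearing_age(
    events: Iterable[CandidateEvent],
    persons: Iterable[Person] | Mapping[str, Person],
    params: AlgorithmParams,
) -> list[CandidateEvent]:
    """Keep events whose person is of childbearing age at the event.

    Age is completed years at the event date; both bounds inclusive
    (default 12-49): the event on the day before the 50th birthday is
    kept, the one on the birthday is not.
    """
    if not isinstance(persons, Mapping):
        persons = {p.person_id: p for p in persons}
    unknown = sorted({e.person_id for e in events if e.person_id not in persons})
    if unknown:
        raise KeyError(f"events reference unknown person_ids: {unknown}")
    lo, hi = params.childbearing_age
    kept = []
    for event in events:
        age = persons[event.person_id].age_at(event.event_date)
        if lo <= age <= hi:
            kept.append(
                CandidateEvent(
                    person_id=event.person_id,
                    event_date=event.event_date,
                    outcome_type=event.outcome_type,
                    source_claims=event.source_claims,
                    age_at_event_years=age,
                )
            )
    return kept
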