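"""Core record types flowing through the episode pipeline."""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field, replace
from typing import Optional

__all__ = [
    "ClaimRecord",
    "Person",
    "CandidateEvent",
    "CandidateEpisode",
    "GaMarker",
    "LmpResult",
    "PregnancyEpisode",
    "FINAL_OUTCOME_TYPES",
    "KEPT",
]

#: Final (refined) outcome taxonomy.
FINAL_OUTCOME_TYPES = (
    "full_term",
    "preterm",
    "stillbirth",
    "spontaneous_abortion",
    "induced_abortion",
)

KEPT = "kept"


@dataclass(frozen=True, order=True)
class ClaimRecord:
    """One dated, coded healthcare event for one person."""

    person_id: str
    service_date: dt.date
    code: str
    system: str  # diagnosis | procedure | drug
    quantity: Optional[int] = None


@dataclass(frozen=True)
class Person:
    person_id: str
    birth_date: dt.date
    sex: str
    observation_start: dt.date
    observation_end: dt.date

    def __post_init__(self) -> None:
        if self.observation_start > self.observation_end:
            raise ValueError(
                f"person {self.person_id}: observation_start > observation_end"
            )
        if self.birth_date > self.observation_start:
            raise ValueError(
                f"person {self.person_id}: birth_date > observation_start"
            )

    def age_at(self, date: dt.date) -> int:
        """Completed years at ``date`` (birthday-based)."""
        years = date.year - self.birth_date.year
        if (date.month, date.day) < (self.birth_date.month, self.birth_date.day):
            years -= 1
        return years


@dataclass(frozen=True)
class CandidateEvent:
    """A dated candidate pregnancy-outcome event (pre-clustering)."""

    person_id: str
    event_date: dt.date
    outcome_type: str  # delivery | stillbirth | abortion
    source_claims: tuple[ClaimRecord, ...] = ()
    age_at_event_years: Optional[int] = None


@dataclass(frozen=True)
class CandidateEpisode:
    """A per-outcome cluster of candidate events."""

    person_id: str
    outcome_type: str
    outcome_date: dt.date
    member_events: tuple[CandidateEvent, ...]
    status: str = "active"  # active | eliminated
    eliminated_by: Optional[str] = None

    def eliminate(self, reason: str) -> "CandidateEpisode":
        return replace(self, status="eliminated", eliminated_by=reason)


@dataclass(frozen=True)
class GaMarker:
    """A GA-informative claim interpreted relative to an episode.

    ``implied_lmp`` is the claim date minus the midpoint of the code's GA
    window (for the fixed-offset unspecified-preterm marker the LMP is
    instead anchored at the outcome, so the midpoint stored here is the
    fixed offset and ``implied_lmp`` is outcome - offset).
    """

    claim_date: dt.date
    category: str
    midpoint_days: int
    implied_lmp: dt.date
    ga_window_days: Optional[tuple[int, int]] = None

    def implied_ga_at(self, date: dt.date) -> int:
        return (date - self.implied_lmp).days


@dataclass(frozen=True)
class LmpResult:
    lmp_date: dt.date
    method: str
    ga_days: int


@dataclass
class PregnancyEpisode:
    """A resolved pregnancy episode: LMP to outcome date.

    ``outcome_type`` starts as the base class (delivery/stillbirth/
    abortion) and is refined to the final five-way taxonomy; ``status``
    records why an episode was dropped, when it was.
    """

    person_id: str
    outcome_date: dt.date
    outcome_type: str
    lmp_date: Optional[dt.date] = None
    ga_days: Optional[int] = None
    lmp_method: Optional[str] = None
    status: str = KEPT
    reclassified_from: Optional[str] = None
    lmp_adjusted_by_retry: bool = False
    member_events: tuple[CandidateEvent, ...] = field(default=(), repr=False)

    @property
    def era_year(self) -> Optional[int]:
        return self.lmp_date.year if self.lmp_date else None

    def set_lmp(self, result: LmpResult) -> None:
        self.lmp_date = result.lmp_date
        self.lmp_method = result.method
        self.ga_days = result.ga_days

    def recompute_ga(self) -> None:
        assert self.lmp_date is not None
        self.ga_days = (self.outcome_date - self.lmp_date).days
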