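"""Clustering of outcome events into episodes and hierarchy resolution.

Multiple outcome claims within the clinically plausible same-episode gap
are one pregnancy; the earliest claim anchors the episode.  Overlapping
episodes of *different* outcome types are resolved by the outcome
hierarchy (default stillbirth > delivery > abortion): the lower-ranked
episode is treated as miscoded and eliminated, but retained with its
status for audit.
"""

from __future__ import annotations

from typing import Iterable

from .config import AlgorithmParams
from .records import CandidateEpisode, CandidateEvent

__all__ = ["cluster_events", "resolve_hierarchy"]


def cluster_events(
    events: Iterable[CandidateEvent], params: AlgorithmParams
) -> list[CandidateEpisode]:
    """Single-linkage chaining per (person, outcome type).

    An event joins the current cluster iff its gap to the cluster's
    latest member is strictly less than the outcome's same-episode gap;
    otherwise it starts a new episode.  The anchor (outcome date) is the
    earliest member date.
    """
    by_group: dict[tuple[str, str], list[CandidateEvent]] = {}
    for e in events:
        by_group.setdefault((e.person_id, e.outcome_type), []).append(e)

    episodes: list[CandidateEpisode] = []
    for (person_id, outcome), group in sorted(by_group.items()):
        group.sort(key=lambda e: e.event_date)
        gap = params.same_episode_gap_days[outcome]
        cluster: list[CandidateEvent] = []
        for event in group:
            if cluster and (event.event_date - cluster[-1].event_date).days >= gap:
                episodes.append(_finish(person_id, outcome, cluster))
                cluster = []
            cluster.append(event)
        if cluster:
            episodes.append(_finish(person_id, outcome, cluster))
    episodes.sort(key=lambda ep: (ep.person_id, ep.outcome_date, ep.outcome_type))
    return episodes


def _finish(
    person_id: str, outcome: str, cluster: list[CandidateEvent]
) -> CandidateEpisode:
    return CandidateEpisode(
        person_id=person_id,
        outcome_type=outcome,
        outcome_date=cluster[0].event_date,
        member_events=tuple(cluster),
    )


def resolve_hierarchy(
    episodes: Iterable[CandidateEpisode], params: AlgorithmParams
) -> list[CandidateEpisode]:
    """Eliminate lower-ranked episodes that conflict with higher ones.

    Two active episodes of different outcome types conflict when their
    outcome dates are closer than the configured cross-outcome window.
    Ranks are processed top-down, so winners are fixed before
    lower-ranked episodes are judged; an episode eliminated by a higher
    rank can no longer eliminate anything itself.
    """
    episodes = list(episodes)
    by_person: dict[str, list[int]] = {}
    for i, ep in enumerate(episodes):
        by_person.setdefault(ep.person_id, []).append(i)

    out = list(episodes)
    for person, idxs in by_person.items():
        for winner_type in params.hierarchy:
            winners = [
                i
                for i in idxs
                if out[i].outcome_type == winner_type and out[i].status == "active"
            ]
            for wi in winners:
                if out[wi].status != "active":
                    continue  # eliminated meanwhile by an earlier winner
                for i in idxs:
                    loser = out[i]
                    if loser.status != "active" or i == wi:
                        continue
                    if params.rank(loser.outcome_type) <= params.rank(winner_type):
                        continue
                    window = params.conflict_days(winner_type, loser.outcome_type)
                    gap = abs((loser.outcome_date - out[wi].outcome_date).days)
                    if gap < window:
                        out[i] = loser.eliminate(
                            f"hierarchy:{winner_type}@{out[wi].outcome_date.isoformat()}"
                        )
    return out
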