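"""Last-menstrual-period estimation for resolved episodes.

Two routes:

1. **Marker route** — gestational-age–informative claims (sonography,
   preterm-delivery diagnoses, abortion procedures) imply an LMP by
   subtracting the midpoint of the code's GA window from the claim date.
   Sonography tiers are prioritised narrowest-first (second/third-
   trimester target scan, first-trimester target scan, first-trimester
   routine, second/third-trimester routine); preterm diagnoses with a
   specified GA outrank unspecified ones (the latter imply a fixed
   35-week GA at the outcome).  Among surviving markers the latest
   implied LMP — i.e. the smallest GA at the outcome — wins.
2. **Outcome-specific fallback** — with no usable marker, subtract a
   fixed GA from the outcome date: 39 weeks (delivery), 28 weeks
   (stillbirth) or 10 weeks (abortion).

Marker eligibility depends on the outcome: deliveries use sonography and
preterm codes, abortions use abortion-procedure and sonography codes,
stillbirths use sonography only.  A marker is admitted only when it is
plausibly part of the episode: claim date within ``max_ga_days`` before
the outcome (and not after it), and implied GA at the outcome within
``[1, max_ga_days]``.
"""

from __future__ import annotations

import datetime as dt
from typing import Iterable, Optional

from .config import GA_WINDOW_CATEGORIES, AlgorithmParams, CodeMap
from .records import CandidateEpisode, ClaimRecord, GaMarker, LmpResult

__all__ = [
    "METHOD_LABELS",
    "SONOGRAPHY_TIERS",
    "collect_markers",
    "pick_marker",
    "estimate_lmp",
    "marker_eligibility",
]

#: Sonography priority, narrowest implied range first.
SONOGRAPHY_TIERS = (
    "sonography_t23_targetscan",
    "sonography_t1_targetscan",
    "sonography_t1",
    "sonography_t23",
)

_PRETERM_TIERS = ("preterm_ga_specified", "preterm_ga_unspecified")

#: Marker categories eligible per base outcome type.
_ELIGIBLE = {
    "delivery": frozenset(SONOGRAPHY_TIERS) | frozenset(_PRETERM_TIERS),
    "stillbirth": frozenset(SONOGRAPHY_TIERS),
    "abortion": frozenset(SONOGRAPHY_TIERS) | {"abortion_procedure"},
}

#: Reporting labels, in the canonical method-table row order.
METHOD_LABELS = (
    "outcome_specific",
    "abortion_procedure",
    "sonography_t23_targetscan",
    "sonography_t1_targetscan",
    "sonography_t1",
    "sonography_t23",
    "preterm_specified",
    "preterm_unspecified",
)

_CATEGORY_TO_LABEL = {
    "abortion_procedure": "abortion_procedure",
    "sonography_t23_targetscan": "sonography_t23_targetscan",
    "sonography_t1_targetscan": "sonography_t1_targetscan",
    "sonography_t1": "sonography_t1",
    "sonography_t23": "sonography_t23",
    "preterm_ga_specified": "preterm_specified",
    "preterm_ga_unspecified": "preterm_unspecified",
}


def marker_eligibility(outcome_type: str) -> frozenset:
    """Marker categories usable for a given base outcome type."""
    return _ELIGIBLE[outcome_type]


def collect_markers(
    episode: CandidateEpisode,
    claims: Iterable[ClaimRecord],
    codemap: CodeMap,
    params: AlgorithmParams,
) -> list[GaMarker]:
    """GA markers of the episode's person admissible for this episode."""
    eligible = _ELIGIBLE[episode.outcome_type]
    outcome = episode.outcome_date
    earliest_claim = outcome - dt.timedelta(days=params.max_ga_days)
    markers: set[GaMarker] = set()
    for claim in claims:
        if claim.person_id != episode.person_id:
            continue
        if not (earliest_claim <= claim.service_date <= outcome):
            continue
        for entry in codemap.matching_entries(claim.code, claim.system):
            if entry.category not in eligible:
                continue
            if entry.category in GA_WINDOW_CATEGORIES:
                mid = entry.midpoint_days
                implied_lmp = claim.service_date - dt.timedelta(days=mid)
                ga_at_outcome = (outcome - implied_lmp).days
                if not (1 <= ga_at_outcome <= params.max_ga_days):
                    continue
                markers.add(
                    GaMarker(
                        claim_date=claim.service_date,
                        category=entry.category,
                        midpoint_days=mid,
                        implied_lmp=implied_lmp,
                        ga_window_days=entry.ga_window_days,
                    )
                )
            elif entry.category == "preterm_ga_unspecified":
                offset = params.unspecified_preterm_ga_days
                markers.add(
                    GaMarker(
                        claim_date=claim.service_date,
                        category=entry.category,
                        midpoint_days=offset,
                        implied_lmp=outcome - dt.timedelta(days=offset),
                        ga_window_days=None,
                    )
                )
    return sorted(
        markers, key=lambda m: (m.claim_date, m.category, m.midpoint_days)
    )


def _tier_filter(markers: list[GaMarker], params: AlgorithmParams) -> list[GaMarker]:
    """Keep the top occupied tier of each marker family."""
    kept: list[GaMarker] = []

    sono = [m for m in markers if m.category in SONOGRAPHY_TIERS]
    if sono:
        if params.tier_strict:
            top = min(sono, key=lambda m: SONOGRAPHY_TIERS.index(m.category))
            kept.extend(m for m in sono if m.category == top.category)
        else:
            kept.extend(sono)

    preterm = [m for m in markers if m.category in _PRETERM_TIERS]
    if preterm:
        top = min(preterm, key=lambda m: _PRETERM_TIERS.index(m.category))
        kept.extend(m for m in preterm if m.category == top.category)

    kept.extend(m for m in markers if m.category == "abortion_procedure")
    return kept


_ALL_TIERS = SONOGRAPHY_TIERS + _PRETERM_TIERS + ("abortion_procedure",)


def pick_marker(
    markers: Iterable[GaMarker],
    outcome_type: str,
    params: AlgorithmParams,
) -> Optional[GaMarker]:
    """Select the winning GA marker, or ``None`` when there is none.

    (1) tier-filter within each family; (2) latest implied LMP (smallest
    GA at outcome) among survivors; (3) residual ties go to the smallest
    GA at the claim date, then tier priority, then earliest claim.
    """
    markers = [m for m in markers if m.category in _ELIGIBLE[outcome_type]]
    if not markers:
        return None
    survivors = _tier_filter(markers, params)
    return min(
        survivors,
        key=lambda m: (
            m.implied_lmp.toordinal() * -1,  # latest LMP first
            m.midpoint_days,  # lowest GA at claim date
            _ALL_TIERS.index(m.category),
            m.claim_date,
        ),
    )


def estimate_lmp(
    episode: CandidateEpisode,
    markers: Iterable[GaMarker],
    params: AlgorithmParams,
) -> LmpResult:
    """Estimate the episode's LMP from markers, else the fixed fallback."""
    chosen = pick_marker(markers, episode.outcome_type, params)
    outcome = episode.outcome_date
    if chosen is not None:
        lmp = chosen.implied_lmp
        method = _CATEGORY_TO_LABEL[chosen.category]
    else:
        ga = params.outcome_specific_ga_days[episode.outcome_type]
        lmp = outcome - dt.timedelta(days=ga)
        method = "outcome_specific"
    return LmpResult(lmp_date=lmp, method=method, ga_days=(outcome - lmp).days)
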