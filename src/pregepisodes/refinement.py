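"""Final adjustment of episodes: retry period, GA bounds, abortion subtype.

The retry period is the clinically required interval between a pregnancy
outcome and the start of the next pregnancy.  When successive episodes
of a woman overlap, the later LMP is pushed to the previous outcome date
plus the retry period.  Afterwards, gestational-age plausibility bounds
reclassify or exclude episodes: stillbirths under 20 weeks become
abortions, deliveries under 20 weeks and any episode over 42 weeks are
excluded as miscoded, and remaining deliveries split into preterm
(<37 weeks) and full-term.  Abortions are finally subtyped as induced
(any induced-abortion code within the episode window) or spontaneous.
"""

from __future__ import annotations

import datetime as dt
from typing import Iterable

from .config import AlgorithmParams, CodeMap
from .records import ClaimRecord, PregnancyEpisode

__all__ = [
    "apply_retry",
    "enforce_bounds",
    "classify_abortion",
    "refine_episodes",
]

_DELIVERY_LIKE = {"delivery", "full_term", "preterm"}
_ABORTION_LIKE = {"abortion", "spontaneous_abortion", "induced_abortion"}


def apply_retry(
    episodes: list[PregnancyEpisode], params: AlgorithmParams
) -> list[PregnancyEpisode]:
    """Push overlapping LMPs forward by the retry period, per person.

    Scanned left-to-right by outcome date so adjustments cascade.  With
    ``retry_trigger="separated"`` (default) the adjustment fires whenever
    the LMP falls before the previous outcome plus the retry period, so
    kept episodes always end up separated by at least the retry period;
    ``"strict"`` fires only when the LMP precedes the previous outcome
    date itself.  An adjustment that would push the LMP to or past its
    own outcome date marks the episode excluded as degenerate.
    """
    by_person: dict[str, list[PregnancyEpisode]] = {}
    for ep in episodes:
        by_person.setdefault(ep.person_id, []).append(ep)

    retry = dt.timedelta(days=params.retry_period_days)
    for person_eps in by_person.values():
        person_eps.sort(key=lambda e: e.outcome_date)
        prev_outcome = None
        for ep in person_eps:
            if ep.status != "kept":
                continue
            assert ep.lmp_date is not None
            if prev_outcome is not None:
                floor = prev_outcome + retry
                trigger = (
                    ep.lmp_date < prev_outcome
                    if params.retry_trigger == "strict"
                    else ep.lmp_date < floor
                )
                if trigger:
                    ep.lmp_date = floor
                    ep.lmp_adjusted_by_retry = True
                    ep.recompute_ga()
                    if ep.lmp_date >= ep.outcome_date:
                        ep.status = "excluded_degenerate"
                        continue
            prev_outcome = ep.outcome_date
    return episodes


def enforce_bounds(
    episodes: list[PregnancyEpisode], params: AlgorithmParams
) -> list[PregnancyEpisode]:
    """Reclassify or exclude episodes outside plausible GA bounds."""
    for ep in episodes:
        if ep.status != "kept":
            continue
        assert ep.ga_days is not None
        if ep.outcome_type == "stillbirth":
            if ep.ga_days < params.stillbirth_reclass_cutoff_days:
                ep.reclassified_from = "stillbirth"
                ep.outcome_type = "abortion"
        if ep.outcome_type in _DELIVERY_LIKE:
            if ep.ga_days < params.min_delivery_ga_days:
                ep.status = "excluded_short_delivery"
                continue
        if ep.ga_days > params.max_ga_days:
            ep.status = "excluded_overlong"
            continue
        if (
            ep.outcome_type in _ABORTION_LIKE
            and ep.ga_days > params.max_abortion_ga_days
        ):
            ep.status = "excluded_overlong"
            continue
        if ep.outcome_type in _DELIVERY_LIKE:
            ep.outcome_type = (
                "preterm" if ep.ga_days < params.preterm_cutoff_days else "full_term"
            )
    return episodes


def classify_abortion(
    episodes: list[PregnancyEpisode],
    claims: Iterable[ClaimRecord],
    codemap: CodeMap,
    params: AlgorithmParams,
) -> list[PregnancyEpisode]:
    """Subtype kept abortions as induced or spontaneous.

    Induced iff at least one induced-abortion code falls in
    ``[lmp, outcome + same-episode gap)`` — the trailing allowance covers
    induced-abortion coding that follows the event.
    """
    induced_dates: dict[str, list[dt.date]] = {}
    for claim in claims:
        if "induced_abortion_marker" in codemap.classify(claim.code, claim.system):
            induced_dates.setdefault(claim.person_id, []).append(claim.service_date)

    trail = dt.timedelta(days=params.same_episode_gap_days["abortion"])
    for ep in episodes:
        if ep.status != "kept" or ep.outcome_type not in _ABORTION_LIKE:
            continue
        assert ep.lmp_date is not None
        end = ep.outcome_date + trail
        hit = any(
            ep.lmp_date <= d < end for d in induced_dates.get(ep.person_id, ())
        )
        ep.outcome_type = "induced_abortion" if hit else "spontaneous_abortion"
    return episodes


def refine_episodes(
    episodes: list[PregnancyEpisode],
    claims: Iterable[ClaimRecord],
    codemap: CodeMap,
    params: AlgorithmParams,
) -> list[PregnancyEpisode]:
    """Full refinement pass: retry adjustment, bounds, abortion subtype.

    Retry runs first so exclusions and the preterm/full-term split see
    final gestational ages.  Idempotent: a second pass changes nothing.
    """
    claims = list(claims)
    apply_retry(episodes, params)
    enforce_bounds(episodes, params)
    classify_abortion(episodes, claims, codemap, params)
    return episodes
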