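"""Independent brute-force oracles for the core algorithm operations.

Each oracle re-derives the expected result from the rule statement with
a different formulation than the implementation uses, so agreement is
meaningful.
"""

from __future__ import annotations

import datetime as dt


def split_on_gaps(dates: list[dt.date], gap_days: int) -> list[list[dt.date]]:
    """Clustering oracle: split a sorted date list wherever the
    difference between consecutive dates reaches the gap."""
    dates = sorted(dates)
    if not dates:
        return []
    clusters = [[dates[0]]]
    for prev, cur in zip(dates, dates[1:]):
        if (cur - prev).days >= gap_days:
            clusters.append([])
        clusters[-1].append(cur)
    return clusters


def hierarchy_survivors(
    episodes: list[tuple[str, dt.date]],
    hierarchy: tuple[str, ...],
    conflict_days,
) -> set[int]:
    """Hierarchy oracle: recursive definition of 'active'.

    An episode is active iff no *active* episode of strictly higher rank
    lies within the pairwise conflict window.  Computed rank by rank.
    ``episodes`` is a list of (outcome_type, outcome_date) for one
    person; returns the set of surviving indices.
    """
    rank = {t: i for i, t in enumerate(hierarchy)}
    active: set[int] = set()
    for r in range(len(hierarchy)):
        for i, (t, d) in enumerate(episodes):
            if rank[t] != r:
                continue
            beaten = any(
                j in active
                and rank[episodes[j][0]] < r
                and abs((episodes[j][1] - d).days) < conflict_days(episodes[j][0], t)
                for j in range(len(episodes))
            )
            if not beaten:
                active.add(i)
    return active


SONO_ORDER = [
    "sonography_t23_targetscan",
    "sonography_t1_targetscan",
    "sonography_t1",
    "sonography_t23",
]
PRETERM_ORDER = ["preterm_ga_specified", "preterm_ga_unspecified"]

ELIGIBLE = {
    "delivery": set(SONO_ORDER) | set(PRETERM_ORDER),
    "stillbirth": set(SONO_ORDER),
    "abortion": set(SONO_ORDER) | {"abortion_procedure"},
}


def pick_marker_oracle(markers, outcome_type, tier_strict=True):
    """Marker-selection oracle over (category, claim_date, midpoint,
    implied_lmp) tuples; returns the winning tuple or None."""
    cand = [m for m in markers if m[0] in ELIGIBLE[outcome_type]]
    if not cand:
        return None
    survivors = []
    sono = [m for m in cand if m[0] in SONO_ORDER]
    if sono:
        if tier_strict:
            best = min(SONO_ORDER.index(m[0]) for m in sono)
            survivors += [m for m in sono if SONO_ORDER.index(m[0]) == best]
        else:
            survivors += sono
    pre = [m for m in cand if m[0] in PRETERM_ORDER]
    if pre:
        best = min(PRETERM_ORDER.index(m[0]) for m in pre)
        survivors += [m for m in pre if PRETERM_ORDER.index(m[0]) == best]
    survivors += [m for m in cand if m[0] == "abortion_procedure"]

    all_tiers = SONO_ORDER + PRETERM_ORDER + ["abortion_procedure"]
    best = None
    for m in survivors:
        if best is None:
            best = m
            continue
        key_m = (m[3], -m[2], -all_tiers.index(m[0]), -m[1].toordinal())
        key_b = (best[3], -best[2], -all_tiers.index(best[0]), -best[1].toordinal())
        if key_m > key_b:
            best = m
    return best
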