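"""Outcome prevalence, LMP-method tabulation, and drug-exposure windows.

Exposure is assessed per episode over a grid of windows anchored at the
estimated LMP: four 90-day preconception quarters counting back from the
LMP, an early-pregnancy window (0-7 weeks) and the three trimesters (the
last ends at the outcome).  Two exposure definitions are always
computed: the primary (> 1 prescription in the window, i.e. at least
``exposure_min_prescriptions``) and the sensitivity definition
(>= 1 prescription).
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass
from typing import Iterable, Optional

import numpy as np
import pandas as pd
from statsmodels.stats.proportion import proportion_confint

from .config import AlgorithmParams, CodeMap
from .lmp import METHOD_LABELS
from .records import FINAL_OUTCOME_TYPES, ClaimRecord, PregnancyEpisode

__all__ = [
    "ExposureWindow",
    "ExposureResult",
    "default_windows",
    "assess_exposure",
    "exposure_trajectory",
    "prevalence_table",
    "lmp_method_table",
    "period_stratify",
]

DRUG_CLASSES = ("drug_cyc_mmf_mtx", "drug_nsaid")


@dataclass(frozen=True)
class ExposureWindow:
    """A half-open exposure window in days relative to the LMP."""

    label: str
    start_offset_days: int
    end_offset_days: Optional[int]  # None = open, runs to the outcome
    anchored: str = "lmp"  # "lmp" | "outcome"

    def __post_init__(self) -> None:
        if self.end_offset_days is not None and self.start_offset_days >= self.end_offset_days:
            raise ValueError(f"window {self.label}: start must precede end")


def default_windows(params: AlgorithmParams) -> tuple[ExposureWindow, ...]:
    """Preconception quarters, 0-7-week window and trimesters."""
    windows = []
    n = len(params.preconception_quarters_days)
    for i, (s, e) in enumerate(params.preconception_quarters_days):
        windows.append(ExposureWindow(f"pre_q{n - i}", s, e))
    s, e = params.early_pregnancy_window_days
    windows.append(ExposureWindow("wk0_7", s, e))
    for i, (s, e) in enumerate(params.trimester_bounds_days, start=1):
        anchored = "outcome" if e is None else "lmp"
        windows.append(ExposureWindow(f"trimester{i}", s, e, anchored=anchored))
    return tuple(windows)


@dataclass(frozen=True)
class ExposureResult:
    person_id: str
    outcome_date: dt.date
    drug_class: str
    window: str
    n_prescriptions: int
    exposed_primary: bool
    exposed_sensitivity: bool
    window_reached: bool

    def __post_init__(self) -> None:
        assert not self.exposed_primary or self.exposed_sensitivity


def assess_exposure(
    episode: PregnancyEpisode,
    drug_claims: Iterable[ClaimRecord],
    windows: Iterable[ExposureWindow],
    codemap: CodeMap,
    params: AlgorithmParams,
) -> list[ExposureResult]:
    """Count per-window prescriptions of each drug class for one episode.

    Pregnancy windows are capped at the outcome date (inclusive); a
    pregnancy window the episode never reaches (outcome before the
    window start) is flagged ``window_reached=False``.
    """
    assert episode.lmp_date is not None
    lmp = episode.lmp_date
    outcome = episode.outcome_date

    dated: dict[str, list[dt.date]] = {d: [] for d in DRUG_CLASSES}
    for claim in drug_claims:
        if claim.person_id != episode.person_id or claim.system != "drug":
            continue
        for cat in codemap.classify(claim.code, claim.system):
            if cat in dated:
                dated[cat].append(claim.service_date)

    results = []
    for window in windows:
        start = lmp + dt.timedelta(days=window.start_offset_days)
        if window.end_offset_days is None:
            end = outcome + dt.timedelta(days=1)
        else:
            end = lmp + dt.timedelta(days=window.end_offset_days)
            if window.start_offset_days >= 0:  # pregnancy window: cap at outcome
                end = min(end, outcome + dt.timedelta(days=1))
        reached = window.start_offset_days < 0 or (outcome - lmp).days > window.start_offset_days
        for drug, dates in dated.items():
            n = sum(1 for d in dates if start <= d < end) if reached else 0
            results.append(
                ExposureResult(
                    person_id=episode.person_id,
                    outcome_date=outcome,
                    drug_class=drug,
                    window=window.label,
                    n_prescriptions=n,
                    exposed_primary=n >= params.exposure_min_prescriptions,
                    exposed_sensitivity=n >= 1,
                    window_reached=reached,
                )
            )
    return results


def exposure_trajectory(
    results: Iterable[ExposureResult],
    windows: Iterable[ExposureWindow],
) -> pd.DataFrame:
    """Per drug class and window: exposure prevalence, both definitions.

    Denominator per window = episodes that reach the window.
    """
    df = pd.DataFrame([r.__dict__ for r in results])
    order = [w.label for w in windows]
    rows = []
    for drug in DRUG_CLASSES:
        for label in order:
            sub = df[(df.drug_class == drug) & (df.window == label)] if len(df) else df
            reached = sub[sub.window_reached] if len(sub) else sub
            n = len(reached)
            rows.append(
                {
                    "drug_class": drug,
                    "window": label,
                    "n_episodes": n,
                    "pct_exposed_primary": (
                        100.0 * reached.exposed_primary.mean() if n else np.nan
                    ),
                    "pct_exposed_sensitivity": (
                        100.0 * reached.exposed_sensitivity.mean() if n else np.nan
                    ),
                }
            )
    return pd.DataFrame(rows)


_GA_STATS = ("mean", "sd", "median", "q1", "q3", "min", "max")


def _ga_summary(ga_weeks: np.ndarray) -> dict[str, float]:
    if ga_weeks.size == 0:
        return {k: np.nan for k in _GA_STATS}
    return {
        "mean": float(np.mean(ga_weeks)),
        "sd": float(np.std(ga_weeks, ddof=1)) if ga_weeks.size > 1 else np.nan,
        "median": float(np.median(ga_weeks)),
        "q1": float(np.percentile(ga_weeks, 25)),
        "q3": float(np.percentile(ga_weeks, 75)),
        "min": float(np.min(ga_weeks)),
        "max": float(np.max(ga_weeks)),
    }


#: Reporting rows: top-level partition members and their subtypes.
_PREVALENCE_ROWS = (
    ("live_birth", ("full_term", "preterm")),
    ("full_term", ("full_term",)),
    ("preterm", ("preterm",)),
    ("stillbirth", ("stillbirth",)),
    ("abortion", ("spontaneous_abortion", "induced_abortion")),
    ("spontaneous_abortion", ("spontaneous_abortion",)),
    ("induced_abortion", ("induced_abortion",)),
)


def prevalence_table(
    episodes: Iterable[PregnancyEpisode], ci_method: str = "wilson"
) -> pd.DataFrame:
    """Outcome prevalence with binomial CIs and GA summaries (weeks).

    GA is reported in completed weeks (``ga_days // 7``).  Proportions
    are over all kept episodes; live birth aggregates full-term and
    preterm, abortion aggregates its two subtypes, so the top-level
    partition (live birth, stillbirth, abortion) sums to 100%.
    """
    kept = [e for e in episodes if e.status == "kept"]
    total = len(kept)
    rows = []
    for label, members in _PREVALENCE_ROWS:
        sub = [e for e in kept if e.outcome_type in members]
        count = len(sub)
        if total:
            prop = count / total
            lo, hi = proportion_confint(count, total, alpha=0.05, method=ci_method)
        else:
            prop = lo = hi = np.nan
        ga_weeks = np.array([e.ga_days // 7 for e in sub], dtype=float)
        rows.append(
            {
                "outcome": label,
                "count": count,
                "proportion": prop,
                "ci_low": lo,
                "ci_high": hi,
                **{f"ga_{k}_weeks": v for k, v in _ga_summary(ga_weeks).items()},
            }
        )
    return pd.DataFrame(rows).set_index("outcome")


def lmp_method_table(
    episodes: Iterable[PregnancyEpisode],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Cross-tabulate LMP-estimation method by final outcome type.

    Returns ``(counts, column_percentages)`` with the full method-row
    taxonomy and outcome columns always present, so structurally
    impossible cells appear as explicit zeros.
    """
    counts = pd.DataFrame(
        0, index=list(METHOD_LABELS), columns=list(FINAL_OUTCOME_TYPES), dtype=int
    )
    for e in episodes:
        if e.status == "kept":
            counts.loc[e.lmp_method, e.outcome_type] += 1
    colsum = counts.sum(axis=0)
    pct = 100.0 * counts.div(colsum.replace(0, np.nan), axis=1)
    return counts, pct.fillna(0.0)


def period_stratify(
    episodes: Iterable[PregnancyEpisode], cut_date: dt.date
) -> dict[str, list[PregnancyEpisode]]:
    """Split kept episodes into pre/post strata by LMP date."""
    strata: dict[str, list[PregnancyEpisode]] = {"pre": [], "post": []}
    for e in episodes:
        if e.status != "kept":
            continue
        assert e.lmp_date is not None
        strata["pre" if e.lmp_date < cut_date else "post"].append(e)
    return strata
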