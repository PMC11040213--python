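"""Synthetic claims with known ground-truth pregnancies and exposures.

The generator emulates the structure of a claims extract the episode
algorithm is designed for: women with zero or more pregnancies, an
outcome mix over the five final outcome classes, outcome-specific
gestational-age distributions, probabilistic emission of GA-informative
marker codes (with an era switch emulating a reimbursement expansion for
prenatal sonography), noise processes (duplicate claims, cross-coded
outcome claims, orphan claims), and drug-prescription streams with known
per-window counts.

Two conventions make ground truth exactly recoverable in the noise-free
setting and are deliberate idealisations:

* every GA-window marker claim is dated ``true_lmp + window midpoint``,
  so the midpoint-subtraction estimator reconstructs the true LMP
  exactly (unspecified-preterm claims are dated at the outcome);
* consecutive pregnancies of a woman are separated by the retry period
  plus at least 360 days, which keeps each pregnancy's claims outside
  both the marker-plausibility corridor and the exposure windows of its
  neighbours.

Orphan noise claims carry codes matching no codelist entry; a claim
carrying a real outcome code would constitute a true episode by
construction rather than noise.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, Field, model_validator
from scipy.stats import truncnorm

from .config import AlgorithmParams, CodeEntry, CodeMap
from .exposure import default_windows
from .records import ClaimRecord, Person

__all__ = [
    "GaDist",
    "NoiseSpec",
    "RxWindowSpec",
    "SyntheticScenario",
    "TrueEpisode",
    "SyntheticTruth",
    "GenerationError",
    "load_scenario",
    "generate_cohort",
    "emit_claims",
    "emit_prescriptions",
]

FINAL_TYPES = (
    "full_term",
    "preterm",
    "stillbirth",
    "spontaneous_abortion",
    "induced_abortion",
)

_BASE_OF = {
    "full_term": "delivery",
    "preterm": "delivery",
    "stillbirth": "stillbirth",
    "spontaneous_abortion": "abortion",
    "induced_abortion": "abortion",
}

#: marker categories a true episode of each final type may emit
_EMITTABLE = {
    "full_term": (
        "sonography_t1",
        "sonography_t1_targetscan",
        "sonography_t23",
        "sonography_t23_targetscan",
    ),
    "preterm": (
        "sonography_t1",
        "sonography_t1_targetscan",
        "sonography_t23",
        "sonography_t23_targetscan",
        "preterm_ga_specified",
        "preterm_ga_unspecified",
    ),
    "stillbirth": (
        "sonography_t1",
        "sonography_t1_targetscan",
        "sonography_t23",
        "sonography_t23_targetscan",
    ),
    "spontaneous_abortion": (
        "abortion_procedure",
        "sonography_t1",
        "sonography_t1_targetscan",
    ),
    "induced_abortion": (
        "abortion_procedure",
        "sonography_t1",
        "sonography_t1_targetscan",
    ),
}

_ORPHAN_CODES = ("Z000", "J069", "K297", "I109")


class GenerationError(RuntimeError):
    """The scenario could not be realised (e.g. pregnancies cannot fit)."""


class GaDist(BaseModel):
    """Truncated-normal gestational-age distribution, in days."""

    mean: float
    sd: float
    min: int
    max: int

    @model_validator(mode="after")
    def _check(self) -> "GaDist":
        if not (0 < self.min <= self.max):
            raise ValueError("GA support must satisfy 0 < min <= max")
        if self.sd <= 0:
            raise ValueError("sd must be positive")
        return self

    def sample(self, rng: np.random.Generator, size: int) -> np.ndarray:
        a = (self.min - self.mean) / self.sd
        b = (self.max - self.mean) / self.sd
        draws = truncnorm.rvs(a, b, loc=self.mean, scale=self.sd, size=size,
                              random_state=rng)
        return np.clip(np.rint(draws).astype(int), self.min, self.max)


class EraProb(BaseModel):
    """Emission probability before/after the era cut date."""

    pre: float = Field(ge=0.0, le=1.0)
    post: float = Field(ge=0.0, le=1.0)


class NoiseSpec(BaseModel):
    duplicate_claim_prob: float = Field(default=0.0, ge=0.0, le=1.0)
    cross_code_prob: float = Field(default=0.0, ge=0.0, le=1.0)
    orphan_claim_rate: float = Field(default=0.0, ge=0.0)


class RxWindowSpec(BaseModel):
    """Prescription emission for one exposure window."""

    count: int = Field(default=2, ge=1)
    prob: float = Field(default=1.0, ge=0.0, le=1.0)


def _default_mix() -> dict[str, float]:
    return {
        "full_term": 0.56,
        "preterm": 0.11,
        "stillbirth": 0.02,
        "spontaneous_abortion": 0.28,
        "induced_abortion": 0.03,
    }


def _default_ga() -> dict[str, GaDist]:
    return {
        "full_term": GaDist(mean=272, sd=7, min=259, max=294),
        "preterm": GaDist(mean=238, sd=21, min=140, max=258),
        "stillbirth": GaDist(mean=189, sd=17, min=140, max=238),
        "abortion": GaDist(mean=60, sd=17, min=21, max=140),
    }


def _default_emission() -> dict[str, EraProb]:
    return {
        "sonography_t1": EraProb(pre=0.10, post=0.65),
        "sonography_t1_targetscan": EraProb(pre=0.03, post=0.35),
        "sonography_t23": EraProb(pre=0.10, post=0.65),
        "sonography_t23_targetscan": EraProb(pre=0.05, post=0.45),
        "preterm_ga_specified": EraProb(pre=0.05, post=0.70),
        "preterm_ga_unspecified": EraProb(pre=0.35, post=0.25),
        "abortion_procedure": EraProb(pre=0.40, post=0.45),
    }


def _default_rx() -> dict[str, dict[str, RxWindowSpec]]:
    # Declining exposure trajectory from preconception into pregnancy,
    # shaped like reported drug-utilization curves for these classes.
    def spec(p: float) -> RxWindowSpec:
        return RxWindowSpec(count=2, prob=p)

    return {
        "drug_cyc_mmf_mtx": {
            "pre_q4": spec(0.076),
            "pre_q3": spec(0.060),
            "pre_q2": spec(0.050),
            "pre_q1": spec(0.036),
            "trimester1": spec(0.020),
            "trimester2": spec(0.006),
            "trimester3": spec(0.002),
        },
        "drug_nsaid": {
            "pre_q4": spec(0.212),
            "pre_q3": spec(0.180),
            "pre_q2": spec(0.150),
            "pre_q1": spec(0.120),
            "trimester1": spec(0.040),
            "trimester2": spec(0.020),
            "trimester3": spec(0.009),
        },
    }


class SyntheticScenario(BaseModel):
    """Full description of a synthetic cohort."""

    n_women: int = Field(default=500, ge=0)
    seed: int = 0
    pregnancy_rate: float = Field(default=1.65, ge=0.0)
    max_pregnancies: int = Field(default=6, ge=1)
    outcome_mix: dict[str, float] = Field(default_factory=_default_mix)
    ga_distributions: dict[str, GaDist] = Field(default_factory=_default_ga)
    marker_emission_probs: dict[str, EraProb] = Field(default_factory=_default_emission)
    era_cut: dt.date = dt.date(2016, 1, 1)
    noise: NoiseSpec = Field(default_factory=NoiseSpec)
    rx_scenario: dict[str, dict[str, RxWindowSpec]] = Field(default_factory=_default_rx)
    observation_start: dt.date = dt.date(2003, 1, 1)
    observation_end: dt.date = dt.date(2018, 12, 31)
    lmp_start: dt.date = dt.date(2005, 7, 1)
    lmp_end: dt.date = dt.date(2017, 6, 30)
    min_gap_extra_days: int = Field(default=360, ge=0)
    max_gap_extra_days: int = Field(default=720, ge=0)

    @model_validator(mode="after")
    def _check(self) -> "SyntheticScenario":
        if set(self.outcome_mix) != set(FINAL_TYPES):
            raise ValueError("outcome_mix must cover the five outcome classes")
        if abs(sum(self.outcome_mix.values()) - 1.0) > 1e-9:
            raise ValueError("outcome_mix must sum to 1")
        if set(self.ga_distributions) != {"full_term", "preterm", "stillbirth", "abortion"}:
            raise ValueError("ga_distributions must cover full_term/preterm/stillbirth/abortion")
        if self.min_gap_extra_days > self.max_gap_extra_days:
            raise ValueError("min_gap_extra_days must not exceed max_gap_extra_days")
        if self.lmp_start >= self.lmp_end:
            raise ValueError("lmp_start must precede lmp_end")
        return self

    def ga_dist_for(self, final_type: str) -> GaDist:
        key = "abortion" if final_type.endswith("abortion") else final_type
        return self.ga_distributions[key]


def load_scenario(path: str | Path) -> SyntheticScenario:
    raw = yaml.safe_load(Path(path).read_text())
    return SyntheticScenario(**(raw or {}))


@dataclass
class TrueEpisode:
    """Ground truth for one pregnancy.

    ``emitted_markers`` and ``injected_crosscode`` are filled in by
    :func:`emit_claims`; ``rx_counts`` by :func:`emit_prescriptions`.
    """

    person_id: str
    true_lmp: dt.date
    true_outcome_date: dt.date
    true_outcome_type: str
    emitted_markers: tuple[str, ...] = ()
    injected_crosscode: Optional[str] = None

    @property
    def base_outcome(self) -> str:
        return _BASE_OF[self.true_outcome_type]

    @property
    def true_ga_days(self) -> int:
        return (self.true_outcome_date - self.true_lmp).days


@dataclass
class TrueExposure:
    person_id: str
    outcome_date: dt.date
    drug_class: str
    window: str
    n_prescriptions: int


@dataclass
class SyntheticTruth:
    episodes: list[TrueEpisode] = field(default_factory=list)
    exposures: list[TrueExposure] = field(default_factory=list)

    def episodes_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "person_id": e.person_id,
                    "true_lmp": e.true_lmp.isoformat(),
                    "true_outcome_date": e.true_outcome_date.isoformat(),
                    "true_outcome_type": e.true_outcome_type,
                    "true_ga_days": e.true_ga_days,
                    "emitted_markers": ";".join(e.emitted_markers),
                    "injected_crosscode": e.injected_crosscode or "",
                }
                for e in self.episodes
            ],
            columns=[
                "person_id",
                "true_lmp",
                "true_outcome_date",
                "true_outcome_type",
                "true_ga_days",
                "emitted_markers",
                "injected_crosscode",
            ],
        )

    def exposures_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "person_id": x.person_id,
                    "outcome_date": x.outcome_date.isoformat(),
                    "drug_class": x.drug_class,
                    "window": x.window,
                    "n_prescriptions": x.n_prescriptions,
                }
                for x in self.exposures
            ],
            columns=["person_id", "outcome_date", "drug_class", "window", "n_prescriptions"],
        )

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.episodes_frame().to_csv(out / "truth_episodes.csv", index=False)
        self.exposures_frame().to_csv(out / "truth_exposures.csv", index=False)


# ---------------------------------------------------------------------------
# cohort generation


def generate_cohort(
    scenario: SyntheticScenario, params: AlgorithmParams
) -> tuple[list[Person], SyntheticTruth]:
    """Draw women and their true pregnancy episodes.

    Deterministic given ``scenario.seed``.  Episode gestational ages are
    validated against the algorithm's per-type GA bounds so a noise-free
    run can never exclude a true episode on plausibility grounds.
    """
    for key, dist in scenario.ga_distributions.items():
        lo, hi = params.ga_bounds_days[key]
        if dist.min < lo or dist.max > hi:
            raise GenerationError(
                f"GA distribution for {key} ({dist.min}-{dist.max}) outside "
                f"algorithm bounds ({lo}-{hi})"
            )

    rng = np.random.default_rng([scenario.seed, 0])
    mix_types = list(FINAL_TYPES)
    mix_probs = np.array([scenario.outcome_mix[t] for t in mix_types])
    persons: list[Person] = []
    truth = SyntheticTruth()

    lmp_span = (scenario.lmp_end - scenario.lmp_start).days
    retry = params.retry_period_days

    for i in range(scenario.n_women):
        pid = f"W{i:05d}"
        k = int(min(rng.poisson(scenario.pregnancy_rate), scenario.max_pregnancies))
        if k == 0:
            age_days = int(rng.integers(20 * 365, 40 * 365))
            birth = dt.date(2010, 6, 1) - dt.timedelta(days=age_days)
            persons.append(
                Person(pid, birth, "F", scenario.observation_start, scenario.observation_end)
            )
            continue

        placed = None
        for attempt in range(12):
            types = [mix_types[j] for j in rng.choice(len(mix_types), size=k, p=mix_probs)]
            gas = [int(scenario.ga_dist_for(t).sample(rng, 1)[0]) for t in types]
            if attempt < 10:
                gaps = rng.integers(
                    scenario.min_gap_extra_days, scenario.max_gap_extra_days + 1, size=k
                )
            else:  # fall back to the tightest admissible packing
                gaps = np.full(k, scenario.min_gap_extra_days)
            lmp_off = []
            out_off = []
            cursor = 0
            for j in range(k):
                if j > 0:
                    cursor = out_off[j - 1] + retry + int(gaps[j])
                lmp_off.append(cursor)
                out_off.append(cursor + gas[j])
            last_lmp = lmp_off[-1]
            last_out = out_off[-1]
            latest_start = min(
                lmp_span - last_lmp,
                (scenario.observation_end - scenario.lmp_start).days - last_out - 30,
            )
            if latest_start < 0:
                continue
            start_off = int(rng.integers(0, latest_start + 1))
            lmp0 = scenario.lmp_start + dt.timedelta(days=start_off)
            placed = [
                (
                    lmp0 + dt.timedelta(days=lmp_off[j] ),
                    lmp0 + dt.timedelta(days=out_off[j]),
                    types[j],
                )
                for j in range(k)
            ]
            break
        if placed is None:
            raise GenerationError(
                f"could not place {k} pregnancies for {pid}; "
                "scenario is infeasible (pregnancy_rate too high for the span)"
            )

        age_years = int(rng.integers(18, 36))
        birth = placed[0][0] - dt.timedelta(days=age_years * 365 + int(rng.integers(0, 365)))
        persons.append(
            Person(pid, birth, "F", scenario.observation_start, scenario.observation_end)
        )
        for lmp, outcome, ftype in placed:
            truth.episodes.append(
                TrueEpisode(
                    person_id=pid,
                    true_lmp=lmp,
                    true_outcome_date=outcome,
                    true_outcome_type=ftype,
                )
            )
    return persons, truth


# ---------------------------------------------------------------------------
# claim emission


def _entries(codemap: CodeMap, category: str) -> tuple[CodeEntry, ...]:
    entries = codemap.entries_for(category)
    if not entries:
        raise ValueError(f"codemap has no entry for required category {category!r}")
    return entries


def _valid_at(entry: CodeEntry, date: dt.date) -> bool:
    if entry.valid_from is not None and date < entry.valid_from:
        return False
    if entry.valid_to is not None and date > entry.valid_to:
        return False
    return True


def _pick_entry(rng: np.random.Generator, entries: list[CodeEntry]) -> CodeEntry:
    return entries[int(rng.integers(0, len(entries)))]


def emit_claims(
    truth: SyntheticTruth,
    codemap: CodeMap,
    scenario: SyntheticScenario,
) -> list[ClaimRecord]:
    """Emit diagnosis/procedure claims for all true episodes.

    Fills ``emitted_markers`` / ``injected_crosscode`` on the truth
    episodes as a side effect.  Deterministic given the scenario seed.
    """
    rng = np.random.default_rng([scenario.seed, 1])
    claims: list[ClaimRecord] = []

    # codes asserting abortion without implying induced abortion
    plain_abortion = [
        e
        for e in _entries(codemap, "abortion_diagnosis")
        if "induced_abortion_marker" not in codemap.classify(e.pattern, "diagnosis")
    ]
    if not plain_abortion:
        raise ValueError("codemap needs an abortion_diagnosis code that is not an induced marker")

    for ep in truth.episodes:
        ep_claims: list[ClaimRecord] = []
        outcome, lmp, ga = ep.true_outcome_date, ep.true_lmp, ep.true_ga_days
        base = ep.base_outcome

        # outcome-asserting claim(s)
        if base == "delivery":
            entry = _pick_entry(rng, list(_entries(codemap, "delivery_procedure")))
            ep_claims.append(ClaimRecord(ep.person_id, outcome, entry.pattern, "procedure"))
        elif base == "stillbirth":
            entry = _pick_entry(rng, list(_entries(codemap, "stillbirth_diagnosis")))
            ep_claims.append(ClaimRecord(ep.person_id, outcome, entry.pattern, "diagnosis"))
        else:
            entry = _pick_entry(rng, plain_abortion)
            ep_claims.append(ClaimRecord(ep.person_id, outcome, entry.pattern, "diagnosis"))
            if ep.true_outcome_type == "induced_abortion":
                ind = _pick_entry(rng, list(_entries(codemap, "induced_abortion_marker")))
                ep_claims.append(ClaimRecord(ep.person_id, outcome, ind.pattern, ind.system))

        # GA-informative markers, dated lmp + window midpoint
        era = "pre" if outcome < scenario.era_cut else "post"
        emitted = []
        for category in _EMITTABLE[ep.true_outcome_type]:
            prob_spec = scenario.marker_emission_probs.get(category)
            if prob_spec is None:
                continue
            prob = getattr(prob_spec, era)
            if prob <= 0.0 or rng.random() >= prob:
                continue
            if category == "preterm_ga_unspecified":
                candidates = [
                    e
                    for e in codemap.entries_for(category)
                    if _valid_at(e, outcome)
                ]
                if not candidates:
                    continue
                entry = _pick_entry(rng, candidates)
                ep_claims.append(
                    ClaimRecord(ep.person_id, outcome, entry.pattern, "diagnosis")
                )
                emitted.append(category)
                continue
            candidates = []
            for e in codemap.entries_for(category):
                mid = e.midpoint_days
                if mid is None or mid >= ga:
                    continue  # claim would postdate the outcome
                if _valid_at(e, lmp + dt.timedelta(days=mid)):
                    candidates.append(e)
            if not candidates:
                continue
            # prefer the narrowest code whose window covers the true GA
            covering = [
                e
                for e in candidates
                if e.ga_window_days[0] <= ga <= e.ga_window_days[1]
            ]
            pool = covering or candidates
            entry = max(pool, key=lambda e: e.midpoint_days)
            claim_date = lmp + dt.timedelta(days=entry.midpoint_days)
            ep_claims.append(
                ClaimRecord(ep.person_id, claim_date, entry.pattern, entry.system)
            )
            emitted.append(category)
        ep.emitted_markers = tuple(emitted)

        # cross-coded lower-rank outcome claim (labelled noise)
        if base in ("delivery", "stillbirth") and rng.random() < scenario.noise.cross_code_prob:
            if base == "stillbirth" and rng.random() < 0.5:
                inj_entry = _pick_entry(rng, list(_entries(codemap, "delivery_procedure")))
                inj_type, system = "delivery", "procedure"
            else:
                inj_entry = _pick_entry(rng, plain_abortion)
                inj_type, system = "abortion", "diagnosis"
            inj_date = outcome + dt.timedelta(days=int(rng.integers(0, 15)))
            ep_claims.append(ClaimRecord(ep.person_id, inj_date, inj_entry.pattern, system))
            ep.injected_crosscode = inj_type

        claims.extend(ep_claims)

    # orphan claims: codes the codelist does not know
    if scenario.noise.orphan_claim_rate > 0:
        persons = sorted({e.person_id for e in truth.episodes})
        span = (scenario.observation_end - scenario.observation_start).days
        for pid in persons:
            for _ in range(int(rng.poisson(scenario.noise.orphan_claim_rate))):
                code = _ORPHAN_CODES[int(rng.integers(0, len(_ORPHAN_CODES)))]
                date = scenario.observation_start + dt.timedelta(
                    days=int(rng.integers(0, span + 1))
                )
                claims.append(ClaimRecord(pid, date, code, "diagnosis"))

    # duplicate-claim noise
    if scenario.noise.duplicate_claim_prob > 0:
        dups = [c for c in claims if rng.random() < scenario.noise.duplicate_claim_prob]
        claims.extend(dups)

    claims.sort(key=lambda c: (c.person_id, c.service_date, c.code, c.system))
    return claims


def emit_prescriptions(
    truth: SyntheticTruth,
    scenario: SyntheticScenario,
    codemap: CodeMap,
    params: AlgorithmParams,
) -> list[ClaimRecord]:
    """Emit drug claims per the rx scenario; record true per-window counts.

    Prescription dates are uniform within the designated window (capped
    at the outcome for pregnancy windows); windows the episode does not
    reach are skipped.  Appends to ``truth.exposures``.
    """
    rng = np.random.default_rng([scenario.seed, 2])
    windows = {w.label: w for w in default_windows(params)}
    for drug_class, per_window in scenario.rx_scenario.items():
        for label in per_window:
            if label not in windows:
                raise ValueError(f"rx_scenario window {label!r} is not a defined bin")
        _entries(codemap, drug_class)

    claims: list[ClaimRecord] = []
    for ep in truth.episodes:
        ga = ep.true_ga_days
        for drug_class, per_window in scenario.rx_scenario.items():
            entries = list(_entries(codemap, drug_class))
            for label, spec in per_window.items():
                w = windows[label]
                start = w.start_offset_days
                if start >= 0:  # pregnancy window: cap at the outcome
                    if ga <= start:
                        continue  # never reached
                    end = ga + 1 if w.end_offset_days is None else min(w.end_offset_days, ga + 1)
                else:
                    end = w.end_offset_days
                if rng.random() >= spec.prob:
                    continue
                offsets = rng.integers(start, end, size=spec.count)
                for off in offsets:
                    entry = _pick_entry(rng, entries)
                    claims.append(
                        ClaimRecord(
                            ep.person_id,
                            ep.true_lmp + dt.timedelta(days=int(off)),
                            entry.pattern,
                            "drug",
                            quantity=1,
                        )
                    )
                truth.exposures.append(
                    TrueExposure(
                        person_id=ep.person_id,
                        outcome_date=ep.true_outcome_date,
                        drug_class=drug_class,
                        window=label,
                        n_prescriptions=spec.count,
                    )
                )
    claims.sort(key=lambda c: (c.person_id, c.service_date, c.code, c.system))
    return claims
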