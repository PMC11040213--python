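"""Codelists and algorithm parameters.

Everything the episode algorithm does is driven by two configuration
artifacts:

* a **codelist** (CSV) mapping code *prefixes* to semantic categories —
  which procedure codes mean delivery, which diagnosis prefixes mean
  abortion, which sonography codes imply a gestational-age window, and
  which drug codes belong to each analysed drug class;
* an **AlgorithmParams** object (YAML) holding every tunable the episode
  algorithm uses: the outcome hierarchy, clustering gaps, the retry
  period, fixed gestational-age fallbacks, GA plausibility bounds, and
  the exposure window grid.

Codes are matched by normalized prefix (dots stripped, upper-cased), the
standard convention for ICD-family claims extracts.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Optional

import pandas as pd
import yaml
from pydantic import BaseModel, Field, field_validator, model_validator

__all__ = [
    "CATEGORIES",
    "GA_WINDOW_CATEGORIES",
    "MARKER_CATEGORIES",
    "CodeEntry",
    "CodeMap",
    "AlgorithmParams",
    "load_codemap",
    "load_params",
    "classify_code",
    "normalize_code",
    "default_codelist_path",
    "default_params",
]

System = Literal["diagnosis", "procedure", "drug"]
Outcome = Literal["delivery", "stillbirth", "abortion"]

#: All recognised code categories.
CATEGORIES = frozenset(
    {
        "delivery_procedure",
        "stillbirth_diagnosis",
        "abortion_diagnosis",
        "induced_abortion_marker",
        "sonography_t1",
        "sonography_t1_targetscan",
        "sonography_t23",
        "sonography_t23_targetscan",
        "preterm_ga_specified",
        "preterm_ga_unspecified",
        "abortion_procedure",
        "drug_cyc_mmf_mtx",
        "drug_nsaid",
    }
)

#: Categories that carry an explicit gestational-age window (days since
#: LMP the code implies).  ``preterm_ga_unspecified`` is GA-informative
#: too, but its implied GA is the fixed 35-week parameter, not a
#: code-level window, so it carries none.
GA_WINDOW_CATEGORIES = frozenset(
    {
        "sonography_t1",
        "sonography_t1_targetscan",
        "sonography_t23",
        "sonography_t23_targetscan",
        "preterm_ga_specified",
        "abortion_procedure",
    }
)

#: Categories usable as LMP markers.
MARKER_CATEGORIES = GA_WINDOW_CATEGORIES | {"preterm_ga_unspecified"}

#: Which claim systems a category may be coded in.
_CATEGORY_SYSTEMS: dict[str, frozenset] = {
    "delivery_procedure": frozenset({"procedure"}),
    "stillbirth_diagnosis": frozenset({"diagnosis"}),
    "abortion_diagnosis": frozenset({"diagnosis"}),
    "induced_abortion_marker": frozenset({"diagnosis", "procedure"}),
    "sonography_t1": frozenset({"procedure"}),
    "sonography_t1_targetscan": frozenset({"procedure"}),
    "sonography_t23": frozenset({"procedure"}),
    "sonography_t23_targetscan": frozenset({"procedure"}),
    "preterm_ga_specified": frozenset({"diagnosis"}),
    "preterm_ga_unspecified": frozenset({"diagnosis"}),
    "abortion_procedure": frozenset({"procedure"}),
    "drug_cyc_mmf_mtx": frozenset({"drug"}),
    "drug_nsaid": frozenset({"drug"}),
}


def normalize_code(code: str) -> str:
    """Normalize a claims code: strip whitespace and dots, upper-case."""
    return code.strip().replace(".", "").upper()


class CodeEntry(BaseModel):
    """One code-prefix -> category mapping."""

    pattern: str
    system: System
    category: str
    ga_window_days: Optional[tuple[int, int]] = None
    valid_from: Optional[dt.date] = None
    valid_to: Optional[dt.date] = None

    @field_validator("pattern")
    @classmethod
    def _pattern_nonempty(cls, v: str) -> str:
        v = normalize_code(v)
        if not v:
            raise ValueError("pattern must be non-empty")
        return v

    @model_validator(mode="after")
    def _check(self) -> "CodeEntry":
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown category {self.category!r}")
        if self.system not in _CATEGORY_SYSTEMS[self.category]:
            raise ValueError(
                f"category {self.category!r} cannot be coded in system {self.system!r}"
            )
        if self.category in GA_WINDOW_CATEGORIES:
            if self.ga_window_days is None:
                raise ValueError(
                    f"category {self.category!r} requires ga_window_days"
                )
            lo, hi = self.ga_window_days
            if not (0 <= lo <= hi):
                raise ValueError("ga_window_days must satisfy 0 <= min <= max")
        elif self.ga_window_days is not None:
            raise ValueError(
                f"ga_window_days not allowed for category {self.category!r}"
            )
        if (
            self.valid_from is not None
            and self.valid_to is not None
            and self.valid_from > self.valid_to
        ):
            raise ValueError("valid_from must not exceed valid_to")
        return self

    @property
    def midpoint_days(self) -> Optional[int]:
        """Integer midpoint of the GA window (floor of the mean)."""
        if self.ga_window_days is None:
            return None
        lo, hi = self.ga_window_days
        return (lo + hi) // 2


@dataclass(frozen=True)
class CodeMap:
    """Category-indexed collection of :class:`CodeEntry`."""

    entries: tuple[CodeEntry, ...]
    _by_category: dict[str, tuple[CodeEntry, ...]] = field(
        init=False, repr=False, compare=False, default_factory=dict
    )

    def __post_init__(self) -> None:
        by_cat: dict[str, list[CodeEntry]] = {}
        for e in self.entries:
            by_cat.setdefault(e.category, []).append(e)
        object.__setattr__(
            self, "_by_category", {k: tuple(v) for k, v in by_cat.items()}
        )

    def entries_for(self, category: str) -> tuple[CodeEntry, ...]:
        return self._by_category.get(category, ())

    def categories(self) -> frozenset:
        return frozenset(self._by_category)

    def classify(self, code: str, system: str) -> set[str]:
        """All categories whose pattern prefixes ``code`` in ``system``.

        Every matching entry contributes; longer prefixes do not shadow
        shorter ones.
        """
        norm = normalize_code(code)
        return {
            e.category
            for e in self.entries
            if e.system == system and norm.startswith(e.pattern)
        }

    def matching_entries(self, code: str, system: str) -> list[CodeEntry]:
        norm = normalize_code(code)
        return [
            e
            for e in self.entries
            if e.system == system and norm.startswith(e.pattern)
        ]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for e in self.entries:
            lo, hi = e.ga_window_days if e.ga_window_days else (None, None)
            rows.append(
                {
                    "pattern": e.pattern,
                    "system": e.system,
                    "category": e.category,
                    "ga_min_days": lo,
                    "ga_max_days": hi,
                    "valid_from": e.valid_from.isoformat() if e.valid_from else None,
                    "valid_to": e.valid_to.isoformat() if e.valid_to else None,
                }
            )
        return pd.DataFrame(
            rows,
            columns=[
                "pattern",
                "system",
                "category",
                "ga_min_days",
                "ga_max_days",
                "valid_from",
                "valid_to",
            ],
        )

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


def classify_code(code: str, system: str, codemap: CodeMap) -> set[str]:
    """Functional alias for :meth:`CodeMap.classify`."""
    return codemap.classify(code, system)


def load_codemap(codelist_file: str | Path) -> CodeMap:
    """Load a codelist CSV into a validated :class:`CodeMap`.

    Expected header: ``pattern,system,category,ga_min_days,ga_max_days,
    valid_from,valid_to`` (the last four optional per row).
    """
    path = Path(codelist_file)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, dtype={"pattern": str})
    required = {"pattern", "system", "category"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"codelist missing columns: {sorted(missing)}")
    entries = []
    for i, row in df.iterrows():
        window = None
        lo, hi = row.get("ga_min_days"), row.get("ga_max_days")
        if pd.notna(lo) or pd.notna(hi):
            if pd.isna(lo) or pd.isna(hi):
                raise ValueError(
                    f"codelist row {i}: ga_min_days/ga_max_days must both be set"
                )
            window = (int(lo), int(hi))

        def _date(v):
            return dt.date.fromisoformat(str(v)) if pd.notna(v) else None

        try:
            entries.append(
                CodeEntry(
                    pattern=str(row["pattern"]),
                    system=str(row["system"]),
                    category=str(row["category"]),
                    ga_window_days=window,
                    valid_from=_date(row.get("valid_from")),
                    valid_to=_date(row.get("valid_to")),
                )
            )
        except Exception as exc:  # re-raise with row context
            raise ValueError(f"codelist row {i}: {exc}") from exc
    return CodeMap(entries=tuple(entries))


# ---------------------------------------------------------------------------
# Algorithm parameters


class AlgorithmParams(BaseModel):
    """Every tunable of the episode algorithm.

    Day constants mirror the published rule set: fixed LMP subtraction of
    39/28/10 weeks by outcome, 35 weeks for unspecified preterm, the
    37-week preterm split, 42-week maximum and 20-week delivery minimum.
    Clustering gaps and the retry period default to values from the
    hierarchy-algorithm family this design descends from and are meant to
    be overridden per data dialect.
    """

    hierarchy: tuple[Outcome, Outcome, Outcome] = ("stillbirth", "delivery", "abortion")
    same_episode_gap_days: dict[Outcome, int] = Field(
        default_factory=lambda: {"delivery": 168, "stillbirth": 168, "abortion": 56}
    )
    cross_outcome_conflict_days: dict[str, int] = Field(default_factory=dict)
    retry_period_days: int = 28
    outcome_specific_ga_days: dict[Outcome, int] = Field(
        default_factory=lambda: {"delivery": 273, "stillbirth": 196, "abortion": 70}
    )
    unspecified_preterm_ga_days: int = 245
    ga_bounds_days: dict[str, tuple[int, int]] = Field(
        default_factory=lambda: {
            "full_term": (259, 294),
            "preterm": (140, 258),
            "stillbirth": (140, 294),
            "abortion": (21, 140),
        }
    )
    preterm_cutoff_days: int = 259
    max_ga_days: int = 294
    min_delivery_ga_days: int = 140
    stillbirth_reclass_cutoff_days: int = 140
    max_abortion_ga_days: int = 140
    childbearing_age: tuple[int, int] = (12, 49)
    trimester_bounds_days: tuple[tuple[int, Optional[int]], ...] = (
        (0, 98),
        (98, 196),
        (196, None),
    )
    preconception_quarters_days: tuple[tuple[int, int], ...] = (
        (-360, -270),
        (-270, -180),
        (-180, -90),
        (-90, 0),
    )
    early_pregnancy_window_days: tuple[int, int] = (0, 49)
    exposure_min_prescriptions: int = 2
    ci_method: str = "wilson"
    tier_strict: bool = True
    retry_trigger: Literal["strict", "separated"] = "separated"

    @model_validator(mode="after")
    def _check(self) -> "AlgorithmParams":
        if sorted(self.hierarchy) != ["abortion", "delivery", "stillbirth"]:
            raise ValueError(
                "hierarchy must be a permutation of stillbirth/delivery/abortion"
            )
        for name in (
            "retry_period_days",
            "unspecified_preterm_ga_days",
            "preterm_cutoff_days",
            "max_ga_days",
            "min_delivery_ga_days",
            "stillbirth_reclass_cutoff_days",
            "max_abortion_ga_days",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if set(self.same_episode_gap_days) != {"delivery", "stillbirth", "abortion"}:
            raise ValueError("same_episode_gap_days must cover all three outcomes")
        if any(v <= 0 for v in self.same_episode_gap_days.values()):
            raise ValueError("same_episode_gap_days must be positive")
        if set(self.outcome_specific_ga_days) != {"delivery", "stillbirth", "abortion"}:
            raise ValueError("outcome_specific_ga_days must cover all three outcomes")
        if any(v <= 0 for v in self.outcome_specific_ga_days.values()):
            raise ValueError("outcome_specific_ga_days must be positive")
        lo, hi = self.childbearing_age
        if not (0 <= lo <= hi):
            raise ValueError("childbearing_age must satisfy 0 <= min <= max")
        # trimester intervals: disjoint, ordered, starting at 0
        prev_end = 0
        for i, (s, e) in enumerate(self.trimester_bounds_days):
            if i == 0 and s != 0:
                raise ValueError("trimester intervals must start at 0")
            if s != prev_end:
                raise ValueError("trimester intervals must be contiguous and ordered")
            if e is not None and e <= s:
                raise ValueError("trimester interval end must exceed start")
            prev_end = e if e is not None else None
            if prev_end is None and i != len(self.trimester_bounds_days) - 1:
                raise ValueError("only the last trimester may be open-ended")
        for s, e in self.preconception_quarters_days:
            if s >= e:
                raise ValueError("preconception quarter start must precede end")
        if self.exposure_min_prescriptions < 1:
            raise ValueError("exposure_min_prescriptions must be >= 1")
        return self

    def conflict_days(self, a: str, b: str) -> int:
        """Cross-outcome conflict window between outcome types ``a``, ``b``.

        Defaults to the smaller of the two same-episode gaps when no
        explicit pair override (``"a|b"``) is configured.
        """
        key = "|".join(sorted((a, b)))
        if key in self.cross_outcome_conflict_days:
            return self.cross_outcome_conflict_days[key]
        return min(self.same_episode_gap_days[a], self.same_episode_gap_days[b])

    def rank(self, outcome: str) -> int:
        """Hierarchy rank (0 = highest priority)."""
        return self.hierarchy.index(outcome)

    def to_yaml(self, path: str | Path) -> None:
        data = self.model_dump(mode="json")
        Path(path).write_text(yaml.safe_dump(data, sort_keys=True))


def default_params() -> AlgorithmParams:
    return AlgorithmParams()


def load_params(params_file: str | Path | None = None) -> AlgorithmParams:
    """Load algorithm parameters from YAML; missing fields take defaults."""
    if params_file is None:
        return AlgorithmParams()
    raw = yaml.safe_load(Path(params_file).read_text())
    if raw is None:
        return AlgorithmParams()
    if not isinstance(raw, dict):
        raise ValueError("params file must contain a mapping")
    return AlgorithmParams(**raw)


def default_codelist_path() -> Path:
    """Path of the placeholder codelist shipped with the package."""
    return Path(__file__).parent / "data" / "default_codelist.csv"


# defaults must satisfy their own invariants
_ = AlgorithmParams()
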