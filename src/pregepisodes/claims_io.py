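"""Tabular I/O for claims, persons and episode artifacts.

CSV is the canonical interchange format; schemas are strict and reads
are deterministic (ties broken by code, then system).  Dates are
ISO-8601 calendar dates throughout.
"""

from __future__ import annotations

import datetime as dt
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .records import ClaimRecord, Person, PregnancyEpisode

__all__ = [
    "read_claims",
    "write_claims",
    "read_persons",
    "write_persons",
    "read_episodes",
    "write_episodes",
]

_CLAIM_COLUMNS = ["person_id", "service_date", "code", "system", "quantity"]
_PERSON_COLUMNS = [
    "person_id",
    "birth_date",
    "sex",
    "observation_start",
    "observation_end",
]
_EPISODE_COLUMNS = [
    "person_id",
    "lmp_date",
    "outcome_date",
    "outcome_type",
    "ga_days",
    "lmp_method",
    "status",
    "era_year",
    "reclassified_from",
    "lmp_adjusted_by_retry",
]


class SchemaError(ValueError):
    """A file is missing required columns."""


def _require_columns(df: pd.DataFrame, required: Sequence[str], what: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{what} file missing columns: {missing}")


def _parse_date(value, what: str, line: int) -> dt.date:
    try:
        return dt.date.fromisoformat(str(value))
    except ValueError as exc:
        raise ValueError(f"{what} line {line}: unparseable date {value!r}") from exc


def read_claims(path: str | Path) -> list[ClaimRecord]:
    """Read a claims CSV into records sorted by (person, date, code, system).

    Exact duplicates are retained — de-duplication is an algorithm
    concern, not an I/O one.
    """
    df = pd.read_csv(path, dtype={"person_id": str, "code": str, "system": str})
    _require_columns(df, ["person_id", "service_date", "code", "system"], "claims")
    records = []
    for i, row in enumerate(df.itertuples(index=False), start=2):
        quantity = getattr(row, "quantity", None)
        if quantity is not None and pd.isna(quantity):
            quantity = None
        records.append(
            ClaimRecord(
                person_id=str(row.person_id),
                service_date=_parse_date(row.service_date, "claims", i),
                code=str(row.code),
                system=str(row.system),
                quantity=int(quantity) if quantity is not None else None,
            )
        )
    records.sort(
        key=lambda r: (r.person_id, r.service_date, r.code, r.system)
    )
    return records


def write_claims(claims: Iterable[ClaimRecord], path: str | Path) -> None:
    df = pd.DataFrame(
        [
            {
                "person_id": c.person_id,
                "service_date": c.service_date.isoformat(),
                "code": c.code,
                "system": c.system,
                "quantity": c.quantity,
            }
            for c in claims
        ],
        columns=_CLAIM_COLUMNS,
    )
    df.to_csv(path, index=False)


def read_persons(path: str | Path) -> list[Person]:
    df = pd.read_csv(path, dtype={"person_id": str, "sex": str})
    _require_columns(df, _PERSON_COLUMNS, "persons")
    persons = []
    for i, row in enumerate(df.itertuples(index=False), start=2):
        persons.append(
            Person(
                person_id=str(row.person_id),
                birth_date=_parse_date(row.birth_date, "persons", i),
                sex=str(row.sex),
                observation_start=_parse_date(row.observation_start, "persons", i),
                observation_end=_parse_date(row.observation_end, "persons", i),
            )
        )
    persons.sort(key=lambda p: p.person_id)
    return persons


def write_persons(persons: Iterable[Person], path: str | Path) -> None:
    df = pd.DataFrame(
        [
            {
                "person_id": p.person_id,
                "birth_date": p.birth_date.isoformat(),
                "sex": p.sex,
                "observation_start": p.observation_start.isoformat(),
                "observation_end": p.observation_end.isoformat(),
            }
            for p in persons
        ],
        columns=_PERSON_COLUMNS,
    )
    df.to_csv(path, index=False)


def write_episodes(episodes: Iterable[PregnancyEpisode], path: str | Path) -> None:
    """Write finalized episodes, one row each; read-back equals input."""
    rows = []
    for e in episodes:
        if e.lmp_date is None:
            raise ValueError(
                f"episode {e.person_id}/{e.outcome_date} not finalized (no LMP)"
            )
        rows.append(
            {
                "person_id": e.person_id,
                "lmp_date": e.lmp_date.isoformat(),
                "outcome_date": e.outcome_date.isoformat(),
                "outcome_type": e.outcome_type,
                "ga_days": e.ga_days,
                "lmp_method": e.lmp_method,
                "status": e.status,
                "era_year": e.era_year,
                "reclassified_from": e.reclassified_from,
                "lmp_adjusted_by_retry": e.lmp_adjusted_by_retry,
            }
        )
    pd.DataFrame(rows, columns=_EPISODE_COLUMNS).to_csv(path, index=False)


def read_episodes(path: str | Path) -> list[PregnancyEpisode]:
    df = pd.read_csv(
        path,
        dtype={"person_id": str, "outcome_type": str, "status": str},
    )
    _require_columns(df, _EPISODE_COLUMNS[:8], "episodes")
    episodes = []
    for i, row in enumerate(df.itertuples(index=False), start=2):
        reclass = getattr(row, "reclassified_from", None)
        if reclass is not None and pd.isna(reclass):
            reclass = None
        method = row.lmp_method if pd.notna(row.lmp_method) else None
        episodes.append(
            PregnancyEpisode(
                person_id=str(row.person_id),
                lmp_date=_parse_date(row.lmp_date, "episodes", i),
                outcome_date=_parse_date(row.outcome_date, "episodes", i),
                outcome_type=str(row.outcome_type),
                ga_days=int(row.ga_days),
                lmp_method=method,
                status=str(row.status),
                reclassified_from=reclass,
                lmp_adjusted_by_retry=bool(row.lmp_adjusted_by_retry),
            )
        )
    return episodes
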