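"""End-to-end orchestration: detect -> cluster -> resolve -> estimate -> refine -> report."""

from __future__ import annotations

import datetime as dt
import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional

from . import __version__
from .claims_io import (
    read_claims,
    read_persons,
    write_claims,
    write_episodes,
    write_persons,
)
from .config import AlgorithmParams, CodeMap, load_codemap, load_params
from .detection import detect_events, filter_childbearing_age
from .episodes import cluster_events, resolve_hierarchy
from .exposure import (
    assess_exposure,
    default_windows,
    exposure_trajectory,
    lmp_method_table,
    period_stratify,
    prevalence_table,
)
from .lmp import collect_markers, estimate_lmp
from .records import ClaimRecord, Person, PregnancyEpisode
from .refinement import refine_episodes
from .synthetic import (
    SyntheticScenario,
    emit_claims,
    emit_prescriptions,
    generate_cohort,
    load_scenario,
)

__all__ = ["RunManifest", "run_pipeline", "run_pipeline_data", "simulate"]


@dataclass
class RunManifest:
    """Reproducibility record of one pipeline run."""

    tool_version: str
    inputs: dict[str, str] = field(default_factory=dict)  # path -> sha256
    counts: dict[str, int] = field(default_factory=dict)
    seed: Optional[int] = None

    def reconciles(self) -> bool:
        c = self.counts
        return c.get("episodes_kept", 0) + c.get("episodes_eliminated", 0) + c.get(
            "episodes_excluded", 0
        ) == c.get("episodes_clustered", 0)

    def write(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2, default=str))


def _sha256(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def run_pipeline_data(
    claims: list[ClaimRecord],
    persons: list[Person],
    codemap: CodeMap,
    params: AlgorithmParams,
) -> tuple[list[PregnancyEpisode], RunManifest]:
    """Run the full episode algorithm on in-memory inputs.

    Returns all episodes (kept, eliminated and excluded, each with its
    status) plus a manifest whose stage counts reconcile:
    kept + eliminated + excluded == clustered.
    """
    events = detect_events(claims, codemap)
    events = filter_childbearing_age(events, persons, params)
    candidates = cluster_events(events, params)
    resolved = resolve_hierarchy(candidates, params)

    claims_by_person: dict[str, list[ClaimRecord]] = {}
    for claim in claims:
        claims_by_person.setdefault(claim.person_id, []).append(claim)

    episodes: list[PregnancyEpisode] = []
    for cand in resolved:
        person_claims = claims_by_person.get(cand.person_id, [])
        ep = PregnancyEpisode(
            person_id=cand.person_id,
            outcome_date=cand.outcome_date,
            outcome_type=cand.outcome_type,
            member_events=cand.member_events,
        )
        ep.set_lmp(
            estimate_lmp(cand, collect_markers(cand, person_claims, codemap, params), params)
        )
        if cand.status == "eliminated":
            ep.status = "eliminated_hierarchy"
        episodes.append(ep)

    refine_episodes(
        [e for e in episodes if e.status != "eliminated_hierarchy"],
        claims,
        codemap,
        params,
    )

    counts = {
        "claims": len(claims),
        "persons": len(persons),
        "events_detected": len(events),
        "episodes_clustered": len(candidates),
        "episodes_eliminated": sum(e.status == "eliminated_hierarchy" for e in episodes),
        "episodes_excluded": sum(e.status.startswith("excluded") for e in episodes),
        "episodes_kept": sum(e.status == "kept" for e in episodes),
    }
    manifest = RunManifest(tool_version=__version__, counts=counts)
    assert manifest.reconciles(), "stage counts failed to reconcile"
    episodes.sort(key=lambda e: (e.person_id, e.outcome_date, e.outcome_type))
    return episodes, manifest


def run_pipeline(
    claims_path: str | Path,
    persons_path: str | Path,
    codelist_path: str | Path,
    params_path: Optional[str | Path],
    out_dir: str | Path,
    strata_cut: Optional[dt.date] = None,
) -> RunManifest:
    """File-level pipeline: read inputs, run, write episodes and reports."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    codemap = load_codemap(codelist_path)
    params = load_params(params_path)
    claims = read_claims(claims_path)
    persons = read_persons(persons_path)

    episodes, manifest = run_pipeline_data(claims, persons, codemap, params)
    manifest.inputs = {
        str(p): _sha256(p)
        for p in [claims_path, persons_path, codelist_path]
        + ([params_path] if params_path else [])
    }

    write_episodes(episodes, out / "episodes.csv")
    kept = [e for e in episodes if e.status == "kept"]
    dropped = [e for e in episodes if e.status != "kept"]
    write_episodes(dropped, out / "audit_dropped_episodes.csv")

    prevalence_table(kept, ci_method=params.ci_method).to_csv(out / "prevalence.csv")
    counts_tbl, pct_tbl = lmp_method_table(kept)
    counts_tbl.to_csv(out / "lmp_methods.csv")
    pct_tbl.to_csv(out / "lmp_methods_pct.csv")

    drug_claims = [c for c in claims if c.system == "drug"]
    if drug_claims:
        windows = default_windows(params)
        drugs_by_person: dict[str, list[ClaimRecord]] = {}
        for c in drug_claims:
            drugs_by_person.setdefault(c.person_id, []).append(c)
        results = []
        for ep in kept:
            results.extend(
                assess_exposure(
                    ep, drugs_by_person.get(ep.person_id, []), windows, codemap, params
                )
            )
        exposure_trajectory(results, windows).to_csv(
            out / "exposure_trajectory.csv", index=False
        )

    if strata_cut is not None:
        for name, stratum in period_stratify(kept, strata_cut).items():
            prevalence_table(stratum, ci_method=params.ci_method).to_csv(
                out / f"prevalence_{name}.csv"
            )
            c_tbl, p_tbl = lmp_method_table(stratum)
            c_tbl.to_csv(out / f"lmp_methods_{name}.csv")
            p_tbl.to_csv(out / f"lmp_methods_pct_{name}.csv")

    manifest.write(out / "manifest.json")
    return manifest


def simulate(
    scenario_path: Optional[str | Path],
    out_dir: str | Path,
    codelist_path: Optional[str | Path] = None,
    params_path: Optional[str | Path] = None,
    scenario: Optional[SyntheticScenario] = None,
) -> RunManifest:
    """Generate a synthetic cohort and write claims + ground truth files."""
    from .config import default_codelist_path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if scenario is None:
        scenario = (
            load_scenario(scenario_path) if scenario_path else SyntheticScenario()
        )
    codemap = load_codemap(codelist_path or default_codelist_path())
    params = load_params(params_path)

    persons, truth = generate_cohort(scenario, params)
    claims = emit_claims(truth, codemap, scenario)
    claims = claims + emit_prescriptions(truth, scenario, codemap, params)
    claims.sort(key=lambda c: (c.person_id, c.service_date, c.code, c.system))

    write_claims(claims, out / "claims.csv")
    write_persons(persons, out / "persons.csv")
    truth.write(out)

    manifest = RunManifest(
        tool_version=__version__,
        seed=scenario.seed,
        counts={
            "persons": len(persons),
            "claims": len(claims),
            "true_episodes": len(truth.episodes),
        },
    )
    manifest.write(out / "manifest.json")
    return manifest
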