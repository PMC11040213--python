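import datetime as dt

import numpy as np
import pytest

from pregepisodes.synthetic import (
    GenerationError,
    SyntheticScenario,
    emit_claims,
    emit_prescriptions,
    generate_cohort,
)


def scenario(**kw):
    return SyntheticScenario(**kw)


class TestGenerateCohort:
    def test_empty_cohort(self, params):
        persons, truth = generate_cohort(scenario(n_women=0), params)
        assert persons == [] and truth.episodes == []

    def test_deterministic_under_seed(self, params, codemap):
        outs = []
        for _ in range(2):
            sc = scenario(n_women=40, seed=123)
            persons, truth = generate_cohort(sc, params)
            claims = emit_claims(truth, codemap, sc)
            rx = emit_prescriptions(truth, sc, codemap, params)
            outs.append((persons, truth.episodes_frame(), claims, rx))
        assert outs[0][0] == outs[1][0]
        assert outs[0][1].equals(outs[1][1])
        assert outs[0][2] == outs[1][2]
        assert outs[0][3] == outs[1][3]

    def test_seed_changes_output(self, params):
        a = generate_cohort(scenario(n_women=40, seed=1), params)[1]
        b = generate_cohort(scenario(n_women=40, seed=2), params)[1]
        assert not a.episodes_frame().equals(b.episodes_frame())

    def test_outcome_mix_within_monte_carlo_error(self, params):
        mix = {
            "full_term": 0.56,
            "preterm": 0.11,
            "stillbirth": 0.02,
            "spontaneous_abortion": 0.28,
            "induced_abortion": 0.03,
        }
        _, truth = generate_cohort(scenario(n_women=500, seed=7, outcome_mix=mix), params)
        n = len(truth.episodes)
        assert n > 400
        for outcome_type, p in mix.items():
            count = sum(t.true_outcome_type == outcome_type for t in truth.episodes)
            se = np.sqrt(p * (1 - p) * n)
            assert abs(count - p * n) <= 3 * se, outcome_type

    def test_truth_invariants(self, params):
        persons, truth = generate_cohort(scenario(n_women=200, seed=3), params)
        people = {p.person_id: p for p in persons}
        by_person = {}
        for t in truth.episodes:
            by_person.setdefault(t.person_id, []).append(t)
        lo, hi = params.childbearing_age
        for pid, eps in by_person.items():
            eps.sort(key=lambda t: t.true_outcome_date)
            for t in eps:
                assert people[pid].observation_start <= t.true_outcome_date
                assert t.true_outcome_date <= people[pid].observation_end
                assert lo <= people[pid].age_at(t.true_outcome_date) <= hi
                key = (
                    "abortion"
                    if t.true_outcome_type.endswith("abortion")
                    else t.true_outcome_type
                )
                dist = params.ga_bounds_days[key]
                assert dist[0] <= t.true_ga_days <= dist[1]
            for prev, cur in zip(eps, eps[1:]):
                gap = (cur.true_lmp - prev.true_outcome_date).days
                assert gap >= params.retry_period_days

    def test_infeasible_scenario_raises(self, params):
        sc = scenario(
            n_women=5,
            seed=0,
            pregnancy_rate=6.0,
            max_pregnancies=40,
            lmp_start=dt.date(2010, 1, 1),
            lmp_end=dt.date(2011, 1, 1),
        )
        with pytest.raises(GenerationError):
            generate_cohort(sc, params)

    def test_mix_must_sum_to_one(self):
        with pytest.raises(ValueError):
            scenario(
                outcome_mix={
                    "full_term": 0.9,
                    "preterm": 0.2,
                    "stillbirth": 0.02,
                    "spontaneous_abortion": 0.28,
                    "induced_abortion": 0.03,
                }
            )


def _marker_probs(p: float):
    cats = (
        "sonography_t1",
        "sonography_t1_targetscan",
        "sonography_t23",
        "sonography_t23_targetscan",
        "preterm_ga_specified",
        "preterm_ga_unspecified",
        "abortion_procedure",
    )
    return {c: {"pre": p, "post": p} for c in cats}


class TestEmitClaims:
    def test_outcome_claims_only_when_markers_off(self, params, codemap):
        sc = scenario(n_women=60, seed=11, marker_emission_probs=_marker_probs(0.0))
        _, truth = generate_cohort(sc, params)
        claims = emit_claims(truth, codemap, sc)
        spontaneous = [
            t for t in truth.episodes if t.true_outcome_type == "spontaneous_abortion"
        ]
        deliveries = [t for t in truth.episodes if t.true_outcome_type == "full_term"]
        assert spontaneous and deliveries
        # one outcome claim per non-induced episode, dated at the outcome
        induced = sum(t.true_outcome_type == "induced_abortion" for t in truth.episodes)
        assert len(claims) == len(truth.episodes) + induced
        for t in truth.episodes:
            own = [c for c in claims if c.person_id == t.person_id
                   and c.service_date == t.true_outcome_date]
            assert own, t

    def test_marker_reconstructs_true_lmp(self, params, codemap):
        # full emission, noise off: every GA-window marker claim sits at
        # true_lmp + window midpoint
        sc = scenario(n_women=60, seed=13, marker_emission_probs=_marker_probs(1.0))
        _, truth = generate_cohort(sc, params)
        claims = emit_claims(truth, codemap, sc)
        for t in truth.episodes:
            for cat in t.emitted_markers:
                if cat == "preterm_ga_unspecified":
                    continue
                entries = {
                    e.pattern: e for e in codemap.entries_for(cat)
                }
                own = [
                    c
                    for c in claims
                    if c.person_id == t.person_id and c.code in entries
                    and t.true_lmp <= c.service_date <= t.true_outcome_date
                ]
                assert any(
                    c.service_date
                    == t.true_lmp + dt.timedelta(days=entries[c.code].midpoint_days)
                    for c in own
                ), (t, cat)

    def test_forced_duplication(self, params, codemap):
        sc = scenario(
            n_women=30,
            seed=17,
            noise={"duplicate_claim_prob": 1.0},
        )
        _, truth = generate_cohort(sc, params)
        claims = emit_claims(truth, codemap, sc)
        from collections import Counter

        counts = Counter(claims)
        assert counts and all(v >= 2 for v in counts.values())

    def test_injected_crosscodes_are_labelled(self, params, codemap):
        sc = scenario(n_women=150, seed=19, noise={"cross_code_prob": 1.0})
        _, truth = generate_cohort(sc, params)
        emit_claims(truth, codemap, sc)
        for t in truth.episodes:
            if t.base_outcome in ("delivery", "stillbirth"):
                assert t.injected_crosscode in ("delivery", "abortion")
                assert t.injected_crosscode != t.base_outcome
            else:
                assert t.injected_crosscode is None


class TestEmitPrescriptions:
    def test_counts_and_dates_inside_designated_windows(self, params, codemap):
        rx = {
            "drug_cyc_mmf_mtx": {
                "pre_q1": {"count": 2, "prob": 1.0},
                "trimester1": {"count": 1, "prob": 1.0},
            }
        }
        sc = scenario(n_women=40, seed=23, rx_scenario=rx)
        _, truth = generate_cohort(sc, params)
        claims = emit_prescriptions(truth, sc, codemap, params)
        by_person_date = {}
        for c in claims:
            by_person_date.setdefault(c.person_id, []).append(c.service_date)
        for t in truth.episodes:
            dates = [
                d
                for d in by_person_date.get(t.person_id, [])
                if t.true_lmp - dt.timedelta(days=90) <= d < t.true_lmp
            ]
            assert len(dates) == 2  # pre_q1 emission for every episode
            t1_end = min(
                t.true_lmp + dt.timedelta(days=98),
                t.true_outcome_date + dt.timedelta(days=1),
            )
            in_t1 = [
                d
                for d in by_person_date.get(t.person_id, [])
                if t.true_lmp <= d < t1_end
            ]
            assert len(in_t1) == 1
        # truth bookkeeping matches the request
        for x in truth.exposures:
            assert x.n_prescriptions == (2 if x.window == "pre_q1" else 1)

    def test_no_prescriptions_requested_none_emitted(self, params, codemap):
        sc = scenario(n_women=20, seed=29, rx_scenario={})
        _, truth = generate_cohort(sc, params)
        assert emit_prescriptions(truth, sc, codemap, params) == []
        assert truth.exposures == []

    def test_unknown_window_rejected(self, params, codemap):
        sc = scenario(
            n_women=5,
            seed=31,
            rx_scenario={"drug_nsaid": {"bogus": {"count": 1, "prob": 1.0}}},
        )
        _, truth = generate_cohort(sc, params)
        with pytest.raises(ValueError, match="bogus"):
            emit_prescriptions(truth, sc, codemap, params)
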