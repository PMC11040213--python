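import copy
import datetime as dt

import pytest

from pregepisodes.records import ClaimRecord, PregnancyEpisode
from pregepisodes.refinement import (
    apply_retry,
    classify_abortion,
    enforce_bounds,
    refine_episodes,
)


def ep(person="A", lmp=None, outcome=None, outcome_type="delivery", **kw):
    e = PregnancyEpisode(
        person_id=person,
        outcome_date=outcome,
        outcome_type=outcome_type,
        lmp_date=lmp,
        lmp_method=kw.pop("lmp_method", "outcome_specific"),
        **kw,
    )
    e.recompute_ga()
    return e


class TestRetry:
    def test_overlapping_lmp_pushed_past_retry_period(self, params):
        episodes = [
            ep(lmp=dt.date(2011, 6, 1), outcome=dt.date(2012, 3, 1)),
            ep(lmp=dt.date(2012, 2, 15), outcome=dt.date(2012, 11, 20)),
        ]
        apply_retry(episodes, params)
        assert episodes[1].lmp_date == dt.date(2012, 3, 29)  # prev outcome + 28 d
        assert episodes[1].lmp_adjusted_by_retry
        assert episodes[1].ga_days == (dt.date(2012, 11, 20) - dt.date(2012, 3, 29)).days

    def test_separated_episode_unchanged(self, params):
        episodes = [
            ep(lmp=dt.date(2011, 6, 1), outcome=dt.date(2012, 3, 1)),
            ep(lmp=dt.date(2012, 6, 1), outcome=dt.date(2013, 3, 1)),
        ]
        before = copy.deepcopy(episodes)
        apply_retry(episodes, params)
        assert episodes == before

    def test_adjustments_cascade_left_to_right(self, params):
        # three chained overlapping episodes: each adjustment is made
        # against the (possibly adjusted) predecessor's outcome
        episodes = [
            ep(lmp=dt.date(2010, 1, 1), outcome=dt.date(2010, 10, 1)),
            ep(lmp=dt.date(2010, 9, 1), outcome=dt.date(2011, 7, 1)),
            ep(lmp=dt.date(2011, 6, 1), outcome=dt.date(2012, 4, 1)),
        ]
        apply_retry(episodes, params)
        assert episodes[1].lmp_date == dt.date(2010, 10, 29)
        assert episodes[2].lmp_date == dt.date(2011, 7, 29)
        assert all(e.lmp_adjusted_by_retry for e in episodes[1:])

    def test_degenerate_adjustment_excluded(self, params):
        episodes = [
            ep(lmp=dt.date(2011, 6, 1), outcome=dt.date(2012, 3, 1)),
            ep(
                lmp=dt.date(2012, 2, 1),
                outcome=dt.date(2012, 3, 15),
                outcome_type="abortion",
            ),
        ]
        apply_retry(episodes, params)
        assert episodes[1].status == "excluded_degenerate"

    def test_strict_trigger_only_fires_on_true_overlap(self, params):
        strict = params.model_copy(update={"retry_trigger": "strict"})
        episodes = [
            ep(lmp=dt.date(2011, 6, 1), outcome=dt.date(2012, 3, 1)),
            ep(lmp=dt.date(2012, 3, 10), outcome=dt.date(2012, 12, 1)),
        ]
        apply_retry(episodes, strict)
        assert episodes[1].lmp_date == dt.date(2012, 3, 10)  # inside retry, kept
        episodes[1].lmp_date = dt.date(2012, 2, 20)
        apply_retry(episodes, strict)
        assert episodes[1].lmp_date == dt.date(2012, 3, 29)


class TestBounds:
    @pytest.mark.parametrize(
        "outcome_type,ga,expected_type,expected_status",
        [
            ("stillbirth", 126, "abortion", "kept"),  # 18 wk -> abortion
            ("stillbirth", 140, "stillbirth", "kept"),
            ("delivery", 252, "preterm", "kept"),  # 36 wk
            ("delivery", 259, "full_term", "kept"),  # exactly 37 wk
            ("delivery", 294, "full_term", "kept"),  # exactly 42 wk
            ("delivery", 301, "delivery", "excluded_overlong"),  # 43 wk
            ("delivery", 139, "delivery", "excluded_short_delivery"),
            ("delivery", 140, "preterm", "kept"),  # exactly 20 wk
            ("abortion", 120, "abortion", "kept"),
            ("abortion", 141, "abortion", "excluded_overlong"),
        ],
    )
    def test_bound_rules(self, params, outcome_type, ga, expected_type, expected_status):
        outcome = dt.date(2012, 6, 1)
        e = ep(lmp=outcome - dt.timedelta(days=ga), outcome=outcome, outcome_type=outcome_type)
        enforce_bounds([e], params)
        assert (e.outcome_type, e.status) == (expected_type, expected_status)

    def test_reclassified_from_recorded(self, params):
        outcome = dt.date(2012, 6, 1)
        e = ep(lmp=outcome - dt.timedelta(days=126), outcome=outcome, outcome_type="stillbirth")
        enforce_bounds([e], params)
        assert e.reclassified_from == "stillbirth"


class TestAbortionSubtype:
    def _abortion(self, lmp, outcome):
        return ep(lmp=lmp, outcome=outcome, outcome_type="abortion")

    def test_induced_marker_inside_episode(self, codemap, params):
        e = self._abortion(dt.date(2012, 1, 1), dt.date(2012, 3, 11))
        claims = [ClaimRecord("A", dt.date(2012, 3, 11), "ABIN", "procedure")]
        classify_abortion([e], claims, codemap, params)
        assert e.outcome_type == "induced_abortion"

    def test_no_marker_means_spontaneous(self, codemap, params):
        e = self._abortion(dt.date(2012, 1, 1), dt.date(2012, 3, 11))
        classify_abortion([e], [], codemap, params)
        assert e.outcome_type == "spontaneous_abortion"

    def test_trailing_marker_within_gap_counts(self, codemap, params):
        e = self._abortion(dt.date(2012, 1, 1), dt.date(2012, 3, 11))
        trail = params.same_episode_gap_days["abortion"]
        inside = ClaimRecord(
            "A", dt.date(2012, 3, 11) + dt.timedelta(days=trail - 1), "O041", "diagnosis"
        )
        classify_abortion([e], [inside], codemap, params)
        assert e.outcome_type == "induced_abortion"

    def test_marker_outside_window_ignored(self, codemap, params):
        e = self._abortion(dt.date(2012, 1, 1), dt.date(2012, 3, 11))
        trail = params.same_episode_gap_days["abortion"]
        outside = ClaimRecord(
            "A", dt.date(2012, 3, 11) + dt.timedelta(days=trail), "ABIN", "procedure"
        )
        classify_abortion([e], [outside], codemap, params)
        assert e.outcome_type == "spontaneous_abortion"

    def test_reclassified_stillbirth_can_be_induced(self, codemap, params):
        # reclassification to abortion happens before subtyping
        outcome = dt.date(2012, 6, 1)
        e = ep(lmp=outcome - dt.timedelta(days=126), outcome=outcome, outcome_type="stillbirth")
        claims = [ClaimRecord("A", outcome, "ABIN", "procedure")]
        refine_episodes([e], claims, codemap, params)
        assert e.outcome_type == "induced_abortion"
        assert e.reclassified_from == "stillbirth"


class TestRefinePipeline:
    def test_idempotent(self, codemap, params):
        episodes = [
            ep(lmp=dt.date(2010, 1, 1), outcome=dt.date(2010, 10, 1)),
            ep(lmp=dt.date(2010, 9, 1), outcome=dt.date(2011, 7, 1)),
            ep(
                lmp=dt.date(2012, 1, 1),
                outcome=dt.date(2012, 3, 1),
                outcome_type="abortion",
            ),
            ep(
                lmp=dt.date(2013, 1, 1),
                outcome=dt.date(2013, 5, 15),
                outcome_type="stillbirth",
            ),
        ]
        claims = [ClaimRecord("A", dt.date(2012, 3, 1), "ABIN", "procedure")]
        once = refine_episodes(copy.deepcopy(episodes), claims, codemap, params)
        twice = refine_episodes(copy.deepcopy(once), claims, codemap, params)
        assert once == twice

    def test_kept_episodes_separated_by_retry(self, codemap, params):
        episodes = [
            ep(lmp=dt.date(2010, 1, 1), outcome=dt.date(2010, 10, 1)),
            ep(lmp=dt.date(2010, 9, 15), outcome=dt.date(2011, 7, 20)),
            ep(
                lmp=dt.date(2011, 7, 25),
                outcome=dt.date(2011, 10, 1),
                outcome_type="abortion",
            ),
        ]
        refine_episodes(episodes, [], codemap, params)
        kept = sorted(
            (e for e in episodes if e.status == "kept"), key=lambda e: e.outcome_date
        )
        for prev, cur in zip(kept, kept[1:]):
            assert (cur.lmp_date - prev.outcome_date).days >= params.retry_period_days
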