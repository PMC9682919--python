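"""Shared fixtures: stimulus plans, hand-built sessions, a calibrated cohort."""

from __future__ import annotations

import pytest

from crtlab import (PopulationConfig, RawSession, SessionScore, TrialRecord,
                    generate_sequence, simulate_cohort_scores)

COHORT_N = 20_000
COHORT_SEED = 7


@pytest.fixture(scope="session")
def plan():
    return generate_sequence(seed=0)


@pytest.fixture(scope="session")
def calibrated_cohort():
    """One simulated cohort at default calibration, reused across tests."""
    config = PopulationConfig(n_subjects=COHORT_N, seed=COHORT_SEED)
    profiles, scores = simulate_cohort_scores(config)
    return config, profiles, scores


def make_session(plan, hit_latencies=None, fa_latencies=None,
                 session_id="fix"):
    """Build a RawSession: dict/position-indexed latencies for repeats
    (hit_latencies) and first showings (fa_latencies); missing = no press."""
    hit_latencies = hit_latencies or {}
    fa_latencies = fa_latencies or {}
    trials = []
    ri = ni = 0
    for p in plan.presentations:
        if p.is_repeat:
            lat = hit_latencies.get(ri)
            ri += 1
        else:
            lat = fa_latencies.get(ni)
            ni += 1
        trials.append(TrialRecord(position=p.position, image_id=p.image_id,
                                  is_repeat=p.is_repeat, latency_ms=lat))
    return RawSession(session_id=session_id, trials=tuple(trials))


@pytest.fixture
def perfect_session(plan):
    """All 25 repeats answered at 850 ms, no other presses."""
    return make_session(plan, hit_latencies={i: 850 for i in range(25)},
                        session_id="perfect")


@pytest.fixture
def hand_scored_session(plan):
    """Session with a frozen, independently hand-tallied score.

    Repeats: 20 valid presses at 700..719 ms, two sub-200 ms presses
    (150, 199 ms -> non-responses), three without any press.
    First showings: one recorded 3000 ms timeout, presses at 500 and
    600 ms, the rest without a press.

    Hand tally: HIT 20, MISS 5, CR 23, FA 2, n_correct 43,
    total_responses 22, mean HIT RT (700+...+719)/20 = 709.5 ms
    -> 0.710 s (half-up at the millisecond).
    """
    hits = {i: 700 + i for i in range(20)}
    hits[20] = 150
    hits[21] = 199
    fas = {0: 3000, 1: 500, 2: 600}
    return make_session(plan, hit_latencies=hits, fa_latencies=fas,
                        session_id="hand")


HAND_SCORE_EXPECTED = dict(hits=20, misses=5, correct_rejections=23,
                           false_alarms=2, n_correct=43, total_responses=22,
                           mean_hit_rt=0.710)


def make_score(hits=25, crs=25, rt=0.85, session_id=None):
    """SessionScore from the three quantities the filters look at."""
    return SessionScore(
        hits=hits, misses=25 - hits, correct_rejections=crs,
        false_alarms=25 - crs, n_correct=hits + crs,
        total_responses=hits + (25 - crs),
        mean_hit_rt=rt if hits > 0 else None,
        session_id=session_id)


@pytest.fixture
def qc_fixture_scores():
    """20 scores with known violations; 13 survive the default validity
    policy (hand count: 7 fail, several for multiple reasons)."""
    return [
        make_score(25, 25, 0.850, "ok1"),
        make_score(20, 20, 1.200, "ok2"),
        make_score(5, 25, 1.000, "ok3"),        # exactly at min_hits
        make_score(25, 5, 0.900, "ok4"),        # exactly at min_crs
        make_score(15, 15, 0.500, "ok5"),       # at rt_low boundary
        make_score(15, 15, 2.000, "ok6"),       # at rt_high boundary
        make_score(18, 12, 0.700, "ok7"),
        make_score(12, 18, 1.800, "ok8"),
        make_score(22, 8, 0.600, "ok9"),
        make_score(8, 22, 1.500, "ok10"),
        make_score(25, 24, 0.750, "ok11"),
        make_score(24, 25, 1.100, "ok12"),
        make_score(16, 14, 1.999, "ok13"),
        make_score(20, 9, 0.900, "bad1"),       # n_correct 29
        make_score(4, 25, 1.000, "bad2"),       # hits 4 (n_correct 29 too)
        make_score(25, 4, 0.900, "bad3"),       # crs 4 (n_correct 29 too)
        make_score(20, 20, 0.499, "bad4"),      # rt below 0.5
        make_score(20, 20, 2.001, "bad5"),      # rt above 2
        make_score(0, 25, None, "bad6"),        # no HITs -> no mean RT
        make_score(3, 25, 0.450, "bad7"),       # several reasons at once
    ]
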