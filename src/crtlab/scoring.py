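"""Trial classification and session scoring.

The task records a latency between 1 and 3000 ms for every key press.
A latency in [200, 2999] ms counts as a response; an absent latency,
one below 200 ms, or one of exactly 3000 ms (the timeout code) counts
as a non-response.  Crossing response/non-response with repeat/first
showing yields the four signal-detection outcomes:

=============  ==============  ===================
stimulus       response        non-response
=============  ==============  ===================
repeat         HIT             MISS
first showing  FALSE_ALARM     CORRECT_REJECTION
=============  ==============  ===================

A session score reduces the 50 trials to the counts of the four
outcomes plus the arithmetic mean HIT latency in seconds.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable

from .errors import ValidationError
from .sequence import N_NEW, N_PRESENTATIONS, N_REPEAT

RESPONSE_MIN_MS = 200
RESPONSE_MAX_MS = 2999
LATENCY_MIN_MS = 1
LATENCY_MAX_MS = 3000


class Outcome(enum.Enum):
    HIT = "HIT"
    MISS = "MISS"
    CORRECT_REJECTION = "CORRECT_REJECTION"
    FALSE_ALARM = "FALSE_ALARM"


@dataclass(frozen=True)
class TrialRecord:
    """One stimulus presentation and the subject's (possible) response.

    ``latency_ms`` is None when no key press was recorded at all; the
    timeout value 3000 is a recorded press that does not count as a
    response, and is kept distinct from absence.
    """

    position: int
    image_id: str
    is_repeat: bool
    latency_ms: int | None = None

    def __post_init__(self):
        if self.latency_ms is not None and not (
                LATENCY_MIN_MS <= self.latency_ms <= LATENCY_MAX_MS):
            raise ValidationError(
                f"latency_ms must be in [{LATENCY_MIN_MS}, {LATENCY_MAX_MS}] "
                f"or absent, got {self.latency_ms}")


@dataclass(frozen=True)
class RawSession:
    """One subject's per-trial records for a 50-presentation plan."""

    session_id: str
    trials: tuple[TrialRecord, ...]

    def __len__(self) -> int:
        return len(self.trials)


@dataclass(frozen=True)
class SessionScore:
    """Signal-detection counts and mean HIT latency for one session.

    Identities maintained by construction:
    hits + misses = 25, correct_rejections + false_alarms = 25,
    n_correct = hits + correct_rejections,
    total_responses = hits + false_alarms.
    ``mean_hit_rt`` (seconds) is present iff hits >= 1.
    """

    hits: int
    misses: int
    correct_rejections: int
    false_alarms: int
    n_correct: int
    total_responses: int
    mean_hit_rt: float | None
    session_id: str | None = None

    def __post_init__(self):
        if self.hits + self.misses != N_REPEAT:
            raise ValidationError(
                f"hits + misses must equal {N_REPEAT}, "
                f"got {self.hits} + {self.misses}")
        if self.correct_rejections + self.false_alarms != N_NEW:
            raise ValidationError(
                f"correct_rejections + false_alarms must equal {N_NEW}, "
                f"got {self.correct_rejections} + {self.false_alarms}")
        if self.n_correct != self.hits + self.correct_rejections:
            raise ValidationError("n_correct != hits + correct_rejections")
        if self.total_responses != self.hits + self.false_alarms:
            raise ValidationError("total_responses != hits + false_alarms")
        if (self.mean_hit_rt is None) != (self.hits == 0):
            raise ValidationError(
                "mean_hit_rt must be present iff the session has any HITs")
        if self.mean_hit_rt is not None and not (
                0.2 <= self.mean_hit_rt <= 2.999):
            raise ValidationError(
                f"mean_hit_rt must lie in [0.2, 2.999] s, got {self.mean_hit_rt}")


def is_response(latency_ms: int | None) -> bool:
    """True when a recorded latency counts as a response (200-2999 ms)."""
    if latency_ms is not None and not (
            LATENCY_MIN_MS <= latency_ms <= LATENCY_MAX_MS):
        raise ValidationError(
            f"latency_ms must be in [{LATENCY_MIN_MS}, {LATENCY_MAX_MS}] "
            f"or absent, got {latency_ms}")
    return (latency_ms is not None
            and RESPONSE_MIN_MS <= latency_ms <= RESPONSE_MAX_MS)


def classify_trial(trial: TrialRecord) -> Outcome:
    """Classify one trial into HIT / MISS / CORRECT_REJECTION / FALSE_ALARM."""
    responded = is_response(trial.latency_ms)
    if trial.is_repeat:
        return Outcome.HIT if responded else Outcome.MISS
    return Outcome.FALSE_ALARM if responded else Outcome.CORRECT_REJECTION


def round_rt(seconds: float) -> float:
    """Round a latency in seconds to milliseconds, half-up."""
    return float(Decimal(repr(seconds)).quantize(Decimal("0.001"),
                                                 rounding=ROUND_HALF_UP))


def score_session(session: RawSession) -> SessionScore:
    """Reduce a 50-trial session to its SessionScore.

    Raises :class:`ValidationError` when the session does not have
    exactly 50 trials split 25 new / 25 repeated.
    """
    if len(session.trials) != N_PRESENTATIONS:
        raise ValidationError(
            f"session {session.session_id!r} has {len(session.trials)} trials, "
            f"expected {N_PRESENTATIONS}")
    n_repeat = sum(t.is_repeat for t in session.trials)
    if n_repeat != N_REPEAT:
        raise ValidationError(
            f"session {session.session_id!r} has {n_repeat} repeats, "
            f"expected {N_REPEAT}")

    counts = {o: 0 for o in Outcome}
    hit_latencies: list[int] = []
    for trial in session.trials:
        outcome = classify_trial(trial)
        counts[outcome] += 1
        if outcome is Outcome.HIT:
            hit_latencies.append(trial.latency_ms)  # type: ignore[arg-type]

    hits = counts[Outcome.HIT]
    mean_hit_rt = (round_rt(sum(hit_latencies) / len(hit_latencies) / 1000.0)
                   if hit_latencies else None)
    return SessionScore(
        hits=hits,
        misses=counts[Outcome.MISS],
        correct_rejections=counts[Outcome.CORRECT_REJECTION],
        false_alarms=counts[Outcome.FALSE_ALARM],
        n_correct=hits + counts[Outcome.CORRECT_REJECTION],
        total_responses=hits + counts[Outcome.FALSE_ALARM],
        mean_hit_rt=mean_hit_rt,
        session_id=session.session_id,
    )


def score_sessions(sessions: Iterable[RawSession]) -> list[SessionScore]:
    """Score an iterable of sessions in order."""
    return [score_session(s) for s in sessions]
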