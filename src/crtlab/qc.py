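"""Validity and analysis-subset filters for session scores.

Two filtering stages are applied in the population analyses:

* the validity filter removes chance-level or implausible sessions
  (fewer than 30/50 correct, fewer than 5 HITs or 5 Correct
  Rejections, mean HIT RT below 0.5 s or above 2 s);
* the stricter analysis-subset filter additionally removes bias and RT
  outliers before correlation analyses (fewer than 10 HITs, fewer
  than 15 Correct Rejections, RT below 0.6 s or above 1.4 s, fewer
  than 35 correct).

RT bounds are strict removal bounds: a session at exactly the bound
survives.  Removal accounting is set-based (a session is removed once,
with every reason it failed recorded), so per-reason tallies may sum
to more than the number removed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Hashable, Iterable

from .scoring import SessionScore

#: machine-readable reason codes for filter failures
BELOW_MIN_CORRECT = "below_min_correct"
TOO_FEW_HITS = "too_few_hits"
TOO_FEW_CRS = "too_few_crs"
MISSING_RT = "missing_rt"
RT_TOO_FAST = "rt_too_fast"
RT_TOO_SLOW = "rt_too_slow"


@dataclass(frozen=True)
class FilterPolicy:
    """Validity criteria a session must meet to enter any analysis."""

    min_correct: int = 30
    min_hits: int = 5
    min_crs: int = 5
    rt_low: float = 0.5
    rt_high: float = 2.0

    def __post_init__(self):
        if not 0 <= self.min_correct <= 50:
            raise ValueError(f"min_correct must be in [0, 50], got {self.min_correct}")
        if not self.rt_low < self.rt_high:
            raise ValueError("rt_low must be below rt_high")


@dataclass(frozen=True)
class SubsetPolicy(FilterPolicy):
    """Stricter outlier criteria for the correlation analyses."""

    min_correct: int = 35
    min_hits: int = 10
    min_crs: int = 15
    rt_low: float = 0.6
    rt_high: float = 1.4


@dataclass(frozen=True)
class ValidityResult:
    """Boolean verdict plus the set of failed criteria."""

    valid: bool
    reasons: frozenset[str]

    def __bool__(self) -> bool:
        return self.valid


def is_valid_session(score: SessionScore,
                     policy: FilterPolicy | None = None) -> ValidityResult:
    """Check a score against a policy, enumerating every failed criterion."""
    policy = FilterPolicy() if policy is None else policy
    reasons: set[str] = set()
    if score.n_correct < policy.min_correct:
        reasons.add(BELOW_MIN_CORRECT)
    if score.hits < policy.min_hits:
        reasons.add(TOO_FEW_HITS)
    if score.correct_rejections < policy.min_crs:
        reasons.add(TOO_FEW_CRS)
    if score.mean_hit_rt is None:
        reasons.add(MISSING_RT)
    else:
        if score.mean_hit_rt < policy.rt_low:
            reasons.add(RT_TOO_FAST)
        if score.mean_hit_rt > policy.rt_high:
            reasons.add(RT_TOO_SLOW)
    return ValidityResult(valid=not reasons, reasons=frozenset(reasons))


@dataclass(frozen=True)
class FilterReport:
    """Survivors of a policy plus set-based removal accounting."""

    kept: tuple[SessionScore, ...]
    n_removed: int
    removal_tally: dict[str, int]


def apply_policy(scores: Iterable[SessionScore],
                 policy: FilterPolicy) -> FilterReport:
    """Retain scores meeting every criterion; tally failures per reason."""
    kept: list[SessionScore] = []
    tally = {code: 0 for code in (BELOW_MIN_CORRECT, TOO_FEW_HITS, TOO_FEW_CRS,
                                  MISSING_RT, RT_TOO_FAST, RT_TOO_SLOW)}
    n_removed = 0
    for score in scores:
        verdict = is_valid_session(score, policy)
        if verdict:
            kept.append(score)
        else:
            n_removed += 1
            for code in verdict.reasons:
                tally[code] += 1
    return FilterReport(kept=tuple(kept), n_removed=n_removed,
                        removal_tally=tally)


def analysis_subset(scores: Iterable[SessionScore],
                    policy: SubsetPolicy | None = None) -> FilterReport:
    """Apply the analysis-subset outlier filter (assumes validity upstream)."""
    return apply_policy(scores, SubsetPolicy() if policy is None else policy)


def select_first_tests(
        records: Iterable[tuple[Hashable, float, SessionScore]]
) -> list[SessionScore]:
    """Keep each user's earliest test.

    ``records`` are (user_id, timestamp, score) triples; ties on the
    minimum timestamp are broken by stable input order, and users are
    reported in order of first appearance.
    """
    best: dict[Hashable, tuple[float, SessionScore]] = {}
    for user_id, timestamp, score in records:
        if user_id not in best or timestamp < best[user_id][0]:
            best[user_id] = (timestamp, score)
    return [score for _, score in best.values()]
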