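"""Synthetic CRT subjects and sessions.

The generator reproduces the statistical structure the population
analyses assume, so that every downstream stage (scoring, QC,
distribution fitting, normative tables) is testable without any data
download:

* subject latent mean HIT response times follow the RevEx law with the
  published calibration (a = 263.94, b = 6.682);
* the expected number of Misses rises linearly with the latent mean RT
  at ``miss_slope`` seconds per Miss above the 25-HIT baseline RT
  (0.837 s), i.e. slower subjects recognise fewer repeats;
* the propensity to respond to first showings (false alarms) is drawn
  independently of the HIT channel, so HIT and Correct Rejection
  counts are uncorrelated across subjects;
* a small fast-guesser stratum (latent mean RT < 0.6 s) responds
  indiscriminately, with collapsing Correct Rejections;
* within a session, HIT latencies scatter symmetrically around the
  subject's latent mean, so the session mean is an unbiased estimate
  of it.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from typing import Iterator

import numpy as np
from scipy import stats

from . import revex
from .errors import ValidationError
from .scoring import (LATENCY_MAX_MS, RESPONSE_MIN_MS, RawSession,
                      SessionScore, TrialRecord, score_session)
from .sequence import (DEFAULT_MAX_RUN, DEFAULT_MIN_LAG, StimulusPlan,
                       generate_sequence)


class Strategy(str, enum.Enum):
    """Response-bias archetypes.

    ``balanced`` subjects respond close to the optimal 25 times;
    ``over_responder`` subjects lose Correct Rejections with stable
    HITs; ``under_responder`` subjects lose HITs with stable Correct
    Rejections; ``fast_guesser`` subjects (mean RT < 0.6 s) trade
    accuracy for speed, responding often and indiscriminately.
    """

    BALANCED = "balanced"
    OVER_RESPONDER = "over_responder"
    UNDER_RESPONDER = "under_responder"
    FAST_GUESSER = "fast_guesser"


@dataclass(frozen=True)
class SubjectProfile:
    """Latent behavioural parameters of one simulated subject."""

    p_hit: float
    p_fa: float
    base_mean_rt: float  # seconds
    rt_trial_sd: float = 0.1  # seconds
    strategy: Strategy = Strategy.BALANCED

    def __post_init__(self):
        if not 0.0 <= self.p_hit <= 1.0:
            raise ValidationError(f"p_hit must be in [0, 1], got {self.p_hit}")
        if not 0.0 <= self.p_fa <= 1.0:
            raise ValidationError(f"p_fa must be in [0, 1], got {self.p_fa}")
        if not 0.2 < self.base_mean_rt < 3.0:
            raise ValidationError(
                f"base_mean_rt must lie in (0.2, 3.0) s, got {self.base_mean_rt}")
        if self.rt_trial_sd < 0:
            raise ValidationError(
                f"rt_trial_sd must be >= 0, got {self.rt_trial_sd}")


#: Mean RT associated with a perfect 25-HIT session, seconds.
RT_AT_MAX_HITS = 0.837
#: Slowing per additional expected Miss: (1.299 - 0.837)/15 s.
DEFAULT_MISS_SLOPE = (1.299 - RT_AT_MAX_HITS) / 15

#: Archetype proportions.  The fast-guesser share matches the mass the
#: RevEx law itself puts below 0.6 s, so the latent mean-RT marginal
#: stays exactly RevEx; the under-responder share sets how much of the
#: population carries the steep RT/Miss coupling.
DEFAULT_STRATEGY_MIX = {
    Strategy.BALANCED: 0.7617,
    Strategy.OVER_RESPONDER: 0.08,
    Strategy.UNDER_RESPONDER: 0.15,
    Strategy.FAST_GUESSER: 0.0083,
}

_P_HIT_CEILING = 0.97  # even ideal subjects miss occasionally
_P_HIT_FLOOR = 0.2
_FAST_GUESS_CUTOFF = 0.6  # seconds


@dataclass(frozen=True)
class PopulationConfig:
    """Calibration of a simulated cohort.

    ``revex_a``/``revex_b`` set the latent mean-RT law; ``miss_slope``
    couples expected Misses to RT; ``strategy_mix`` gives archetype
    proportions (must sum to 1); ``hit_cr_correlation_target`` is kept
    at 0 (HIT and CR channels sampled independently) and documented for
    interface completeness.
    """

    n_subjects: int = 1000
    revex_a: float = revex.PUBLISHED_A
    revex_b: float = revex.PUBLISHED_B
    miss_slope: float = DEFAULT_MISS_SLOPE
    rt_at_max_hits: float = RT_AT_MAX_HITS
    hit_cr_correlation_target: float = 0.0
    strategy_mix: dict = field(default_factory=lambda: dict(DEFAULT_STRATEGY_MIX))
    rt_trial_sd: float = 0.1
    min_lag: int = DEFAULT_MIN_LAG
    max_run: int = DEFAULT_MAX_RUN
    seed: int | None = None

    def __post_init__(self):
        if self.n_subjects < 1:
            raise ValidationError(
                f"n_subjects must be >= 1, got {self.n_subjects}")
        if self.revex_a <= 0 or self.revex_b <= 0:
            raise ValidationError("revex_a and revex_b must be positive")
        if self.miss_slope <= 0:
            raise ValidationError("miss_slope must be positive")
        mix = {Strategy(k): v for k, v in self.strategy_mix.items()}
        if abs(sum(mix.values()) - 1.0) > 1e-9:
            raise ValidationError("strategy_mix proportions must sum to 1")
        if any(v < 0 for v in mix.values()):
            raise ValidationError("strategy_mix proportions must be >= 0")
        object.__setattr__(self, "strategy_mix", mix)

    @property
    def params(self) -> revex.RevExParams:
        return revex.RevExParams(a=self.revex_a, b=self.revex_b)


def _draw_latencies(rng: np.random.Generator, n: int,
                    mean_s: float, sd_s: float) -> np.ndarray:
    """Integer-ms response latencies, symmetric about the latent mean.

    Truncated normal at +/- 3 sd, further clipped into the response
    window so a simulated press always scores as a response.
    """
    if n == 0:
        return np.empty(0, dtype=int)
    if sd_s == 0:
        ms = np.full(n, mean_s * 1000.0)
    else:
        lo = max((RESPONSE_MIN_MS / 1000.0 - mean_s) / sd_s, -3.0)
        hi = min(((LATENCY_MAX_MS - 1) / 1000.0 - mean_s) / sd_s, 3.0)
        draws = stats.truncnorm.rvs(lo, hi, loc=mean_s, scale=sd_s,
                                    size=n, random_state=rng)
        ms = draws * 1000.0
    return np.clip(np.rint(ms), RESPONSE_MIN_MS, LATENCY_MAX_MS - 1).astype(int)


def simulate_session(plan: StimulusPlan, profile: SubjectProfile,
                     seed=None, session_id: str = "s1",
                     rng: np.random.Generator | None = None) -> RawSession:
    """Simulate one subject performing one stimulus plan.

    Repeats elicit a response with probability ``p_hit`` and first
    showings with probability ``p_fa``; response latencies (HITs and
    False Alarms alike) are drawn around ``base_mean_rt``.
    Non-responses carry an absent latency.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    n = len(plan.presentations)
    is_repeat = np.fromiter((p.is_repeat for p in plan.presentations),
                            dtype=bool, count=n)
    p_respond = np.where(is_repeat, profile.p_hit, profile.p_fa)
    responded = rng.uniform(size=n) < p_respond
    latencies = _draw_latencies(rng, int(responded.sum()),
                                profile.base_mean_rt, profile.rt_trial_sd)
    lat_iter = iter(latencies)
    trials = tuple(
        TrialRecord(position=p.position, image_id=p.image_id,
                    is_repeat=p.is_repeat,
                    latency_ms=int(next(lat_iter)) if r else None)
        for p, r in zip(plan.presentations, responded))
    return RawSession(session_id=session_id, trials=trials)


def _draw_profiles(config: PopulationConfig,
                   rng: np.random.Generator) -> list[SubjectProfile]:
    params = config.params
    strategies = list(config.strategy_mix)
    probs = np.array([config.strategy_mix[s] for s in strategies])
    chosen = rng.choice(len(strategies), size=config.n_subjects, p=probs)

    u = rng.uniform(size=config.n_subjects)
    profiles: list[SubjectProfile] = []
    fast_mass = float(revex.cdf(_FAST_GUESS_CUTOFF, params))
    for i in range(config.n_subjects):
        strategy = strategies[chosen[i]]
        # Latent mean RT: fast guessers draw from the RevEx law
        # truncated below the cutoff, everyone else from the law
        # truncated above it, so with the default fast-guesser share
        # (= the law's own sub-cutoff mass) the marginal is RevEx.
        if strategy is Strategy.FAST_GUESSER:
            q = max(u[i] * fast_mass, 1e-12)
        else:
            q = min(fast_mass + u[i] * (1.0 - fast_mass), 1.0 - 1e-12)
        rt = float(np.clip(revex.quantile(q, params), 0.25, 2.95))

        # Two-regime miss model.  Conditional on RT, balanced and
        # over-responding subjects keep a high HIT count at any speed
        # (average HITs stay near or above 20 across the valid RT
        # range), while under-responders carry the steep linear
        # RT/Miss coupling: their expected misses track
        # (rt - rt_at_max_hits)/miss_slope, with stable Correct
        # Rejections.  Large miss counts therefore arise almost only
        # among slow under-responders, so averaging RT within a HIT
        # stratum recovers the miss_slope seconds-per-miss law, while
        # the validity filter stays nearly neutral in RT.
        if strategy is Strategy.UNDER_RESPONDER:
            expected_misses = np.clip(
                (rt - config.rt_at_max_hits) / config.miss_slope, 0.0, 15.0)
        else:
            expected_misses = 1.0 + 3.5 * np.clip((rt - 0.65) / 0.75, 0.0, 1.0)
        p_hit = float(np.clip(1.0 - expected_misses / 25.0,
                              _P_HIT_FLOOR, _P_HIT_CEILING))
        if strategy is Strategy.FAST_GUESSER:
            p_hit = _P_HIT_CEILING

        if strategy is Strategy.OVER_RESPONDER:
            p_fa = rng.beta(6.0, 9.0)  # mean 0.4: Correct Rejections collapse
        elif strategy is Strategy.FAST_GUESSER:
            p_fa = rng.beta(6.0, 4.0)  # mean 0.6: indiscriminate responding
        else:
            p_fa = rng.beta(2.0, 18.0)  # mean 0.1: ~22-23 Correct Rejections

        profiles.append(SubjectProfile(
            p_hit=p_hit, p_fa=float(p_fa), base_mean_rt=rt,
            rt_trial_sd=config.rt_trial_sd, strategy=strategy))
    return profiles


def generate_population(config: PopulationConfig
                        ) -> list[tuple[SubjectProfile, RawSession]]:
    """Simulate a cohort: one (profile, 50-trial session) per subject.

    Deterministic for a fixed ``config`` (including its seed).  Each
    subject receives a freshly generated constrained stimulus order.
    """
    return list(iter_population(config))


def iter_population(config: PopulationConfig, share_plan: bool = False
                    ) -> Iterator[tuple[SubjectProfile, RawSession]]:
    """Streaming variant of :func:`generate_population`.

    With ``share_plan=True`` a single constrained stimulus order is
    generated and reused for the whole cohort.  Session scores are
    invariant to the presentation order (responses depend only on the
    new/repeat split), so sharing changes no score statistic; it only
    skips redundant sequence generation at population scale.
    """
    rng = np.random.default_rng(config.seed)
    profiles = _draw_profiles(config, rng)
    width = max(1, int(math.log10(config.n_subjects)) + 1)
    plan = (generate_sequence(min_lag=config.min_lag,
                              max_run=config.max_run, rng=rng)
            if share_plan else None)
    for i, profile in enumerate(profiles):
        if not share_plan:
            plan = generate_sequence(min_lag=config.min_lag,
                                     max_run=config.max_run, rng=rng)
        yield profile, simulate_session(plan, profile, rng=rng,
                                        session_id=f"sub{i:0{width}d}")


def simulate_cohort_scores(config: PopulationConfig, share_plan: bool = True
                           ) -> tuple[list[SubjectProfile], list[SessionScore]]:
    """Simulate and score a cohort without retaining trial records.

    Convenience for population-scale analyses; runs the full
    plan -> session -> score pipeline per subject (with a cohort-shared
    stimulus order by default, see :func:`iter_population`).
    """
    profiles: list[SubjectProfile] = []
    scores: list[SessionScore] = []
    for profile, session in iter_population(config, share_plan=share_plan):
        profiles.append(profile)
        scores.append(score_session(session))
    return profiles, scores
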