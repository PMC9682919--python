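"""Constrained pseudo-random stimulus sequences for the 50-item CRT.

A session presents 50 images: 25 first showings ("new") and 25 repeats.
The 25 unique images come from 5 categories with 5 images each; within
every category three images are shown twice, one is shown three times
(i.e. repeated twice), and one is never repeated.  The presentation
order is pseudo-random under Gellerman-like run constraints: no more
than ``max_run`` consecutive new images or consecutive repeats, and a
repeat always occurs after the previous showing of the same image.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import SequenceGenerationError, ValidationError

N_CATEGORIES = 5
IMAGES_PER_CATEGORY = 5
N_PRESENTATIONS = 50
N_NEW = 25
N_REPEAT = 25
#: per-category multiset of showing counts: three images twice, one
#: three times, one once.
CATEGORY_OCCURRENCE_COUNTS = (2, 2, 2, 3, 1)

DEFAULT_MAX_RUN = 4
DEFAULT_MIN_LAG = 1
DEFAULT_MAX_ATTEMPTS = 10_000


@dataclass(frozen=True)
class Presentation:
    """One stimulus presentation within a session."""

    position: int  # 1..50
    image_id: str  # e.g. "c3i2" = category 3, image 2
    is_repeat: bool
    occurrence_index: int  # 1 for a first showing, 2 or 3 for repeats


@dataclass(frozen=True)
class StimulusPlan:
    """The ordered 50-presentation sequence with repeat bookkeeping."""

    presentations: tuple[Presentation, ...]
    seed: int | None = None
    min_lag: int = DEFAULT_MIN_LAG
    max_run: int = DEFAULT_MAX_RUN

    def __len__(self) -> int:
        return len(self.presentations)

    @property
    def n_new(self) -> int:
        return sum(not p.is_repeat for p in self.presentations)

    @property
    def n_repeat(self) -> int:
        return sum(p.is_repeat for p in self.presentations)


def image_id(category: int, index: int) -> str:
    return f"c{category}i{index}"


def validate_plan(plan: StimulusPlan,
                  min_lag: int | None = None,
                  max_run: int | None = None) -> list[str]:
    """Brute-force check of every StimulusPlan invariant.

    Returns a list of human-readable violations (empty when valid).
    Used both by the generator and, independently, by the test suite.
    """
    min_lag = plan.min_lag if min_lag is None else min_lag
    max_run = plan.max_run if max_run is None else max_run
    problems: list[str] = []
    ps = plan.presentations

    if len(ps) != N_PRESENTATIONS:
        problems.append(f"expected {N_PRESENTATIONS} presentations, got {len(ps)}")
        return problems

    if [p.position for p in ps] != list(range(1, N_PRESENTATIONS + 1)):
        problems.append("positions are not 1..50 in order")

    n_new = sum(not p.is_repeat for p in ps)
    if n_new != N_NEW:
        problems.append(f"expected {N_NEW} first showings, got {n_new}")
    if len(ps) - n_new != N_REPEAT:
        problems.append(f"expected {N_REPEAT} repeats, got {len(ps) - n_new}")

    # Per-category structure: 5 images each, occurrence multiset {2,2,2,3,1}.
    by_category: dict[str, dict[str, int]] = {}
    for p in ps:
        cat = p.image_id.split("i")[0]
        by_category.setdefault(cat, {}).setdefault(p.image_id, 0)
        by_category[cat][p.image_id] += 1
    if len(by_category) != N_CATEGORIES:
        problems.append(f"expected {N_CATEGORIES} categories, got {len(by_category)}")
    for cat, counts in sorted(by_category.items()):
        if len(counts) != IMAGES_PER_CATEGORY:
            problems.append(f"category {cat}: expected {IMAGES_PER_CATEGORY} "
                            f"distinct images, got {len(counts)}")
        if sorted(counts.values()) != sorted(CATEGORY_OCCURRENCE_COUNTS):
            problems.append(f"category {cat}: occurrence counts "
                            f"{sorted(counts.values())} != "
                            f"{sorted(CATEGORY_OCCURRENCE_COUNTS)}")

    # Run-length constraint on the new/repeat alternation.
    run = 0
    prev: bool | None = None
    for p in ps:
        run = run + 1 if p.is_repeat == prev else 1
        prev = p.is_repeat
        if run > max_run:
            problems.append(f"run of more than {max_run} "
                            f"{'repeats' if p.is_repeat else 'first showings'} "
                            f"ending at position {p.position}")
            break

    # Repeat ordering and lag: every repeat strictly after the previous
    # occurrence of the same image, by at least min_lag positions.
    last_seen: dict[str, int] = {}
    occ_seen: dict[str, int] = {}
    for p in ps:
        occ_seen[p.image_id] = occ_seen.get(p.image_id, 0) + 1
        if p.occurrence_index != occ_seen[p.image_id]:
            problems.append(f"position {p.position}: occurrence_index "
                            f"{p.occurrence_index} != observed {occ_seen[p.image_id]}")
        if p.is_repeat:
            if p.image_id not in last_seen:
                problems.append(f"position {p.position}: repeat of {p.image_id} "
                                "before any first showing")
            elif p.position - last_seen[p.image_id] < min_lag:
                problems.append(f"position {p.position}: repeat of {p.image_id} "
                                f"violates minimum lag {min_lag}")
        elif p.image_id in last_seen:
            problems.append(f"position {p.position}: {p.image_id} marked new "
                            "but already shown")
        last_seen[p.image_id] = p.position

    return problems


def _draw_skeleton(rng: np.random.Generator,
                   max_run: int) -> np.ndarray | None:
    """Random 25-new/25-repeat arrangement, rejected on run length."""
    kinds = np.zeros(N_PRESENTATIONS, dtype=bool)
    kinds[:N_REPEAT] = True
    rng.shuffle(kinds)
    if kinds[0]:  # cannot open with a repeat
        return None
    # longest run = longest gap between change points
    changes = np.flatnonzero(np.diff(kinds)) + 1
    edges = np.concatenate(([0], changes, [N_PRESENTATIONS]))
    if np.diff(edges).max() > max_run:
        return None
    return kinds


def _attempt_sequence(rng: np.random.Generator,
                      min_lag: int, max_run: int) -> list[Presentation] | None:
    """One rejection-sampling attempt; None when a constraint dead-ends."""
    kinds = _draw_skeleton(rng, max_run)
    if kinds is None:
        return None

    # Assign occurrence counts to images within each category.
    repeats_left: dict[str, int] = {}
    images: list[str] = []
    for cat in range(1, N_CATEGORIES + 1):
        counts = list(CATEGORY_OCCURRENCE_COUNTS)
        rng.shuffle(counts)
        for idx, count in enumerate(counts, start=1):
            img = image_id(cat, idx)
            images.append(img)
            repeats_left[img] = count - 1

    # Feasibility of a first-show order depends only on prefix repeat
    # supply (each repeat slot needs a pending repeat among the images
    # already shown), so cheap orders can be rejected before assignment.
    counts = np.array([repeats_left[img] for img in images])
    first_order: list[str] | None = None
    for _ in range(50):
        order = rng.permutation(len(images))
        delta = np.full(N_PRESENTATIONS, -1, dtype=int)
        delta[~kinds] = counts[order]
        if np.cumsum(delta).min() >= 0:
            first_order = [images[i] for i in order]
            break
    if first_order is None:
        return None
    first_iter = iter(first_order)

    presentations: list[Presentation] = []
    last_seen: dict[str, int] = {}
    occ: dict[str, int] = {}
    for pos, is_repeat in enumerate(kinds, start=1):
        if not is_repeat:
            img = next(first_iter)
        else:
            eligible = [i for i, p in last_seen.items()
                        if repeats_left[i] > 0 and pos - p >= min_lag]
            if not eligible:
                return None
            img = eligible[rng.integers(len(eligible))]
            repeats_left[img] -= 1
        occ[img] = occ.get(img, 0) + 1
        last_seen[img] = pos
        presentations.append(Presentation(pos, img, bool(is_repeat), occ[img]))
    return presentations


def generate_sequence(seed: int | None = None,
                      min_lag: int = DEFAULT_MIN_LAG,
                      max_run: int = DEFAULT_MAX_RUN,
                      max_attempts: int = DEFAULT_MAX_ATTEMPTS,
                      rng: np.random.Generator | None = None) -> StimulusPlan:
    """Generate a constrained pseudo-random StimulusPlan.

    Rejection sampling: attempts are drawn until one satisfies every
    constraint; identical seeds yield identical plans.

    Parameters
    ----------
    seed :
        RNG seed (ignored when ``rng`` is given).
    min_lag :
        Minimum position difference between an image's repeat and its
        previous showing; 1 permits immediate adjacency.
    max_run :
        Longest allowed run of consecutive first showings or repeats.
    max_attempts :
        Retry budget before raising :class:`SequenceGenerationError`.
    """
    if min_lag < 1:
        raise ValidationError(f"min_lag must be >= 1, got {min_lag}")
    if max_run < 1:
        raise ValidationError(f"max_run must be >= 1, got {max_run}")
    if min_lag > max_run:
        # the first repeat needs min_lag leading first showings, which
        # would exceed the permitted run length
        raise ValidationError(
            f"min_lag={min_lag} with max_run={max_run} admits no sequence")
    if rng is None:
        rng = np.random.default_rng(seed)
    for _ in range(max_attempts):
        result = _attempt_sequence(rng, min_lag, max_run)
        if result is not None:
            plan = StimulusPlan(tuple(result), seed=seed,
                                min_lag=min_lag, max_run=max_run)
            problems = validate_plan(plan)
            if problems:  # pragma: no cover - generator/validator disagreement
                raise SequenceGenerationError("; ".join(problems))
            return plan
    raise SequenceGenerationError(
        f"no admissible sequence found in {max_attempts} attempts "
        f"(min_lag={min_lag}, max_run={max_run})")
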