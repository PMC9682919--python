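"""Population-level tables and conditional curves from session scores.

Conventions mirror the normative table: for the count metrics
(n_correct, hits, crs) the tabulated fraction at a threshold x is the
fraction of tests STRICTLY BELOW x; for mean HIT response time the
fraction is that of tests STRICTLY SLOWER than the threshold (the
survival convention).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError
from .qc import SubsetPolicy, analysis_subset
from .scoring import SessionScore

COUNT_METRICS = ("n_correct", "hits", "crs", "total_responses")
#: variables a conditional curve may stratify or average over
CURVE_METRICS = ("rt", "hits", "crs", "n_correct", "total_responses")

_SCORE_ATTR = {
    "n_correct": "n_correct",
    "hits": "hits",
    "crs": "correct_rejections",
    "total_responses": "total_responses",
    "rt": "mean_hit_rt",
}

DEFAULT_THRESHOLDS = {
    "n_correct": list(range(30, 51)),
    "hits": list(range(9, 26)),
    "crs": list(range(9, 26)),
    "rt": [round(0.5 + 0.1 * i, 1) for i in range(16)],
}


def scores_to_frame(scores: Iterable[SessionScore]) -> pd.DataFrame:
    """Tabulate scores as a DataFrame (``rt`` = mean HIT RT, seconds)."""
    rows = [{
        "session_id": s.session_id,
        "hits": s.hits,
        "misses": s.misses,
        "crs": s.correct_rejections,
        "false_alarms": s.false_alarms,
        "n_correct": s.n_correct,
        "total_responses": s.total_responses,
        "rt": np.nan if s.mean_hit_rt is None else s.mean_hit_rt,
    } for s in scores]
    if not rows:
        return pd.DataFrame(columns=["session_id", "hits", "misses", "crs",
                                     "false_alarms", "n_correct",
                                     "total_responses", "rt"])
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class PercentileTable:
    """Cumulative percentile columns keyed by metric.

    ``columns[metric]`` is a (thresholds, fractions) pair of aligned
    arrays; thresholds ascend, and fractions follow the strictly-below
    (counts) or strictly-slower (rt) convention.
    """

    columns: dict[str, tuple[np.ndarray, np.ndarray]]
    n: int | None = None

    def metrics(self) -> list[str]:
        return list(self.columns)

    def lookup(self, metric: str, value: float) -> tuple[float, bool]:
        """Percentile fraction at ``value``, linearly interpolated.

        Returns ``(fraction, clamped)``; ``clamped`` flags a value
        outside the tabulated threshold range (clamped to the ends).
        """
        if metric not in self.columns:
            raise ValidationError(f"unknown metric {metric!r}; "
                                  f"have {sorted(self.columns)}")
        thresholds, fractions = self.columns[metric]
        clamped = bool(value < thresholds[0] or value > thresholds[-1])
        frac = float(np.interp(value, thresholds, fractions))
        return frac, clamped

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for metric, (thresholds, fractions) in self.columns.items():
            for t, f in zip(thresholds, fractions):
                rows.append({"metric": metric, "threshold": float(t),
                             "fraction": float(f)})
        return pd.DataFrame(rows)


def percentile_table(scores: Sequence[SessionScore],
                     thresholds: dict[str, Sequence[float]] | None = None
                     ) -> PercentileTable:
    """Tabulate cumulative percentile columns from scores.

    For count metrics, entry(x) = #{score < x}/N; for rt,
    entry(t) = #{mean_hit_rt > t}/N (sessions without a mean HIT RT
    count as not slower).
    """
    scores = list(scores)
    if not scores:
        raise ValidationError("percentile_table requires a nonempty score set")
    thresholds = DEFAULT_THRESHOLDS if thresholds is None else thresholds
    n = len(scores)
    columns: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for metric, ts in thresholds.items():
        if metric not in _SCORE_ATTR:
            raise ValidationError(f"unknown metric {metric!r}")
        ts = np.asarray(sorted(ts), dtype=float)
        values = np.array([
            v for s in scores
            if (v := getattr(s, _SCORE_ATTR[metric])) is not None
        ], dtype=float)
        if metric == "rt":
            fractions = np.array([(values > t).sum() / n for t in ts])
        else:
            fractions = np.array([(values < t).sum() / n for t in ts])
        columns[metric] = (ts, fractions)
    return PercentileTable(columns=columns, n=n)


@dataclass(frozen=True)
class MetricPercentile:
    metric: str
    value: float
    fraction: float
    clamped: bool


def individual_percentile(score: SessionScore,
                          reference: PercentileTable
                          ) -> dict[str, MetricPercentile]:
    """Locate one session's metrics within a reference percentile table.

    Reports every reference metric the score carries; a missing mean
    HIT RT simply omits the rt entry.
    """
    out: dict[str, MetricPercentile] = {}
    for metric in reference.metrics():
        value = getattr(score, _SCORE_ATTR[metric], None)
        if value is None:
            continue
        fraction, clamped = reference.lookup(metric, float(value))
        out[metric] = MetricPercentile(metric=metric, value=float(value),
                                       fraction=fraction, clamped=clamped)
    return out


@dataclass(frozen=True)
class ConditionalCurve:
    """Per-stratum means of one metric conditioned on another."""

    by: str
    of: str
    strata: np.ndarray
    means: np.ndarray
    counts: np.ndarray
    #: True where a stratum holds fewer than the stability threshold
    sparse: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({self.by: self.strata, f"mean_{self.of}": self.means,
                             "n": self.counts, "sparse": self.sparse})


def conditional_curve(scores: Iterable[SessionScore], by: str, of: str,
                      rt_bin_width: float = 0.001,
                      min_stratum: int = 5) -> ConditionalCurve:
    """Average ``of`` within strata of ``by``.

    ``by`` may be any of rt, hits, crs, n_correct, total_responses; rt
    strata are right-open bins of ``rt_bin_width`` seconds (labelled by
    their left edge), defaulting to the millisecond resolution the
    session means are recorded at.  Strata with fewer than
    ``min_stratum`` observations are flagged sparse, not dropped.
    """
    if by not in CURVE_METRICS:
        raise ValidationError(f"unknown stratum variable {by!r}; "
                              f"choose from {CURVE_METRICS}")
    if of not in CURVE_METRICS:
        raise ValidationError(f"unknown response metric {of!r}; "
                              f"choose from {CURVE_METRICS}")
    frame = scores_to_frame(scores)
    if frame.empty:
        raise ValidationError("conditional_curve requires a nonempty score set")
    cols = pd.DataFrame({"_by": frame[by], "_of": frame[of]})
    if "rt" in (by, of):
        cols = cols.dropna()
    key = cols["_by"]
    if by == "rt":
        key = np.floor(key / rt_bin_width + 1e-9) * rt_bin_width
        key = key.round(9)
    grouped = cols.groupby(key)["_of"].agg(["mean", "size"]).sort_index()
    return ConditionalCurve(
        by=by, of=of,
        strata=grouped.index.to_numpy(dtype=float),
        means=grouped["mean"].to_numpy(dtype=float),
        counts=grouped["size"].to_numpy(dtype=int),
        sparse=grouped["size"].to_numpy() < min_stratum,
    )


@dataclass(frozen=True)
class CorrelationReport:
    """Squared Pearson correlation of one metric pair."""

    pair: tuple[str, str]
    r_squared: float | None
    n: int
    undefined: bool = False


def correlation_report(scores: Sequence[SessionScore],
                       pairs: Sequence[tuple[str, str]],
                       subset_policy: SubsetPolicy | None = SubsetPolicy()
                       ) -> list[CorrelationReport]:
    """Squared Pearson correlations for metric pairs.

    By default the analysis-subset outlier filter is applied first
    (pass ``subset_policy=None`` to correlate the scores as given).
    Zero-variance inputs yield an undefined report instead of NaN.
    """
    scores = list(scores)
    if len(scores) < 3:
        raise ValidationError("correlation_report requires at least 3 scores")
    if subset_policy is not None:
        scores = list(analysis_subset(scores, subset_policy).kept)
    frame = scores_to_frame(scores)
    reports = []
    for x, y in pairs:
        for name in (x, y):
            if name not in _SCORE_ATTR:
                raise ValidationError(f"unknown metric {name!r}")
        sub = frame[[x, y]].dropna()
        n = len(sub)
        if n < 3 or sub[x].nunique() < 2 or sub[y].nunique() < 2:
            reports.append(CorrelationReport(pair=(x, y), r_squared=None,
                                             n=n, undefined=True))
            continue
        r = np.corrcoef(sub[x], sub[y])[0, 1]
        reports.append(CorrelationReport(pair=(x, y), r_squared=float(r ** 2),
                                         n=n))
    return reports
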