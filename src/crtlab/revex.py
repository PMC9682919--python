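"""The reverse-exponential (RevEx) model for mean response times.

The distribution of per-session mean HIT response times is described by
a two-parameter law in which the negative natural log of the cumulative
distribution (fraction of sessions faster than t) decays exponentially
in t:

    -ln CD(t) = a * exp(-b * t)

so that

    CD(t)            = exp(-a * exp(-b * t))          (fraction faster)
    Percentile(t)    = 1 - exp(-a * exp(-b * t))      (fraction slower)
    density(t)       = a * b * exp(-b * t) * CD(t)

Algebraically this is a Gumbel (extreme-value, maximum) distribution
with location mu = ln(a)/b and scale beta = 1/b; the closed forms below
are written in the (a, b) parameterization the model is reported in.
``a`` is a dimensionless amplitude and ``b`` a decay rate per second:
every ln(2)/b seconds of slowing halves -ln(CD), which for the fitted
b of about 6.7/s is the "~100 ms per halving of processing resources"
reading of the model.

Fitting follows the original spreadsheet procedure: build the empirical
fraction-faster cumulative distribution on a millisecond grid over a
central RT window, take y = -ln(CD), and fit y = a*exp(-b*t) by
ordinary least squares on ln(y) versus t (an exponential-trendline
fit); the reported R^2 is that of the log-linear regression.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats
from sklearn.base import BaseEstimator
from sklearn.utils import check_random_state

from .errors import FitError, ValidationError

#: Published amplitude and decay rate of the model fitted to 282,140
#: online CRT sessions; used as calibration defaults throughout.
PUBLISHED_A = 263.94
PUBLISHED_B = 6.682

DEFAULT_FIT_LOW = 0.6
DEFAULT_FIT_HIGH = 1.6
DEFAULT_TRIM = 0.005
DEFAULT_GRID_WIDTH = 0.001
MIN_FIT_VALUES = 100


@dataclass(frozen=True)
class RevExParams:
    """Amplitude ``a`` and decay rate ``b`` (per second) of the model."""

    a: float = PUBLISHED_A
    b: float = PUBLISHED_B

    def __post_init__(self):
        if not (self.a > 0 and math.isfinite(self.a)):
            raise ValidationError(f"amplitude a must be positive, got {self.a}")
        if not (self.b > 0 and math.isfinite(self.b)):
            raise ValidationError(f"decay rate b must be positive, got {self.b}")

    @property
    def location(self) -> float:
        """Gumbel location mu = ln(a)/b, seconds (equals the mode)."""
        return math.log(self.a) / self.b

    @property
    def scale(self) -> float:
        """Gumbel scale beta = 1/b, seconds."""
        return 1.0 / self.b

    @property
    def mode(self) -> float:
        return self.location

    @property
    def median(self) -> float:
        return (math.log(self.a) - math.log(math.log(2.0))) / self.b

    @property
    def halving_time(self) -> float:
        """RT shift that halves -ln(CD): ln(2)/b, seconds."""
        return math.log(2.0) / self.b


@dataclass(frozen=True)
class FitResult:
    """Outcome of a RevEx fit to a sample of mean RTs."""

    params: RevExParams
    r_squared: float
    fit_range: tuple[float, float]
    n_used: int
    n_grid: int
    n_grid_excluded: int


def _as_params(params: RevExParams | None) -> RevExParams:
    return RevExParams() if params is None else params


def cdf(t, params: RevExParams | None = None):
    """Fraction of the population faster than (at or below) ``t`` seconds."""
    p = _as_params(params)
    return np.exp(-p.a * np.exp(-p.b * np.asarray(t, dtype=float)))


def survival_percentile(t, params: RevExParams | None = None):
    """Fraction of the population slower than ``t`` seconds.

    This is the percentile convention of the normative table:
    ``1 - exp(-a * exp(-b * t))``, strictly decreasing in t.
    """
    t = np.asarray(t, dtype=float)
    if np.any(t <= 0):
        raise ValidationError("t must be positive")
    p = _as_params(params)
    out = -np.expm1(-p.a * np.exp(-p.b * t))
    return float(out) if out.ndim == 0 else out

def density(t, params: RevExParams | None = None):
    """Probability density (per second) of the model at ``t``."""
    p = _as_params(params)
    t = np.asarray(t, dtype=float)
    return p.a * p.b * np.exp(-p.b * t) * np.exp(-p.a * np.exp(-p.b * t))


def quantile(q, params: RevExParams | None = None):
    """Exact inverse of :func:`cdf`: the RT at fraction-faster ``q``."""
    q = np.asarray(q, dtype=float)
    if np.any((q <= 0) | (q >= 1)):
        raise ValidationError("quantile probability must lie in (0, 1)")
    p = _as_params(params)
    out = -np.log(-np.log(q) / p.a) / p.b
    return float(out) if out.ndim == 0 else out


def model_mode(params: RevExParams | None = None) -> float:
    """Peak of the density: ln(a)/b seconds."""
    return _as_params(params).mode


def model_median(params: RevExParams | None = None) -> float:
    """50% point of the cumulative distribution: (ln a - ln ln 2)/b."""
    return _as_params(params).median


def sample(n: int, params: RevExParams | None = None,
           seed=None) -> np.ndarray:
    """Draw ``n`` mean RTs by inverse-transform sampling."""
    if n < 1:
        raise ValidationError(f"n must be >= 1, got {n}")
    rng = np.random.default_rng(seed)
    return quantile(rng.uniform(size=n), _as_params(params))


def empirical_cd_grid(values: np.ndarray,
                      low: float, high: float,
                      grid_width: float = DEFAULT_GRID_WIDTH
                      ) -> tuple[np.ndarray, np.ndarray]:
    """Empirical fraction-faster CD on a regular grid over [low, high].

    Right-closed counting (CD(t) = #{x <= t} / n), matching per-
    millisecond cumulative tabulation of the session means.
    """
    values = np.sort(np.asarray(values, dtype=float))
    n_grid = int(np.floor((high - low) / grid_width + 1e-9)) + 1
    grid = low + grid_width * np.arange(n_grid)
    cd = np.searchsorted(values, grid + grid_width * 1e-6,
                         side="right") / len(values)
    return grid, cd


def fit_revex(values,
              fit_low: float = DEFAULT_FIT_LOW,
              fit_high: float = DEFAULT_FIT_HIGH,
              trim: float = DEFAULT_TRIM,
              grid_width: float = DEFAULT_GRID_WIDTH) -> FitResult:
    """Fit the RevEx model to a sample of per-session mean RTs.

    Procedure: round(trim*n) values are set aside from each tail
    (count-based symmetric trimming, restricting the evaluated grid to
    the retained range); the empirical fraction-faster CD over the full
    sample is evaluated at ``grid_width`` steps across the intersection
    of [fit_low, fit_high] with that range; grid points with CD = 0 or
    CD = 1 are excluded (y = -ln CD is undefined there) and counted;
    ln(y) is regressed on t by OLS.  The slope gives -b, the intercept
    exp-transforms to a, and ``r_squared`` is the coefficient of
    determination of the log-linear regression.

    Raises :class:`FitError` when fewer than 100 values fall inside the
    fit range.
    """
    if not 0 <= trim < 0.5:
        raise ValidationError(f"trim must be in [0, 0.5), got {trim}")
    if not fit_low < fit_high:
        raise ValidationError("fit_low must be below fit_high")
    values = np.sort(np.asarray(values, dtype=float).ravel())
    n = len(values)
    n_used = int(np.sum((values >= fit_low) & (values <= fit_high)))
    if n_used < MIN_FIT_VALUES:
        raise FitError(
            f"only {n_used} values inside [{fit_low}, {fit_high}] s; "
            f"need at least {MIN_FIT_VALUES}")

    k = int(round(trim * n))
    lo = max(fit_low, values[k]) if k else fit_low
    hi = min(fit_high, values[n - 1 - k]) if k else fit_high
    grid, cd = empirical_cd_grid(values, lo, hi, grid_width)

    keep = (cd > 0.0) & (cd < 1.0)
    n_excluded = int(np.sum(~keep))
    y = -np.log(cd[keep])
    reg = stats.linregress(grid[keep], np.log(y))
    b = -reg.slope
    a = math.exp(reg.intercept)
    return FitResult(params=RevExParams(a=a, b=b),
                     r_squared=reg.rvalue ** 2,
                     fit_range=(float(lo), float(hi)),
                     n_used=n_used,
                     n_grid=len(grid),
                     n_grid_excluded=n_excluded)


class RevExFitter(BaseEstimator):
    """Scikit-learn style estimator for the RevEx mean-RT distribution.

    Mirrors the density-estimator interface (``fit`` / ``score_samples``
    / ``sample``).  ``fit`` takes a 1-D array (or single-column matrix)
    of per-session mean HIT response times in seconds.

    Parameters
    ----------
    fit_low, fit_high :
        RT window (seconds) over which the cumulative distribution is
        regressed.
    trim :
        Fraction of values set aside from each tail before gridding.
    grid_width :
        Grid step (seconds) of the empirical cumulative distribution.

    Attributes
    ----------
    a_, b_ : float
        Fitted amplitude and decay rate.
    params_ : RevExParams
        Fitted parameters with derived location/scale/median/mode.
    r_squared_ : float
        Coefficient of determination of the log-linear regression.
    fit_range_ : tuple of float
        Actual (post-trim) RT range the grid covered.
    n_used_ : int
        Number of sample values inside the fit range.
    """

    def __init__(self, fit_low: float = DEFAULT_FIT_LOW,
                 fit_high: float = DEFAULT_FIT_HIGH,
                 trim: float = DEFAULT_TRIM,
                 grid_width: float = DEFAULT_GRID_WIDTH):
        self.fit_low = fit_low
        self.fit_high = fit_high
        self.trim = trim
        self.grid_width = grid_width

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if X.ndim == 2 and X.shape[1] == 1:
            X = X.ravel()
        if X.ndim != 1:
            raise ValidationError(
                "RevExFitter expects a 1-D sample of mean RTs "
                f"(or a single-column matrix), got shape {X.shape}")
        result = fit_revex(X, fit_low=self.fit_low, fit_high=self.fit_high,
                           trim=self.trim, grid_width=self.grid_width)
        self.params_ = result.params
        self.a_ = result.params.a
        self.b_ = result.params.b
        self.r_squared_ = result.r_squared
        self.fit_range_ = result.fit_range
        self.n_used_ = result.n_used
        self.fit_result_ = result
        return self

    def score_samples(self, X):
        """Log density of the fitted model at each value of ``X``."""
        X = np.asarray(X, dtype=float).ravel()
        return np.log(density(X, self.params_))

    def score(self, X, y=None):
        """Mean log density (log-likelihood per observation)."""
        return float(np.mean(self.score_samples(X)))

    def sample(self, n_samples: int = 1, random_state=None) -> np.ndarray:
        """Inverse-transform draws from the fitted distribution."""
        rng = check_random_state(random_state)
        return quantile(rng.uniform(size=n_samples), self.params_)
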