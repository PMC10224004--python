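"""Drug-cyclodextrin association constants by the phase-distribution method.

A 1:1 inclusion complex confined to the aqueous phase suppresses the
apparent distribution coefficient:

    D(C) = D0 / (1 + Kc * C)          (exact 1:1 binding model)

where D0 is the no-host coefficient and C the total cyclodextrin
concentration.  The working estimator is the log-log linearization

    log10((D0 - D) / D0) = log10(Kc) + alpha * log10(C)

whose slope ``alpha`` indicates the complex stoichiometry (alpha ~ 1 for
1:1) and whose intercept is reported both as-is and as its antilog.  In
the small-saturation limit Kc*C << 1 the linearization is exact because
(D0 - D)/D0 = Kc*C/(1 + Kc*C) ~ Kc*C.

``CdBinding1to1`` fits the exact hyperbolic model directly and serves as
an independent oracle for the linearized estimator.

Note the two logarithm conventions in this package: the linearization
here is base 10, the van't Hoff analysis uses natural log.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats
from sklearn.base import BaseEstimator, RegressorMixin

from .errors import InsufficientDataError, NonSuppressedPointError

__all__ = [
    "CdSuppressionSeries",
    "KcFit",
    "NonlinearKcFit",
    "linearized_point",
    "PhaseDistributionKc",
    "CdBinding1to1",
    "fit_kc",
    "fit_kc_nonlinear",
]


@dataclass
class CdSuppressionSeries:
    """Distribution coefficients of one solute at several host concentrations."""

    system_id: str
    cd_name: str
    D0: float
    points: list[tuple]  # (C_CD mol/L, D)

    def __post_init__(self):
        if self.D0 <= 0:
            raise ValueError("D0 must be positive")
        pts = [(float(c), float(d)) for c, d in self.points]
        for c, d in pts:
            if c <= 0:
                raise ValueError(f"non-positive host concentration {c}")
            if not 0 < d <= self.D0:
                # D == D0 (no binding) is representable; the log transform
                # itself rejects non-suppressed points.
                raise ValueError(
                    f"D={d} outside (0, D0={self.D0}] at C={c}")
        self.points = pts
        ordered = sorted(pts)
        if any(d2 >= d1 for (_, d1), (_, d2) in zip(ordered, ordered[1:])):
            warnings.warn(
                "distribution coefficients are not strictly decreasing with "
                "host concentration", stacklevel=2)

    @property
    def concentrations(self) -> np.ndarray:
        return np.array([c for c, _ in self.points])

    @property
    def coefficients(self) -> np.ndarray:
        return np.array([d for _, d in self.points])


@dataclass(frozen=True)
class KcFit:
    """Linearized-regression estimate of the association constant."""

    intercept: float      # log10 Kc as reported
    Kc_antilog: float     # 10**intercept, per mol
    alpha: float          # stoichiometry exponent
    se_intercept: float
    se_alpha: float
    R: float              # pair correlation coefficient
    rss: float
    F: float              # Fisher criterion R^2*(n-2)/(1-R^2)
    n: int


@dataclass(frozen=True)
class NonlinearKcFit:
    Kc: float  # per mol
    rss: float
    n: int


def linearized_point(D0: float, D: float, C_CD: float) -> tuple:
    """Map one suppression measurement to (x, y) of the log-log line."""
    if C_CD <= 0:
        raise ValueError("C_CD must be positive")
    if not 0 < D < D0:
        raise NonSuppressedPointError(
            f"D={D} must lie strictly inside (0, D0={D0})")
    return math.log10(C_CD), math.log10((D0 - D) / D0)


class PhaseDistributionKc(RegressorMixin, BaseEstimator):
    """OLS on the log-log suppression linearization.

    Parameters
    ----------
    d0 : float
        Distribution coefficient without cyclodextrin.

    ``fit(C, D)`` takes host concentrations (mol/L) and suppressed
    distribution coefficients.  Fitted attributes: ``intercept_``
    (log10 Kc), ``kc_`` (its antilog), ``alpha_`` (slope), standard
    errors, ``rvalue_``, ``rss_``, ``fvalue_`` and ``n_obs_``.
    """

    def __init__(self, d0: float = None):
        self.d0 = d0

    def fit(self, X, y):
        if self.d0 is None or self.d0 <= 0:
            raise ValueError("d0 must be set to a positive value")
        c = np.asarray(X, dtype=float).reshape(-1)
        d = np.asarray(y, dtype=float).reshape(-1)
        if c.shape != d.shape:
            raise ValueError("C and D must have the same length")
        if c.size < 2:
            raise InsufficientDataError("need at least 2 suppression points")
        xy = [linearized_point(self.d0, di, ci) for ci, di in zip(c, d)]
        x = np.array([p[0] for p in xy])
        yv = np.array([p[1] for p in xy])
        if np.unique(x).size < 2:
            raise InsufficientDataError("need at least 2 distinct host levels")
        res = stats.linregress(x, yv)
        n = x.size
        resid = yv - (res.intercept + res.slope * x)
        rss = float(resid @ resid)
        r2 = res.rvalue**2
        if n == 2 or rss <= 1e-300 or (1 - r2) <= 0:
            fval = math.inf if n > 2 else 0.0
        else:
            fval = r2 / (1 - r2) * (n - 2)
        self.intercept_ = float(res.intercept)
        self.kc_ = 10.0 ** self.intercept_
        self.alpha_ = float(res.slope)
        self.se_intercept_ = float(res.intercept_stderr) if n > 2 else 0.0
        self.se_alpha_ = float(res.stderr) if n > 2 else 0.0
        self.rvalue_ = float(res.rvalue)
        self.rss_ = 0.0 if n == 2 else rss
        self.fvalue_ = fval
        self.n_obs_ = int(n)
        return self

    def predict(self, X):
        """Predicted distribution coefficients D0*(1 - 10^(i + a*log10 C))."""
        c = np.asarray(X, dtype=float).reshape(-1)
        frac = 10.0 ** (self.intercept_ + self.alpha_ * np.log10(c))
        return self.d0 * (1.0 - frac)

    def to_fit(self) -> KcFit:
        return KcFit(self.intercept_, self.kc_, self.alpha_,
                     self.se_intercept_, self.se_alpha_, self.rvalue_,
                     self.rss_, self.fvalue_, self.n_obs_)


class CdBinding1to1(RegressorMixin, BaseEstimator):
    """Exact 1:1 binding fit D = D0/(1 + Kc*C), least squares with Kc >= 0.

    Independent oracle for :class:`PhaseDistributionKc`: no
    linearization, no log transform.
    """

    def __init__(self, d0: float = None):
        self.d0 = d0

    def fit(self, X, y):
        if self.d0 is None or self.d0 <= 0:
            raise ValueError("d0 must be set to a positive value")
        c = np.asarray(X, dtype=float).reshape(-1)
        d = np.asarray(y, dtype=float).reshape(-1)
        if c.size < 1:
            raise InsufficientDataError("need at least 1 point")
        if np.all(d >= self.d0):
            warnings.warn("no suppression in any point; returning Kc = 0",
                          stacklevel=2)
            self.kc_ = 0.0
            self.rss_ = float(((d - self.d0) ** 2).sum())
            self.n_obs_ = int(c.size)
            return self

        def resid(k):
            return d - self.d0 / (1.0 + k[0] * c)

        # moment start from the most-suppressed point
        i = int(np.argmin(d))
        k0 = max((self.d0 / d[i] - 1.0) / c[i], 1e-9)
        sol = optimize.least_squares(resid, x0=[k0], bounds=([0.0], [np.inf]))
        self.kc_ = float(sol.x[0])
        self.rss_ = float(2 * sol.cost)
        self.n_obs_ = int(c.size)
        return self

    def predict(self, X):
        c = np.asarray(X, dtype=float).reshape(-1)
        return self.d0 / (1.0 + self.kc_ * c)

    def to_fit(self) -> NonlinearKcFit:
        return NonlinearKcFit(self.kc_, self.rss_, self.n_obs_)


def fit_kc(series: CdSuppressionSeries) -> KcFit:
    """Linearized (log-log) association-constant fit."""
    est = PhaseDistributionKc(d0=series.D0)
    est.fit(series.concentrations, series.coefficients)
    return est.to_fit()


def fit_kc_nonlinear(series: CdSuppressionSeries) -> NonlinearKcFit:
    """Exact 1:1 hyperbolic fit (oracle for the linearized estimator)."""
    est = CdBinding1to1(d0=series.D0)
    est.fit(series.concentrations, series.coefficients)
    return est.to_fit()
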