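"""Franz diffusion cell flux and apparent permeability.

A vertical Franz cell holds a donor solution above a membrane and a
small acceptor compartment below it.  Acceptor aliquots are withdrawn on
a fixed schedule and replaced with blank buffer, so the raw acceptor
concentrations must be corrected for the analyte carried away by the
earlier withdrawals before a flux can be read off:

    Q_k = C_k * V_acceptor + sum_{i<k} C_i * V_sample      (mol)

The steady-state flux J is the OLS slope of Q/A against time (s), and
the apparent permeability is Papp = J / C0 with the donor concentration
expressed per cm^3.  Sink compliance means no acceptor sample exceeded
10% of the donor concentration.

Units: inputs in mol/L, mL, cm^2 and minutes; internal computation in
mol, cm and seconds; Papp in cm/s.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats
from sklearn.base import BaseEstimator, RegressorMixin

from .errors import DomainError, InsufficientDataError

__all__ = [
    "FranzCellGeometry",
    "PAPER_GEOMETRY",
    "PermeationRun",
    "PermeabilityResult",
    "cumulative_amount",
    "steady_state_flux",
    "apparent_permeability",
    "sink_check",
    "FranzPermeability",
    "analyze_run",
]

SINK_LIMIT = 0.10  # acceptor/donor concentration ratio


@dataclass(frozen=True)
class FranzCellGeometry:
    """Cell geometry and sampling schedule."""

    area: float = 0.785          # cm^2 effective membrane area
    V_donor: float = 7.0         # mL
    V_acceptor: float = 1.0      # mL
    V_sample: float = 0.5        # mL withdrawn per sampling
    sample_interval: float = 30  # min
    duration: float = 300        # min

    def __post_init__(self):
        vals = (self.area, self.V_donor, self.V_acceptor, self.V_sample,
                self.sample_interval, self.duration)
        if any(v <= 0 for v in vals):
            raise ValueError("all geometry fields must be positive")
        if self.V_sample > self.V_acceptor:
            raise ValueError("V_sample cannot exceed V_acceptor")


#: 0.785 cm^2 membrane, 7 mL donor / 1 mL acceptor, 0.5 mL each 30 min, 5 h
PAPER_GEOMETRY = FranzCellGeometry()


@dataclass
class PermeationRun:
    """Acceptor time course of one permeation experiment.

    ``samples`` holds (t_min, C_acceptor mol/L) pairs measured at
    withdrawal, before replacement with blank buffer.
    """

    solute_id: str
    C0: float  # donor concentration, mol/L
    geometry: FranzCellGeometry
    samples: list[tuple]

    def __post_init__(self):
        if self.C0 <= 0:
            raise ValueError("C0 must be positive")
        pts = [(float(t), float(c)) for t, c in self.samples]
        times = [t for t, _ in pts]
        if any(t2 <= t1 for t1, t2 in zip(times, times[1:])):
            raise ValueError("sample times must be strictly increasing")
        if any(c < 0 for _, c in pts):
            raise ValueError("concentrations must be non-negative")
        self.samples = pts

    @property
    def times(self) -> np.ndarray:
        return np.array([t for t, _ in self.samples])

    @property
    def concentrations(self) -> np.ndarray:
        return np.array([c for _, c in self.samples])


@dataclass(frozen=True)
class PermeabilityResult:
    J: float                  # mol cm^-2 s^-1
    Papp: float               # cm/s
    fit_r: float
    lag_points_dropped: int
    sink_ok: bool
    max_acceptor_ratio: float = math.nan

    def __post_init__(self):
        # Papp must equal J normalized by C0 by construction; nothing to
        # re-check here without C0, the factory below guarantees it.
        if self.J >= 0 and self.Papp < 0:
            raise ValueError("Papp must be non-negative when J is")


def cumulative_amount(run: PermeationRun,
                      correct_sampling: bool = True) -> list:
    """Cumulative permeated amount (mol) at each sampling time.

    With ``correct_sampling`` (default) the analyte removed by earlier
    withdrawals is added back; without it Q is just C*V_acceptor.
    """
    va = run.geometry.V_acceptor / 1000.0  # L
    vs = run.geometry.V_sample / 1000.0
    out = []
    withdrawn = 0.0
    dilution = (run.geometry.V_acceptor - run.geometry.V_sample) \
        / run.geometry.V_acceptor
    prev_c = None
    for t, c in run.samples:
        q = c * va + (withdrawn if correct_sampling else 0.0)
        out.append((t, q))
        if prev_c is not None and c < prev_c * dilution * (1 - 1e-9):
            warnings.warn(
                f"acceptor concentration at t={t} min falls below the "
                "dilution-consistent floor; cumulative amount may decrease",
                stacklevel=2)
        withdrawn += c * vs
        prev_c = c
    return out


def steady_state_flux(run: PermeationRun, window: str = "all",
                      correct_sampling: bool = True) -> tuple:
    """OLS slope of Q/A vs t -> (J in mol cm^-2 s^-1, fit r, points dropped).

    ``window='auto'`` drops leading lag points while the correlation of
    the fit improves and at least 3 points remain.
    """
    if window not in ("all", "auto"):
        raise ValueError(f"unknown window {window!r}")
    tq = cumulative_amount(run, correct_sampling=correct_sampling)
    if len(tq) < 2:
        raise InsufficientDataError("need at least 2 samples for a flux")
    t = np.array([p[0] for p in tq]) * 60.0  # s
    qa = np.array([p[1] for p in tq]) / run.geometry.area

    def fit(lo):
        res = stats.linregress(t[lo:], qa[lo:])
        return float(res.slope), float(res.rvalue)

    dropped = 0
    j, r = fit(0)
    if window == "auto":
        while len(t) - (dropped + 1) >= 3:
            j2, r2 = fit(dropped + 1)
            if abs(r2) > abs(r):
                dropped += 1
                j, r = j2, r2
            else:
                break
    return j, r, dropped


def apparent_permeability(J: float, C0: float) -> float:
    """Papp = J / C0 with C0 converted from mol/L to mol/cm^3."""
    if C0 <= 0:
        raise DomainError("C0 must be positive")
    return J / (C0 / 1000.0)


def sink_check(run: PermeationRun) -> tuple:
    """(sink maintained?, worst acceptor/donor concentration ratio)."""
    if not run.samples:
        return True, 0.0
    worst = float(max(c for _, c in run.samples) / run.C0)
    return worst <= SINK_LIMIT, worst


class FranzPermeability(RegressorMixin, BaseEstimator):
    """Steady-state flux / apparent permeability estimator.

    Parameters
    ----------
    geometry : FranzCellGeometry
    c0 : float
        Donor concentration, mol/L.
    window : {'all', 'auto'}
        Whether to drop leading lag points automatically.
    correct_sampling : bool
        Apply the withdrawal correction to the cumulative amount.

    ``fit(t, C)`` takes sampling times (min) and acceptor concentrations
    (mol/L, pre-replacement).  Fitted attributes: ``flux_``
    (mol cm^-2 s^-1), ``papp_`` (cm/s), ``rvalue_``, ``n_dropped_``,
    ``sink_ok_``, ``max_acceptor_ratio_``.
    """

    def __init__(self, geometry: FranzCellGeometry = PAPER_GEOMETRY,
                 c0: float = None, window: str = "all",
                 correct_sampling: bool = True):
        self.geometry = geometry
        self.c0 = c0
        self.window = window
        self.correct_sampling = correct_sampling

    def fit(self, X, y):
        if self.c0 is None or self.c0 <= 0:
            raise ValueError("c0 must be set to a positive value")
        t = np.asarray(X, dtype=float).reshape(-1)
        c = np.asarray(y, dtype=float).reshape(-1)
        run = PermeationRun("", self.c0, self.geometry, list(zip(t, c)))
        j, r, dropped = steady_state_flux(
            run, window=self.window, correct_sampling=self.correct_sampling)
        ok, worst = sink_check(run)
        self.flux_ = j
        self.papp_ = apparent_permeability(j, self.c0)
        self.rvalue_ = r
        self.n_dropped_ = dropped
        self.sink_ok_ = ok
        self.max_acceptor_ratio_ = worst
        return self

    def predict(self, X):
        """Predicted cumulative amount per area (mol/cm^2) at t (min)."""
        t = np.asarray(X, dtype=float).reshape(-1) * 60.0
        return self.flux_ * t

    def to_result(self) -> PermeabilityResult:
        return PermeabilityResult(self.flux_, self.papp_, self.rvalue_,
                                  self.n_dropped_, self.sink_ok_,
                                  self.max_acceptor_ratio_)


def analyze_run(run: PermeationRun, window: str = "all",
                correct_sampling: bool = True) -> PermeabilityResult:
    """One-call flux + Papp + sink summary for a run."""
    est = FranzPermeability(geometry=run.geometry, c0=run.C0, window=window,
                            correct_sampling=correct_sampling)
    est.fit(run.times, run.concentrations)
    return est.to_result()
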