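"""Dissolution thermodynamics from temperature-dependent solubility.

Molar solubilities are first converted to mole fractions, the van't Hoff
line ``ln X2 = A + B/T`` is fitted by ordinary least squares, and the
apparent dissolution functions follow from the coefficients:

    dH  = -R*B                 (apparent dissolution enthalpy, T-independent)
    dG  = -R*T*(A + B/T)       (dissolution Gibbs energy at T)
    TdS = dH - dG = R*T*A      (entropy term at T)

The enthalpy fraction ``zeta_H = |dH| / (|dH| + |TdS|) * 100`` summarizes
whether a dissolution (or transfer) process is enthalpy- or entropy-driven.
Transfer functions between two solvents are destination-minus-source
differences of the dissolution functions.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from sklearn.base import BaseEstimator, RegressorMixin

from .constants import R_GAS
from .errors import (
    DegenerateDesignError,
    InsufficientDataError,
    InvalidCompositionError,
)

__all__ = [
    "SolventSpec",
    "SoluteSpec",
    "SolubilitySeries",
    "VantHoffFit",
    "ThermoFunctions",
    "mole_fraction",
    "to_mole_fraction",
    "VantHoffRegression",
    "fit_vant_hoff",
    "enthalpy_from_fit",
    "gibbs_at",
    "thermo_functions",
    "transfer_functions",
    "thermo_uncertainties",
]


@dataclass(frozen=True)
class SolventSpec:
    """Pure-solvent properties used by the mole-fraction conversion."""

    name: str
    molar_mass: float  # g/mol
    density: float  # g/cm^3
    density_reference_T: float = 298.2  # K

    def __post_init__(self):
        if self.molar_mass <= 0 or self.density <= 0:
            raise ValueError("molar_mass and density must be positive")


@dataclass(frozen=True)
class SoluteSpec:
    name: str
    molar_mass: float  # g/mol

    def __post_init__(self):
        if self.molar_mass <= 0:
            raise ValueError("molar_mass must be positive")


@dataclass
class SolubilitySeries:
    """Temperature-indexed solubility of one solute in one solvent.

    ``composition`` records whether values are molar concentrations
    (mol/L) or already mole fractions; the van't Hoff fit requires
    mole fractions.
    """

    solute_id: str
    solvent_id: str
    points: list[tuple]  # (T_K, value, sd-or-None)
    composition: str = "molar"  # or "mole_fraction"

    def __post_init__(self):
        if self.composition not in ("molar", "mole_fraction"):
            raise ValueError(f"unknown composition scale {self.composition!r}")
        cleaned = []
        for p in self.points:
            t, s2 = float(p[0]), float(p[1])
            sd = float(p[2]) if len(p) > 2 and p[2] is not None else None
            if t <= 0:
                raise ValueError(f"non-positive temperature {t}")
            if s2 <= 0:
                raise ValueError(f"non-positive solubility {s2} at T={t}")
            cleaned.append((t, s2, sd))
        cleaned.sort(key=lambda p: p[0])
        self.points = cleaned

    @property
    def temperatures(self) -> np.ndarray:
        return np.array([p[0] for p in self.points])

    @property
    def values(self) -> np.ndarray:
        return np.array([p[1] for p in self.points])


def mole_fraction(s2, solute: SoluteSpec, solvent: SolventSpec,
                  mode: str = "as_printed"):
    """Convert molar solubility (mol/L) to mole fraction.

    Two conventions are provided.  ``as_printed`` uses

        X2 = M2*S2 / (S2*(M1 - M2) + 1000*rho)

    with M1, M2 the solute and solvent molar masses (g/mol) and rho the
    pure-solvent density (g/cm^3).  ``mass_balance`` is the
    first-principles variant with the sign of the correction term
    flipped: X2 = M2*S2 / (1000*rho - S2*(M1 - M2)).  The two differ by
    under ~4% for dilute systems; see the methods note.
    """
    if mode not in ("as_printed", "mass_balance"):
        raise ValueError(f"unknown mode {mode!r}")
    s2_arr = np.asarray(s2, dtype=float)
    if np.any(s2_arr <= 0):
        raise InvalidCompositionError("S2 must be positive")
    m1, m2, rho = solute.molar_mass, solvent.molar_mass, solvent.density
    corr = s2_arr * (m1 - m2)
    denom = corr + 1000.0 * rho if mode == "as_printed" else 1000.0 * rho - corr
    if np.any(denom <= 0):
        raise InvalidCompositionError(
            f"non-positive denominator in mole-fraction conversion ({mode})")
    x2 = m2 * s2_arr / denom
    if np.any(x2 >= 1.0):
        raise InvalidCompositionError("computed mole fraction >= 1")
    return float(x2) if np.isscalar(s2) else x2


def to_mole_fraction(series: SolubilitySeries, solute: SoluteSpec,
                     solvent: SolventSpec,
                     mode: str = "as_printed") -> SolubilitySeries:
    """Return a copy of ``series`` on the mole-fraction scale."""
    if series.composition == "mole_fraction":
        return series
    pts = []
    for t, s2, sd in series.points:
        x2 = mole_fraction(s2, solute, solvent, mode=mode)
        # relative uncertainty is preserved to first order
        pts.append((t, x2, sd / s2 * x2 if sd is not None else None))
    return SolubilitySeries(series.solute_id, series.solvent_id, pts,
                            composition="mole_fraction")


@dataclass(frozen=True)
class VantHoffFit:
    """Coefficients of ``ln X2 = A + B/T`` with OLS diagnostics."""

    A: float
    B: float  # K
    se_A: float
    se_B: float
    r: float
    rss: float
    n: int
    cov_AB: float = 0.0

    def __post_init__(self):
        if self.n < 2:
            raise InsufficientDataError("van't Hoff fit needs >= 2 points")


@dataclass(frozen=True)
class ThermoFunctions:
    """Thermodynamic functions (J/mol) of one process at one temperature.

    ``zeta_h`` is the percent enthalpy fraction; it is NaN (with a
    warning) for the degenerate all-zero process.
    """

    T: float
    dG: float
    dH: float
    TdS: float
    zeta_h: float = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        resid = abs(self.dG - (self.dH - self.TdS))
        if resid > 1e-6 * max(1.0, abs(self.dG)):
            raise ValueError("dG != dH - TdS beyond tolerance")
        if self.zeta_h is None:
            object.__setattr__(self, "zeta_h", zeta_enthalpy(self.dH, self.TdS))


def zeta_enthalpy(dh: float, tds: float) -> float:
    """Percent enthalpic contribution |dH|/(|dH|+|TdS|)*100."""
    total = abs(dh) + abs(tds)
    if total == 0.0:
        warnings.warn("zeta_H undefined for an all-zero process", stacklevel=2)
        return math.nan
    return abs(dh) / total * 100.0


class VantHoffRegression(RegressorMixin, BaseEstimator):
    """OLS of ln(mole-fraction solubility) on reciprocal temperature.

    Follows the scikit-learn estimator protocol: ``fit(T, x2)`` with
    temperatures in kelvin and mole fractions, ``predict(T)`` returning
    mole fractions.  Fitted attributes:

    intercept_ : A (dimensionless)
    slope_ : B (kelvin); the apparent enthalpy is -R*B
    se_intercept_, se_slope_, cov_ : first-order OLS uncertainties
    rvalue_ : Pearson correlation of ln X2 with 1/T
    rss_ : residual sum of squares on the ln X2 scale
    n_obs_ : number of points
    """

    def fit(self, X, y):
        T = np.asarray(X, dtype=float).reshape(-1)
        x2 = np.asarray(y, dtype=float).reshape(-1)
        if T.shape != x2.shape:
            raise ValueError("T and X2 must have the same length")
        if T.size < 2:
            raise InsufficientDataError("need at least 2 points")
        if np.any(T <= 0) or np.any(x2 <= 0):
            raise ValueError("temperatures and mole fractions must be positive")
        if np.unique(T).size < 2:
            raise DegenerateDesignError("all temperatures identical")
        x = 1.0 / T
        ly = np.log(x2)
        res = stats.linregress(x, ly)
        n = T.size
        resid = ly - (res.intercept + res.slope * x)
        rss = float(resid @ resid)
        if n == 2:  # exact interpolation, no residual degrees of freedom
            se_a = se_b = cov = 0.0
            rss = 0.0
        else:
            se_a = float(res.intercept_stderr)
            se_b = float(res.stderr)
            cov = -float(np.mean(x)) * se_b**2
        self.intercept_ = float(res.intercept)
        self.slope_ = float(res.slope)
        self.se_intercept_ = se_a
        self.se_slope_ = se_b
        self.cov_ = cov
        self.rvalue_ = float(res.rvalue)
        self.rss_ = rss
        self.n_obs_ = int(n)
        return self

    def predict(self, X):
        T = np.asarray(X, dtype=float).reshape(-1)
        return np.exp(self.intercept_ + self.slope_ / T)

    def to_fit(self) -> VantHoffFit:
        return VantHoffFit(self.intercept_, self.slope_, self.se_intercept_,
                           self.se_slope_, self.rvalue_, self.rss_,
                           self.n_obs_, self.cov_)

    # thermodynamic conveniences -------------------------------------
    def enthalpy(self) -> float:
        return enthalpy_from_fit(self.to_fit())

    def gibbs(self, T: float) -> float:
        return gibbs_at(self.to_fit(), T)

    def thermo(self, T: float) -> ThermoFunctions:
        return thermo_functions(self.to_fit(), T)


def fit_vant_hoff(series: SolubilitySeries) -> VantHoffFit:
    """Fit ``ln X2 = A + B/T`` on a mole-fraction solubility series."""
    if series.composition != "mole_fraction":
        raise ValueError("series must be on the mole-fraction scale; "
                         "use to_mole_fraction() first")
    est = VantHoffRegression().fit(series.temperatures, series.values)
    return est.to_fit()


def enthalpy_from_fit(fit: VantHoffFit) -> float:
    """Apparent dissolution enthalpy -R*B, J/mol."""
    return -R_GAS * fit.B


def gibbs_at(fit: VantHoffFit, T: float) -> float:
    """Dissolution Gibbs energy -R*T*ln X2(T), J/mol."""
    if T <= 0:
        raise ValueError("T must be positive")
    return -R_GAS * T * (fit.A + fit.B / T)


def thermo_functions(fit: VantHoffFit, T: float) -> ThermoFunctions:
    """All dissolution functions at T; TdS = dH - dG (= R*T*A)."""
    dh = enthalpy_from_fit(fit)
    dg = gibbs_at(fit, T)
    return ThermoFunctions(T=T, dG=dg, dH=dh, TdS=dh - dg)


def transfer_functions(from_fit: VantHoffFit, to_fit: VantHoffFit,
                       T: float) -> ThermoFunctions:
    """Hypothetical transfer functions, destination minus source."""
    a, b = thermo_functions(from_fit, T), thermo_functions(to_fit, T)
    return ThermoFunctions(T=T, dG=b.dG - a.dG, dH=b.dH - a.dH,
                           TdS=b.TdS - a.TdS)


def thermo_uncertainties(fit: VantHoffFit, T: float) -> dict:
    """First-order standard errors of dG, dH, TdS from the fit covariance."""
    var_a, var_b, cov = fit.se_A**2, fit.se_B**2, fit.cov_AB
    se_dh = R_GAS * fit.se_B
    # dG = -R*T*A - R*B
    var_dg = (R_GAS * T) ** 2 * var_a + R_GAS**2 * var_b \
        + 2 * R_GAS**2 * T * cov
    se_tds = R_GAS * T * fit.se_A  # TdS = R*T*A exactly
    return {"dG": math.sqrt(max(var_dg, 0.0)), "dH": se_dh, "TdS": se_tds}
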