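"""Apparent distribution coefficients in organic/aqueous two-phase systems.

The distribution coefficient D is the equilibrium concentration ratio
organic/aqueous at fixed pH (no ionization correction: the compounds of
interest are un-ionized at pH 7.4, so D behaves as an intrinsic
partition coefficient).  Two evaluation modes are supported:

``direct_ratio``
    D = C_org / C_aq when both phases were assayed.
``mass_balance``
    D = (C0_aq - C_aq) * V_aq / (C_aq * V_org), inferring the organic
    amount by conservation from the initial aqueous stock — the usual
    shake-flask practice of assaying only the aqueous phase.  This is
    the volume-bearing form and the default.

The Seiler parameter dlogD = logD(1-octanol/buffer) - logD(alkane/buffer)
indexes the hydrogen-bonding capacity of the solute.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from statistics import mean, stdev

from .errors import DomainError

__all__ = [
    "DistributionMeasurement",
    "DistributionResult",
    "apparent_distribution",
    "delta_logD",
    "aggregate_replicates",
]


@dataclass(frozen=True)
class DistributionMeasurement:
    """Equilibrium phase data for one two-phase partition experiment."""

    system_id: str
    solute_id: str
    C_aq: float                 # mol/L, aqueous phase at equilibrium
    C_org: float = None         # mol/L, organic phase (direct_ratio mode)
    C0_aq: float = None         # mol/L, initial aqueous stock (mass_balance)
    V_org: float = 3.0          # mL
    V_aq: float = 3.0           # mL
    cd_name: str = None
    cd_conc: float = 0.0        # mol/L cyclodextrin in aqueous phase

    def __post_init__(self):
        if self.V_org <= 0 or self.V_aq <= 0:
            raise ValueError("phase volumes must be positive")
        if self.C_aq < 0:
            raise ValueError("C_aq must be non-negative")
        if self.C_org is None and self.C0_aq is None:
            raise ValueError("need C_org or C0_aq")
        if self.cd_conc < 0:
            raise ValueError("cd_conc must be non-negative")


@dataclass(frozen=True)
class DistributionResult:
    D: float
    logD: float
    mode_used: str

    def __post_init__(self):
        if self.D <= 0:
            raise DomainError("D must be positive")
        if abs(self.logD - math.log10(self.D)) > 1e-12 * max(1, abs(self.logD)):
            raise ValueError("logD inconsistent with D")


def apparent_distribution(m: DistributionMeasurement,
                          mode: str = "mass_balance") -> DistributionResult:
    """Apparent distribution coefficient of one measurement."""
    if mode == "direct_ratio":
        if m.C_org is None or m.C_aq <= 0:
            raise DomainError("direct_ratio needs C_org and C_aq > 0")
        d = m.C_org / m.C_aq
    elif mode == "mass_balance":
        if m.C0_aq is None or m.C_aq <= 0:
            raise DomainError("mass_balance needs C0_aq and C_aq > 0")
        if m.C0_aq <= m.C_aq:
            raise DomainError(
                "C0_aq <= C_aq: no material partitioned into the organic phase")
        d = (m.C0_aq - m.C_aq) * m.V_aq / (m.C_aq * m.V_org)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return DistributionResult(D=d, logD=math.log10(d), mode_used=mode)


def delta_logD(logD_oct: float, logD_hex: float) -> float:
    """Seiler hydrogen-bonding parameter logD(octanol) - logD(alkane)."""
    if not (math.isfinite(logD_oct) and math.isfinite(logD_hex)):
        raise DomainError("logD values must be finite")
    return logD_oct - logD_hex


def aggregate_replicates(results: list[DistributionResult]) -> tuple:
    """Arithmetic mean D over replicates with sample standard deviation.

    Returns ``(DistributionResult, sd)``; sd is 0.0 for a single replicate.
    """
    if not results:
        raise DomainError("no replicates to aggregate")
    ds = [r.D for r in results]
    d = mean(ds)
    sd = stdev(ds) if len(ds) > 1 else 0.0
    mode = results[0].mode_used
    return DistributionResult(D=d, logD=math.log10(d), mode_used=mode), sd
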