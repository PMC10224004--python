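"""CSV readers/writers, configuration and report assembly.

All tables are comma-delimited UTF-8 with required headers and decimal
points.  Readers validate schemas up front and name the offending
row/column in errors; writers round-trip values exactly.

Two tiny reference tables ship with the package under ``partisol/data``:
``solubility.csv`` (molar solubility of the three pyridinecarboxamides
in 1-octanol and n-hexane) and ``distribution.csv`` (distribution
coefficients in both two-phase systems, with and without cyclodextrins).
``load_packaged_table`` returns them as DataFrames.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import pandas as pd
import yaml

from . import constants
from .complexation import CdSuppressionSeries, KcFit, NonlinearKcFit
from .distribution import DistributionMeasurement
from .errors import SchemaError
from .permeation import FranzCellGeometry, PermeabilityResult, PermeationRun
from .solvation import SolubilitySeries, SoluteSpec, SolventSpec, ThermoFunctions, VantHoffFit

__all__ = [
    "SCHEMAS",
    "AnalysisConfig",
    "load_config",
    "load_packaged_table",
    "read_solubility_csv",
    "read_distribution_csv",
    "read_distribution_table",
    "read_suppression_csv",
    "read_permeation_csv",
    "write_series_csv",
    "suppression_series_from_table",
    "report",
    "write_report",
]

SCHEMAS = {
    "solubility": ["solute", "solvent", "T_K", "S2_mol_per_L"],
    "distribution": ["system", "solute", "C0_aq", "C_aq", "C_org",
                     "V_org_mL", "V_aq_mL", "cd_name", "cd_conc_M"],
    "distribution_table": ["system", "solute", "cd_name", "cd_conc_M", "D"],
    "suppression": ["system", "cd_name", "C_CD_M", "D"],
    "permeation": ["solute", "t_min", "C_acceptor_M"],
}


def _read_csv(path, schema_id: str) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise SchemaError(f"input file not found: {path}")
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        raise SchemaError(f"empty input file: {path}") from None
    if df.empty:
        raise SchemaError(f"no data rows in {path}")
    missing = [c for c in SCHEMAS[schema_id] if c not in df.columns]
    if missing:
        raise SchemaError(
            f"{path}: missing required column(s) {missing} "
            f"for schema '{schema_id}'")
    return df


def _numeric(df: pd.DataFrame, col: str, path, required: bool = True):
    out = pd.to_numeric(df[col], errors="coerce")
    bad = out.isna() & df[col].notna()
    if bad.any():
        row = int(bad.idxmax()) + 2  # header + 1-based
        raise SchemaError(f"{path}: non-numeric value in column '{col}' "
                          f"at line {row}")
    if required and out.isna().any():
        row = int(out.isna().idxmax()) + 2
        raise SchemaError(f"{path}: missing value in column '{col}' "
                          f"at line {row}")
    return out


@dataclass
class AnalysisConfig:
    """Run configuration: substance registry, mode flags, precision, seed."""

    solvents: dict = field(default_factory=dict)   # name -> SolventSpec
    solutes: dict = field(default_factory=dict)    # name -> SoluteSpec
    mole_fraction_mode: str = "as_printed"
    distribution_mode: str = "mass_balance"
    flux_window: str = "all"
    precision: int = 3
    seed: int = 0

    def __post_init__(self):
        for name, (mm, rho) in constants.SOLVENTS.items():
            self.solvents.setdefault(name, SolventSpec(name, mm, rho))
        for name, mm in constants.SOLUTES.items():
            self.solutes.setdefault(name, SoluteSpec(name, mm))
        if self.precision < 1:
            raise ValueError("precision must be at least 1 digit")

    def solvent(self, name: str) -> SolventSpec:
        try:
            return self.solvents[name]
        except KeyError:
            raise SchemaError(f"solvent '{name}' not defined in config") from None

    def solute(self, name: str) -> SoluteSpec:
        try:
            return self.solutes[name]
        except KeyError:
            raise SchemaError(f"solute '{name}' not defined in config") from None


def load_config(path=None) -> AnalysisConfig:
    """Load a YAML config; with no path, return package defaults."""
    if path is None:
        return AnalysisConfig()
    raw = yaml.safe_load(Path(path).read_text()) or {}
    solvents = {
        name: SolventSpec(name, float(v["molar_mass"]), float(v["density"]))
        for name, v in (raw.get("solvents") or {}).items()
    }
    solutes = {
        name: SoluteSpec(name, float(v["molar_mass"]) if isinstance(v, dict)
                         else float(v))
        for name, v in (raw.get("solutes") or {}).items()
    }
    kw = {k: raw[k] for k in ("mole_fraction_mode", "distribution_mode",
                              "flux_window", "precision", "seed") if k in raw}
    return AnalysisConfig(solvents=solvents, solutes=solutes, **kw)


def load_packaged_table(name: str) -> pd.DataFrame:
    """Return a packaged reference table ('solubility' or 'distribution')."""
    ref = resources.files("partisol.data") / f"{name}.csv"
    with resources.as_file(ref) as p:
        return pd.read_csv(p)


def read_solubility_csv(path) -> dict:
    """Parse a solubility table into ``{(solute, solvent): SolubilitySeries}``."""
    df = _read_csv(path, "solubility")
    _numeric(df, "T_K", path)
    _numeric(df, "S2_mol_per_L", path)
    has_sd = "sd" in df.columns
    out = {}
    for (solute, solvent), grp in df.groupby(["solute", "solvent"], sort=False):
        pts = [(r.T_K, r.S2_mol_per_L,
                getattr(r, "sd", None) if has_sd else None)
               for r in grp.itertuples()]
        out[(solute, solvent)] = SolubilitySeries(solute, solvent, pts)
    return out


def read_distribution_csv(path) -> list:
    """Parse raw two-phase measurements into DistributionMeasurement records."""
    df = _read_csv(path, "distribution")
    for col in ("C0_aq", "C_aq", "C_org", "V_org_mL", "V_aq_mL", "cd_conc_M"):
        _numeric(df, col, path, required=col in ("C_aq", "V_org_mL", "V_aq_mL"))
    out = []
    for i, r in df.iterrows():
        try:
            out.append(DistributionMeasurement(
                system_id=str(r["system"]), solute_id=str(r["solute"]),
                C_aq=float(r["C_aq"]),
                C_org=None if pd.isna(r["C_org"]) else float(r["C_org"]),
                C0_aq=None if pd.isna(r["C0_aq"]) else float(r["C0_aq"]),
                V_org=float(r["V_org_mL"]), V_aq=float(r["V_aq_mL"]),
                cd_name=None if pd.isna(r["cd_name"]) else str(r["cd_name"]),
                cd_conc=0.0 if pd.isna(r["cd_conc_M"]) else float(r["cd_conc_M"]),
            ))
        except ValueError as e:
            raise SchemaError(f"{path}: line {i + 2}: {e}") from None
    return out


def read_distribution_table(path) -> pd.DataFrame:
    """Parse a table of already-computed distribution coefficients."""
    df = _read_csv(path, "distribution_table")
    _numeric(df, "cd_conc_M", path)
    _numeric(df, "D", path)
    return df


def read_suppression_csv(path, d0: float = None) -> list:
    """Parse suppression data into CdSuppressionSeries per (system, cd).

    The no-host baseline D0 comes from rows with ``C_CD_M == 0`` or from
    the ``d0`` argument.
    """
    df = _read_csv(path, "suppression")
    _numeric(df, "C_CD_M", path)
    _numeric(df, "D", path)
    out = []
    for (system, cd), grp in df.groupby(["system", "cd_name"], sort=False):
        base = grp[grp.C_CD_M == 0]
        d0_here = float(base.D.iloc[0]) if len(base) else d0
        if d0_here is None:
            raise SchemaError(
                f"{path}: no D0 row (C_CD_M=0) for system '{system}' / "
                f"'{cd}' and no --d0 given")
        pts = grp[grp.C_CD_M > 0]
        out.append(CdSuppressionSeries(str(system), str(cd), d0_here,
                                       list(zip(pts.C_CD_M, pts.D))))
    return out


def suppression_series_from_table(df: pd.DataFrame, system: str, cd_name: str,
                                  solute: str = "IPN") -> CdSuppressionSeries:
    """Build a suppression series from a distribution-table DataFrame."""
    sub = df[(df.system == system) & (df.solute == solute)]
    base = sub[sub.cd_conc_M == 0]
    if base.empty:
        raise SchemaError(f"no CD-free baseline for {solute} in {system}")
    d0 = float(base.D.iloc[0])
    pts = sub[(sub.cd_name == cd_name) & (sub.cd_conc_M > 0)]
    if pts.empty:
        raise SchemaError(f"no {cd_name} rows for {solute} in {system}")
    return CdSuppressionSeries(system, cd_name, d0,
                               list(zip(pts.cd_conc_M, pts.D)))


def read_permeation_csv(path, c0: float,
                        geometry: FranzCellGeometry = None) -> dict:
    """Parse acceptor time courses into ``{solute: PermeationRun}``."""
    df = _read_csv(path, "permeation")
    _numeric(df, "t_min", path)
    _numeric(df, "C_acceptor_M", path)
    geometry = geometry or FranzCellGeometry()
    out = {}
    for solute, grp in df.groupby("solute", sort=False):
        samples = list(zip(grp.t_min, grp.C_acceptor_M))
        out[str(solute)] = PermeationRun(str(solute), c0, geometry, samples)
    return out


def load_geometry(path=None) -> FranzCellGeometry:
    """Geometry from a YAML block (area_cm2, V_donor_mL, ...)."""
    if path is None:
        return FranzCellGeometry()
    raw = yaml.safe_load(Path(path).read_text()) or {}
    keymap = {"area_cm2": "area", "V_donor_mL": "V_donor",
              "V_acceptor_mL": "V_acceptor", "V_sample_mL": "V_sample",
              "interval_min": "sample_interval", "duration_min": "duration"}
    kw = {keymap[k]: float(v) for k, v in raw.items() if k in keymap}
    return FranzCellGeometry(**kw)


def write_series_csv(series: SolubilitySeries, path) -> None:
    """Write a solubility series back to the input schema (round-trips)."""
    rows = [{"solute": series.solute_id, "solvent": series.solvent_id,
             "T_K": t, "S2_mol_per_L": v, "sd": sd}
            for t, v, sd in series.points]
    pd.DataFrame(rows).to_csv(path, index=False)


# --------------------------------------------------------------------
# report assembly

def _thermo_rows(entries, precision):
    rows = []
    for e in entries:
        fit: VantHoffFit = e["fit"]
        row = {"process": e["process"], "A": fit.A, "B_K": fit.B,
               "se_A": fit.se_A, "se_B": fit.se_B, "r": fit.r,
               "rss": fit.rss, "n": fit.n,
               "provenance": "van't Hoff OLS of ln X2 on 1/T"}
        for tf in e["functions"]:
            tf: ThermoFunctions
            tag = f"{tf.T:g}"
            row[f"dG_{tag}_kJ"] = round(tf.dG / 1000, precision)
            row[f"TdS_{tag}_kJ"] = round(tf.TdS / 1000, precision)
            row["dH_kJ"] = round(tf.dH / 1000, precision)
            row[f"zeta_H_{tag}_pct"] = round(tf.zeta_h, precision)
        rows.append(row)
    return rows


def report(thermo=None, distribution=None, kc=None, permeability=None,
           precision: int = 3) -> dict:
    """Assemble analysis results into one structured document.

    Each argument is a list of dict entries produced by the analysis
    helpers (see the CLI); at least one block is required.  Every block
    carries a provenance field naming the operation that produced it.
    """
    blocks = {}
    if thermo:
        blocks["thermo"] = _thermo_rows(thermo, precision)
    if distribution:
        blocks["distribution"] = [
            {**row, "provenance": f"apparent_distribution[{row.get('mode', '')}]"}
            for row in distribution]
    if kc:
        rows = []
        for e in kc:
            f = e["fit"]
            if isinstance(f, KcFit):
                rows.append({"system": e["system"], "cd_name": e["cd_name"],
                             "intercept": round(f.intercept, precision),
                             "Kc_antilog": round(f.Kc_antilog, precision),
                             "alpha": round(f.alpha, precision),
                             "se_intercept": f.se_intercept,
                             "se_alpha": f.se_alpha, "R": f.R, "rss": f.rss,
                             "F": f.F, "n": f.n,
                             "provenance": "log-log suppression OLS"})
            elif isinstance(f, NonlinearKcFit):
                rows.append({"system": e["system"], "cd_name": e["cd_name"],
                             "Kc": round(f.Kc, precision), "rss": f.rss,
                             "n": f.n,
                             "provenance": "exact 1:1 binding least squares"})
        blocks["kc"] = rows
    if permeability:
        rows = []
        for e in permeability:
            r: PermeabilityResult = e["result"]
            rows.append({"solute": e["solute"], "J_mol_cm2_s": r.J,
                         "Papp_cm_s": r.Papp, "fit_r": r.fit_r,
                         "lag_points_dropped": r.lag_points_dropped,
                         "sink_ok": r.sink_ok,
                         "max_acceptor_ratio": r.max_acceptor_ratio,
                         "provenance": "Q/A vs t OLS slope / C0"})
        blocks["permeability"] = rows
    if not blocks:
        raise ValueError("report requires at least one analysis result")
    return blocks


def write_report(blocks: dict, out_prefix) -> list:
    """Write the report as one JSON plus one CSV per block; return paths."""
    out_prefix = Path(out_prefix)
    out_prefix.parent.mkdir(parents=True, exist_ok=True)
    paths = []
    jpath = out_prefix.with_suffix(".json")
    jpath.write_text(json.dumps(blocks, indent=2, default=float))
    paths.append(jpath)
    for name, rows in blocks.items():
        cpath = out_prefix.parent / f"{out_prefix.name}_{name}.csv"
        pd.DataFrame(rows).to_csv(cpath, index=False)
        paths.append(cpath)
    return paths
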