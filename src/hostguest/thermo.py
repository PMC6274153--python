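"""Thermodynamic conversions and identity auditing.

The two identities this module owns:

    dG  = -R * T * ln(Ka)          (R = 1.987204e-3 kcal mol^-1 K^-1)
    TdS = dH - dG

Both are exact bookkeeping, not fits.  ``audit_record`` checks published
(N, Ka, dH, dG, TdS) tables against them at a stated tolerance, reporting
per-identity residuals; it never mutates the record.  For end-point
free-energy decompositions (MM/GBSA-style), ``dh`` holds the total
interaction energy and ``tds`` the entropy term, and the same
``dG = dH - TdS`` identity applies.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from typing import List, Optional

import pandas as pd

from .errors import DomainError

__all__ = [
    "R_KCAL",
    "DEFAULT_TEMPERATURE",
    "ThermodynamicRecord",
    "IdentityCheck",
    "AuditReport",
    "delta_g_from_ka",
    "ka_from_delta_g",
    "tds_from_dh_dg",
    "audit_record",
    "audit_table",
    "load_published_table",
]

#: Gas constant in kcal mol^-1 K^-1 (thermochemical calorie).
R_KCAL = 1.987204e-3

#: 25 degC.  Published dG values round-trip from the published Ka at this
#: temperature (see docs/methods.md on the temperature choice).
DEFAULT_TEMPERATURE = 298.15


def delta_g_from_ka(ka: float, temperature: float = DEFAULT_TEMPERATURE) -> float:
    """Gibbs free energy change dG = -R*T*ln(Ka), in kcal/mol."""
    if not (ka > 0.0):
        raise DomainError(f"ka must be > 0, got {ka!r}")
    if not (temperature > 0.0):
        raise DomainError(f"temperature must be > 0, got {temperature!r}")
    return -R_KCAL * temperature * math.log(ka)


def ka_from_delta_g(dg: float, temperature: float = DEFAULT_TEMPERATURE) -> float:
    """Inverse of :func:`delta_g_from_ka`: Ka = exp(-dG / (R*T))."""
    if not (temperature > 0.0):
        raise DomainError(f"temperature must be > 0, got {temperature!r}")
    return math.exp(-dg / (R_KCAL * temperature))


def tds_from_dh_dg(dh: float, dg: float) -> float:
    """Entropy term TdS = dH - dG (kcal/mol)."""
    return dh - dg


@dataclass(frozen=True)
class ThermodynamicRecord:
    """One row of a thermodynamic parameter table (energies in kcal/mol)."""

    label: str
    method: str  # itc | uvvis | nmr | mmgbsa
    dg: float
    temperature: float = DEFAULT_TEMPERATURE
    n: Optional[float] = None
    ka: Optional[float] = None
    dh: Optional[float] = None  # total interaction energy for mmgbsa records
    tds: Optional[float] = None


@dataclass(frozen=True)
class IdentityCheck:
    identity: str
    residual: float
    passed: bool


@dataclass
class AuditReport:
    record: ThermodynamicRecord
    tolerance: float
    checks: List[IdentityCheck] = field(default_factory=list)
    sufficient: bool = True

    @property
    def passed(self) -> bool:
        return self.sufficient and all(c.passed for c in self.checks)


def _passes(residual: float, tolerance: float) -> bool:
    # strict: a residual exactly equal to the tolerance fails (a printed
    # table consistent at the rounding precision has residual 0, not tol)
    return abs(residual) < tolerance - 1e-9


def audit_record(record: ThermodynamicRecord, tolerance: float = 0.01) -> AuditReport:
    """Check a record's internal identities at ``tolerance`` (kcal/mol).

    Two checks where the fields allow: ``dg`` vs ``-R*T*ln(ka)`` and
    ``dh - tds - dg``.  A record exposing fewer than two of
    {ka, dh, tds} alongside dg yields an insufficient-fields report.
    """
    report = AuditReport(record=record, tolerance=tolerance)
    available = sum(x is not None for x in (record.ka, record.dh, record.tds))
    if available < 1:
        report.sufficient = False
        return report
    if record.ka is not None:
        resid = record.dg - delta_g_from_ka(record.ka, record.temperature)
        report.checks.append(
            IdentityCheck("dg_vs_minus_RT_lnKa", resid, _passes(resid, tolerance))
        )
    if record.dh is not None and record.tds is not None:
        resid = record.dh - record.tds - record.dg
        report.checks.append(
            IdentityCheck("dh_minus_tds_minus_dg", resid, _passes(resid, tolerance))
        )
    if not report.checks:
        report.sufficient = False
    return report


def audit_table(
    records: List[ThermodynamicRecord], tolerance: float = 0.01
) -> pd.DataFrame:
    """Audit a list of records; one row per identity check."""
    rows = []
    for rec in records:
        rep = audit_record(rec, tolerance)
        if not rep.sufficient:
            rows.append(
                {
                    "label": rec.label,
                    "method": rec.method,
                    "identity": "insufficient_fields",
                    "residual": float("nan"),
                    "passed": False,
                }
            )
            continue
        for chk in rep.checks:
            rows.append(
                {
                    "label": rec.label,
                    "method": rec.method,
                    "identity": chk.identity,
                    "residual": chk.residual,
                    "passed": chk.passed,
                }
            )
    return pd.DataFrame(rows, columns=["label", "method", "identity", "residual", "passed"])


def _record_from_row(row: pd.Series) -> ThermodynamicRecord:
    def opt(key: str) -> Optional[float]:
        v = row.get(key)
        return None if v is None or (isinstance(v, float) and math.isnan(v)) else float(v)

    return ThermodynamicRecord(
        label=str(row["label"]),
        method=str(row["method"]),
        dg=float(row["dg_kcal_mol"]),
        temperature=float(row.get("temperature_K", DEFAULT_TEMPERATURE)),
        n=opt("n"),
        ka=opt("ka_per_M"),
        dh=opt("dh_kcal_mol"),
        tds=opt("tds_kcal_mol"),
    )


def load_published_table(path: Optional[str] = None) -> List[ThermodynamicRecord]:
    """Load a thermodynamic parameter table from CSV.

    With no argument, loads the packaged table of published CB[7]
    encapsulation parameters for cimetidine (CT), famotidine (FT) and
    nizatidine (NT) — ITC / spectroscopic rows and MM/GBSA-style
    decomposition columns — used by the audit examples and tests.
    """
    if path is None:
        with resources.files("hostguest.data").joinpath("published_thermo.csv").open() as fh:
            df = pd.read_csv(fh)
    else:
        df = pd.read_csv(path)
    required = {"label", "method", "dg_kcal_mol"}
    missing = required - set(df.columns)
    if missing:
        raise DomainError(f"thermo table missing columns: {sorted(missing)}")
    return [_record_from_row(row) for _, row in df.iterrows()]
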