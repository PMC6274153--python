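"""Monoisotopic mass and protonated host-guest adduct m/z assignment.

ESI-MS of host-guest mixtures shows multiply protonated adduct ions
``[n_host*Host + n_guest*Guest + z*H]^z+``.  The calculated m/z of such an
ion is

    m/z = (n_host*M_host + n_guest*M_guest + z*m_proton) / z

with monoisotopic masses M (sum of most-abundant-isotope masses) and the
proton mass added per charge — not the hydrogen atom mass, since the
electron leaves with the charge.  Matching an observed peak against
candidate (n_host, n_guest) compositions reads off the binding
stoichiometry directly.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Dict, List, Optional, Union

from .errors import DomainError, UnknownElementError

__all__ = [
    "MONOISOTOPIC_MASS",
    "PROTON_MASS",
    "FORMULAS",
    "AdductAssignment",
    "parse_formula",
    "monoisotopic_mass",
    "adduct_mz",
    "assign_peak",
]

#: Most-abundant-isotope masses (Da): 12C, 1H, 14N, 16O, 32S.
MONOISOTOPIC_MASS: Dict[str, float] = {
    "C": 12.0,
    "H": 1.0078250319,
    "N": 14.0030740052,
    "O": 15.9949146221,
    "S": 31.97207069,
}

#: Proton mass in Da (CODATA).
PROTON_MASS = 1.00727646688

Composition = Dict[str, int]
FormulaLike = Union[str, Composition]

_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")

#: Molecular formulas of the study species: the macrocyclic host
#: cucurbit[7]uril (CB[7], C42H42N28O14) and the three H2-receptor
#: antagonist guests.  Standard chemical identities of the drawn structures.
FORMULAS: Dict[str, Composition] = {
    "cb7": {"C": 42, "H": 42, "N": 28, "O": 14},
    "cimetidine": {"C": 10, "H": 16, "N": 6, "S": 1},
    "famotidine": {"C": 8, "H": 15, "N": 7, "O": 2, "S": 3},
    "nizatidine": {"C": 12, "H": 21, "N": 5, "O": 2, "S": 2},
}


def parse_formula(formula: str) -> Composition:
    """Parse a Hill-style formula string ("C42H42N28O14") into element counts.

    Case-sensitive; repeated symbols accumulate.  Unknown elements raise
    :class:`UnknownElementError` naming the symbol.
    """
    counts: Composition = {}
    pos = 0
    for m in _TOKEN.finditer(formula):
        if m.start() != pos:
            raise DomainError(f"cannot parse formula {formula!r} at position {pos}")
        pos = m.end()
        symbol, digits = m.group(1), m.group(2)
        if symbol not in MONOISOTOPIC_MASS:
            raise UnknownElementError(symbol)
        counts[symbol] = counts.get(symbol, 0) + (int(digits) if digits else 1)
    if pos != len(formula):
        raise DomainError(f"cannot parse formula {formula!r} at position {pos}")
    return counts


def _as_composition(formula: FormulaLike) -> Composition:
    if isinstance(formula, str):
        return FORMULAS.get(formula.lower(), None) or parse_formula(formula)
    return formula


def monoisotopic_mass(formula: FormulaLike) -> float:
    """Monoisotopic mass (Da) of a formula string, known species name, or
    element-count map.  The empty formula has mass 0."""
    comp = _as_composition(formula)
    total = 0.0
    for symbol, count in comp.items():
        if symbol not in MONOISOTOPIC_MASS:
            raise UnknownElementError(symbol)
        if count < 0:
            raise DomainError(f"count for {symbol} must be >= 0, got {count}")
        total += MONOISOTOPIC_MASS[symbol] * count
    return total


def adduct_mz(
    host: FormulaLike,
    guest: FormulaLike,
    n_host: int = 1,
    n_guest: int = 1,
    charge: int = 1,
) -> float:
    """m/z (Th) of the protonated adduct [n_host*H + n_guest*G + charge*H+]^charge+.

    Full precision; round to 2 dp for comparison with instrument-reported
    calculated values.
    """
    if charge < 1:
        raise DomainError(f"charge must be >= 1, got {charge}")
    if n_host + n_guest < 1:
        raise DomainError("n_host + n_guest must be >= 1")
    mass = (
        n_host * monoisotopic_mass(host)
        + n_guest * monoisotopic_mass(guest)
        + charge * PROTON_MASS
    )
    return mass / charge


@dataclass(frozen=True)
class AdductAssignment:
    """A candidate composition for an observed m/z peak."""

    n_host: int
    n_guest: int
    charge: int
    calc_mz: float
    obs_mz: Optional[float] = None
    error_ppm: Optional[float] = None


def assign_peak(
    obs_mz: float,
    charge: int,
    host: FormulaLike,
    guest: FormulaLike,
    max_n: int = 2,
    tol_ppm: float = 30.0,
) -> List[AdductAssignment]:
    """Enumerate (n_host, n_guest) adducts matching an observed peak.

    Candidates with 0 <= n <= max_n, n_host + n_guest >= 1, within
    ``tol_ppm`` of ``obs_mz``, sorted by |error_ppm|; ties broken by the
    smaller total composition n_host + n_guest.
    """
    if not (obs_mz > 0.0):
        raise DomainError(f"obs_mz must be > 0, got {obs_mz!r}")
    if max_n < 1:
        raise DomainError(f"max_n must be >= 1, got {max_n}")
    matches: List[AdductAssignment] = []
    for nh in range(max_n + 1):
        for ng in range(max_n + 1):
            if nh + ng < 1:
                continue
            calc = adduct_mz(host, guest, nh, ng, charge)
            err = (obs_mz - calc) / calc * 1e6
            if abs(err) <= tol_ppm:
                matches.append(
                    AdductAssignment(nh, ng, charge, calc, obs_mz, err)
                )
    matches.sort(key=lambda a: (abs(a.error_ppm), a.n_host + a.n_guest))
    return matches
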