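"""Exact 1:1 host-guest mass-balance equilibrium and continuous-variation (Job) analysis.

For a single complexation equilibrium H + G <=> HG with association constant
``Ka = [HG] / ([H][G])`` (M^-1), the complex concentration at total
concentrations H0 and G0 is the smaller root of the quadratic mass balance

    Ka*(H0 - c)*(G0 - c) = c.

Everything downstream (spectroscopic titration models, ITC injection heats,
Job curves) is built on this root.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Optional, Sequence, Tuple

import numpy as np

from .errors import DomainError, NoMaximumError, UndefinedFractionError

__all__ = [
    "EquilibriumState",
    "JobCurve",
    "solve_equilibrium_1to1",
    "complex_concentration",
    "bound_fraction",
    "solve_equilibrium_general",
    "job_curve",
    "job_maximum",
]

_GOLDEN = (math.sqrt(5.0) - 1.0) / 2.0


@dataclass(frozen=True)
class EquilibriumState:
    """Speciation of a 1:1 host-guest equilibrium at fixed totals and Ka.

    All concentrations are mol/L; ``ka`` is the association constant in M^-1.
    Mass balance holds by construction: ``free_host + complex_conc ==
    total_host`` and ``free_guest + complex_conc == total_guest``.
    """

    total_host: float
    total_guest: float
    ka: float
    complex_conc: float
    free_host: float
    free_guest: float


@dataclass
class JobCurve:
    """A continuous-variation series at constant total concentration.

    ``mole_fractions`` are host mole fractions x in [0, 1]; at each x the
    sample contains ``x * total_conc`` host and ``(1 - x) * total_conc``
    guest.  ``complex_concs`` is the equilibrium complex concentration at
    each point.  Model-backed curves additionally carry ``ka`` and
    ``stoichiometry`` so the continuous curve can be re-evaluated between
    grid points; purely experimental curves leave them unset.
    """

    total_conc: float
    mole_fractions: np.ndarray
    complex_concs: np.ndarray
    observable: Optional[np.ndarray] = None
    ka: Optional[float] = None
    stoichiometry: Tuple[int, int] = (1, 1)

    def __post_init__(self) -> None:
        self.mole_fractions = np.asarray(self.mole_fractions, dtype=float)
        self.complex_concs = np.asarray(self.complex_concs, dtype=float)
        if self.mole_fractions.shape != self.complex_concs.shape:
            raise DomainError(
                "mole_fractions and complex_concs must have the same length"
            )
        if self.observable is not None:
            self.observable = np.asarray(self.observable, dtype=float)
            if self.observable.shape != self.mole_fractions.shape:
                raise DomainError("observable must match mole_fractions in length")


def _check_nonnegative(name: str, value: float) -> None:
    if not (value >= 0.0):  # also rejects NaN
        raise DomainError(f"{name} must be >= 0, got {value!r}")


def complex_concentration(total_host: float, total_guest: float, ka: float) -> float:
    """Complex concentration of the 1:1 equilibrium (mol/L).

    Uses the conjugate form of the quadratic root,

        c = 2*H0*G0 / (S + sqrt(S^2 - 4*H0*G0)),   S = H0 + G0 + 1/Ka,

    which avoids the catastrophic cancellation of the textbook
    ``(S - sqrt(...)) / 2`` form when ``S^2 >> 4*H0*G0`` (weak binding or
    strongly unequal totals).  Ka = 0 and Ka = inf are handled as explicit
    limits (0 and min(H0, G0)).
    """
    _check_nonnegative("total_host", total_host)
    _check_nonnegative("total_guest", total_guest)
    _check_nonnegative("ka", ka)
    if total_host == 0.0 or total_guest == 0.0 or ka == 0.0:
        return 0.0
    if math.isinf(ka):
        return min(total_host, total_guest)
    s = total_host + total_guest + 1.0 / ka
    disc = s * s - 4.0 * total_host * total_guest
    # disc >= (H0 - G0)^2 + ... >= 0 analytically; clamp rounding noise
    root = math.sqrt(disc) if disc > 0.0 else 0.0
    return 2.0 * total_host * total_guest / (s + root)


def solve_equilibrium_1to1(
    total_host: float, total_guest: float, ka: float
) -> EquilibriumState:
    """Solve the 1:1 mass balance and return the full speciation."""
    c = complex_concentration(total_host, total_guest, ka)
    return EquilibriumState(
        total_host=total_host,
        total_guest=total_guest,
        ka=ka,
        complex_conc=c,
        free_host=total_host - c,
        free_guest=total_guest - c,
    )


def bound_fraction(state: EquilibriumState) -> float:
    """Fraction of the total guest present as complex, in [0, 1].

    This is the quantity the fast-exchange spectroscopic observables are
    linear in.
    """
    if state.total_guest <= 0.0:
        raise UndefinedFractionError(
            "bound_fraction is undefined for total_guest = 0"
        )
    f = state.complex_conc / state.total_guest
    return min(max(f, 0.0), 1.0)


def solve_equilibrium_general(
    total_host: float,
    total_guest: float,
    ka: float,
    n_host: int = 1,
    n_guest: int = 1,
) -> float:
    """Complex concentration of a single m:n complex ``m H + n G <=> HmGn``.

    ``ka = [HmGn] / ([H]^m [G]^n)``.  Solved by bisection on the extent of
    reaction; included to let Job-maximum analysis discriminate
    stoichiometries (the 1:1 curve peaks at x = 0.5, a 1:2 host:guest curve
    at x = 1/3, ...).  m, n restricted to 1..3.
    """
    m, n = int(n_host), int(n_guest)
    if not (1 <= m <= 3 and 1 <= n <= 3):
        raise DomainError(f"stoichiometry ({m}:{n}) outside supported range 1..3")
    _check_nonnegative("total_host", total_host)
    _check_nonnegative("total_guest", total_guest)
    _check_nonnegative("ka", ka)
    if total_host == 0.0 or total_guest == 0.0 or ka == 0.0:
        return 0.0
    hi = min(total_host / m, total_guest / n)
    if math.isinf(ka):
        return hi

    def f(c: float) -> float:
        return ka * (total_host - m * c) ** m * (total_guest - n * c) ** n - c

    lo = 0.0
    if f(hi) >= 0.0:  # numerically saturated
        return hi
    for _ in range(200):  # bisection: f decreasing, f(lo) >= 0 > f(hi)
        mid = 0.5 * (lo + hi)
        if f(mid) > 0.0:
            lo = mid
        else:
            hi = mid
        if hi - lo <= 1e-15 * hi:
            break
    return 0.5 * (lo + hi)


def job_curve(
    total_conc: float,
    mole_fractions: Optional[Sequence[float]] = None,
    ka: float = 0.0,
    stoichiometry: Tuple[int, int] = (1, 1),
) -> JobCurve:
    """Continuous-variation curve: complex concentration vs host mole fraction.

    At each mole fraction x the totals are ``H0 = x * total_conc`` and
    ``G0 = (1 - x) * total_conc`` (constant host+guest sum, as in the
    continuous-variation method).  Default grid: 11 evenly spaced mole
    fractions 0..1.
    """
    if not (total_conc > 0.0):
        raise DomainError(f"total_conc must be > 0, got {total_conc!r}")
    xs = (
        np.linspace(0.0, 1.0, 11)
        if mole_fractions is None
        else np.asarray(mole_fractions, dtype=float)
    )
    if xs.size and (xs.min() < 0.0 or xs.max() > 1.0):
        raise DomainError("mole_fractions must lie in [0, 1]")
    m, n = stoichiometry
    cs = np.array(
        [
            solve_equilibrium_general(x * total_conc, (1.0 - x) * total_conc, ka, m, n)
            if (m, n) != (1, 1)
            else complex_concentration(x * total_conc, (1.0 - x) * total_conc, ka)
            for x in xs
        ]
    )
    return JobCurve(
        total_conc=total_conc,
        mole_fractions=xs,
        complex_concs=cs,
        ka=ka,
        stoichiometry=(m, n),
    )


def _golden_section_max(
    f: Callable[[float], float], a: float, b: float, tol: float = 1e-9
) -> float:
    """Argmax of a unimodal f on [a, b] by golden-section search."""
    c = b - _GOLDEN * (b - a)
    d = a + _GOLDEN * (b - a)
    fc, fd = f(c), f(d)
    while abs(b - a) > tol:
        if fc > fd:
            b, d, fd = d, c, fc
            c = b - _GOLDEN * (b - a)
            fc = f(c)
        else:
            a, c, fc = c, d, fd
            d = a + _GOLDEN * (b - a)
            fd = f(d)
    return 0.5 * (a + b)


def job_maximum(curve: JobCurve) -> float:
    """Host mole fraction at which the Job curve peaks.

    For model-backed curves the continuous curve is re-evaluated and the
    argmax refined by golden-section search between the best grid point's
    neighbours (a 1:1 curve returns 0.5 to ~1e-6 or better).  Experimental
    curves (no stored ka) fall back to the parabola through the best point
    and its neighbours.
    """
    y = curve.observable if curve.observable is not None and curve.ka is None else None
    signal = curve.complex_concs if y is None else y
    xs = curve.mole_fractions
    if xs.size < 3 or xs.min() > 0.5 or xs.max() < 0.5:
        raise DomainError("curve must have >= 3 points spanning (0, 1)")
    if np.allclose(signal, signal[0]):
        raise NoMaximumError("curve is flat; no maximum to locate")
    i = int(np.argmax(signal))
    lo = xs[max(i - 1, 0)]
    hi = xs[min(i + 1, xs.size - 1)]
    if curve.ka is not None:
        m, n = curve.stoichiometry
        ctot, ka = curve.total_conc, curve.ka

        def f(x: float) -> float:
            if (m, n) == (1, 1):
                return complex_concentration(x * ctot, (1.0 - x) * ctot, ka)
            return solve_equilibrium_general(x * ctot, (1.0 - x) * ctot, ka, m, n)

        return _golden_section_max(f, lo, hi)
    # discrete data: parabolic vertex through (i-1, i, i+1)
    if i == 0 or i == xs.size - 1:
        return float(xs[i])
    x0, x1, x2 = xs[i - 1], xs[i], xs[i + 1]
    y0, y1, y2 = signal[i - 1], signal[i], signal[i + 1]
    denom = (x0 - x1) * (x0 - x2) * (x1 - x2)
    a = (x2 * (y1 - y0) + x1 * (y0 - y2) + x0 * (y2 - y1)) / denom
    b = (x2 * x2 * (y0 - y1) + x1 * x1 * (y2 - y0) + x0 * x0 * (y1 - y2)) / denom
    if a >= 0.0:
        return float(x1)
    return float(-b / (2.0 * a))
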