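"""Incremental-injection 1:1 ITC forward model and (N, Ka, dH) estimation.

An ITC run titrates host from the syringe into guest in a fixed-volume
cell.  Each injection of volume dV expels an equal volume of the current
mixture (the recursive overflow convention), so after injection i

    M_i = M_{i-1} * (1 - dV_i/V0)                      (guest in cell)
    X_i = X_{i-1} * (1 - dV_i/V0) + X_syr * dV_i/V0    (host in cell)

The heat of injection i measures the change in moles of complex held in
the cell, the complex expelled with the overflow carrying no signal:

    q_i = dH * V0 * (c_i - c_{i-1} * (1 - dV_i/V0))

with c_i the 1:1 equilibrium complex concentration at totals (X_i, n*M_i),
n being the fitted binding-site stoichiometry.  Heats are stored in
microcalories, dH in kcal/mol (1 kcal = 1e9 ucal).

Fitting (n, log10 Ka, dH) to the heat vector recovers the standard ITC
parameter triple; dG = -RT ln Ka and TdS = dH - dG are filled by identity.
The c-value Ka*M0*n controls curve shape: sigmoidal and well-identified
for c in roughly 1-1000.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import List, Optional, Tuple

import numpy as np
from scipy.optimize import least_squares

from .equilibria import complex_concentration
from .errors import DomainError, UnidentifiableModelError
from .thermo import DEFAULT_TEMPERATURE, delta_g_from_ka, tds_from_dh_dg

__all__ = [
    "KCAL_TO_UCAL",
    "ITCExperiment",
    "ITCFitResult",
    "track_cell_concentrations",
    "simulate_itc_heats",
    "fit_itc",
]

#: 1 kcal = 1e3 cal = 1e9 ucal.
KCAL_TO_UCAL = 1e9


@dataclass
class ITCExperiment:
    """Design (and optionally measured heats) of an incremental ITC run.

    Volumes in litres, concentrations in mol/L, temperature in kelvin,
    heats in microcalories per injection.  The syringe titrant must be more
    concentrated than the cell solution, and the cumulative injected volume
    may not exceed the cell volume (the overflow model loses accuracy for
    schedules that replace the whole cell).
    """

    cell_volume: float
    cell_conc: float
    syringe_conc: float
    injection_volumes: np.ndarray
    temperature: float = DEFAULT_TEMPERATURE
    heats: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.injection_volumes = np.asarray(self.injection_volumes, dtype=float)
        if not (self.cell_volume > 0.0):
            raise DomainError(f"cell_volume must be > 0, got {self.cell_volume!r}")
        if np.any(self.injection_volumes <= 0.0):
            raise DomainError("injection_volumes must all be > 0")
        if not (self.syringe_conc > self.cell_conc > 0.0):
            raise DomainError(
                "require syringe_conc > cell_conc > 0, got "
                f"syringe_conc={self.syringe_conc!r}, cell_conc={self.cell_conc!r}"
            )
        if float(self.injection_volumes.sum()) > self.cell_volume:
            raise DomainError(
                "cumulative injection volume exceeds cell_volume"
            )
        if not (self.temperature > 0.0):
            raise DomainError(f"temperature must be > 0, got {self.temperature!r}")
        if self.heats is not None:
            self.heats = np.asarray(self.heats, dtype=float)
            if self.heats.shape != self.injection_volumes.shape:
                raise DomainError("heats must match injection_volumes in length")

    @property
    def n_injections(self) -> int:
        return int(self.injection_volumes.size)


def track_cell_concentrations(exp: ITCExperiment) -> Tuple[np.ndarray, np.ndarray]:
    """Total (host, guest) cell concentrations after each injection."""
    f = exp.injection_volumes / exp.cell_volume
    host = np.empty(exp.n_injections)
    guest = np.empty(exp.n_injections)
    x, m = 0.0, exp.cell_conc
    for i, fi in enumerate(f):
        m *= 1.0 - fi
        x = x * (1.0 - fi) + exp.syringe_conc * fi
        host[i], guest[i] = x, m
    return host, guest


def simulate_itc_heats(
    exp: ITCExperiment, n: float, ka: float, dh: float
) -> np.ndarray:
    """Per-injection heats (ucal) for binding parameters (n, Ka, dH).

    The guest offers ``n * M_i`` binding sites; the complex concentration
    after each injection comes from the 1:1 mass-balance root.  As the cell
    saturates the cumulative heat approaches dH * V0 * n * M_final.
    """
    if ka < 0.0:
        raise DomainError(f"ka must be >= 0, got {ka!r}")
    if not (n > 0.0):
        raise DomainError(f"n must be > 0, got {n!r}")
    host, guest = track_cell_concentrations(exp)
    f = exp.injection_volumes / exp.cell_volume
    q = np.empty(exp.n_injections)
    c_prev = 0.0
    for i in range(exp.n_injections):
        c_i = complex_concentration(host[i], n * guest[i], ka)
        q[i] = dh * exp.cell_volume * (c_i - c_prev * (1.0 - f[i])) * KCAL_TO_UCAL
        c_prev = c_i
    return q


@dataclass
class ITCFitResult:
    """Fitted ITC parameters with identity-derived dG and TdS (kcal/mol)."""

    n: float
    ka: float
    dh: float
    dg: float
    tds: float
    temperature: float
    n_stderr: float
    ka_stderr: float
    dh_stderr: float
    converged: bool
    residual_rms_ucal: float = float("nan")
    warnings: List[str] = field(default_factory=list)
    message: str = ""


def fit_itc(exp: ITCExperiment) -> ITCFitResult:
    """Least-squares fit of (n, log10 Ka, dH) to the measured heats.

    Initialization: n = 1; dH from the first-injection heat assuming
    complete binding; Ka by coarse grid over log10(Ka) in {1, ..., 8}.
    dG and TdS are filled from the thermodynamic identities, never fitted.
    A run whose final molar ratio does not reach the fitted n is flagged
    ``identifiability_low``.
    """
    if exp.heats is None:
        raise DomainError("experiment has no heats to fit")
    if exp.n_injections < 8:
        raise DomainError("fit_itc requires at least 8 injections")
    q = exp.heats
    if np.allclose(q, 0.0):
        raise UnidentifiableModelError("all heats are zero; nothing to fit")

    moles_1 = exp.syringe_conc * float(exp.injection_volumes[0])
    dh0 = float(q[0]) / KCAL_TO_UCAL / moles_1

    def residuals(params: np.ndarray) -> np.ndarray:
        n, log10_ka, dh = params
        return simulate_itc_heats(exp, n, 10.0 ** log10_ka, dh) - q

    best = None
    for log10_ka in range(1, 9):
        cost = float(np.sum(residuals(np.array([1.0, log10_ka, dh0])) ** 2))
        if best is None or cost < best[0] - 1e-30:
            best = (cost, log10_ka)
    x0 = np.array([1.0, best[1], dh0])
    qscale = max(float(np.max(np.abs(q))) / KCAL_TO_UCAL / moles_1, 1e-12)
    res = least_squares(
        residuals,
        x0,
        bounds=([1e-3, -2.0, -np.inf], [10.0, 12.0, np.inf]),
        ftol=1e-12,
        xtol=1e-14,
        gtol=1e-14,
        x_scale=[1.0, 1.0, qscale],
        max_nfev=3000,
    )
    n, log10_ka, dh = res.x
    ka = 10.0 ** log10_ka
    m, p = q.size, 3
    stderr = np.full(p, np.nan)
    if res.status > 0 and m > p:
        try:
            cov = np.linalg.inv(res.jac.T @ res.jac) * (2.0 * res.cost / (m - p))
            stderr = np.sqrt(np.clip(np.diag(cov), 0.0, None))
        except np.linalg.LinAlgError:
            pass

    warnings: List[str] = []
    host, guest = track_cell_concentrations(exp)
    if host[-1] / guest[-1] < n:
        warnings.append("identifiability_low")

    dg = delta_g_from_ka(ka, exp.temperature)
    return ITCFitResult(
        n=float(n),
        ka=float(ka),
        dh=float(dh),
        dg=dg,
        tds=tds_from_dh_dg(float(dh), dg),
        temperature=exp.temperature,
        n_stderr=float(stderr[0]),
        ka_stderr=math.log(10.0) * float(ka) * float(stderr[1]),
        dh_stderr=float(stderr[2]),
        converged=bool(res.status > 0),
        residual_rms_ucal=float(np.sqrt(np.mean(res.fun ** 2))),
        warnings=warnings,
        message=str(res.message),
    )
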