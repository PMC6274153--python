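"""Seeded generators for titration, Job and ITC datasets.

The defaults mirror the encapsulation study's experimental designs:

* famotidine (FT)-like UV-vis titration — 0.05 mM guest, host 0-6 equiv,
  signal decreasing;
* nizatidine (NT)-like UV-vis titration — 0.04 mM guest, host 0-3 equiv,
  signal increasing;
* cimetidine (CT)-like fast-exchange NMR titration — 1.0 mM guest,
  host 0-3 equiv, probe proton shifting upfield;
* Job series at constant total concentration on an 11-point mole-fraction
  grid;
* ITC — 200 uL cell, 20 x 2 uL injections of 2 mM host into 0.05-0.1 mM
  guest at 25 degC.

Noise is additive homoscedastic Gaussian on the observable, seeded through
one `numpy` Generator per dataset, so identical configs are bit-identical.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Optional, Tuple

import numpy as np

from .equilibria import JobCurve, job_curve
from .errors import DomainError
from .itc import ITCExperiment, simulate_itc_heats
from .thermo import DEFAULT_TEMPERATURE
from .titration import SpectroTitration, predict_observable

__all__ = ["GeneratorConfig", "generate_titration", "generate_job", "generate_itc", "study_configs"]


@dataclass(frozen=True)
class GeneratorConfig:
    """Ground truth plus design for one synthetic dataset.

    ``experiment`` selects the generator: "uvvis" | "nmr_fast" | "job" |
    "itc".  Concentrations are mol/L, volumes litres, energies kcal/mol;
    ``noise_sigma`` is in the observable's own units (AU, ppm, or ucal).
    Identical configs (same seed) generate identical datasets.
    """

    experiment: str
    true_ka: float
    seed: int = 0
    noise_sigma: float = 0.0
    # spectroscopic / job designs
    guest_total: float = 5e-5
    max_equiv: float = 6.0
    n_points: int = 12
    obs_free: float = 1.0
    obs_bound: float = 0.4
    total_conc: float = 5e-5
    stoichiometry: Tuple[int, int] = (1, 1)
    probe_label: str = ""
    # ITC design
    true_dh: Optional[float] = None
    true_n: Optional[float] = None
    cell_volume: float = 200e-6
    cell_conc: float = 5e-5
    syringe_conc: float = 2e-3
    n_injections: int = 20
    injection_volume: float = 2e-6
    temperature: float = DEFAULT_TEMPERATURE

    def __post_init__(self) -> None:
        if self.experiment not in ("uvvis", "nmr_fast", "job", "itc"):
            raise DomainError(f"unknown experiment {self.experiment!r}")
        if self.noise_sigma < 0.0:
            raise DomainError("noise_sigma must be >= 0")
        if self.n_points < 4:
            raise DomainError("n_points must be >= 4")
        if self.true_ka < 0.0:
            raise DomainError("true_ka must be >= 0")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


def generate_titration(config: GeneratorConfig) -> SpectroTitration:
    """Synthetic spectroscopic titration: evenly spaced host totals from 0
    to ``max_equiv * guest_total`` plus Gaussian noise on the observable."""
    if config.experiment not in ("uvvis", "nmr_fast"):
        raise DomainError(
            f"generate_titration requires experiment uvvis|nmr_fast, got {config.experiment!r}"
        )
    hosts = np.linspace(0.0, config.max_equiv * config.guest_total, config.n_points)
    clean = predict_observable(
        hosts, config.guest_total, config.true_ka, config.obs_free, config.obs_bound
    )
    noise = config.rng().normal(0.0, config.noise_sigma, size=clean.size) if config.noise_sigma else 0.0
    return SpectroTitration(
        mode="uvvis" if config.experiment == "uvvis" else "nmr",
        guest_total=config.guest_total,
        host_totals=hosts,
        observables=clean + noise,
        probe_label=config.probe_label,
    )


def generate_job(config: GeneratorConfig) -> JobCurve:
    """Synthetic continuous-variation series on an 11-point grid.

    The observable is proportional to the complex concentration (scaled to
    the config's signal range) plus noise; the underlying model curve is
    retained so the continuous maximum can be refined.
    """
    if config.experiment != "job":
        raise DomainError(f"generate_job requires experiment 'job', got {config.experiment!r}")
    curve = job_curve(
        config.total_conc,
        np.linspace(0.0, 1.0, 11),
        config.true_ka,
        stoichiometry=config.stoichiometry,
    )
    peak = curve.complex_concs.max()
    scale = (config.obs_bound - config.obs_free) / peak if peak > 0 else 0.0
    clean = scale * curve.complex_concs
    noise = config.rng().normal(0.0, config.noise_sigma, size=clean.size) if config.noise_sigma else 0.0
    curve.observable = clean + noise
    return curve


def generate_itc(config: GeneratorConfig) -> ITCExperiment:
    """Synthetic ITC run with heats from the injection model plus noise."""
    if config.experiment != "itc":
        raise DomainError(f"generate_itc requires experiment 'itc', got {config.experiment!r}")
    if config.true_dh is None or config.true_n is None:
        raise DomainError("itc generation requires true_dh and true_n")
    exp = ITCExperiment(
        cell_volume=config.cell_volume,
        cell_conc=config.cell_conc,
        syringe_conc=config.syringe_conc,
        injection_volumes=np.full(config.n_injections, config.injection_volume),
        temperature=config.temperature,
    )
    clean = simulate_itc_heats(exp, config.true_n, config.true_ka, config.true_dh)
    noise = config.rng().normal(0.0, config.noise_sigma, size=clean.size) if config.noise_sigma else 0.0
    exp.heats = clean + noise
    return exp


def study_configs(seed: int = 0, noise: bool = False) -> Dict[str, GeneratorConfig]:
    """Configs emulating the study's designs, keyed by dataset name.

    Ground-truth parameters are the published estimates (spectroscopic Ka
    from the titrations; ITC N / Ka / dH rows).  With ``noise=True`` the
    spectroscopic sigma is 1 % of the signal range and the ITC sigma 2 % of
    the largest heat, our stand-ins for unpublished instrument noise.
    """
    ft_uv = GeneratorConfig(
        experiment="uvvis", true_ka=1.30e4, guest_total=5e-5, max_equiv=6.0,
        obs_free=1.0, obs_bound=0.4, probe_label="283 nm", seed=seed,
        noise_sigma=0.006 if noise else 0.0,
    )
    nt_uv = GeneratorConfig(
        experiment="uvvis", true_ka=1.05e5, guest_total=4e-5, max_equiv=3.0,
        obs_free=0.30, obs_bound=0.85, probe_label="315 nm", seed=seed + 1,
        noise_sigma=0.0055 if noise else 0.0,
    )
    ct_nmr = GeneratorConfig(
        experiment="nmr_fast", true_ka=6.57e3, guest_total=1e-3, max_equiv=3.0,
        obs_free=2.95, obs_bound=2.70, probe_label="H(5)", seed=seed + 2,
        noise_sigma=0.0025 if noise else 0.0,
    )
    ft_job = GeneratorConfig(
        experiment="job", true_ka=1.30e4, total_conc=5e-5,
        obs_free=0.0, obs_bound=0.2, probe_label="269 nm", seed=seed + 3,
        noise_sigma=0.002 if noise else 0.0,
    )
    nt_job = GeneratorConfig(
        experiment="job", true_ka=1.05e5, total_conc=4e-5,
        obs_free=0.0, obs_bound=0.2, seed=seed + 4,
        noise_sigma=0.002 if noise else 0.0,
    )
    ft_itc = GeneratorConfig(
        experiment="itc", true_ka=4.95e4, true_dh=-11.08, true_n=1.12,
        cell_conc=5e-5, seed=seed + 5, noise_sigma=0.25 if noise else 0.0,
    )
    ct_itc = GeneratorConfig(
        experiment="itc", true_ka=1.44e4, true_dh=-13.23, true_n=0.99,
        cell_conc=5e-5, seed=seed + 6, noise_sigma=0.25 if noise else 0.0,
    )
    nt_itc = GeneratorConfig(
        experiment="itc", true_ka=1.34e4, true_dh=-15.60, true_n=0.95,
        cell_conc=1e-4, seed=seed + 7, noise_sigma=0.6 if noise else 0.0,
    )
    return {
        "FT_uvvis": ft_uv, "NT_uvvis": nt_uv, "CT_nmr": ct_nmr,
        "FT_job": ft_job, "NT_job": nt_job,
        "FT_itc": ft_itc, "CT_itc": ct_itc, "NT_itc": nt_itc,
    }
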