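"""CSV/JSON input-output, report assembly and the config-driven pipeline.

File conventions: tabular data is UTF-8 CSV with a header row and "."
decimal; configs and machine-readable reports are JSON.  User-facing
config keys carry unit suffixes (``..._mM``, ``..._uL``, ``..._C``) and
are converted to SI (mol/L, L, K) at parse time; numeric CSV columns are
written at full precision — rounding happens only in the human-readable
report text.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path
from typing import Any, Dict, List, Optional, Union

import numpy as np
import pandas as pd

from . import __version__
from .equilibria import JobCurve, job_maximum
from .errors import DomainError, PipelineConfigError
from .itc import ITCExperiment, fit_itc
from .synthetic import GeneratorConfig, generate_itc, generate_job, generate_titration
from .thermo import audit_table, delta_g_from_ka, load_published_table
from .titration import SpectroTitration, fit_titration

__all__ = [
    "read_titration_csv",
    "write_titration_csv",
    "read_job_csv",
    "write_job_csv",
    "read_itc_experiment",
    "write_itc_experiment",
    "AnalysisReport",
    "run_pipeline",
]

PathLike = Union[str, Path]


def _require_columns(df: pd.DataFrame, cols: List[str], what: str) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise DomainError(f"{what} is missing required columns: {missing}")


def read_titration_csv(
    path: PathLike,
    mode: Optional[str] = None,
    guest_total: Optional[float] = None,
    probe_label: str = "",
    meta_path: Optional[PathLike] = None,
) -> SpectroTitration:
    """Read a titration series (columns ``host_total_M``, ``observable``).

    Metadata (mode, guest total, probe label) comes from a sidecar JSON
    (keys ``mode``, ``guest_total_mM``, ``probe_label``) or the keyword
    arguments; explicit keywords win.
    """
    df = pd.read_csv(path)
    _require_columns(df, ["host_total_M", "observable"], f"titration CSV {path}")
    meta: Dict[str, Any] = {}
    if meta_path is not None:
        meta = json.loads(Path(meta_path).read_text())
    mode = mode or meta.get("mode")
    if guest_total is None and "guest_total_mM" in meta:
        guest_total = float(meta["guest_total_mM"]) * 1e-3
    if mode is None or guest_total is None:
        raise DomainError(
            "titration metadata incomplete: need mode and guest_total "
            "(keyword or sidecar JSON)"
        )
    return SpectroTitration(
        mode=mode,
        guest_total=guest_total,
        host_totals=df["host_total_M"].to_numpy(),
        observables=df["observable"].to_numpy(),
        probe_label=probe_label or meta.get("probe_label", ""),
        slow_exchange=bool(meta.get("slow_exchange", False)),
    )


def write_titration_csv(
    series: SpectroTitration, path: PathLike, meta_path: Optional[PathLike] = None
) -> None:
    pd.DataFrame(
        {"host_total_M": series.host_totals, "observable": series.observables}
    ).to_csv(path, index=False)
    if meta_path is not None:
        Path(meta_path).write_text(
            json.dumps(
                {
                    "mode": series.mode,
                    "guest_total_mM": series.guest_total * 1e3,
                    "probe_label": series.probe_label,
                    "slow_exchange": series.slow_exchange,
                },
                indent=2,
            )
            + "\n"
        )


def read_job_csv(path: PathLike, total_conc: Optional[float] = None) -> JobCurve:
    """Read a Job series (columns ``mole_fraction``, ``observable``).

    An optional ``complex_conc_M`` column (written by the generator) is
    used when present; otherwise the observable stands in and the curve is
    treated as experimental (discrete maximum location).
    """
    df = pd.read_csv(path)
    _require_columns(df, ["mole_fraction", "observable"], f"Job CSV {path}")
    obs = df["observable"].to_numpy()
    complexes = (
        df["complex_conc_M"].to_numpy() if "complex_conc_M" in df.columns else obs
    )
    return JobCurve(
        total_conc=total_conc if total_conc is not None else float("nan"),
        mole_fractions=df["mole_fraction"].to_numpy(),
        complex_concs=complexes,
        observable=obs,
    )


def write_job_csv(curve: JobCurve, path: PathLike) -> None:
    df = pd.DataFrame(
        {
            "mole_fraction": curve.mole_fractions,
            "complex_conc_M": curve.complex_concs,
        }
    )
    if curve.observable is not None:
        df["observable"] = curve.observable
    df.to_csv(path, index=False)


def read_itc_experiment(
    descriptor_path: PathLike, heats_path: Optional[PathLike] = None
) -> ITCExperiment:
    """Read an ITC run from a JSON descriptor plus optional heats CSV.

    Descriptor keys (units in the names): ``cell_volume_uL``,
    ``cell_conc_mM``, ``syringe_conc_mM``, ``injection_volumes_uL``,
    ``temperature_C``.  Heats CSV columns: ``injection_index``,
    ``heat_ucal`` (ordered by index).
    """
    d = json.loads(Path(descriptor_path).read_text())
    for key in ("cell_volume_uL", "cell_conc_mM", "syringe_conc_mM", "injection_volumes_uL"):
        if key not in d:
            raise DomainError(f"ITC descriptor {descriptor_path} missing key {key!r}")
    heats = None
    if heats_path is not None:
        hdf = pd.read_csv(heats_path)
        _require_columns(hdf, ["injection_index", "heat_ucal"], f"heats CSV {heats_path}")
        heats = hdf.sort_values("injection_index")["heat_ucal"].to_numpy()
    return ITCExperiment(
        cell_volume=float(d["cell_volume_uL"]) * 1e-6,
        cell_conc=float(d["cell_conc_mM"]) * 1e-3,
        syringe_conc=float(d["syringe_conc_mM"]) * 1e-3,
        injection_volumes=np.asarray(d["injection_volumes_uL"], dtype=float) * 1e-6,
        temperature=float(d.get("temperature_C", 25.0)) + 273.15,
        heats=heats,
    )


def write_itc_experiment(
    exp: ITCExperiment, descriptor_path: PathLike, heats_path: Optional[PathLike] = None
) -> None:
    Path(descriptor_path).write_text(
        json.dumps(
            {
                "cell_volume_uL": exp.cell_volume * 1e6,
                "cell_conc_mM": exp.cell_conc * 1e3,
                "syringe_conc_mM": exp.syringe_conc * 1e3,
                "injection_volumes_uL": (exp.injection_volumes * 1e6).tolist(),
                "temperature_C": exp.temperature - 273.15,
            },
            indent=2,
        )
        + "\n"
    )
    if heats_path is not None and exp.heats is not None:
        pd.DataFrame(
            {
                "injection_index": np.arange(1, exp.n_injections + 1),
                "heat_ucal": exp.heats,
            }
        ).to_csv(heats_path, index=False)


# ---------------------------------------------------------------------------
# pipeline


@dataclass
class AnalysisReport:
    """Fit summaries, audit residuals and provenance for one pipeline run."""

    rows: List[Dict[str, Any]] = field(default_factory=list)
    audits: Optional[pd.DataFrame] = None
    provenance: Dict[str, Any] = field(default_factory=dict)

    def to_json(self) -> str:
        payload = {
            "rows": self.rows,
            "audits": (
                self.audits.to_dict(orient="records") if self.audits is not None else []
            ),
            "provenance": self.provenance,
        }
        return json.dumps(payload, indent=2, default=float) + "\n"

    def to_text(self) -> str:
        """Human-readable report; the timestamp is isolated to the first line."""
        lines = [f"# generated: {datetime.now(timezone.utc).isoformat()}"]
        lines.append(f"# hostguest {self.provenance.get('version', '?')} "
                     f"seed={self.provenance.get('seed')} "
                     f"config_sha256={self.provenance.get('config_sha256', '')[:12]}")
        if self.rows:
            lines.append("")
            lines.append(
                f"{'label':<14}{'method':<8}{'N':>7}{'Ka (1/M)':>12}{'+/-':>10}"
                f"{'dH':>8}{'dG':>8}{'TdS':>8}"
            )
            for r in self.rows:
                def fmt(key, nd=2, width=8):
                    v = r.get(key)
                    if v is None or (isinstance(v, float) and math.isnan(v)):
                        return " " * (width - 1) + "-"
                    return f"{v:>{width}.{nd}f}"

                ka = r.get("ka")
                ka_s = f"{ka:>12.4g}" if ka is not None else f"{'-':>12}"
                kerr = r.get("ka_stderr")
                kerr_s = f"{kerr:>10.2g}" if kerr is not None and not math.isnan(kerr) else f"{'-':>10}"
                if r["method"] == "job":
                    lines.append(
                        f"{r['label']:<14}{'job':<8} maximum at x = {r['job_max']:.3f}"
                    )
                    continue
                lines.append(
                    f"{r['label']:<14}{r['method']:<8}{fmt('n', 2, 7)}{ka_s}{kerr_s}"
                    f"{fmt('dh')}{fmt('dg')}{fmt('tds')}"
                )
        if self.audits is not None and len(self.audits):
            lines.append("")
            lines.append("identity audit (kcal/mol):")
            for _, a in self.audits.iterrows():
                status = "ok " if a["passed"] else "FAIL"
                lines.append(
                    f"  [{status}] {a['label']:<10}{a['method']:<8}{a['identity']:<24}"
                    f"residual={a['residual']:+.4f}"
                )
        return "\n".join(lines) + "\n"


def _fit_dataset(entry: Dict[str, Any], base: Path, seed: int) -> Dict[str, Any]:
    label = entry.get("label", "dataset")
    if "generate" in entry:
        gen = dict(entry["generate"])
        gen.setdefault("seed", seed)
        if "stoichiometry" in gen:
            gen["stoichiometry"] = tuple(gen["stoichiometry"])
        cfg = GeneratorConfig(**gen)
        if cfg.experiment in ("uvvis", "nmr_fast"):
            series = generate_titration(cfg)
        elif cfg.experiment == "job":
            curve = generate_job(cfg)
            return {"label": label, "method": "job", "job_max": job_maximum(curve)}
        else:
            exp = generate_itc(cfg)
            return _itc_row(label, exp)
        return _titration_row(label, series)
    if "titration_csv" in entry:
        series = read_titration_csv(
            base / entry["titration_csv"],
            mode=entry.get("mode"),
            guest_total=(
                float(entry["guest_total_mM"]) * 1e-3
                if "guest_total_mM" in entry
                else None
            ),
            meta_path=base / entry["meta_json"] if "meta_json" in entry else None,
        )
        return _titration_row(label, series)
    if "itc_json" in entry:
        exp = read_itc_experiment(
            base / entry["itc_json"],
            base / entry["heats_csv"] if "heats_csv" in entry else None,
        )
        return _itc_row(label, exp)
    if "job_csv" in entry:
        curve = read_job_csv(base / entry["job_csv"])
        return {"label": label, "method": "job", "job_max": job_maximum(curve)}
    raise PipelineConfigError(
        f"dataset {label!r} needs one of: generate, titration_csv, itc_json, job_csv"
    )


def _titration_row(label: str, series: SpectroTitration) -> Dict[str, Any]:
    fit = fit_titration(series)
    dg = delta_g_from_ka(fit.ka)
    return {
        "label": label,
        "method": series.mode,
        "n": None,
        "ka": fit.ka,
        "ka_stderr": fit.ka_stderr,
        "dh": None,
        "dg": dg,
        "tds": None,
        "temperature": 298.15,
        "converged": fit.converged,
    }


def _itc_row(label: str, exp: ITCExperiment) -> Dict[str, Any]:
    fit = fit_itc(exp)
    return {
        "label": label,
        "method": "itc",
        "n": fit.n,
        "ka": fit.ka,
        "ka_stderr": fit.ka_stderr,
        "dh": fit.dh,
        "dg": fit.dg,
        "tds": fit.tds,
        "temperature": fit.temperature,
        "converged": fit.converged,
        "warnings": fit.warnings,
    }


def run_pipeline(config: Union[PathLike, Dict[str, Any]]) -> AnalysisReport:
    """Execute a config-driven run: generate/load -> fit -> audit -> report.

    The config is a JSON document (or an equivalent dict) with an optional
    ``datasets`` list (generator blocks or file references) and an optional
    ``audit`` block (``table_csv``, ``tolerance``).  At least one of the
    two must be present; an empty dataset list is a validation error.
    """
    if isinstance(config, (str, Path)):
        raw = Path(config).read_text()
        cfg = json.loads(raw)
        base = Path(config).parent
    else:
        cfg = config
        raw = json.dumps(config, sort_keys=True)
        base = Path(".")
    if "datasets" not in cfg and "audit" not in cfg:
        raise PipelineConfigError("config needs a 'datasets' list or an 'audit' block")
    if "datasets" in cfg and not cfg["datasets"]:
        raise PipelineConfigError("'datasets' list is empty")
    seed = int(cfg.get("seed", 0))
    report = AnalysisReport()
    report.provenance = {
        "version": __version__,
        "seed": seed,
        "config_sha256": hashlib.sha256(raw.encode()).hexdigest(),
        "inputs": [
            entry[k]
            for entry in cfg.get("datasets", [])
            for k in ("titration_csv", "itc_json", "job_csv")
            if k in entry
        ],
    }
    for i, entry in enumerate(cfg.get("datasets", [])):
        row = _fit_dataset(entry, base, seed + i)
        report.rows.append(row)
    if "audit" in cfg:
        audit_cfg = cfg["audit"] or {}
        table_csv = audit_cfg.get("table_csv")
        records = load_published_table(
            str(base / table_csv) if table_csv else None
        )
        report.audits = audit_table(records, float(audit_cfg.get("tolerance", 0.01)))
    return report
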