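"""Orchestrate charge → titration → SAXS → WAXS stages into one seeded run.

A run is described by a validated :class:`RunConfig` (typically loaded from
YAML).  Each requested stage writes its outputs into its own subdirectory
of the run directory, and a machine-readable ``report.json`` summarizes
every number produced.  Identical config + seeds give identical outputs;
a failing stage is recorded in the report without discarding the outputs
of stages that already completed.
"""

from __future__ import annotations

import json
import logging
import time
from pathlib import Path

import numpy as np
from pydantic import BaseModel, Field, ValidationError

from . import __version__
from .charge import charge_curve, default_pka_table, enumerate_groups, load_pka_table
from .io import (
    write_charge_curve,
    write_fit_report,
    write_peak_table,
    write_scattering,
    write_titration_csv,
)
from .saxs_analysis import fit_elliptical_cylinder, guinier_cross_section, power_law_fit
from .saxs_models import EllipticalCylinderParams
from .synthetic import (
    SaxsScenario,
    TitrationScenario,
    WaxsScenario,
    gen_saxs,
    gen_titration,
    gen_waxs,
)
from .titration import fit_apparent_pka, itc_profile, transition_ratio
from .waxs import assign_orders, classify_beta_sheet, detect_peaks

__all__ = ["RunConfig", "RunReport", "run_pipeline", "load_config"]

log = logging.getLogger("peptide_nanoform")


class ChargeStage(BaseModel):
    ph_min: float = 0.0
    ph_max: float = 14.0
    ph_step: float = 0.05


class TitrationStage(BaseModel):
    conc_mg_ml: float = Field(1.0, gt=0)
    titrant_molarity: float = Field(0.025, gt=0)
    n_injections: int = Field(60, ge=1)
    max_ratio: float = Field(6.0, gt=0)
    initial_ph: float | None = 2.6
    pka_shifts: dict[str, float] = Field(default_factory=dict)
    fit_class: str | None = "E"
    ph_noise_sigma: float = Field(0.0, ge=0)


class SaxsStage(BaseModel):
    r_minor: float = Field(..., gt=0)
    axis_ratio: float = Field(..., ge=1)
    length: float = Field(..., gt=0)
    scale: float = Field(1.0, ge=0)
    background: float = Field(0.0, ge=0)
    noise: str = "multiplicative"
    noise_level: float = Field(0.01, ge=0)
    fit_q_range: tuple[float, float] = (0.1, 7.0)
    fixed: list[str] = Field(default_factory=lambda: ["length", "scale"])
    init_perturbation: float = 1.3
    power_law_window: tuple[float, float] | None = None
    guinier_window: tuple[float, float] | None = None


class WaxsStage(BaseModel):
    prominence: float = Field(0.05, gt=0)
    tolerance: float = Field(0.05, gt=0)
    noise_sigma: float = Field(0.002, ge=0)


class RunConfig(BaseModel):
    """Validated description of one pipeline run."""

    peptides: dict[str, str] = Field(default_factory=dict)  # name -> sequence
    pka_table: str | None = None  # path; None = built-in table
    seed: int = 0
    charge: ChargeStage | None = None
    titration: TitrationStage | None = None
    saxs: SaxsStage | None = None
    waxs: WaxsStage | None = None


class RunReport(dict):
    """JSON-serializable per-stage report (a thin dict wrapper)."""


def load_config(path) -> RunConfig:
    import yaml

    with open(path) as fh:
        raw = yaml.safe_load(fh)
    try:
        return RunConfig.model_validate(raw)
    except ValidationError as exc:
        raise ValueError(f"invalid run config {path}: {exc}") from exc


def _stage_dir(outdir: Path, name: str) -> Path:
    d = outdir / name
    d.mkdir(parents=True, exist_ok=True)
    return d


def run_pipeline(config: RunConfig, outdir) -> RunReport:
    """Execute the configured stages in dependency order.

    Stage outputs land in ``outdir/<stage>/``; the report (also written to
    ``outdir/report.json``) maps stage → outputs/parameters, with a
    ``failed`` marker replacing the payload of any stage that raised.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    table = load_pka_table(config.pka_table) if config.pka_table else default_pka_table()
    report: RunReport = RunReport(
        version=__version__,
        seed=config.seed,
        started=time.strftime("%Y-%m-%dT%H:%M:%S"),
        stages={},
    )

    stages = [
        ("charge", config.charge, _run_charge),
        ("titration", config.titration, _run_titration),
        ("saxs", config.saxs, _run_saxs),
        ("waxs", config.waxs, _run_waxs),
    ]
    for name, stage_cfg, runner in stages:
        if stage_cfg is None:
            continue
        log.info("stage %s: starting", name)
        try:
            report["stages"][name] = runner(
                stage_cfg, config, table, _stage_dir(outdir, name)
            )
        except Exception as exc:  # noqa: BLE001 - partial failure is reported
            log.exception("stage %s failed", name)
            report["stages"][name] = {"failed": str(exc)}
    report["finished"] = time.strftime("%Y-%m-%dT%H:%M:%S")
    (outdir / "report.json").write_text(json.dumps(report, indent=2, default=str) + "\n")
    return report


def _run_charge(cfg: ChargeStage, config: RunConfig, table, outdir: Path) -> dict:
    out = {}
    grid = np.arange(cfg.ph_min, cfg.ph_max + 0.5 * cfg.ph_step, cfg.ph_step)
    for name, seq in config.peptides.items():
        groups = enumerate_groups(seq, table)
        curve = charge_curve(groups, grid)
        path = outdir / f"charge_{name}.csv"
        write_charge_curve(curve, path)
        out[name] = {
            "file": str(path),
            "z_min": float(curve.z.min()),
            "z_max": float(curve.z.max()),
        }
    return out


def _run_titration(cfg: TitrationStage, config: RunConfig, table, outdir: Path) -> dict:
    out = {}
    for name, seq in config.peptides.items():
        scenario = TitrationScenario(
            sequence=seq,
            conc_mg_ml=cfg.conc_mg_ml,
            pka_shifts=cfg.pka_shifts,
            titrant_molarity=cfg.titrant_molarity,
            n_injections=cfg.n_injections,
            max_ratio=cfg.max_ratio,
            initial_ph=cfg.initial_ph,
            ph_noise_sigma=cfg.ph_noise_sigma,
            seed=config.seed,
        )
        curve = gen_titration(scenario)
        profile = itc_profile(curve)
        path = outdir / f"titration_{name}.csv"
        write_titration_csv(curve, path, profile)
        entry = {
            "file": str(path),
            "initial_pH": float(curve.ph[0]),
            "final_pH": float(curve.ph[-1]),
            "transition_ratio": transition_ratio(profile),
        }
        if cfg.fit_class:
            from dataclasses import replace

            from .titration import as_observed

            theoretical = replace(curve.system, groups=enumerate_groups(seq, table))
            fit = fit_apparent_pka(as_observed(curve, theoretical), cfg.fit_class)
            entry["apparent_pka"] = {
                "class": cfg.fit_class,
                "pka": fit.pka,
                "shift": fit.shift,
            }
        out[name] = entry
    return out


def _run_saxs(cfg: SaxsStage, config: RunConfig, table, outdir: Path) -> dict:
    truth = EllipticalCylinderParams(
        r_minor=cfg.r_minor,
        axis_ratio=cfg.axis_ratio,
        length=cfg.length,
        scale=cfg.scale,
        background=cfg.background,
    )
    scenario = SaxsScenario(
        params=truth, noise=cfg.noise, noise_level=cfg.noise_level, seed=config.seed
    )
    curve = gen_saxs(scenario)
    data_path = outdir / "saxs_synthetic.dat"
    write_scattering(curve, data_path, header="synthetic elliptical-cylinder curve")
    (outdir / "saxs_truth.json").write_text(json.dumps(truth.as_dict(), indent=2) + "\n")

    init = EllipticalCylinderParams(
        r_minor=truth.r_minor * cfg.init_perturbation,
        axis_ratio=max(1.0, truth.axis_ratio * cfg.init_perturbation),
        length=truth.length,
        scale=truth.scale,
        background=truth.background + 1e-4,
    )
    fit = fit_elliptical_cylinder(
        curve, init, fixed=tuple(cfg.fixed), q_range=cfg.fit_q_range
    )
    write_fit_report(fit, outdir / "saxs_fit.json")
    entry = {
        "data": str(data_path),
        "fit": fit.params.as_dict(),
        "status": fit.status,
        "reduced_chi2": fit.reduced_chi2,
    }
    if cfg.power_law_window:
        pl = power_law_fit(curve, cfg.power_law_window)
        entry["power_law"] = {"exponent": pl.exponent, "window": list(pl.q_window)}
    if cfg.guinier_window:
        gu = guinier_cross_section(curve, cfg.guinier_window)
        entry["guinier"] = {"r_sigma": gu.r_sigma, "valid": gu.valid}
    return entry


def _run_waxs(cfg: WaxsStage, config: RunConfig, table, outdir: Path) -> dict:
    scenario = WaxsScenario(noise_sigma=cfg.noise_sigma, seed=config.seed)
    pattern = gen_waxs(scenario)
    data_path = outdir / "waxs_synthetic.dat"
    write_scattering(pattern, data_path, header="synthetic wide-angle pattern (q in 1/A)")
    peaks = assign_orders(
        detect_peaks(pattern, prominence=cfg.prominence, units="invA"),
        tolerance=cfg.tolerance,
    )
    write_peak_table(peaks, outdir / "waxs_peaks.csv")
    beta = classify_beta_sheet(peaks)
    return {
        "data": str(data_path),
        "n_peaks": len(peaks),
        "d_values_A": [round(p.d, 3) for p in peaks],
        "most_intense_d_A": peaks.most_intense().d if len(peaks) else None,
        "beta_sheet": beta.is_beta_sheet,
    }
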