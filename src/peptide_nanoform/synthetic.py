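"""Seeded synthetic data with the statistical structure the analyses assume.

The study's beamline and calorimetry raw data are not deposited, so these
generators stand in for them: dilute-fibre SAXS curves from the cylinder
form factors with multiplicative or Poisson-like noise, WAXS patterns as
Gaussian Bragg peaks on a smooth polynomial background, and strong-base
titration curves from the charge-balance model with optional apparent-pKa
shifts.  Every generator is a pure function of (scenario, seed), and the
generating truth travels in curve metadata (or a side record), never in the
data columns.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .charge import enumerate_groups, default_pka_table
from .saxs_models import (
    EllipticalCylinderParams,
    ScatteringCurve,
    elliptical_cylinder_intensity,
)
from .titration import TitrationCurve, TitrationSystem, titration_curve
from .waxs import d_to_q

__all__ = [
    "REPORTED_CROSS_SECTIONS",
    "WAXS_D_SPACINGS",
    "SaxsScenario",
    "WaxsScenario",
    "TitrationScenario",
    "gen_saxs",
    "gen_waxs",
    "gen_titration",
]

#: Elliptical-cylinder parameter sets for the two assembling sequences at
#: 5 and 10 mg/mL (minor radius nm, axis ratio, length nm).
REPORTED_CROSS_SECTIONS = {
    ("KPE", 5): EllipticalCylinderParams(r_minor=4.761, axis_ratio=2.783, length=733.71),
    ("KPE", 10): EllipticalCylinderParams(r_minor=4.946, axis_ratio=2.581, length=284.80),
    ("EPK", 5): EllipticalCylinderParams(r_minor=3.099, axis_ratio=7.470, length=862.39),
    ("EPK", 10): EllipticalCylinderParams(r_minor=3.087, axis_ratio=7.650, length=465.40),
}

#: The five Bragg spacings (Å) seen in the wide-angle patterns of both
#: assembling peptides; 4.8 Å (β-sheet inter-strand) is the most prominent.
WAXS_D_SPACINGS = (5.7, 4.8, 3.7, 2.4, 1.2)


@dataclass(frozen=True)
class SaxsScenario:
    """A dilute-fibre SAXS measurement to emulate.

    The default q grid is the experimental window 0.086–7.76 nm⁻¹ with 200
    log-spaced points; default noise is 1% multiplicative Gaussian, a
    stand-in for unreported beamline uncertainties.
    """

    params: EllipticalCylinderParams
    q_min: float = 0.086
    q_max: float = 7.76
    n_q: int = 200
    log_spaced: bool = True
    noise: str = "multiplicative"  # none | multiplicative | poisson
    noise_level: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        if self.q_min <= 0 or self.q_max <= self.q_min:
            raise ValueError("require 0 < q_min < q_max")
        if self.noise not in ("none", "multiplicative", "poisson"):
            raise ValueError(f"unknown noise model {self.noise!r}")
        if self.noise_level < 0:
            raise ValueError("noise level must be non-negative")


def gen_saxs(scenario: SaxsScenario) -> ScatteringCurve:
    """Synthesize a SAXS curve; truth parameters ride in ``metadata['truth']``."""
    if scenario.log_spaced:
        q = np.geomspace(scenario.q_min, scenario.q_max, scenario.n_q)
    else:
        q = np.linspace(scenario.q_min, scenario.q_max, scenario.n_q)
    model = elliptical_cylinder_intensity(q, scenario.params)
    i = model.i.copy()
    sigma = None
    rng = np.random.default_rng(scenario.seed)
    if scenario.noise == "multiplicative" and scenario.noise_level > 0:
        sigma = scenario.noise_level * i
        i = i * (1.0 + scenario.noise_level * rng.standard_normal(i.size))
    elif scenario.noise == "poisson" and scenario.noise_level > 0:
        sigma = scenario.noise_level * np.sqrt(i)
        i = i + sigma * rng.standard_normal(i.size)
    i = np.maximum(i, 1e-12)
    return ScatteringCurve(
        q=q,
        i=i,
        sigma=sigma,
        metadata={
            "kind": "saxs",
            "noise": scenario.noise,
            "noise_level": scenario.noise_level,
            "seed": scenario.seed,
            "truth": scenario.params.as_dict(),
        },
    )


@dataclass(frozen=True)
class WaxsScenario:
    """A wide-angle pattern: Gaussian peaks at given Bragg spacings.

    ``peaks`` lists (d in Å, amplitude, Gaussian σ in Å⁻¹); the default set
    places the five observed spacings with the β-sheet 4.8 Å peak tallest.
    The grid is in Å⁻¹ (2000 linear points over 1–6 Å⁻¹ by default) and the
    background is a polynomial in q (coefficients low-order first).
    """

    peaks: tuple[tuple[float, float, float], ...] = (
        (5.7, 0.60, 0.02),
        (4.8, 1.00, 0.02),
        (3.7, 0.50, 0.02),
        (2.4, 0.35, 0.03),
        (1.2, 0.20, 0.04),
    )
    background: tuple[float, ...] = (0.30, -0.03)
    q_min: float = 1.0
    q_max: float = 6.0
    n_q: int = 2000
    noise_sigma: float = 0.002
    seed: int = 0

    def __post_init__(self) -> None:
        ds = [d for d, _, _ in self.peaks]
        if any(d <= 0 for d in ds):
            raise ValueError("d spacings must be positive")


def gen_waxs(scenario: WaxsScenario) -> ScatteringCurve:
    """Sum of Gaussians at q = 2π/d plus polynomial background plus noise.

    Peaks whose centers fall within 2σ of each other are flagged as
    overlapping in the metadata (they would merge under detection).
    """
    q = np.linspace(scenario.q_min, scenario.q_max, scenario.n_q)
    i = np.polynomial.polynomial.polyval(q, scenario.background)
    centers = []
    for d, amp, width in scenario.peaks:
        c = d_to_q(d, "invA")
        centers.append((c, width))
        i = i + amp * np.exp(-0.5 * ((q - c) / width) ** 2)
    overlaps = [
        (a, b)
        for k, (a, wa) in enumerate(centers)
        for b, wb in centers[k + 1 :]
        if abs(a - b) < 2.0 * (wa + wb)
    ]
    rng = np.random.default_rng(scenario.seed)
    if scenario.noise_sigma > 0:
        i = i + scenario.noise_sigma * rng.standard_normal(q.size)
    meta = {
        "kind": "waxs",
        "units": "invA",
        "seed": scenario.seed,
        "truth": {"peaks": list(scenario.peaks), "background": list(scenario.background)},
    }
    if overlaps:
        meta["overlapping_peaks"] = overlaps
    return ScatteringCurve(q=q, i=np.maximum(i, 0.0), metadata=meta)


@dataclass(frozen=True)
class TitrationScenario:
    """A strong-base titration measurement to emulate.

    Defaults mirror the calorimetric protocol: 1 mg/mL peptide in a 500 µL
    cell titrated with 0.025 M NaOH in 1.6 µL injections.  ``pka_shifts``
    applies apparent-pKa offsets (label → ΔpKa) to the theoretical table
    before simulating; ``initial_ph`` fixes the as-dissolved acidity via
    inferred chloride equivalents when set.
    """

    sequence: str = "FEFKFEFK"
    conc_mg_ml: float = 1.0
    pka_shifts: dict = field(default_factory=dict)
    titrant_molarity: float = 0.025
    n_injections: int = 60
    injection_volume_ul: float | None = None
    max_ratio: float = 6.0
    initial_ph: float | None = 2.6
    ph_noise_sigma: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.conc_mg_ml <= 0:
            raise ValueError("concentration must be positive")
        if self.n_injections < 1:
            raise ValueError("injection schedule must be non-empty")


def gen_titration(scenario: TitrationScenario) -> TitrationCurve:
    """Forward-model a titration; truth pKa values ride on ``system.groups``.

    Optional Gaussian pH noise (σ = ``ph_noise_sigma``) is added to the
    solved pH values; the returned curve keeps the *noisy* pH but the exact
    protonation bookkeeping of the noiseless forward model.
    """
    from .titration import infer_chloride_equivalents

    groups = enumerate_groups(scenario.sequence, default_pka_table())
    for label, shift in scenario.pka_shifts.items():
        groups = groups.with_pka(label, groups.group(label).pka + shift)
    system = TitrationSystem.from_mg_per_ml(
        groups,
        scenario.conc_mg_ml,
        sequence=scenario.sequence,
        titrant_conc=scenario.titrant_molarity,
        injection_volume=(
            scenario.injection_volume_ul * 1e-6
            if scenario.injection_volume_ul is not None
            else None
        ),
    )
    if scenario.initial_ph is not None:
        x = infer_chloride_equivalents(
            groups, system.peptide_conc, scenario.initial_ph
        )
        system = replace(system, chloride_equivalents=x)
    ratios = np.linspace(0.0, scenario.max_ratio, scenario.n_injections + 1)
    curve = titration_curve(system, ratios)
    if scenario.ph_noise_sigma > 0:
        rng = np.random.default_rng(scenario.seed)
        noisy = curve.ph + scenario.ph_noise_sigma * rng.standard_normal(curve.ph.size)
        curve = TitrationCurve(
            base_ratio=curve.base_ratio,
            ph=noisy,
            protonation=curve.protonation,
            protons_released=curve.protons_released,
            system=curve.system,
        )
    return curve
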