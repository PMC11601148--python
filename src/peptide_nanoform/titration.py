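"""Strong-base titration of peptide solutions by charge balance.

Peptides supplied as HCl salts dissolve to acidic solutions; adding NaOH
deprotonates their ionizable groups class by class.  The solution pH at any
point of the titration is the unique root of the charge-balance residual

.. math::

    f(\\mathrm{pH}) = [\\mathrm{Na}^+] + C_p Z_+(\\mathrm{pH}) + [\\mathrm{H}^+]
                    - [\\mathrm{Cl}^-] - C_p Z_-(\\mathrm{pH}) - [\\mathrm{OH}^-],

with :math:`Z_+` the protonated-base and :math:`Z_-` the deprotonated-acid
sums per peptide, :math:`[\\mathrm{H}^+] = 10^{-\\mathrm{pH}}` and
:math:`[\\mathrm{OH}^-] = 10^{\\mathrm{pH}-pK_w}` (pKw = 14, 25 °C).  f is
strictly decreasing in pH, so bisection on [0, 14] is exact and robust.

Calorimetric (ITC-style) energy-shift profiles are modelled as heat
released per injection proportional to the number of deprotonation events
in that injection, one enthalpy coefficient per group class, plus a
constant dilution heat.  This reproduces the *position* of the transitions
on the M_NaOH/M_pep axis, which is the quantity read off such diagrams.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Mapping

import numpy as np

from .charge import IonizableGroupSet

__all__ = [
    "AVERAGE_RESIDUE_MASS",
    "peptide_molar_mass",
    "TitrationSystem",
    "TitrationCurve",
    "ITCProfile",
    "ApparentPkaFit",
    "solve_ph",
    "infer_chloride_equivalents",
    "titration_curve",
    "equivalents_to_deprotonate",
    "itc_profile",
    "transition_ratio",
    "as_observed",
    "fit_apparent_pka",
]

PKW = 14.0

#: Average (not monoisotopic) residue masses in Da; add one water per chain.
AVERAGE_RESIDUE_MASS = {
    "A": 71.0788, "R": 156.1875, "N": 114.1038, "D": 115.0886, "C": 103.1388,
    "E": 129.1155, "Q": 128.1307, "G": 57.0519, "H": 137.1411, "I": 113.1594,
    "L": 113.1594, "K": 128.1741, "M": 131.1926, "F": 147.1766, "P": 97.1167,
    "S": 87.0782, "T": 101.1051, "W": 186.2132, "Y": 163.1760, "V": 99.1326,
}
WATER_MASS = 18.0153
HCL_MASS = 36.461


def peptide_molar_mass(sequence: str, hcl_equivalents: float = 0.0) -> float:
    """Average molar mass (g/mol) of a peptide chain, optionally as HCl salt."""
    return (
        sum(AVERAGE_RESIDUE_MASS[r] for r in sequence)
        + WATER_MASS
        + hcl_equivalents * HCL_MASS
    )


@dataclass(frozen=True)
class TitrationSystem:
    """A peptide solution being titrated with strong base.

    Parameters
    ----------
    groups : ionizable inventory of the peptide
    peptide_conc : peptide molarity, mol/L
    chloride_equivalents : Cl⁻ counter-ions per peptide (HCl-salt excess acid)
    titrant_conc : NaOH molarity of the titrant, mol/L
    injection_volume : volume per injection in L; when set, titrant dilution
        of the cell contents is applied
    cell_volume : initial cell volume in L
    """

    groups: IonizableGroupSet
    peptide_conc: float
    chloride_equivalents: float = 0.0
    titrant_conc: float = 0.025
    injection_volume: float | None = None
    cell_volume: float = 500e-6

    def __post_init__(self) -> None:
        if self.peptide_conc <= 0:
            raise ValueError("peptide concentration must be positive")
        if self.chloride_equivalents < 0:
            raise ValueError("chloride equivalents must be non-negative")
        if self.titrant_conc <= 0:
            raise ValueError("titrant concentration must be positive")

    @classmethod
    def from_mg_per_ml(
        cls,
        groups: IonizableGroupSet,
        conc_mg_ml: float,
        sequence: str | None = None,
        **kwargs,
    ) -> "TitrationSystem":
        """Build a system from a mass concentration.

        Molarity uses the free-peptide molar mass (HCl counter-ion mass
        excluded by default; pass ``hcl_equivalents`` via
        :func:`peptide_molar_mass` yourself to include it).
        """
        seq = sequence or (groups.peptide.sequence if groups.peptide else None)
        if seq is None:
            raise ValueError("sequence required to convert mg/mL to molarity")
        molar = conc_mg_ml / peptide_molar_mass(seq)  # mg/mL ≡ g/L
        return cls(groups=groups, peptide_conc=molar, **kwargs)


def _bound_protons_per_peptide(groups: IonizableGroupSet, ph) -> float:
    return sum(g.count * g.protonation_fraction(ph) for g in groups)


def _charge_balance_residual(
    groups: IonizableGroupSet, ph, c_pep: float, c_na: float, c_cl: float
) -> float:
    z_plus = sum(g.count * g.protonation_fraction(ph) for g in groups.bases)
    z_minus = sum(g.count * (1.0 - g.protonation_fraction(ph)) for g in groups.acids)
    return c_na + c_pep * z_plus + 10.0 ** (-ph) - c_cl - c_pep * z_minus - 10.0 ** (ph - PKW)


def solve_ph(
    system: TitrationSystem,
    base_added: float = 0.0,
    *,
    _conc_override: tuple[float, float, float] | None = None,
    tol: float = 1e-8,
) -> float:
    """Equilibrium pH after adding ``base_added`` mol/L of strong base.

    Bisection on pH ∈ [0, 14] to ``tol``; raises if the charge-balance
    residual has no sign change on that interval (ill-posed system).
    """
    if base_added < 0:
        raise ValueError("base_added must be non-negative")
    if _conc_override is not None:
        c_pep, c_na, c_cl = _conc_override
    else:
        c_pep = system.peptide_conc
        c_na = base_added
        c_cl = system.chloride_equivalents * c_pep
    lo, hi = 0.0, PKW
    f_lo = _charge_balance_residual(system.groups, lo, c_pep, c_na, c_cl)
    f_hi = _charge_balance_residual(system.groups, hi, c_pep, c_na, c_cl)
    if f_lo < 0 or f_hi > 0:
        raise ValueError("charge balance has no root on pH in [0, 14]")
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if _charge_balance_residual(system.groups, mid, c_pep, c_na, c_cl) > 0:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def infer_chloride_equivalents(
    groups: IonizableGroupSet,
    peptide_conc: float,
    initial_ph: float,
    tol: float = 1e-4,
) -> float:
    """Cl⁻ equivalents per peptide that reproduce the as-dissolved pH.

    HCl-salt peptides dissolve acidic; the salt stoichiometry is rarely
    stated, so the excess-acid content x is inferred: bisection on
    x ∈ [0, protonatable sites + 10] such that the zero-base equilibrium pH
    equals ``initial_ph`` within ``tol``.
    """
    if not (0 < initial_ph < 7):
        raise ValueError("initial pH must be acidic (0 < pH < 7)")

    def ph_at(x: float) -> float:
        sys_x = TitrationSystem(
            groups=groups, peptide_conc=peptide_conc, chloride_equivalents=x
        )
        return solve_ph(sys_x, 0.0)

    lo, hi = 0.0, groups.total_base_count + groups.total_acid_count + 10.0
    if ph_at(lo) < initial_ph - tol:
        raise ValueError(
            f"pH {initial_ph} unreachable: solution is already below it with no HCl"
        )
    if ph_at(hi) > initial_ph + tol:
        raise ValueError(f"pH {initial_ph} unreachable for any x in [0, {hi}]")
    # pH is decreasing in x
    while True:
        mid = 0.5 * (lo + hi)
        ph_mid = ph_at(mid)
        if abs(ph_mid - initial_ph) <= tol or hi - lo < 1e-12:
            return mid
        if ph_mid > initial_ph:
            lo = mid
        else:
            hi = mid


@dataclass(frozen=True)
class TitrationCurve:
    """pH and protonation state along a NaOH titration.

    ``base_ratio`` is M_NaOH/M_pep; ``protonation`` maps each group label to
    its mean protonated fraction per point; ``protons_released`` is the
    cumulative number of protons lost per peptide since the start.
    """

    base_ratio: np.ndarray
    ph: np.ndarray
    protonation: Mapping[str, np.ndarray]
    protons_released: np.ndarray
    system: TitrationSystem

    def half_deprotonation_ratio(self, residue: str) -> float:
        """Base ratio at which the given class crosses 50% protonation."""
        frac = np.asarray(self.protonation[residue])
        below = np.nonzero(frac <= 0.5)[0]
        if frac[0] <= 0.5 or below.size == 0:
            raise ValueError(f"class {residue!r} does not cross 0.5 on this grid")
        j = below[0]
        r0, r1 = self.base_ratio[j - 1], self.base_ratio[j]
        f0, f1 = frac[j - 1], frac[j]
        return r0 + (0.5 - f0) * (r1 - r0) / (f1 - f0)


def titration_curve(system: TitrationSystem, ratio_grid) -> TitrationCurve:
    """Simulate a titration over an ascending M_NaOH/M_pep grid.

    Titrant-volume dilution is applied when ``system.injection_volume`` is
    set (moles of base fix the delivered volume through the titrant
    molarity); otherwise concentrations are held at their initial values.
    """
    ratios = np.asarray(ratio_grid, dtype=float)
    if ratios.size == 0:
        raise ValueError("ratio grid is empty")
    if ratios[0] < 0 or (ratios.size > 1 and not np.all(np.diff(ratios) > 0)):
        raise ValueError("ratio grid must ascend from 0")

    n_pep = system.peptide_conc * system.cell_volume  # moles in the cell
    dilute = system.injection_volume is not None
    ph_out = np.empty_like(ratios)
    for i, r in enumerate(ratios):
        n_na = r * n_pep
        v = system.cell_volume + (n_na / system.titrant_conc if dilute else 0.0)
        c_pep = n_pep / v
        c_na = n_na / v
        c_cl = system.chloride_equivalents * c_pep
        ph_out[i] = solve_ph(system, _conc_override=(c_pep, c_na, c_cl))

    protonation = {
        g.residue: g.protonation_fraction(ph_out) for g in system.groups
    }
    bound = sum(
        g.count * protonation[g.residue] for g in system.groups
    )
    released = bound[0] - bound
    return TitrationCurve(
        base_ratio=ratios,
        ph=ph_out,
        protonation=protonation,
        protons_released=released,
        system=system,
    )


def equivalents_to_deprotonate(
    groups: IonizableGroupSet, initial_state_ph: float, target_class: str
) -> int:
    """Stoichiometric NaOH equivalents to fully deprotonate one group class.

    The initial protonation state is rounded: a group holds its proton iff
    the starting pH is below its pKa.  Groups already deprotonated at the
    start contribute nothing.  ``target_class`` is a group label (a
    side-chain one-letter code or a terminus tag).
    """
    matched = [g for g in groups if g.residue == target_class]
    if not matched:
        raise KeyError(f"unknown group class {target_class!r}")
    return sum(g.count for g in matched if initial_state_ph < g.pka)


@dataclass(frozen=True)
class ITCProfile:
    """Heat per injection versus the NaOH:peptide molar ratio.

    ``heat`` has one entry per injection (interval of the titration grid)
    and is reported at the post-injection ratio.
    """

    base_ratio: np.ndarray
    heat: np.ndarray
    enthalpies: Mapping[str, float]
    dilution_constant: float

    @property
    def integrated_heat(self) -> float:
        return float(np.sum(self.heat))


def itc_profile(
    curve: TitrationCurve,
    enthalpies: Mapping[str, float] | None = None,
    dilution_constant: float = 0.0,
) -> ITCProfile:
    """Energy-shift profile from a titration curve.

    Heat of injection i = Σ_class ΔH_class × (protons lost by that class per
    peptide during the injection) + dilution constant.  ΔH defaults to
    1 kcal/mol (relative units) for every class, since only relative energy
    shifts are interpreted.
    """
    if curve.base_ratio.size < 2:
        raise ValueError("titration grid too coarse: need at least two points")
    if enthalpies is None:
        enthalpies = {g.residue: 1.0 for g in curve.system.groups}
    heat = np.full(curve.base_ratio.size - 1, float(dilution_constant))
    for g in curve.system.groups:
        dh = float(enthalpies.get(g.residue, 0.0))
        if dh == 0.0:
            continue
        bound = g.count * np.asarray(curve.protonation[g.residue])
        heat += dh * (-np.diff(bound))
    return ITCProfile(
        base_ratio=curve.base_ratio[1:],
        heat=heat,
        enthalpies=dict(enthalpies),
        dilution_constant=float(dilution_constant),
    )


def transition_ratio(profile: ITCProfile) -> float:
    """Molar ratio of the sharpest change in the heat profile.

    Defined as the argmax of |d heat / d ratio| between consecutive
    injections; ties break toward the lower ratio.
    """
    if profile.base_ratio.size < 2:
        raise ValueError("profile too short for a derivative")
    deriv = np.abs(np.diff(profile.heat) / np.diff(profile.base_ratio))
    i = int(np.argmax(deriv))  # argmax returns the first (lowest-ratio) tie
    return float(0.5 * (profile.base_ratio[i] + profile.base_ratio[i + 1]))


def as_observed(curve: TitrationCurve, system: TitrationSystem) -> TitrationCurve:
    """Relabel a curve with the (theoretical) system used for analysis.

    Synthetic curves carry their generating system; before fitting an
    apparent pKa the curve is analysed against the theoretical table, so
    the reported shift is apparent-minus-theoretical.
    """
    return TitrationCurve(
        base_ratio=curve.base_ratio,
        ph=curve.ph,
        protonation=curve.protonation,
        protons_released=curve.protons_released,
        system=system,
    )


@dataclass(frozen=True)
class ApparentPkaFit:
    """Apparent pKa of one class fitted to an observed titration curve."""

    residue: str
    pka: float
    theoretical_pka: float
    residual_rms: float

    @property
    def shift(self) -> float:
        return self.pka - self.theoretical_pka


def fit_apparent_pka(observed: TitrationCurve, which_class: str) -> ApparentPkaFit:
    """Least-squares fit of a single overridden pKa to an observed curve.

    The self-assembled environment can displace a side-chain pKa from its
    theoretical value; this refits only the pKa of ``which_class``,
    re-simulating the titration at each trial value and minimizing the
    pH residuals over the whole curve.
    """
    from scipy.optimize import minimize_scalar

    theo = observed.system.groups.group(which_class).pka
    ph_lo, ph_hi = float(np.min(observed.ph)), float(np.max(observed.ph))
    if not (ph_lo - 2.0 <= theo <= ph_hi + 2.0):
        raise ValueError(
            f"transition of {which_class!r} (pKa ~{theo}) lies outside the observed pH range"
        )

    def cost(pka: float) -> float:
        shifted = replace(
            observed.system, groups=observed.system.groups.with_pka(which_class, pka)
        )
        model = titration_curve(shifted, observed.base_ratio)
        return float(np.sum((model.ph - observed.ph) ** 2))

    res = minimize_scalar(
        cost, bounds=(ph_lo - 2.0, ph_hi + 2.0), method="bounded",
        options={"xatol": 1e-6},
    )
    rms = float(np.sqrt(res.fun / observed.ph.size))
    return ApparentPkaFit(
        residue=which_class, pka=float(res.x), theoretical_pka=theo, residual_rms=rms
    )
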