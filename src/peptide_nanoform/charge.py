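"""Net charge of short peptides as a function of pH.

A peptide's ionizable inventory consists of the two termini plus the acidic
and basic side chains.  Each group of class *g* with conjugate-acid pKa
:math:`pK_g` contributes its mean protonation fraction

.. math:: f_g(\\mathrm{pH}) = \\frac{1}{1 + 10^{\\mathrm{pH} - pK_g}},

so the net charge in elementary-charge units is the multi-site
Henderson--Hasselbalch sum

.. math::

    Z(\\mathrm{pH}) = \\sum_i \\frac{N_i}{1 + 10^{\\mathrm{pH} - pK_i}}
                    - \\sum_j \\frac{N_j}{1 + 10^{pK_j - \\mathrm{pH}}},

with :math:`N_i` counting basic groups (amines, charged when protonated)
and :math:`N_j` acidic groups (carboxylates, charged when deprotonated).
No activity corrections are applied (ideal-dilute assumption).
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from typing import Iterable, Mapping

import numpy as np
import yaml

__all__ = [
    "CANONICAL_RESIDUES",
    "IONIZABLE_SIDE_CHAINS",
    "Peptide",
    "IonizableGroup",
    "IonizableGroupSet",
    "ChargeCurve",
    "load_pka_table",
    "default_pka_table",
    "enumerate_groups",
    "net_charge",
    "charge_curve",
    "isoelectric_point",
]

CANONICAL_RESIDUES = frozenset("ACDEFGHIKLMNPQRSTVWY")

#: Side chains that titrate in the ordinary pH range.  A sequence containing
#: one of these must have a pKa entry for it; every other canonical residue
#: is treated as non-ionizable.
IONIZABLE_SIDE_CHAINS = frozenset("DECYHKR")

#: Side chains that protonate to a positive charge (conjugate acid charged).
_BASIC_SIDE_CHAINS = frozenset("KRH")

N_TERMINUS = "N-terminus"
C_TERMINUS = "C-terminus"
SIDE_CHAIN = "side-chain"


@dataclass(frozen=True)
class Peptide:
    """A named one-letter peptide sequence."""

    name: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError("peptide sequence must be non-empty")
        bad = set(self.sequence) - CANONICAL_RESIDUES
        if bad:
            raise ValueError(
                f"non-canonical residue(s) {sorted(bad)} in sequence {self.sequence!r}"
            )

    @classmethod
    def from_sequence(cls, sequence: str, name: str | None = None) -> "Peptide":
        return cls(name=name or sequence, sequence=sequence.upper())


@dataclass(frozen=True)
class IonizableGroup:
    """One titratable class: a terminus or a side-chain residue type.

    ``sign`` is +1 for bases (charged while protonated) and -1 for acids
    (charged once deprotonated); ``count`` is the multiplicity N of the
    class in the sequence.
    """

    kind: str
    residue: str
    pka: float
    sign: int
    count: int

    def __post_init__(self) -> None:
        if self.sign not in (+1, -1):
            raise ValueError("sign must be +1 or -1")
        if self.count < 0:
            raise ValueError("count must be non-negative")
        if not np.isfinite(self.pka):
            raise ValueError("pKa must be finite")

    def protonation_fraction(self, ph):
        """Mean fraction of this class carrying its proton at ``ph``."""
        return 1.0 / (1.0 + 10.0 ** (np.asarray(ph, dtype=float) - self.pka))


@dataclass(frozen=True)
class IonizableGroupSet:
    """The full ionizable inventory of one peptide."""

    groups: tuple[IonizableGroup, ...]
    peptide: Peptide | None = None

    def __iter__(self):
        return iter(self.groups)

    def __len__(self) -> int:
        return len(self.groups)

    @property
    def bases(self) -> tuple[IonizableGroup, ...]:
        return tuple(g for g in self.groups if g.sign > 0)

    @property
    def acids(self) -> tuple[IonizableGroup, ...]:
        return tuple(g for g in self.groups if g.sign < 0)

    @property
    def total_base_count(self) -> int:
        return sum(g.count for g in self.bases)

    @property
    def total_acid_count(self) -> int:
        return sum(g.count for g in self.acids)

    def with_pka(self, residue: str, pka: float) -> "IonizableGroupSet":
        """Return a copy with the pKa of every group labelled ``residue`` replaced.

        Used to apply apparent-pKa shifts (the self-assembled environment
        displaces side-chain pKa values) without mutating the table.
        """
        hit = False
        out = []
        for g in self.groups:
            if g.residue == residue:
                out.append(IonizableGroup(g.kind, g.residue, float(pka), g.sign, g.count))
                hit = True
            else:
                out.append(g)
        if not hit:
            raise KeyError(f"no group with residue label {residue!r}")
        return IonizableGroupSet(tuple(out), self.peptide)

    def group(self, residue: str) -> IonizableGroup:
        for g in self.groups:
            if g.residue == residue:
                return g
        raise KeyError(f"no group with residue label {residue!r}")


@dataclass(frozen=True)
class ChargeCurve:
    """Net charge evaluated on an ascending pH grid."""

    ph: np.ndarray
    z: np.ndarray

    def __post_init__(self) -> None:
        if self.ph.size != self.z.size:
            raise ValueError("ph and z must have equal length")


def load_pka_table(path) -> dict:
    """Read a pKa table from a YAML/JSON key-value file."""
    with open(path) as fh:
        table = yaml.safe_load(fh)
    _validate_table(table)
    return table


def default_pka_table() -> dict:
    """The built-in pKa table (C-term 2.18, Glu 4.25, N-term 9.13/8.95, Lys 10.53)."""
    text = resources.files("peptide_nanoform.data").joinpath("pka_default.yaml").read_text()
    table = yaml.safe_load(text)
    _validate_table(table)
    return table


def _validate_table(table: Mapping) -> None:
    for key in ("c_terminus", "n_terminus", "side_chains"):
        if key not in table:
            raise ValueError(f"pKa table missing required key {key!r}")


def enumerate_groups(
    peptide: Peptide | str, pka_table: Mapping | None = None
) -> IonizableGroupSet:
    """Enumerate the ionizable groups of ``peptide`` under ``pka_table``.

    Exactly one N-terminus and one C-terminus entry are produced, plus one
    entry per ionizable side-chain type with its count in the sequence.
    The N-terminal pKa is chosen by the leading residue when the table's
    ``n_terminus_by_residue`` mapping distinguishes it.

    Raises ``KeyError`` naming the residue if the sequence contains an
    ionizable side chain with no table entry.
    """
    if isinstance(peptide, str):
        peptide = Peptide.from_sequence(peptide)
    table = dict(pka_table) if pka_table is not None else default_pka_table()
    _validate_table(table)

    seq = peptide.sequence
    by_res = table.get("n_terminus_by_residue") or {}
    nterm_pka = float(by_res.get(seq[0], table["n_terminus"]))

    groups = [
        IonizableGroup(N_TERMINUS, N_TERMINUS, nterm_pka, +1, 1),
        IonizableGroup(C_TERMINUS, C_TERMINUS, float(table["c_terminus"]), -1, 1),
    ]
    side = table["side_chains"] or {}
    for res in sorted(set(seq)):
        n = seq.count(res)
        if res in side:
            sign = +1 if res in _BASIC_SIDE_CHAINS else -1
            groups.append(IonizableGroup(SIDE_CHAIN, res, float(side[res]), sign, n))
        elif res in IONIZABLE_SIDE_CHAINS:
            raise KeyError(
                f"residue {res!r} is ionizable but has no pKa entry in the table"
            )
    return IonizableGroupSet(tuple(groups), peptide)


def net_charge(groups: IonizableGroupSet | Iterable[IonizableGroup], ph):
    """Net charge (elementary-charge units) at ``ph``.

    Accepts a scalar or array pH; broadcasts accordingly.
    """
    ph = np.asarray(ph, dtype=float)
    if not np.all(np.isfinite(ph)):
        raise ValueError("pH must be finite")
    z = np.zeros_like(ph, dtype=float)
    for g in groups:
        frac = g.protonation_fraction(ph)
        if g.sign > 0:
            z += g.count * frac          # protonated base carries +1
        else:
            z -= g.count * (1.0 - frac)  # deprotonated acid carries -1
    return z if z.ndim else float(z)


def charge_curve(groups: IonizableGroupSet, ph_grid) -> ChargeCurve:
    """Pointwise :func:`net_charge` over an ascending pH grid."""
    ph = np.asarray(ph_grid, dtype=float)
    if ph.size == 0:
        raise ValueError("pH grid is empty")
    if ph.size > 1 and not np.all(np.diff(ph) > 0):
        raise ValueError("pH grid must be strictly ascending")
    return ChargeCurve(ph=ph, z=np.atleast_1d(net_charge(groups, ph)))


def isoelectric_point(
    groups: IonizableGroupSet, lo: float = -5.0, hi: float = 19.0, tol: float = 1e-6
) -> float:
    """pH at which the net charge crosses zero.

    The crossing is unique because Z(pH) is strictly decreasing; located by
    bisection to ``tol``.  Raises ``ValueError`` for all-acid or all-base
    sets, which never cross zero.
    """
    if not groups.bases or not groups.acids:
        raise ValueError("no zero crossing: need at least one acid and one base")
    f_lo, f_hi = net_charge(groups, lo), net_charge(groups, hi)
    if f_lo <= 0 or f_hi >= 0:
        raise ValueError("no zero crossing within bracket")
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if net_charge(groups, mid) > 0:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)
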