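"""Physicochemical features computed from sequence alone.

Implements the ProtParam-class descriptors used in expression-correlation
analysis: length, average molecular weight, residue composition, charged
residue counts and densities, Henderson–Hasselbalch net charge, isoelectric
point (bisection on the titration curve) and GRAVY (grand average of
hydropathy, Kyte–Doolittle scale).

Conventions
-----------
* Average (not monoisotopic) residue masses, Expasy values; one water is
  added per chain.
* The pKa set defaults to the EMBOSS values; ProtParam itself uses the
  Bjellqvist set — both are expressible through :class:`PhyschemConfig`.
* Histidine is titrated but excluded from the "charged residue" counts
  (``n_positive = K + R``), the convention at pH 7.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

from .dataset import STANDARD_RESIDUES, AminoAcidSequence

__all__ = [
    "KYTE_DOOLITTLE",
    "AVERAGE_RESIDUE_MASS",
    "EMBOSS_PKA",
    "WATER_MASS",
    "PhyschemConfig",
    "PhyschemFeatures",
    "composition",
    "molecular_weight",
    "net_charge",
    "isoelectric_point",
    "gravy",
    "physchem_features",
]

#: Kyte & Doolittle hydropathy values.
KYTE_DOOLITTLE: dict[str, float] = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5,
    "Q": -3.5, "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5,
    "L": 3.8, "K": -3.9, "M": 1.9, "F": 2.8, "P": -1.6,
    "S": -0.8, "T": -0.7, "W": -0.9, "Y": -1.3, "V": 4.2,
}

#: Average residue (i.e. dehydrated) masses in Da, Expasy convention.
AVERAGE_RESIDUE_MASS: dict[str, float] = {
    "A": 71.0788, "R": 156.1875, "N": 114.1038, "D": 115.0886,
    "C": 103.1388, "E": 129.1155, "Q": 128.1307, "G": 57.0519,
    "H": 137.1411, "I": 113.1594, "L": 113.1594, "K": 128.1741,
    "M": 131.1926, "F": 147.1766, "P": 97.1167, "S": 87.0782,
    "T": 101.1051, "W": 186.2132, "Y": 163.1760, "V": 99.1326,
}

WATER_MASS = 18.0153

#: EMBOSS pKa set: termini plus ionizable side chains.
EMBOSS_PKA: dict[str, float] = {
    "Nterm": 8.6, "Cterm": 3.6,
    "C": 8.5, "D": 3.9, "E": 4.1, "H": 6.5,
    "K": 10.8, "R": 12.5, "Y": 10.1,
}

_BASIC_GROUPS = ("Nterm", "H", "K", "R")
_ACIDIC_GROUPS = ("Cterm", "C", "D", "E", "Y")


@dataclass(frozen=True)
class PhyschemConfig:
    """Tables and settings behind the physicochemical features.

    All 20 residues must be covered by the mass and hydropathy tables; pKa
    values must lie inside (0, 14).  ``charge_pH`` is the pH at which the
    exported net-charge feature is evaluated.
    """

    pka_table: Mapping[str, float] = field(default_factory=lambda: dict(EMBOSS_PKA))
    mass_table: Mapping[str, float] = field(
        default_factory=lambda: dict(AVERAGE_RESIDUE_MASS)
    )
    hydropathy_table: Mapping[str, float] = field(
        default_factory=lambda: dict(KYTE_DOOLITTLE)
    )
    charge_pH: float = 7.0

    def __post_init__(self) -> None:
        for table, name in (
            (self.mass_table, "mass_table"),
            (self.hydropathy_table, "hydropathy_table"),
        ):
            missing = STANDARD_RESIDUES - set(table)
            if missing:
                raise ValueError(f"{name} missing residues {sorted(missing)}")
        for group, pka in self.pka_table.items():
            if not (0.0 < pka < 14.0):
                raise ValueError(f"pKa for {group} out of (0, 14): {pka}")


DEFAULT_PHYSCHEM = PhyschemConfig()


@dataclass(frozen=True)
class PhyschemFeatures:
    """Bundle of sequence-level physicochemical descriptors."""

    length: int
    molecular_weight: float
    composition: dict[str, float]
    n_positive: int
    n_negative: int
    net_charge: float
    pI: float
    gravy: float

    @property
    def positive_density(self) -> float:
        return self.n_positive / self.length

    @property
    def negative_density(self) -> float:
        return self.n_negative / self.length

    @property
    def charge_density(self) -> float:
        return self.net_charge / self.length


def composition(seq: AminoAcidSequence) -> dict[str, float]:
    """Fraction of each of the 20 residue types (sums to 1)."""
    n = len(seq)
    counts = {aa: 0 for aa in sorted(STANDARD_RESIDUES)}
    for ch in seq.residues:
        counts[ch] += 1
    return {aa: c / n for aa, c in counts.items()}


def molecular_weight(
    seq: AminoAcidSequence, cfg: PhyschemConfig = DEFAULT_PHYSCHEM
) -> float:
    """Average molecular weight in Da (residue masses plus one water)."""
    return sum(cfg.mass_table[ch] for ch in seq.residues) + WATER_MASS


def _ionizable_counts(seq: AminoAcidSequence) -> dict[str, int]:
    counts = {"Nterm": 1, "Cterm": 1}
    for group in ("C", "D", "E", "H", "K", "R", "Y"):
        counts[group] = 0
    for ch in seq.residues:
        if ch in counts:
            counts[ch] += 1
    return counts


def net_charge(
    seq: AminoAcidSequence,
    pH: float | None = None,
    cfg: PhyschemConfig = DEFAULT_PHYSCHEM,
) -> float:
    """Henderson–Hasselbalch net charge at *pH* in elementary charges.

    Basic groups contribute ``+1/(1 + 10^(pH - pKa))``, acidic groups
    ``-1/(1 + 10^(pKa - pH))``; both termini are included.  Strictly
    decreasing in pH.
    """
    if pH is None:
        pH = cfg.charge_pH
    if not (0.0 < pH < 14.0):
        raise ValueError(f"pH out of (0, 14): {pH}")
    counts = _ionizable_counts(seq)
    charge = 0.0
    for group in _BASIC_GROUPS:
        pka = cfg.pka_table.get(group)
        if pka is not None and counts.get(group, 0):
            charge += counts[group] / (1.0 + 10.0 ** (pH - pka))
    for group in _ACIDIC_GROUPS:
        pka = cfg.pka_table.get(group)
        if pka is not None and counts.get(group, 0):
            charge -= counts[group] / (1.0 + 10.0 ** (pka - pH))
    return charge


def isoelectric_point(
    seq: AminoAcidSequence,
    cfg: PhyschemConfig = DEFAULT_PHYSCHEM,
    tol: float = 1e-4,
    max_iter: int = 200,
) -> float:
    """pH at which the net charge vanishes, by bisection on [0, 14].

    The titration curve is strictly decreasing so the root is unique;
    iteration stops once ``|net_charge| < tol``.
    """
    lo, hi = 0.0, 14.0
    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        q = net_charge(seq, mid, cfg)
        if abs(q) < tol:
            return mid
        if q > 0:
            lo = mid
        else:
            hi = mid
    raise ArithmeticError(
        f"pI bisection did not converge for {seq.id!r}"
    )  # pragma: no cover - unreachable for monotone curves


def gravy(seq: AminoAcidSequence, cfg: PhyschemConfig = DEFAULT_PHYSCHEM) -> float:
    """Grand average of hydropathy: mean Kyte–Doolittle value per residue."""
    table = cfg.hydropathy_table
    return math.fsum(table[ch] for ch in seq.residues) / len(seq)


def physchem_features(
    seq: AminoAcidSequence, cfg: PhyschemConfig = DEFAULT_PHYSCHEM
) -> PhyschemFeatures:
    """All physicochemical descriptors for one sequence."""
    residues = seq.residues
    return PhyschemFeatures(
        length=len(seq),
        molecular_weight=molecular_weight(seq, cfg),
        composition=composition(seq),
        n_positive=sum(residues.count(aa) for aa in "KR"),
        n_negative=sum(residues.count(aa) for aa in "DE"),
        net_charge=net_charge(seq, cfg.charge_pH, cfg),
        pI=isoelectric_point(seq, cfg),
        gravy=gravy(seq, cfg),
    )
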