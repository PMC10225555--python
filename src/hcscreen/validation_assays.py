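"""Downstream validation calculators.

Flow-cytometry MFI and top-percentile gating, double-delta-Ct relative
quantification, and molarity/mass-concentration conversion from a molecular
formula.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass

import numpy as np

__all__ = [
    "RQResult",
    "CompoundSpec",
    "mfi",
    "gate_top_percent",
    "rq_ddct",
    "parse_formula",
    "molar_mass",
    "micromolar_to_ug_per_ml",
    "ATOMIC_MASSES",
]

# Conventional standard atomic weights (IUPAC 2021 abridged values), g/mol.
ATOMIC_MASSES: dict[str, float] = {
    "H": 1.008, "He": 4.0026, "Li": 6.94, "Be": 9.0122, "B": 10.81,
    "C": 12.011, "N": 14.007, "O": 15.999, "F": 18.998, "Ne": 20.180,
    "Na": 22.990, "Mg": 24.305, "Al": 26.982, "Si": 28.085, "P": 30.974,
    "S": 32.06, "Cl": 35.45, "Ar": 39.95, "K": 39.098, "Ca": 40.078,
    "Sc": 44.956, "Ti": 47.867, "V": 50.942, "Cr": 51.996, "Mn": 54.938,
    "Fe": 55.845, "Co": 58.933, "Ni": 58.693, "Cu": 63.546, "Zn": 65.38,
    "Ga": 69.723, "Ge": 72.630, "As": 74.922, "Se": 78.971, "Br": 79.904,
    "Kr": 83.798, "Rb": 85.468, "Sr": 87.62, "Y": 88.906, "Zr": 91.224,
    "Nb": 92.906, "Mo": 95.95, "Ru": 101.07, "Rh": 102.91, "Pd": 106.42,
    "Ag": 107.87, "Cd": 112.41, "In": 114.82, "Sn": 118.71, "Sb": 121.76,
    "Te": 127.60, "I": 126.90, "Xe": 131.29, "Cs": 132.91, "Ba": 137.33,
    "La": 138.91, "Ce": 140.12, "Pr": 140.91, "Nd": 144.24, "Sm": 150.36,
    "Eu": 151.96, "Gd": 157.25, "Tb": 158.93, "Dy": 162.50, "Ho": 164.93,
    "Er": 167.26, "Tm": 168.93, "Yb": 173.05, "Lu": 174.97, "Hf": 178.49,
    "Ta": 180.95, "W": 183.84, "Re": 186.21, "Os": 190.23, "Ir": 192.22,
    "Pt": 195.08, "Au": 196.97, "Hg": 200.59, "Tl": 204.38, "Pb": 207.2,
    "Bi": 208.98, "Th": 232.04, "Pa": 231.04, "U": 238.03,
}

_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


def parse_formula(formula: str) -> dict[str, int]:
    """Parse a Hill-notation molecular formula like ``C15H22O``.

    Raises ``ValueError`` on unknown element symbols, zero counts, or any
    unparseable text.
    """
    if not formula or not isinstance(formula, str):
        raise ValueError("formula must be a non-empty string")
    counts: dict[str, int] = {}
    pos = 0
    for match in _FORMULA_TOKEN.finditer(formula):
        if match.start() != pos:
            raise ValueError(f"unparseable formula {formula!r} at position {pos}")
        symbol, digits = match.groups()
        if symbol not in ATOMIC_MASSES:
            raise ValueError(f"unknown element symbol {symbol!r} in {formula!r}")
        n = int(digits) if digits else 1
        if n < 1:
            raise ValueError(f"element count must be >= 1 in {formula!r}")
        counts[symbol] = counts.get(symbol, 0) + n
        pos = match.end()
    if pos != len(formula) or not counts:
        raise ValueError(f"unparseable formula {formula!r}")
    return counts


def molar_mass(formula: str | dict[str, int]) -> float:
    """Sum of standard atomic masses times element counts, in g/mol."""
    counts = parse_formula(formula) if isinstance(formula, str) else dict(formula)
    for symbol, n in counts.items():
        if symbol not in ATOMIC_MASSES:
            raise ValueError(f"unknown element symbol {symbol!r}")
        if n < 1:
            raise ValueError("element counts must be >= 1")
    return sum(ATOMIC_MASSES[s] * n for s, n in counts.items())


@dataclass(frozen=True)
class CompoundSpec:
    """A compound identified by formula with its derived molar mass."""

    molecular_formula: dict[str, int]
    molar_mass: float

    @classmethod
    def from_formula(cls, formula: str) -> "CompoundSpec":
        counts = parse_formula(formula)
        return cls(molecular_formula=counts, molar_mass=molar_mass(counts))


def mfi(events) -> float:
    """Arithmetic mean fluorescence intensity of an event sample."""
    arr = np.asarray(events, dtype=float)
    if arr.size == 0:
        raise ValueError("mfi requires at least one event")
    return float(arr.mean())


def gate_top_percent(values, p: float) -> np.ndarray:
    """Select the ceil(p/100 * n) largest values, including ties at the cut.

    Returns the selected values in descending order.
    """
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise ValueError("gate_top_percent requires a non-empty sample")
    if not 0 < p <= 100:
        raise ValueError(f"p must lie in (0, 100], got {p}")
    k = math.ceil(p / 100.0 * arr.size)
    ordered = np.sort(arr)[::-1]
    cutoff = ordered[k - 1]
    return ordered[ordered >= cutoff]


@dataclass(frozen=True)
class RQResult:
    """Fold-change relative to the reference condition: rq = 2**(-ddct)."""

    condition: str
    rq: float
    ddct: float


def rq_ddct(
    ct_target_treated: float,
    ct_hk_treated: float,
    ct_target_ref: float,
    ct_hk_ref: float,
    condition: str = "treated",
) -> RQResult:
    """Double-delta-Ct relative quantification.

    ddct = (Ct_target,treated - Ct_hk,treated) - (Ct_target,ref - Ct_hk,ref);
    the reference condition itself always maps to rq = 1.
    """
    cts = (ct_target_treated, ct_hk_treated, ct_target_ref, ct_hk_ref)
    if not all(math.isfinite(c) for c in cts):
        raise ValueError(f"Ct values must be finite, got {cts}")
    ddct = (ct_target_treated - ct_hk_treated) - (ct_target_ref - ct_hk_ref)
    return RQResult(condition=condition, rq=2.0 ** (-ddct), ddct=ddct)


def micromolar_to_ug_per_ml(concentration_um: float, compound: CompoundSpec | str) -> float:
    """Convert µM to µg/mL: c[µM] × M[g/mol] / 1000."""
    if concentration_um < 0:
        raise ValueError(f"concentration must be >= 0, got {concentration_um}")
    if isinstance(compound, str):
        compound = CompoundSpec.from_formula(compound)
    return concentration_um * compound.molar_mass / 1000.0
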