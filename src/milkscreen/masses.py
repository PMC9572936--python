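"""Monoisotopic mass arithmetic for small-molecule adduct ions.

Electrospray screening of veterinary drugs identifies each analyte by the
accurate m/z of its (de)protonated or sodiated molecular ion.  This module
provides the exact-mass primitives: a monoisotopic element mass table,
molecular-formula mass summation, adduct m/z computation with electron-mass
correction, and the ppm mass-error measure used for tolerance matching.

Conventions
-----------
* Masses are in daltons (Da), m/z in thomsons (Th).
* The ion m/z subtracts one electron mass per unit positive charge, so a
  proton contributes 1.007276 Th rather than the hydrogen atom mass.
* Full double precision is carried everywhere; rounding to 4 decimals is a
  display concern only (see :func:`adduct_mz` ``ndigits``).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping
import re

__all__ = [
    "MONOISOTOPIC_MASS",
    "ELECTRON_MASS",
    "PROTON_MASS",
    "AdductSpec",
    "ADDUCTS",
    "FormulaError",
    "parse_formula",
    "monoisotopic_mass",
    "adduct_mz",
    "ppm_error",
]

#: IUPAC/AME monoisotopic atomic masses (Da), principal isotope.
MONOISOTOPIC_MASS: dict[str, float] = {
    "H": 1.00782503207,
    "C": 12.0,
    "N": 14.0030740048,
    "O": 15.9949146196,
    "S": 31.97207100,
    "F": 18.99840322,
    "Cl": 34.96885268,
    "Na": 22.9897692809,
    # isotopic labels used by the internal standards
    "D": 2.01410177785,   # deuterium, 2H
    "[13C]": 13.0033548378,
}

#: Electron rest mass (Da).
ELECTRON_MASS = 0.00054857990907

#: Mass of a bare proton (Da): hydrogen atom minus one electron.
PROTON_MASS = MONOISOTOPIC_MASS["H"] - ELECTRON_MASS


class FormulaError(ValueError):
    """Raised for an unparsable formula or an unknown element symbol."""


@dataclass(frozen=True)
class AdductSpec:
    """An electrospray adduct: atoms gained/lost and the resulting charge.

    ``atoms`` maps element symbols to signed counts relative to the neutral
    molecule M; e.g. the ammonia-loss ion [M+H-NH3]+ is ``{"H": -2, "N": -1}``
    (one proton gained, NH3 lost).  ``charge`` is the positive charge state.
    """

    label: str
    atoms: Mapping[str, int] = field(default_factory=dict)
    charge: int = 1

    def __post_init__(self) -> None:
        if self.charge < 1:
            raise ValueError(f"adduct charge must be >= 1, got {self.charge}")

    def mass_shift(self) -> float:
        """Neutral-atom mass gained/lost, before electron correction (Da)."""
        return sum(MONOISOTOPIC_MASS[el] * n for el, n in self.atoms.items())


#: The four positive-mode adduct species observed on this panel.
ADDUCTS: dict[str, AdductSpec] = {
    "[M+H]+": AdductSpec("[M+H]+", {"H": 1}, 1),
    "[M+Na]+": AdductSpec("[M+Na]+", {"Na": 1}, 1),
    "[M+2H]2+": AdductSpec("[M+2H]2+", {"H": 2}, 2),
    "[M+H-NH3]+": AdductSpec("[M+H-NH3]+", {"H": -2, "N": -1}, 1),
}

_FORMULA_TOKEN = re.compile(r"(\[13C\]|[A-Z][a-z]?)(\d*)")


def parse_formula(formula: str) -> dict[str, int]:
    """Parse a Hill-style formula string (``C16H19N3O5S``) to element counts."""
    counts: dict[str, int] = {}
    pos = 0
    for match in _FORMULA_TOKEN.finditer(formula):
        if match.start() != pos:
            raise FormulaError(f"unparsable formula {formula!r} at position {pos}")
        el, num = match.group(1), match.group(2)
        if el not in MONOISOTOPIC_MASS:
            raise FormulaError(f"unknown element symbol {el!r} in formula {formula!r}")
        counts[el] = counts.get(el, 0) + (int(num) if num else 1)
        pos = match.end()
    if pos != len(formula) or not counts:
        raise FormulaError(f"unparsable formula {formula!r}")
    return counts


def _as_counts(formula: Mapping[str, int] | str) -> Mapping[str, int]:
    return parse_formula(formula) if isinstance(formula, str) else formula


def monoisotopic_mass(formula: Mapping[str, int] | str) -> float:
    """Monoisotopic mass (Da) of a neutral molecule.

    Parameters
    ----------
    formula : mapping or str
        Element -> count map, or a formula string such as ``"C22H24N2O8"``.
    """
    counts = _as_counts(formula)
    total = 0.0
    for el, n in counts.items():
        if el not in MONOISOTOPIC_MASS:
            raise FormulaError(f"unknown element symbol {el!r}")
        total += MONOISOTOPIC_MASS[el] * n
    return total


def adduct_mz(
    formula: Mapping[str, int] | str,
    adduct: AdductSpec | str,
    ndigits: int | None = None,
) -> float:
    """Theoretical m/z (Th) of an adduct ion of the given molecule.

    m/z = (M + sum of added-atom masses - z * m_e) / z, with z the charge.
    Pass ``ndigits=4`` to round for display; comparisons should use the
    unrounded value.
    """
    if isinstance(adduct, str):
        try:
            adduct = ADDUCTS[adduct]
        except KeyError:
            raise FormulaError(
                f"unsupported adduct label {adduct!r}; known: {sorted(ADDUCTS)}"
            ) from None
    m = monoisotopic_mass(formula)
    mz = (m + adduct.mass_shift() - adduct.charge * ELECTRON_MASS) / adduct.charge
    return round(mz, ndigits) if ndigits is not None else mz


def ppm_error(observed: float, theoretical: float) -> float:
    """Signed mass error in parts per million: 1e6 * (obs - theo) / theo."""
    if theoretical <= 0:
        raise ValueError(f"theoretical m/z must be positive, got {theoretical}")
    return 1e6 * (observed - theoretical) / theoretical
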