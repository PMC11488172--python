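"""Molecular-formula arithmetic for negative-mode LC/MS annotation.

A molecular formula is an element→count map. Monoisotopic masses use the
most-abundant-isotope values shipped with pyteomics (NIST/IUPAC). Two
negative-mode ion species are supported: the deprotonated molecule [M-H]⁻
and the formate adduct [M+HCOO]⁻, the two species observed in negative-ESI
profiling of herbal decoctions.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from enum import Enum

from pyteomics.mass import nist_mass

__all__ = [
    "Adduct",
    "FormulaError",
    "MolecularFormula",
    "PROTON_MASS",
    "FORMATE_MASS",
    "parse_formula",
    "monoisotopic_mass",
    "adduct_mz",
    "ppm_error",
]

#: Mass of a proton, Da. [M-H]⁻ m/z = M − proton (the lost H leaves its electron behind).
PROTON_MASS = 1.00727646

#: Mass of the formate anion HCOO⁻, Da (CHO₂ monoisotopic plus one electron).
FORMATE_MASS = 44.99820


class Adduct(Enum):
    """Negative-mode ion species."""

    M_MINUS_H = "[M-H]-"
    M_PLUS_HCOO = "[M+HCOO]-"

    @classmethod
    def from_label(cls, label: str) -> "Adduct":
        norm = label.replace(" ", "").replace("−", "-").replace("^", "")
        for a in cls:
            if a.value == norm:
                return a
        raise ValueError(f"unsupported adduct label: {label!r}")


class FormulaError(ValueError):
    """Malformed or chemically unknown formula text."""

    def __init__(self, message: str, offset: int | None = None):
        super().__init__(message if offset is None else f"{message} (offset {offset})")
        self.offset = offset


_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


@dataclass(frozen=True)
class MolecularFormula:
    """Element symbol → count map; the unit of all mass arithmetic."""

    counts: tuple[tuple[str, int], ...]

    def __post_init__(self):
        if not self.counts:
            raise FormulaError("formula must contain at least one atom")
        for el, n in self.counts:
            if el not in nist_mass:
                raise FormulaError(f"unknown element {el!r}")
            if n <= 0:
                raise FormulaError(f"non-positive count for {el}")

    @classmethod
    def from_dict(cls, d: dict[str, int]) -> "MolecularFormula":
        return cls(tuple(sorted(d.items())))

    def as_dict(self) -> dict[str, int]:
        return dict(self.counts)

    def __str__(self) -> str:
        # Hill order: C first, then H, then the rest alphabetically.
        d = self.as_dict()
        out = []
        for el in ("C", "H"):
            if el in d:
                n = d.pop(el)
                out.append(el + (str(n) if n != 1 else ""))
        for el in sorted(d):
            out.append(el + (str(d[el]) if d[el] != 1 else ""))
        return "".join(out)


def parse_formula(text: str) -> MolecularFormula:
    """Parse Hill-style formula text like ``C6H8O7`` (no charges, no isotopes).

    Raises :class:`FormulaError` with the character offset of the first
    offending token.
    """
    if not isinstance(text, str) or not text.strip():
        raise FormulaError("empty formula")
    text = text.strip()
    counts: dict[str, int] = {}
    pos = 0
    while pos < len(text):
        m = _TOKEN.match(text, pos)
        if not m or not m.group(1):
            raise FormulaError(f"malformed token at {text[pos]!r}", offset=pos)
        el, num = m.group(1), m.group(2)
        if el not in nist_mass:
            raise FormulaError(f"unknown element {el!r}", offset=pos)
        counts[el] = counts.get(el, 0) + (int(num) if num else 1)
        pos = m.end()
    return MolecularFormula.from_dict(counts)


def monoisotopic_mass(f: MolecularFormula) -> float:
    """Sum of count × most-abundant-isotope mass over all elements, Da."""
    return sum(n * nist_mass[el][0][0] for el, n in f.counts)


def adduct_mz(f: MolecularFormula, adduct: Adduct) -> float:
    """Theoretical m/z of the ion species formed from neutral *f*."""
    m = monoisotopic_mass(f)
    if adduct is Adduct.M_MINUS_H:
        return m - PROTON_MASS
    if adduct is Adduct.M_PLUS_HCOO:
        return m + FORMATE_MASS
    raise ValueError(f"unsupported adduct: {adduct!r}")


def ppm_error(observed: float, theoretical: float) -> float:
    """Signed relative mass error, parts per million."""
    if theoretical <= 0:
        raise ValueError("theoretical m/z must be positive")
    return (observed - theoretical) / theoretical * 1e6
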