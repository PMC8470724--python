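"""Elemental formulas, adducts and isotopologue m/z arithmetic.

High-resolution screening lives and dies by sub-mDa mass arithmetic: the
monoisotopic mass of a neutral molecule, the m/z of its adduct ions
(M+H, M-H, M+Na, ...), the +1.0033548 Da spacing of the 13C isotopologue
ladder, and parts-per-million comparison of observed against theoretical
m/z. This module provides exactly that arithmetic, to the precision a
QTOF instrument resolves.

Conventions
-----------
* Atomic masses are IUPAC/CODATA monoisotopic values (12C = 12 exactly).
* Adduct mass shifts are electron-corrected: M+Na is Na minus an
  electron, M+Cl is Cl plus an electron.
* Isotopologues model 13C substitutions only; ``isotope_index`` counts
  the number of 13C atoms (0 = monoisotopic peak).
* ppm errors are signed: (observed - theoretical) / theoretical * 1e6.
"""

from __future__ import annotations

import bisect
import csv
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

__all__ = [
    "MONOISOTOPIC_MASS",
    "PROTON_MASS",
    "ELECTRON_MASS",
    "C13_MASS_DELTA",
    "FormulaError",
    "ElementalFormula",
    "AdductSpec",
    "TheoreticalIon",
    "DEFAULT_ADDUCTS",
    "get_adduct",
    "load_adduct_registry",
    "monoisotopic_mass",
    "ion_mz",
    "ppm_error",
    "match_mz",
]

#: Monoisotopic atomic masses (Da) of the supported elements.
MONOISOTOPIC_MASS: Mapping[str, float] = {
    "C": 12.0,
    "H": 1.00782503207,
    "N": 14.0030740048,
    "O": 15.9949146196,
    "S": 31.97207100,
    "P": 30.97376163,
    "Na": 22.9897692809,
    "K": 38.96370668,
    "Cl": 34.96885268,
}

PROTON_MASS = 1.007276466879
ELECTRON_MASS = 0.00054857990907
#: Mass difference 13C - 12C (Da), the isotopologue ladder spacing.
C13_MASS_DELTA = 1.0033548378


class FormulaError(ValueError):
    """Raised for malformed or unsupported elemental formulas."""


_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


@dataclass(frozen=True)
class ElementalFormula:
    """An elemental composition, e.g. C23H45NO4 for palmitoylcarnitine.

    ``counts`` maps element symbols to positive integer counts. Unknown
    elements and non-positive counts are rejected at construction; the
    empty formula is allowed (mass 0).
    """

    counts: Mapping[str, int]

    def __post_init__(self) -> None:
        clean: dict[str, int] = {}
        for symbol, count in self.counts.items():
            if symbol not in MONOISOTOPIC_MASS:
                raise FormulaError(f"unsupported element symbol: {symbol!r}")
            if not isinstance(count, int) or count < 1:
                raise FormulaError(
                    f"element count must be a positive integer: {symbol}={count!r}"
                )
            clean[symbol] = count
        object.__setattr__(self, "counts", clean)

    @classmethod
    def parse(cls, text: str) -> "ElementalFormula":
        """Parse a Hill-style formula string such as ``"C21H39NO4"``."""
        text = text.strip()
        counts: dict[str, int] = {}
        pos = 0
        for match in _FORMULA_TOKEN.finditer(text):
            if match.start() != pos:
                raise FormulaError(f"cannot parse formula {text!r} at position {pos}")
            symbol, digits = match.groups()
            counts[symbol] = counts.get(symbol, 0) + (int(digits) if digits else 1)
            pos = match.end()
        if pos != len(text):
            raise FormulaError(f"cannot parse formula {text!r} at position {pos}")
        return cls(counts)

    @property
    def mass(self) -> float:
        """Monoisotopic mass in Da."""
        return sum(MONOISOTOPIC_MASS[el] * n for el, n in self.counts.items())

    def __add__(self, other: "ElementalFormula") -> "ElementalFormula":
        merged = dict(self.counts)
        for el, n in other.counts.items():
            merged[el] = merged.get(el, 0) + n
        return ElementalFormula(merged)

    def __str__(self) -> str:  # Hill order: C, H, then alphabetical
        order = sorted(
            self.counts,
            key=lambda el: (el != "C", el != "H", el),
        )
        return "".join(
            f"{el}{self.counts[el] if self.counts[el] > 1 else ''}" for el in order
        )


def monoisotopic_mass(formula: ElementalFormula | str) -> float:
    """Monoisotopic mass (Da) of a formula or formula string."""
    if isinstance(formula, str):
        formula = ElementalFormula.parse(formula)
    return formula.mass


@dataclass(frozen=True)
class AdductSpec:
    """An ionization rule turning a neutral mass into an observed m/z.

    ``mass_shift`` is the signed Da shift applied to
    ``molecule_multiplier * M`` before dividing by ``charge``; it already
    includes the electron correction.
    """

    name: str
    polarity: str  # "positive" | "negative"
    mass_shift: float
    charge: int = 1
    molecule_multiplier: int = 1

    def __post_init__(self) -> None:
        if self.polarity not in ("positive", "negative"):
            raise ValueError(f"polarity must be positive|negative: {self.polarity!r}")
        if self.charge < 1:
            raise ValueError("charge must be >= 1")
        if self.molecule_multiplier < 1:
            raise ValueError("molecule_multiplier must be >= 1")


def _normalize_adduct_name(name: str) -> str:
    return name.replace(" ", "").replace("−", "-").replace("–", "-")


#: Built-in adduct registry. Shifts are electron-corrected.
DEFAULT_ADDUCTS: Mapping[str, AdductSpec] = {
    "M+H": AdductSpec("M+H", "positive", PROTON_MASS),
    "M-H": AdductSpec("M-H", "negative", -PROTON_MASS),
    "M+Na": AdductSpec(
        "M+Na", "positive", MONOISOTOPIC_MASS["Na"] - ELECTRON_MASS
    ),
    "M+K": AdductSpec("M+K", "positive", MONOISOTOPIC_MASS["K"] - ELECTRON_MASS),
    "M+Cl": AdductSpec(
        "M+Cl", "negative", MONOISOTOPIC_MASS["Cl"] + ELECTRON_MASS
    ),
}


def get_adduct(
    name: str, registry: Mapping[str, AdductSpec] | None = None
) -> AdductSpec:
    """Look up an adduct by name; tolerates spaces and unicode minus."""
    registry = DEFAULT_ADDUCTS if registry is None else registry
    key = _normalize_adduct_name(name)
    try:
        return registry[key]
    except KeyError:
        raise KeyError(f"unknown adduct {name!r}; registered: {sorted(registry)}")


def load_adduct_registry(path: str | Path) -> dict[str, AdductSpec]:
    """Load an adduct registry from a TSV with columns
    name, polarity, charge, mass_shift, multiplier."""
    registry: dict[str, AdductSpec] = {}
    with open(path, newline="") as handle:
        for row in csv.DictReader(handle, delimiter="\t"):
            name = _normalize_adduct_name(row["name"])
            registry[name] = AdductSpec(
                name=name,
                polarity=row["polarity"].strip().lower(),
                mass_shift=float(row["mass_shift"]),
                charge=int(row.get("charge") or 1),
                molecule_multiplier=int(row.get("multiplier") or 1),
            )
    return registry


@dataclass(frozen=True)
class TheoreticalIon:
    """A predicted ion: compound, adduct, number of 13C substitutions, m/z."""

    compound_id: str
    adduct_name: str
    isotope_index: int
    mz: float


def ion_mz(
    neutral_mass: float, adduct: AdductSpec, isotope_index: int = 0
) -> float:
    """m/z of an adduct ion of a neutral molecule.

    ``(multiplier * M + shift + isotope_index * 1.0033548) / charge``.
    """
    if neutral_mass <= 0:
        raise ValueError(f"neutral mass must be positive: {neutral_mass}")
    if isotope_index < 0:
        raise ValueError(f"isotope_index must be >= 0: {isotope_index}")
    return (
        adduct.molecule_multiplier * neutral_mass
        + adduct.mass_shift
        + isotope_index * C13_MASS_DELTA
    ) / adduct.charge


def ppm_error(observed: float, theoretical: float) -> float:
    """Signed relative mass error in parts per million."""
    if theoretical <= 0:
        raise ValueError(f"theoretical m/z must be positive: {theoretical}")
    return (observed - theoretical) / theoretical * 1e6


def match_mz(
    observed: float,
    ions: Sequence[TheoreticalIon],
    tolerance: float,
) -> list[tuple[TheoreticalIon, float]]:
    """All ions within ``tolerance`` ppm of an observed m/z.

    Returns ``(ion, ppm_error)`` pairs sorted by absolute ppm error
    (ties by ion m/z then compound id, for determinism). ``ions`` need
    not be pre-sorted.
    """
    if tolerance <= 0:
        raise ValueError("tolerance must be positive")
    ordered = sorted(ions, key=lambda ion: ion.mz)
    mzs = [ion.mz for ion in ordered]
    # |obs - th|/th <= tol  <=>  th in [obs/(1+tol), obs/(1-tol)]
    tol = tolerance * 1e-6
    lo = bisect.bisect_left(mzs, observed / (1.0 + tol))
    hi = bisect.bisect_right(mzs, observed / (1.0 - tol) if tol < 1 else float("inf"))
    hits = []
    for ion in ordered[lo:hi]:
        err = ppm_error(observed, ion.mz)
        if abs(err) <= tolerance:
            hits.append((ion, err))
    hits.sort(key=lambda pair: (abs(pair[1]), pair[0].mz, pair[0].compound_id))
    return hits
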