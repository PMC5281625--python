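"""Exact-mass arithmetic for small-molecule mass spectrometry.

This module is the numeric foundation of the package: molecular-formula
parsing, monoisotopic and average mass computation, conversion between
measured ion m/z and neutral mass for electrospray adducts, ppm/mDa error
arithmetic, and the nitrogen-rule parity call used by the odd-mass (RN)
statistic.

The nitrogen rule: a CHNOPS molecule satisfying ordinary valence rules has
an odd nominal (integer) mass exactly when it contains an odd number of
nitrogen atoms.  The rule is exact on formulas; applied to a measured
neutral mass it relies on rounding the monoisotopic mass to the nearest
integer, which becomes unreliable once the accumulated mass defect
approaches half a dalton (flagged here above a configurable limit,
500 Da by default).
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Mapping, NamedTuple

__all__ = [
    "PROTON_MASS_DA",
    "FormulaError",
    "MolecularFormula",
    "ParityCall",
    "MassError",
    "parse_formula",
    "monoisotopic_mass",
    "average_mass",
    "nominal_mass",
    "neutral_from_ion",
    "ion_from_neutral",
    "mass_error",
    "ppm_difference",
    "nitrogen_parity",
    "formula_nitrogen_parity",
    "millimolar",
]

#: Mass of a proton (the charge carrier of ESI [M+H]+ / [M-H]- ions), Da.
#: Deliberately not the hydrogen-atom mass: the electron stays behind.
PROTON_MASS_DA = 1.00727646688


class FormulaError(ValueError):
    """Raised for malformed or chemically inadmissible formula strings."""


def _load_element_table() -> dict[str, tuple[float, float]]:
    table: dict[str, tuple[float, float]] = {}
    text = resources.files("corrosomics.data").joinpath("element_masses.tsv").read_text()
    lines = text.strip().splitlines()
    for line in lines[1:]:
        symbol, mono, avg = line.split("\t")
        table[symbol] = (float(mono), float(avg))
    return table


#: symbol -> (monoisotopic mass, standard atomic weight), loaded once.
ELEMENT_MASSES: dict[str, tuple[float, float]] = _load_element_table()

_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


@dataclass(eq=True)
class MolecularFormula:
    """An element->count map, e.g. ``{"C": 6, "H": 10, "O": 4}``.

    All counts are >= 1 and every symbol must be in the allowed element
    table (CHNOPS plus halogens).  The string form uses Hill order
    (C, H, then alphabetical).
    """

    counts: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for symbol, count in self.counts.items():
            if symbol not in ELEMENT_MASSES:
                raise FormulaError(f"unknown element symbol {symbol!r}")
            if not isinstance(count, int) or count < 1:
                raise FormulaError(f"count for {symbol} must be a positive integer, got {count!r}")

    @classmethod
    def from_string(cls, text: str) -> "MolecularFormula":
        return parse_formula(text)

    def __str__(self) -> str:
        parts = []
        for symbol in _hill_order(self.counts):
            n = self.counts[symbol]
            parts.append(symbol if n == 1 else f"{symbol}{n}")
        return "".join(parts)

    def __getitem__(self, symbol: str) -> int:
        return self.counts.get(symbol, 0)

    @property
    def n_nitrogen(self) -> int:
        return self.counts.get("N", 0)

    def merge(self, other: "MolecularFormula") -> "MolecularFormula":
        """Element-wise sum of two formulas (e.g. building homologs)."""
        merged = dict(self.counts)
        for symbol, count in other.counts.items():
            merged[symbol] = merged.get(symbol, 0) + count
        return MolecularFormula(merged)

    @property
    def monoisotopic_mass(self) -> float:
        return monoisotopic_mass(self)

    @property
    def average_mass(self) -> float:
        return average_mass(self)


def _hill_order(counts: Mapping[str, int]) -> list[str]:
    symbols = sorted(counts)
    ordered = [s for s in ("C", "H") if s in counts]
    ordered += [s for s in symbols if s not in ("C", "H")]
    return ordered


def parse_formula(text: str) -> MolecularFormula:
    """Parse a plain formula string like ``"C6H10O4"``.

    Grammar: a sequence of element symbols, each followed by an optional
    positive integer count (absent means 1).  No parentheses, charges, or
    isotope labels.  Repeated symbols accumulate.
    """
    if not text or not text.strip():
        raise FormulaError("empty formula string")
    text = text.strip()
    counts: dict[str, int] = {}
    pos = 0
    while pos < len(text):
        match = _TOKEN.match(text, pos)
        if match is None or match.start() != pos or not match.group(1):
            raise FormulaError(f"malformed formula {text!r} at {text[pos:]!r}")
        symbol, digits = match.groups()
        if symbol not in ELEMENT_MASSES:
            raise FormulaError(f"unknown element symbol {symbol!r} in {text!r}")
        if digits == "":
            count = 1
        else:
            count = int(digits)
            if count == 0:
                raise FormulaError(f"zero count for element {symbol!r} in {text!r}")
        counts[symbol] = counts.get(symbol, 0) + count
        pos = match.end()
    return MolecularFormula(counts)


def _as_formula(formula: "MolecularFormula | str") -> MolecularFormula:
    if isinstance(formula, str):
        return parse_formula(formula)
    return formula


def monoisotopic_mass(formula: "MolecularFormula | str") -> float:
    """Sum of most-abundant-isotope masses over the formula, Da."""
    f = _as_formula(formula)
    return sum(ELEMENT_MASSES[s][0] * n for s, n in f.counts.items())


def average_mass(formula: "MolecularFormula | str") -> float:
    """Molar mass from standard atomic weights, g/mol."""
    f = _as_formula(formula)
    return sum(ELEMENT_MASSES[s][1] * n for s, n in f.counts.items())


def nominal_mass(formula: "MolecularFormula | str") -> int:
    """Integer mass from the mass numbers of the principal isotopes."""
    f = _as_formula(formula)
    return sum(int(round(ELEMENT_MASSES[s][0])) * n for s, n in f.counts.items())


#: adduct label -> (ion mode it belongs to, m/z shift relative to neutral).
#: Extensible: register more singly charged adducts by appending here.
ADDUCTS: dict[str, tuple[str, float]] = {
    "protonated": ("positive", +PROTON_MASS_DA),   # [M+H]+
    "deprotonated": ("negative", -PROTON_MASS_DA),  # [M-H]-
}


def neutral_from_ion(mz: float, ion_mode: str, adduct: str | None = None) -> float:
    """Neutral monoisotopic mass from a measured singly charged m/z.

    When ``adduct`` is omitted the default adduct of the ion mode is used
    (protonated for positive, deprotonated for negative).
    """
    if adduct is None:
        adduct = {"positive": "protonated", "negative": "deprotonated"}.get(ion_mode)
    if adduct not in ADDUCTS:
        raise ValueError(f"unknown adduct {adduct!r}; known: {sorted(ADDUCTS)}")
    mode, shift = ADDUCTS[adduct]
    if mode != ion_mode:
        raise ValueError(f"adduct {adduct!r} belongs to {mode} mode, not {ion_mode}")
    neutral = mz - shift
    if neutral <= 0:
        raise ValueError(f"m/z {mz} is not above the adduct mass shift")
    return neutral


def ion_from_neutral(neutral_mass: float, ion_mode: str, adduct: str | None = None) -> float:
    """Inverse of :func:`neutral_from_ion`."""
    if adduct is None:
        adduct = {"positive": "protonated", "negative": "deprotonated"}.get(ion_mode)
    if adduct not in ADDUCTS:
        raise ValueError(f"unknown adduct {adduct!r}; known: {sorted(ADDUCTS)}")
    mode, shift = ADDUCTS[adduct]
    if mode != ion_mode:
        raise ValueError(f"adduct {adduct!r} belongs to {mode} mode, not {ion_mode}")
    return neutral_mass + shift


class MassError(NamedTuple):
    ppm: float
    mda: float


def mass_error(observed: float, theoretical: float) -> MassError:
    """Signed mass error as (ppm, mDa); positive means observed is heavier."""
    if theoretical <= 0:
        raise ValueError("theoretical mass must be positive")
    delta = observed - theoretical
    return MassError(ppm=delta / theoretical * 1e6, mda=delta * 1e3)


def ppm_difference(mass_a: float, mass_b: float) -> float:
    """Symmetric ppm difference between two measured masses.

    Uses the pair mean as the reference so the result does not depend on
    argument order; this is the comparison used for feature alignment.
    """
    mean = 0.5 * (mass_a + mass_b)
    if mean <= 0:
        raise ValueError("masses must be positive")
    return abs(mass_a - mass_b) / mean * 1e6


@dataclass(frozen=True)
class ParityCall:
    """Nitrogen-rule call on a neutral mass."""

    nominal_mass: int
    is_odd: bool
    #: for valence-consistent CHNOPS molecules, odd nominal mass implies an
    #: odd nitrogen count; this mirrors ``is_odd`` and is kept explicit so
    #: callers state which interpretation they use.
    implied_odd_nitrogen: bool
    #: True when the neutral mass exceeds the reliability limit and the
    #: round-to-integer step may misassign parity (mass-defect drift).
    unreliable: bool = False


def nitrogen_parity(neutral_mass: float, reliable_below_da: float = 500.0) -> ParityCall:
    """Classify a neutral monoisotopic mass as odd or even nominal mass.

    The nominal mass is the neutral mass rounded half-up to the nearest
    integer.  Above ``reliable_below_da`` the call is still made but
    flagged unreliable.
    """
    if neutral_mass <= 0:
        raise ValueError("neutral mass must be positive")
    nominal = math.floor(neutral_mass + 0.5)  # round half-up
    is_odd = nominal % 2 == 1
    return ParityCall(
        nominal_mass=nominal,
        is_odd=is_odd,
        implied_odd_nitrogen=is_odd,
        unreliable=neutral_mass > reliable_below_da,
    )


def formula_nitrogen_parity(formula: "MolecularFormula | str") -> bool:
    """True when the formula carries an odd number of nitrogen atoms."""
    return _as_formula(formula).n_nitrogen % 2 == 1


def millimolar(mg_per_liter: float, formula: "MolecularFormula | str") -> float:
    """Convert a mass concentration (mg/L) to millimolar using the molar mass."""
    if mg_per_liter < 0:
        raise ValueError("concentration must be non-negative")
    return mg_per_liter / average_mass(formula)
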