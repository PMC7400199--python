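"""Elemental-formula arithmetic, monoisotopic masses, adduct m/z and ppm errors.

This module is the numeric substrate for the rest of the package.  Atomic
masses are monoisotopic IUPAC/CODATA values loaded from a versioned
plain-text table shipped with the package (``data/atomic_masses.tsv``); the
electron mass is subtracted once per positive charge when forming cations,
so ``adduct_mz`` returns the m/z of a singly charged even-electron adduct
ion ([M+H]+, [M+NH4]+ or [M+Na]+).

Internally everything is computed at full float precision; rounding to the
four decimal places customary for orbitrap-style instruments is left to the
reporting layer.
"""

from __future__ import annotations

import re
from collections import Counter
from dataclasses import dataclass
from importlib import resources
from typing import Iterator, Mapping, Union


class ChemError(ValueError):
    """Base class for chemistry-layer errors."""


class UnknownElementError(ChemError):
    """An element symbol is absent from the atomic mass table."""


class UnknownAdductError(ChemError):
    """An adduct name is not one of the supported cations."""


class FormulaParseError(ChemError):
    """A formula string could not be parsed."""


class InvalidMassError(ChemError):
    """A mass or m/z value violates a precondition (e.g. non-positive)."""


def _load_mass_table() -> dict[str, float]:
    text = (
        resources.files("depsimatch.data").joinpath("atomic_masses.tsv").read_text()
    )
    table: dict[str, float] = {}
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) != 2:
            continue
        symbol, value = fields
        try:
            table[symbol] = float(value)
        except ValueError:
            continue  # header row
    return table


_TABLE = _load_mass_table()

#: Electron mass in Da, used for the charge correction of cations.
ELECTRON_MASS: float = _TABLE.pop("e-")

#: Element symbol -> monoisotopic mass in Da.
ATOMIC_MASS: Mapping[str, float] = dict(_TABLE)

_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


@dataclass(frozen=True)
class Formula(Mapping):
    """Immutable elemental formula: a map from element symbol to count.

    Supports ``+`` (element-wise sum) and ``*`` (integer scaling), both of
    which model how residue formulas combine in a cyclic depsipeptide
    (no water is gained or lost when residues are already in-chain).
    """

    _items: tuple[tuple[str, int], ...]

    def __init__(self, counts: Mapping[str, int] | None = None):
        counts = dict(counts or {})
        for symbol, count in counts.items():
            if symbol not in ATOMIC_MASS:
                raise UnknownElementError(f"unknown element symbol: {symbol!r}")
            if not isinstance(count, int) or count < 0:
                raise FormulaParseError(
                    f"count for {symbol} must be a non-negative integer, got {count!r}"
                )
        items = tuple(sorted((s, c) for s, c in counts.items() if c > 0))
        object.__setattr__(self, "_items", items)

    # -- Mapping protocol -------------------------------------------------
    def __getitem__(self, key: str) -> int:
        for symbol, count in self._items:
            if symbol == key:
                return count
        raise KeyError(key)

    def __iter__(self) -> Iterator[str]:
        return (symbol for symbol, _ in self._items)

    def __len__(self) -> int:
        return len(self._items)

    # -- arithmetic -------------------------------------------------------
    def __add__(self, other: "Formula") -> "Formula":
        if not isinstance(other, Formula):
            return NotImplemented
        counts = Counter(dict(self._items))
        counts.update(dict(other._items))
        return Formula(counts)

    def __mul__(self, n: int) -> "Formula":
        if not isinstance(n, int):
            return NotImplemented
        if n < 0:
            raise FormulaParseError("formula multiplier must be non-negative")
        return Formula({s: c * n for s, c in self._items})

    __rmul__ = __mul__

    # -- construction / display -------------------------------------------
    @classmethod
    def from_string(cls, text: str) -> "Formula":
        """Parse a Hill-style formula string such as ``"C45H57N3O9"``."""
        text = text.strip()
        if not text:
            return cls({})
        counts: Counter[str] = Counter()
        pos = 0
        for match in _TOKEN.finditer(text):
            if match.start() != pos:
                raise FormulaParseError(f"cannot parse formula {text!r} at {pos}")
            symbol = match.group(1)
            if symbol not in ATOMIC_MASS:
                raise UnknownElementError(f"unknown element symbol: {symbol!r}")
            counts[symbol] += int(match.group(2) or 1)
            pos = match.end()
        if pos != len(text):
            raise FormulaParseError(f"cannot parse formula {text!r} at {pos}")
        return cls(counts)

    def __str__(self) -> str:
        counts = dict(self._items)
        parts = []
        for symbol in ("C", "H"):
            if symbol in counts:
                count = counts.pop(symbol)
                parts.append(symbol if count == 1 else f"{symbol}{count}")
        for symbol in sorted(counts):
            count = counts[symbol]
            parts.append(symbol if count == 1 else f"{symbol}{count}")
        return "".join(parts)

    @property
    def mass(self) -> float:
        """Monoisotopic mass in Da."""
        return sum(ATOMIC_MASS[s] * c for s, c in self._items)


FormulaLike = Union[Formula, str, Mapping]


def as_formula(value: FormulaLike) -> Formula:
    """Coerce a string or mapping to a :class:`Formula`."""
    if isinstance(value, Formula):
        return value
    if isinstance(value, str):
        return Formula.from_string(value)
    return Formula(value)


def formula_add(a: FormulaLike, b: FormulaLike) -> Formula:
    """Element-wise sum of two formulas."""
    return as_formula(a) + as_formula(b)


def monoisotopic_mass(formula: FormulaLike) -> float:
    """Monoisotopic mass of a formula in Da (0.0 for the empty formula)."""
    return as_formula(formula).mass


@dataclass(frozen=True)
class Adduct:
    """A singly charged cationizing adduct: [M+H]+, [M+NH4]+ or [M+Na]+."""

    name: str
    added: Formula
    charge: int = 1

    @property
    def cation_mass(self) -> float:
        """Mass of the charged adduct species (formula mass minus electrons)."""
        return self.added.mass - self.charge * ELECTRON_MASS


ADDUCTS: Mapping[str, Adduct] = {
    "proton": Adduct("proton", Formula.from_string("H")),
    "ammonium": Adduct("ammonium", Formula.from_string("NH4")),
    "sodium": Adduct("sodium", Formula.from_string("Na")),
}

#: Canonical adduct order used throughout reports (dominant ion first).
ADDUCT_NAMES: tuple[str, ...] = ("proton", "ammonium", "sodium")


def get_adduct(adduct: Union[str, Adduct]) -> Adduct:
    if isinstance(adduct, Adduct):
        return adduct
    try:
        return ADDUCTS[adduct]
    except KeyError:
        raise UnknownAdductError(
            f"unsupported adduct {adduct!r}; expected one of {sorted(ADDUCTS)}"
        ) from None


def adduct_mz(neutral_mass: float, adduct: Union[str, Adduct]) -> float:
    """m/z of the singly charged adduct ion of a neutral of given mass."""
    if neutral_mass < 0:
        raise InvalidMassError(f"neutral mass must be >= 0, got {neutral_mass}")
    spec = get_adduct(adduct)
    return (neutral_mass + spec.cation_mass) / spec.charge


def ppm_error(measured: float, theoretical: float) -> float:
    """Signed relative mass error, (measured - theoretical)/theoretical * 1e6."""
    if theoretical <= 0:
        raise InvalidMassError(
            f"theoretical m/z must be positive, got {theoretical}"
        )
    return (measured - theoretical) / theoretical * 1e6
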