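"""Monomer building blocks, composition enumeration and the compound registry.

Beauvericins (BEA), allobeauvericins (ALLOBEA), enniatins (ENN) and
beauvenniatins (BEAE) are cyclic hexadepsipeptides built from three
alternating hydroxy-acid and three N-methyl amino-acid residues.  A
*composition* here is the unordered residue content of the ring; ring
sequence and stereochemistry are intentionally out of scope because they
are not observable by mass spectrometry alone.

Amino residues are modelled as *mass classes* rather than named amino
acids: N-methyl-valine and leucine share the in-chain formula C6H11NO
(nominal 113 Da), N-methyl-leucine and N-methyl-isoleucine share C7H13NO
(127 Da), and N-methyl-phenylalanine is C10H11NO (161 Da).  Hydroxy-acid
residues are D-Hiv (C5H8O2), D-Hmp (C6H10O2) and D-Hbu (C4H6O2).  Because
the ring is closed, the neutral formula of a composition is the plain sum
of its residue formulas — no terminal water.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .chem import Formula


class LibraryError(ValueError):
    """Base class for library-layer errors."""


class EmptyResidueSetError(LibraryError):
    """Enumeration was asked to run over an empty residue set."""


class InvalidCompositionError(LibraryError):
    """A composition violates the 3 hydroxy + 3 amino residue contract."""


class UnknownResidueError(LibraryError):
    """A residue id does not appear in the residue table."""


HYDROXY_ACID = "hydroxy_acid"
AMINO_ACID = "amino_acid"


@dataclass(frozen=True)
class MonomerResidue:
    """A named in-chain building block (free acid minus water).

    ``nominal_loss`` is the integer neutral-loss value quoted in product-ion
    spectra for a single residue of this class (e.g. -161 Da for N-Me-Phe).
    """

    id: str
    role: str
    formula: Formula
    display_name: str

    @property
    def mass(self) -> float:
        return self.formula.mass

    @property
    def nominal_loss(self) -> int:
        return round(self.mass)


DEFAULT_HYDROXY_RESIDUES: tuple[MonomerResidue, ...] = (
    MonomerResidue("Hbu", HYDROXY_ACID, Formula.from_string("C4H6O2"), "D-Hbu"),
    MonomerResidue("Hiv", HYDROXY_ACID, Formula.from_string("C5H8O2"), "D-Hiv"),
    MonomerResidue("Hmp", HYDROXY_ACID, Formula.from_string("C6H10O2"), "D-Hmp"),
)

DEFAULT_AMINO_RESIDUES: tuple[MonomerResidue, ...] = (
    MonomerResidue("113", AMINO_ACID, Formula.from_string("C6H11NO"), "N-Me-Val"),
    MonomerResidue("127", AMINO_ACID, Formula.from_string("C7H13NO"), "N-Me-Leu/Ile"),
    MonomerResidue("161", AMINO_ACID, Formula.from_string("C10H11NO"), "N-Me-Phe"),
)

#: id -> residue for the default building blocks.
RESIDUES: Mapping[str, MonomerResidue] = {
    r.id: r for r in DEFAULT_HYDROXY_RESIDUES + DEFAULT_AMINO_RESIDUES
}


def _canonical(residues: Iterable[MonomerResidue]) -> tuple[MonomerResidue, ...]:
    return tuple(sorted(residues, key=lambda r: (r.mass, r.id)))


@dataclass(frozen=True)
class Composition:
    """Multiset of exactly 3 hydroxy-acid and 3 amino-acid residues."""

    hydroxy: tuple[MonomerResidue, ...]
    amino: tuple[MonomerResidue, ...]

    def __post_init__(self):
        hydroxy = _canonical(self.hydroxy)
        amino = _canonical(self.amino)
        if len(hydroxy) != 3 or len(amino) != 3:
            raise InvalidCompositionError(
                "a cyclic hexadepsipeptide composition needs exactly "
                f"3 hydroxy + 3 amino residues, got {len(hydroxy)}+{len(amino)}"
            )
        if any(r.role != HYDROXY_ACID for r in hydroxy):
            raise InvalidCompositionError("non-hydroxy residue in hydroxy slot")
        if any(r.role != AMINO_ACID for r in amino):
            raise InvalidCompositionError("non-amino residue in amino slot")
        object.__setattr__(self, "hydroxy", hydroxy)
        object.__setattr__(self, "amino", amino)

    @property
    def residues(self) -> tuple[MonomerResidue, ...]:
        return self.hydroxy + self.amino

    @property
    def key(self) -> str:
        """Stable text serialization, e.g. ``"Hiv,Hiv,Hmp|113,113,161"``."""
        return "{}|{}".format(
            ",".join(r.id for r in self.hydroxy),
            ",".join(r.id for r in self.amino),
        )

    @property
    def formula(self) -> Formula:
        total = Formula()
        for residue in self.residues:
            total = total + residue.formula
        return total

    @property
    def mass(self) -> float:
        """Neutral monoisotopic mass: plain residue-mass sum (cyclic)."""
        return sum(r.mass for r in self.residues)

    @property
    def residue_class_ids(self) -> frozenset[str]:
        return frozenset(r.id for r in self.residues)

    def __str__(self) -> str:  # pragma: no cover - display sugar
        return self.key


def composition_formula(c: Composition) -> Formula:
    """Neutral elemental formula of a composition (no water added)."""
    return c.formula


def composition_from_key(
    key: str, residues: Mapping[str, MonomerResidue] = RESIDUES
) -> Composition:
    """Inverse of :attr:`Composition.key`."""
    try:
        hydroxy_part, amino_part = key.split("|")
    except ValueError:
        raise InvalidCompositionError(f"malformed composition key {key!r}") from None

    def _resolve(part: str) -> tuple[MonomerResidue, ...]:
        out = []
        for rid in part.split(","):
            rid = rid.strip()
            if rid not in residues:
                raise UnknownResidueError(f"unknown residue id {rid!r} in {key!r}")
            out.append(residues[rid])
        return tuple(out)

    return Composition(_resolve(hydroxy_part), _resolve(amino_part))


def enumerate_compositions(
    hydroxy_set: Sequence[MonomerResidue] = DEFAULT_HYDROXY_RESIDUES,
    amino_set: Sequence[MonomerResidue] = DEFAULT_AMINO_RESIDUES,
) -> list[Composition]:
    """All 3+3 residue multisets over the given building-block sets.

    With the default 3 hydroxy x 3 amino blocks this yields
    C(3+2,3)^2 = 100 compositions.  The list is ordered by descending
    neutral mass, ties broken by the canonical key, so output is
    deterministic and diffable.
    """
    if not hydroxy_set:
        raise EmptyResidueSetError("hydroxy residue set is empty")
    if not amino_set:
        raise EmptyResidueSetError("amino residue set is empty")
    hydroxy_multisets = itertools.combinations_with_replacement(
        _canonical(hydroxy_set), 3
    )
    amino_multisets = list(
        itertools.combinations_with_replacement(_canonical(amino_set), 3)
    )
    out = [
        Composition(h, a)
        for h in hydroxy_multisets
        for a in amino_multisets
    ]
    out.sort(key=lambda c: (-c.mass, c.key))
    return out


def isobaric_groups(library: Iterable[Composition]) -> dict[str, list[Composition]]:
    """Partition compositions by exact neutral formula.

    Groups of size > 1 are the isobaric ambiguities that precursor m/z alone
    cannot resolve; they require fragment (neutral-loss) evidence.
    """
    groups: dict[str, list[Composition]] = {}
    for comp in library:
        groups.setdefault(str(comp.formula), []).append(comp)
    for members in groups.values():
        members.sort(key=lambda c: c.key)
    return groups


SYSTEMATIC = "systematic"


@dataclass(frozen=True)
class RegistryEntry:
    """Names and isomer-group metadata attached to one composition.

    Several canonical names may map to a single composition (positional
    isomers such as BEA B and ALLOBEA B share residue content and are not
    distinguishable by MS).  ``confidence`` is one of ``text_defined``,
    ``table_derived``, ``name_only`` (no composition available) or
    ``systematic`` (auto-generated label for unnamed compositions).
    """

    names: tuple[str, ...]
    isomer_group: str
    confidence: str
    composition: Composition | None = None
    note: str = ""

    @property
    def display_name(self) -> str:
        return "/".join(self.names)


def systematic_entry(c: Composition) -> RegistryEntry:
    label = f"cHD[{c.key}]"
    return RegistryEntry(
        names=(label,), isomer_group=label, confidence=SYSTEMATIC, composition=c
    )


class CompoundRegistry:
    """Lookup from composition to canonical compound names.

    Backed by a user-extensible tab-separated file with columns
    ``composition_key, names, isomer_group, confidence, note``; names are
    ``;``-separated and a ``-`` key marks a name-only stub.
    """

    def __init__(self, entries: Iterable[RegistryEntry]):
        self.entries: tuple[RegistryEntry, ...] = tuple(entries)
        self._by_key: dict[str, RegistryEntry] = {
            e.composition.key: e for e in self.entries if e.composition is not None
        }

    @classmethod
    def from_text(
        cls, text: str, residues: Mapping[str, MonomerResidue] = RESIDUES
    ) -> "CompoundRegistry":
        entries = []
        lines = [ln for ln in text.splitlines() if ln.strip()]
        for line in lines[1:]:  # skip header
            fields = line.split("\t")
            fields += [""] * (5 - len(fields))
            key, names, group, confidence, note = fields[:5]
            composition = (
                None if key.strip() in {"", "-"} else composition_from_key(key, residues)
            )
            entries.append(
                RegistryEntry(
                    names=tuple(n.strip() for n in names.split(";") if n.strip()),
                    isomer_group=group.strip(),
                    confidence=confidence.strip(),
                    composition=composition,
                    note=note.strip(),
                )
            )
        return cls(entries)

    @classmethod
    def from_file(cls, path: str | Path) -> "CompoundRegistry":
        return cls.from_text(Path(path).read_text())

    @classmethod
    def default(cls) -> "CompoundRegistry":
        text = resources.files("depsimatch.data").joinpath("registry.tsv").read_text()
        return cls.from_text(text)

    def lookup(self, c: Composition) -> RegistryEntry:
        """Registry entry for a composition; systematic label if unnamed."""
        return self._by_key.get(c.key) or systematic_entry(c)

    def composed_entries(self) -> list[RegistryEntry]:
        """Entries that carry a composition (excludes name-only stubs)."""
        return [e for e in self.entries if e.composition is not None]

    def entry_by_name(self, name: str) -> RegistryEntry:
        for entry in self.entries:
            if name in entry.names:
                return entry
        raise KeyError(name)


def lookup_names(
    c: Composition, registry: CompoundRegistry | None = None
) -> RegistryEntry:
    """Convenience wrapper over :meth:`CompoundRegistry.lookup`."""
    registry = registry or CompoundRegistry.default()
    return registry.lookup(c)
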