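"""Elemental-composition arithmetic for the dendrimer mass calculus.

An :class:`ElementalComposition` is an immutable element -> count mapping
supporting element-wise addition, subtraction (which must never go
negative: a molecule cannot lose atoms it does not have) and scaling by a
non-negative integer.  Average masses use the IUPAC conventional standard
atomic weights; monoisotopic masses use the principal-isotope masses.
Formulae are parsed from and rendered to Hill notation (carbon first,
hydrogen second, remaining elements alphabetical).
"""

from __future__ import annotations

import re
from collections.abc import Iterator, Mapping

# IUPAC 2021 conventional standard atomic weights (g/mol).
STANDARD_ATOMIC_WEIGHT: dict[str, float] = {
    "H": 1.008,
    "B": 10.81,
    "C": 12.011,
    "N": 14.007,
    "O": 15.999,
    "F": 18.998,
    "Na": 22.990,
    "Mg": 24.305,
    "Al": 26.982,
    "Si": 28.085,
    "P": 30.974,
    "S": 32.06,
    "Cl": 35.45,
    "K": 39.098,
    "Ca": 40.078,
    "Br": 79.904,
    "I": 126.904,
}

# Principal (most abundant) isotope masses (u).
PRINCIPAL_ISOTOPE_MASS: dict[str, float] = {
    "H": 1.0078250319,
    "B": 11.0093054,
    "C": 12.0,
    "N": 14.0030740052,
    "O": 15.9949146221,
    "F": 18.9984032,
    "Na": 22.98976928,
    "Mg": 23.98504170,
    "Al": 26.9815385,
    "Si": 27.9769265327,
    "P": 30.97376199,
    "S": 31.97207069,
    "Cl": 34.96885271,
    "K": 38.96370649,
    "Ca": 39.96259086,
    "Br": 78.9183376,
    "I": 126.9044719,
}

_FORMULA_RE = re.compile(r"([A-Z][a-z]?)(\d*)")


class ElementalComposition(Mapping[str, int]):
    """Immutable multiset of atoms, keyed by element symbol.

    Parameters
    ----------
    counts
        Mapping of element symbol to a non-negative integer count.
        Zero counts are dropped; unknown symbols are accepted (the weight
        tables are only consulted when a mass is requested).
    """

    __slots__ = ("_counts",)

    def __init__(self, counts: Mapping[str, int] | None = None, **kwargs: int):
        merged: dict[str, int] = {}
        for source in (counts or {}), kwargs:
            for element, n in source.items():
                if not isinstance(n, int) or isinstance(n, bool):
                    raise TypeError(
                        f"count for {element!r} must be an integer, got {n!r}"
                    )
                if n < 0:
                    raise ValueError(
                        f"count for {element!r} must be >= 0, got {n}"
                    )
                if n:
                    merged[element] = merged.get(element, 0) + n
        object.__setattr__(self, "_counts", dict(sorted(merged.items())))

    # -- construction ----------------------------------------------------

    @classmethod
    def from_formula(cls, formula: str) -> "ElementalComposition":
        """Parse a Hill-notation formula string such as ``"C19H26O3Si"``."""
        counts: dict[str, int] = {}
        pos = 0
        for match in _FORMULA_RE.finditer(formula):
            if match.start() != pos:
                raise ValueError(
                    f"malformed formula {formula!r} at position {pos}"
                )
            pos = match.end()
            element, digits = match.groups()
            counts[element] = counts.get(element, 0) + (int(digits) if digits else 1)
        if pos != len(formula) or (formula and not counts):
            raise ValueError(f"malformed formula {formula!r} at position {pos}")
        return cls(counts)

    # -- Mapping protocol ------------------------------------------------

    def __getitem__(self, element: str) -> int:
        return self._counts.get(element, 0)

    def __iter__(self) -> Iterator[str]:
        return iter(self._counts)

    def __len__(self) -> int:
        return len(self._counts)

    def __contains__(self, element: object) -> bool:
        return element in self._counts

    # -- arithmetic ------------------------------------------------------

    def __add__(self, other: "ElementalComposition") -> "ElementalComposition":
        if not isinstance(other, ElementalComposition):
            return NotImplemented
        counts = dict(self._counts)
        for element, n in other._counts.items():
            counts[element] = counts.get(element, 0) + n
        return ElementalComposition(counts)

    def __sub__(self, other: "ElementalComposition") -> "ElementalComposition":
        if not isinstance(other, ElementalComposition):
            return NotImplemented
        counts = dict(self._counts)
        for element, n in other._counts.items():
            remaining = counts.get(element, 0) - n
            if remaining < 0:
                raise ValueError(
                    f"subtraction would leave {remaining} atoms of {element} "
                    f"({self.hill_formula} - {other.hill_formula})"
                )
            counts[element] = remaining
        return ElementalComposition({e: n for e, n in counts.items() if n})

    def __mul__(self, k: int) -> "ElementalComposition":
        if not isinstance(k, int) or isinstance(k, bool):
            return NotImplemented
        if k < 0:
            raise ValueError(f"scaling factor must be >= 0, got {k}")
        return ElementalComposition({e: n * k for e, n in self._counts.items()})

    __rmul__ = __mul__

    def __eq__(self, other: object) -> bool:
        if isinstance(other, ElementalComposition):
            return self._counts == other._counts
        return NotImplemented

    def __hash__(self) -> int:
        return hash(tuple(self._counts.items()))

    # -- derived quantities ----------------------------------------------

    def _mass(self, table: Mapping[str, float], kind: str) -> float:
        total = 0.0
        for element, n in self._counts.items():
            try:
                total += n * table[element]
            except KeyError:
                raise ValueError(
                    f"no {kind} mass tabulated for element {element!r}"
                ) from None
        return total

    @property
    def average_mass(self) -> float:
        """Average molar mass in g/mol (standard atomic weights)."""
        return self._mass(STANDARD_ATOMIC_WEIGHT, "average")

    @property
    def monoisotopic_mass(self) -> float:
        """Monoisotopic mass in u (principal-isotope masses)."""
        return self._mass(PRINCIPAL_ISOTOPE_MASS, "monoisotopic")

    @property
    def atom_count(self) -> int:
        """Total number of atoms (all elements, hydrogens included)."""
        return sum(self._counts.values())

    @property
    def hill_formula(self) -> str:
        """Hill-notation formula: C, then H, then other elements A-Z."""
        if not self._counts:
            return ""
        elements = sorted(self._counts)
        ordered = [e for e in ("C", "H") if e in self._counts]
        ordered += [e for e in elements if e not in ("C", "H")]
        return "".join(
            f"{e}{self._counts[e]}" if self._counts[e] > 1 else e for e in ordered
        )

    def __repr__(self) -> str:
        return f"ElementalComposition({self.hill_formula!r})"


EMPTY = ElementalComposition()

#: Water, lost in every amide condensation.
WATER = ElementalComposition.from_formula("H2O")
#: Hydrogen chloride, additionally lost when the amine is an ammonium
#: chloride salt.
HYDROGEN_CHLORIDE = ElementalComposition.from_formula("HCl")
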