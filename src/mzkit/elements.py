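"""Static element and isotope data.

Exact isotope masses (Da) and natural abundances for the elements that
occur in small-molecule LC-MS work.  Values follow the IUPAC/NIST atomic
mass evaluation; abundances of each element sum to 1 within 1e-6.

The table is versioned so that persisted results can record which
constants produced them.
"""

from __future__ import annotations

from dataclasses import dataclass

ELEMENT_TABLE_VERSION = "2021-nist-1"

#: symbol -> tuple of (nominal mass number, exact mass in Da, abundance)
_ISOTOPES: dict[str, tuple[tuple[int, float, float], ...]] = {
    "H": ((1, 1.0078250319, 0.999885), (2, 2.0141017780, 0.000115)),
    "C": ((12, 12.0, 0.9893), (13, 13.0033548378, 0.0107)),
    "N": ((14, 14.0030740052, 0.99636), (15, 15.0001088984, 0.00364)),
    "O": (
        (16, 15.9949146221, 0.99757),
        (17, 16.9991315000, 0.00038),
        (18, 17.9991604000, 0.00205),
    ),
    "S": (
        (32, 31.9720706900, 0.9499),
        (33, 32.9714585000, 0.0075),
        (34, 33.9678668300, 0.0425),
        (36, 35.9670808800, 0.0001),
    ),
    "P": ((31, 30.9737615100, 1.0),),
    "F": ((19, 18.9984032200, 1.0),),
    "I": ((127, 126.9044680000, 1.0),),
    "Na": ((23, 22.9897692800, 1.0),),
    "K": (
        (39, 38.9637069000, 0.932581),
        (40, 39.9639986700, 0.000117),
        (41, 40.9618259700, 0.067302),
    ),
    "Cl": ((35, 34.9688527100, 0.7576), (37, 36.9659026000, 0.2424)),
    "Br": ((79, 78.9183376000, 0.5069), (81, 80.9162906000, 0.4931)),
    "Si": (
        (28, 27.9769265300, 0.92223),
        (29, 28.9764947200, 0.04685),
        (30, 29.9737702200, 0.03092),
    ),
    "Se": (
        (74, 73.9224766000, 0.0089),
        (76, 75.9192141000, 0.0937),
        (77, 76.9199146000, 0.0763),
        (78, 77.9173095000, 0.2377),
        (80, 79.9165218000, 0.4961),
        (82, 81.9167000000, 0.0873),
    ),
    "Fe": (
        (54, 53.9396148000, 0.05845),
        (56, 55.9349421000, 0.91754),
        (57, 56.9353987000, 0.02119),
        (58, 57.9332805000, 0.00282),
    ),
    "Mg": (
        (24, 23.9850417000, 0.7899),
        (25, 24.9858370200, 0.1000),
        (26, 25.9825930400, 0.1101),
    ),
    "Ca": (
        (40, 39.9625912000, 0.96941),
        (42, 41.9586183000, 0.00647),
        (43, 42.9587668000, 0.00135),
        (44, 43.9554811000, 0.02086),
        (46, 45.9536928000, 0.00004),
        (48, 47.9525340000, 0.00187),
    ),
    "B": ((10, 10.0129370000, 0.199), (11, 11.0093055000, 0.801)),
    "Li": ((6, 6.0151223000, 0.0759), (7, 7.0160040000, 0.9241)),
    "Zn": (
        (64, 63.9291466000, 0.4917),
        (66, 65.9260368000, 0.2773),
        (67, 66.9271309000, 0.0404),
        (68, 67.9248476000, 0.1845),
        (70, 69.9253250000, 0.0061),
    ),
}

#: electron rest mass in Da
ELECTRON_MASS = 0.000548579909

#: proton mass in Da (mass of 1H minus one electron)
PROTON_MASS = _ISOTOPES["H"][0][1] - ELECTRON_MASS


@dataclass(frozen=True)
class Isotope:
    mass_number: int
    mass: float
    abundance: float


class ElementTable:
    """Lookup of isotopes per element with validated invariants."""

    def __init__(self, isotopes: dict[str, tuple[tuple[int, float, float], ...]] | None = None):
        raw = isotopes if isotopes is not None else _ISOTOPES
        self._elements: dict[str, tuple[Isotope, ...]] = {}
        for symbol, entries in raw.items():
            isos = tuple(Isotope(*e) for e in sorted(entries, key=lambda e: e[0]))
            total = sum(i.abundance for i in isos)
            if abs(total - 1.0) > 1e-6:
                raise ValueError(f"abundances of {symbol} sum to {total}, not 1")
            masses = [i.mass for i in isos]
            if any(b <= a for a, b in zip(masses, masses[1:])):
                raise ValueError(f"isotope masses of {symbol} not strictly increasing")
            self._elements[symbol] = isos

    def __contains__(self, symbol: str) -> bool:
        return symbol in self._elements

    def symbols(self) -> list[str]:
        return sorted(self._elements)

    def isotopes(self, symbol: str) -> tuple[Isotope, ...]:
        try:
            return self._elements[symbol]
        except KeyError:
            raise KeyError(f"unknown element symbol {symbol!r}") from None

    def isotope(self, symbol: str, mass_number: int) -> Isotope:
        for iso in self.isotopes(symbol):
            if iso.mass_number == mass_number:
                return iso
        raise KeyError(f"element {symbol} has no isotope with mass number {mass_number}")

    def most_abundant(self, symbol: str) -> Isotope:
        return max(self.isotopes(symbol), key=lambda i: i.abundance)

    def average_mass(self, symbol: str) -> float:
        return sum(i.mass * i.abundance for i in self.isotopes(symbol))


#: the default table used throughout the package
DEFAULT_ELEMENTS = ElementTable()
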