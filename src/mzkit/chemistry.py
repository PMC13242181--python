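"""Molecular formulas, exact masses, isotope patterns and adducts.

A :class:`MolecularFormula` is an immutable multiset of atoms, where each
atom is either an element at natural isotopic composition (``C``) or an
element fixed to one isotope (``[13]C``).  Formulas support addition and
integer multiplication, monoisotopic and average mass computation, and
isotope-pattern generation by per-element multinomial convolution.

Adducts describe the ionized form of a neutral molecule ([M+H]+,
[2M+Na]+, ...) as a mass delta, a charge and a molecular multiplier; the
delta includes the gained or lost electrons.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from math import comb, sqrt

from .elements import DEFAULT_ELEMENTS, ELECTRON_MASS, ElementTable

__all__ = [
    "MolecularFormula",
    "FormulaError",
    "parse_formula",
    "monoisotopic_mass",
    "average_mass",
    "IsotopePattern",
    "isotope_pattern",
    "Adduct",
    "adduct_mz",
    "default_adducts",
    "load_adducts",
]

AtomKey = tuple[str, int | None]


class FormulaError(ValueError):
    """Raised for malformed formula strings or unknown elements."""


_TOKEN = re.compile(
    r"""
    (?P<isotope>\[\d+\][A-Z][a-z]?)   # [13]C
  | (?P<element>[A-Z][a-z]?)          # C, Na
  | (?P<count>\d+)
  | (?P<open>\()
  | (?P<close>\))
  | (?P<bad>.)
    """,
    re.VERBOSE,
)


class MolecularFormula:
    """Immutable element/isotope composition."""

    __slots__ = ("_comp",)

    def __init__(self, composition: dict[AtomKey, int] | None = None,
                 elements: ElementTable = DEFAULT_ELEMENTS):
        comp: dict[AtomKey, int] = {}
        for (symbol, massnum), count in (composition or {}).items():
            if symbol not in elements:
                raise FormulaError(f"unknown element symbol {symbol!r}")
            if not isinstance(count, int) or count < 1:
                raise FormulaError(f"count for {symbol} must be a positive integer, got {count!r}")
            if massnum is not None:
                elements.isotope(symbol, massnum)  # raises if absent
            comp[(symbol, massnum)] = comp.get((symbol, massnum), 0) + count
        self._comp = comp

    @property
    def composition(self) -> dict[AtomKey, int]:
        return dict(self._comp)

    def __len__(self) -> int:
        return sum(self._comp.values())

    def __bool__(self) -> bool:
        return bool(self._comp)

    def __eq__(self, other) -> bool:
        return isinstance(other, MolecularFormula) and self._comp == other._comp

    def __hash__(self) -> int:
        return hash(frozenset(self._comp.items()))

    def __add__(self, other: "MolecularFormula") -> "MolecularFormula":
        comp = dict(self._comp)
        for key, n in other._comp.items():
            comp[key] = comp.get(key, 0) + n
        return MolecularFormula(comp)

    def __mul__(self, n: int) -> "MolecularFormula":
        if not isinstance(n, int) or n < 1:
            raise FormulaError("formula multiplier must be a positive integer")
        return MolecularFormula({k: v * n for k, v in self._comp.items()})

    __rmul__ = __mul__

    def _sort_key(self, key: AtomKey):
        symbol, massnum = key
        # Hill convention: C, then H, then alphabetical; fixed isotopes
        # sort after the natural element, by mass number.
        rank = {"C": 0, "H": 1}.get(symbol, 2)
        return (rank, symbol, massnum is not None, massnum or 0)

    def as_string(self) -> str:
        parts = []
        for (symbol, massnum) in sorted(self._comp, key=self._sort_key):
            n = self._comp[(symbol, massnum)]
            token = symbol if massnum is None else f"[{massnum}]{symbol}"
            parts.append(token + (str(n) if n > 1 else ""))
        return "".join(parts)

    def __repr__(self) -> str:
        return f"MolecularFormula({self.as_string()!r})"

    def __str__(self) -> str:
        return self.as_string()


def parse_formula(text: str, elements: ElementTable = DEFAULT_ELEMENTS) -> MolecularFormula:
    """Parse ``"C6H12O6"``, ``"(CH2)4"`` or ``"[13]C2C4H13NO2"``.

    Charge notation is rejected: charges belong to :class:`Adduct`.
    """
    tokens = []
    for m in _TOKEN.finditer(text):
        kind = m.lastgroup
        if kind == "bad":
            ch = m.group()
            if ch.isspace():
                continue
            raise FormulaError(f"unexpected character {ch!r} in formula {text!r}")
        tokens.append((kind, m.group()))

    pos = 0

    def parse_group(depth: int) -> dict[AtomKey, int]:
        nonlocal pos
        comp: dict[AtomKey, int] = {}

        def take_count() -> int:
            nonlocal pos
            if pos < len(tokens) and tokens[pos][0] == "count":
                n = int(tokens[pos][1])
                pos += 1
                if n == 0:
                    raise FormulaError(f"count 0 is not allowed in {text!r}")
                return n
            return 1

        while pos < len(tokens):
            kind, tok = tokens[pos]
            if kind == "close":
                if depth == 0:
                    raise FormulaError(f"unbalanced ')' in {text!r}")
                return comp
            pos += 1
            if kind == "open":
                inner = parse_group(depth + 1)
                if pos >= len(tokens) or tokens[pos][0] != "close":
                    raise FormulaError(f"unbalanced '(' in {text!r}")
                pos += 1
                mult = take_count()
                for key, n in inner.items():
                    comp[key] = comp.get(key, 0) + n * mult
            elif kind == "element":
                if tok not in elements:
                    raise FormulaError(f"unknown element symbol {tok!r} in {text!r}")
                n = take_count()
                comp[(tok, None)] = comp.get((tok, None), 0) + n
            elif kind == "isotope":
                mm = re.match(r"\[(\d+)\]([A-Z][a-z]?)", tok)
                assert mm is not None
                massnum, symbol = int(mm.group(1)), mm.group(2)
                if symbol not in elements:
                    raise FormulaError(f"unknown element symbol {symbol!r} in {text!r}")
                try:
                    elements.isotope(symbol, massnum)
                except KeyError as exc:
                    raise FormulaError(str(exc)) from None
                n = take_count()
                key = (symbol, massnum)
                comp[key] = comp.get(key, 0) + n
            elif kind == "count":
                raise FormulaError(f"stray count {tok!r} in {text!r}")
        return comp

    comp = parse_group(0)
    if pos != len(tokens):
        raise FormulaError(f"unbalanced ')' in {text!r}")
    return MolecularFormula(comp, elements)


def _as_formula(f: "MolecularFormula | str",
                elements: ElementTable = DEFAULT_ELEMENTS) -> MolecularFormula:
    return f if isinstance(f, MolecularFormula) else parse_formula(f, elements)


def monoisotopic_mass(f: "MolecularFormula | str",
                      elements: ElementTable = DEFAULT_ELEMENTS) -> float:
    """Sum of most-abundant-isotope masses (fixed isotopes use their own mass)."""
    f = _as_formula(f, elements)
    total = 0.0
    for (symbol, massnum), n in f.composition.items():
        iso = elements.most_abundant(symbol) if massnum is None else elements.isotope(symbol, massnum)
        total += n * iso.mass
    return total


def average_mass(f: "MolecularFormula | str",
                 elements: ElementTable = DEFAULT_ELEMENTS) -> float:
    """Abundance-weighted mean isotope mass summed over atoms."""
    f = _as_formula(f, elements)
    total = 0.0
    for (symbol, massnum), n in f.composition.items():
        if massnum is None:
            total += n * elements.average_mass(symbol)
        else:
            total += n * elements.isotope(symbol, massnum).mass
    return total


# --------------------------------------------------------------------------
# isotope patterns

#: entries closer than this in mass are merged (abundance-weighted)
MERGE_TOL_DA = 1e-9


@dataclass(frozen=True)
class IsotopePattern:
    """Isotopologue distribution: (mass, abundance) sorted by mass.

    Abundances are absolute (they sum to at most 1); ``pruned`` is the
    total abundance discarded below ``threshold`` during convolution, so
    ``sum(abundances) >= 1 - pruned`` always holds.
    """

    entries: tuple[tuple[float, float], ...]
    threshold: float
    pruned: float

    @property
    def masses(self) -> tuple[float, ...]:
        return tuple(m for m, _ in self.entries)

    @property
    def abundances(self) -> tuple[float, ...]:
        return tuple(a for _, a in self.entries)

    def normalized(self) -> "IsotopePattern":
        """Max-normalized copy (base peak abundance = 1)."""
        if not self.entries:
            return self
        top = max(a for _, a in self.entries)
        return IsotopePattern(
            tuple((m, a / top) for m, a in self.entries), self.threshold, self.pruned
        )


def _merge(entries: list[tuple[float, float]]) -> list[tuple[float, float]]:
    entries.sort(key=lambda e: e[0])
    out: list[tuple[float, float]] = []
    for m, a in entries:
        if out and m - out[-1][0] <= MERGE_TOL_DA:
            pm, pa = out[-1]
            tot = pa + a
            out[-1] = ((pm * pa + m * a) / tot, tot)
        else:
            out.append((m, a))
    return out


def _convolve(a: list[tuple[float, float]], b: list[tuple[float, float]],
              threshold: float) -> tuple[list[tuple[float, float]], float]:
    prod = [(ma + mb, aa * ab) for ma, aa in a for mb, ab in b]
    merged = _merge(prod)
    kept = [(m, ab) for m, ab in merged if ab >= threshold]
    pruned = sum(ab for _, ab in merged) - sum(ab for _, ab in kept)
    return kept, pruned


def _element_power(isotopes, n: int, threshold: float):
    """Distribution of n atoms of one element, by sequential convolution.

    Convolving with the unit-sum single-atom distribution keeps the
    pruned-abundance bookkeeping exact at every step, so the
    conservation invariant (sum >= 1 - pruned) is checkable.
    """
    base = [(iso.mass, iso.abundance) for iso in isotopes]
    result: list[tuple[float, float]] = [(0.0, 1.0)]
    pruned = 0.0
    for _ in range(n):
        result, p = _convolve(result, base, threshold)
        pruned += p
    return result, pruned


def isotope_pattern(f: "MolecularFormula | str", min_abundance: float = 1e-6,
                    elements: ElementTable = DEFAULT_ELEMENTS) -> IsotopePattern:
    """Isotopologue distribution of a formula.

    Per-element multinomial distributions are convolved over the
    composition; entries with abundance below ``min_abundance`` are pruned
    after each convolution step and their total mass tracked.  Entries
    within 1e-9 Da are merged by abundance-weighted mass.
    """
    if not 0.0 <= min_abundance < 1.0:
        raise ValueError("min_abundance must be in [0, 1)")
    f = _as_formula(f, elements)
    acc: list[tuple[float, float]] = [(0.0, 1.0)]
    pruned = 0.0
    # deterministic element order; the result is order-independent anyway
    for (symbol, massnum) in sorted(f.composition, key=lambda k: (k[0], k[1] or 0)):
        n = f.composition[(symbol, massnum)]
        if massnum is not None:
            iso = elements.isotope(symbol, massnum)
            part = [(n * iso.mass, 1.0)]
        else:
            part, p = _element_power(elements.isotopes(symbol), n, min_abundance)
            pruned += p
        acc, p = _convolve(acc, part, min_abundance)
        pruned += p
    return IsotopePattern(tuple(acc), min_abundance, pruned)


# --------------------------------------------------------------------------
# adducts

@dataclass(frozen=True)
class Adduct:
    """Ionized form of a neutral molecule.

    ``mass_delta`` already accounts for gained/lost electrons, so
    m/z = (multiplier * M + mass_delta) / |charge|.
    """

    name: str
    mass_delta: float
    charge: int
    multiplier: int = 1

    def __post_init__(self):
        if self.charge == 0:
            raise ValueError("adduct charge must be non-zero")
        if self.multiplier < 1:
            raise ValueError("adduct multiplier must be >= 1")


def adduct_mz(neutral_monoisotopic_mass: float, adduct: Adduct) -> float:
    """m/z of the adduct ion of a neutral molecule of the given mass."""
    if neutral_monoisotopic_mass <= 0:
        raise ValueError("neutral mass must be positive")
    return (adduct.multiplier * neutral_monoisotopic_mass + adduct.mass_delta) / abs(adduct.charge)


def _delta(gain: str = "", loss: str = "", charge: int = 1) -> float:
    d = -charge * ELECTRON_MASS
    if gain:
        d += monoisotopic_mass(gain)
    if loss:
        d -= monoisotopic_mass(loss)
    return d


def default_adducts() -> list[Adduct]:
    """Common ESI adducts with deltas derived from the element table."""
    spec = [
        # name, gained, lost, charge, multiplier
        ("[M+H]+", "H", "", 1, 1),
        ("[M+Na]+", "Na", "", 1, 1),
        ("[M+K]+", "K", "", 1, 1),
        ("[M+NH4]+", "NH4", "", 1, 1),
        ("[M+H-H2O]+", "H", "H2O", 1, 1),
        ("[M+CH3OH+H]+", "CH4OH", "", 1, 1),
        ("[M+CH3CN+H]+", "C2H4N", "", 1, 1),
        ("[M]+", "", "", 1, 1),
        ("[M+2H]2+", "H2", "", 2, 1),
        ("[M+H+Na]2+", "HNa", "", 2, 1),
        ("[M+2Na]2+", "Na2", "", 2, 1),
        ("[2M+H]+", "H", "", 1, 2),
        ("[2M+Na]+", "Na", "", 1, 2),
        ("[2M+NH4]+", "NH4", "", 1, 2),
        ("[M-H]-", "", "H", -1, 1),
        ("[M+Cl]-", "Cl", "", -1, 1),
        ("[M+HCOO]-", "CHO2", "", -1, 1),
        ("[M+CH3COO]-", "C2H3O2", "", -1, 1),
        ("[M-H2O-H]-", "", "H3O", -1, 1),
        ("[M-2H]2-", "", "H2", -2, 1),
        ("[2M-H]-", "", "H", -1, 2),
    ]
    return [Adduct(name, _delta(g, l, z), z, mult) for name, g, l, z, mult in spec]


def load_adducts(path, delimiter: str = ",") -> list[Adduct]:
    """Load an adduct library from delimited text.

    Expected header: ``name, delta_da, charge, multiplier``.
    """
    import csv

    adducts = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter=delimiter)
        required = {"name", "delta_da", "charge", "multiplier"}
        if reader.fieldnames is None or not required <= set(reader.fieldnames):
            raise ValueError(f"adduct file must have columns {sorted(required)}")
        for row in reader:
            adducts.append(
                Adduct(row["name"], float(row["delta_da"]), int(row["charge"]),
                       int(row["multiplier"]))
            )
    return adducts


def find_adduct(name: str, library: list[Adduct] | None = None) -> Adduct:
    for a in library if library is not None else default_adducts():
        if a.name == name:
            return a
    raise KeyError(f"unknown adduct {name!r}")
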