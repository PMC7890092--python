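"""Molecular formula arithmetic and the biotransformation catalog.

Monoisotopic masses underpin every mass delta used in CSPP (candidate
substrate-product pair) analysis: a biotransformation such as a
methylation (+CH2, 14.016 Da) or a hexosylation (+C6H10O5, 162.052 Da)
is observed in LC-MS data as a characteristic difference between the
m/z values of two features.  This module provides Hill-notation formula
parsing, exact monoisotopic mass computation, ion/neutral conversions
for singly (de)protonated species, and a curated default catalog of 34
well-known biotransformations with their chromatographic elution-order
rules.
"""
from __future__ import annotations

import csv
import re
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional

__all__ = [
    "ISOTOPE_MASSES",
    "PROTON_MASS",
    "C13_C12_DELTA",
    "Formula",
    "Biotransformation",
    "parse_formula",
    "monoisotopic_mass",
    "apply_formula_delta",
    "neutral_mass",
    "ion_mz",
    "default_catalog",
    "isotope_entry",
    "read_catalog",
    "write_catalog",
    "CATALOG_COLUMNS",
]

# Monoisotopic masses of the lightest (most abundant) isotope, Da.
# CODATA/AME-derived values, >= 9 decimal places; 12C defines the scale.
ISOTOPE_MASSES: Dict[str, float] = {
    "H": 1.007825032,
    "C": 12.0,
    "N": 14.003074005,
    "O": 15.994914620,
    "P": 30.973761998,
    "S": 31.972071174,
    "Na": 22.989769282,
    "K": 38.963706487,
    "Cl": 34.968852682,
    "F": 18.998403163,
}

#: Mass of the proton (Da); the difference between [M+H]+ / [M-H]- ions
#: and the neutral molecule M.
PROTON_MASS: float = 1.007276467

#: Mass gap between the 13C and 12C isotopes (Da); natural-isotope
#: feature pairs differ by exactly this amount.
C13_C12_DELTA: float = 13.003354835 - 12.0

_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


class UnknownElementError(ValueError):
    """Raised when a formula names an element without a tabulated mass."""


@dataclass(frozen=True)
class Formula:
    """An elemental composition (element symbol -> count).

    Immutable; supports ``+`` and ``-`` (element-wise, ``-`` raises if any
    count would go negative) and hashing, so formulas can key dictionaries
    during annotation propagation.
    """

    element_counts: Mapping[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        clean = {}
        for sym, n in self.element_counts.items():
            if sym not in ISOTOPE_MASSES:
                raise UnknownElementError(f"unknown element symbol: {sym!r}")
            n = int(n)
            if n < 0:
                raise ValueError(f"negative count for element {sym}: {n}")
            if n > 0:
                clean[sym] = n
        object.__setattr__(self, "element_counts", dict(clean))

    @property
    def mass(self) -> float:
        return monoisotopic_mass(self)

    def __add__(self, other: "Formula") -> "Formula":
        return apply_formula_delta(self, other, "add")

    def __sub__(self, other: "Formula") -> "Formula":
        return apply_formula_delta(self, other, "remove")

    def __bool__(self) -> bool:
        return bool(self.element_counts)

    def __hash__(self) -> int:
        return hash(frozenset(self.element_counts.items()))

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Formula):
            return NotImplemented
        return self.element_counts == other.element_counts

    def hill(self) -> str:
        """Format in Hill order (C, H, then alphabetical)."""
        counts = dict(self.element_counts)
        parts: List[str] = []
        order: List[str] = []
        if "C" in counts:
            order.append("C")
            if "H" in counts:
                order.append("H")
            order.extend(sorted(s for s in counts if s not in ("C", "H")))
        else:
            order.extend(sorted(counts))
        for sym in order:
            n = counts[sym]
            parts.append(sym if n == 1 else f"{sym}{n}")
        return "".join(parts)

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.hill()


def parse_formula(text: str) -> Formula:
    """Parse a Hill-notation formula string, e.g. ``"C6H10O5"``.

    Counts of 1 may be omitted; element symbols are case-sensitive
    (``Co`` is cobalt-like two-letter parsing, ``CO`` is carbon+oxygen).
    The empty string parses to the empty formula (mass 0).
    """
    text = text.strip()
    if not text:
        return Formula({})
    counts: Dict[str, int] = {}
    pos = 0
    for m in _FORMULA_TOKEN.finditer(text):
        if m.start() != pos:
            raise ValueError(f"cannot parse formula {text!r} at position {pos}")
        sym, num = m.group(1), m.group(2)
        if sym not in ISOTOPE_MASSES:
            raise UnknownElementError(f"unknown element symbol: {sym!r} in {text!r}")
        counts[sym] = counts.get(sym, 0) + (int(num) if num else 1)
        pos = m.end()
    if pos != len(text):
        raise ValueError(f"cannot parse formula {text!r} at position {pos}")
    return Formula(counts)


def monoisotopic_mass(f: Formula) -> float:
    """Sum of count x tabulated monoisotopic mass over all elements (Da)."""
    return sum(n * ISOTOPE_MASSES[sym] for sym, n in f.element_counts.items())


def apply_formula_delta(base: Formula, delta: Formula, direction: str) -> Formula:
    """Element-wise add or remove ``delta`` from ``base``.

    ``direction`` is ``"add"`` or ``"remove"``.  Removing more atoms of an
    element than the base contains raises, naming the deficient element.
    """
    if direction not in ("add", "remove"):
        raise ValueError(f"direction must be 'add' or 'remove', got {direction!r}")
    counts = dict(base.element_counts)
    for sym, n in delta.element_counts.items():
        if direction == "add":
            counts[sym] = counts.get(sym, 0) + n
        else:
            have = counts.get(sym, 0)
            if have < n:
                raise ValueError(
                    f"cannot remove {delta.hill()} from {base.hill()}: "
                    f"insufficient {sym} ({have} < {n})"
                )
            counts[sym] = have - n
    return Formula(counts)


def neutral_mass(mz: float, polarity: str, adduct: str = None) -> float:
    """Neutral monoisotopic mass of a singly (de)protonated ion.

    Negative mode assumes [M-H]- (``mz + proton``), positive mode [M+H]+
    (``mz - proton``).  Only deprotonated/protonated adducts are supported.
    """
    if polarity not in ("neg", "pos"):
        raise ValueError(f"polarity must be 'neg' or 'pos', got {polarity!r}")
    if adduct is None:
        adduct = "deprotonated" if polarity == "neg" else "protonated"
    if polarity == "neg":
        if adduct != "deprotonated":
            raise ValueError(f"unsupported adduct for negative mode: {adduct!r}")
        return mz + PROTON_MASS
    if adduct != "protonated":
        raise ValueError(f"unsupported adduct for positive mode: {adduct!r}")
    return mz - PROTON_MASS


def ion_mz(neutral: float, polarity: str) -> float:
    """Inverse of :func:`neutral_mass` for [M-H]-/[M+H]+ ions."""
    if polarity == "neg":
        return neutral - PROTON_MASS
    if polarity == "pos":
        return neutral + PROTON_MASS
    raise ValueError(f"polarity must be 'neg' or 'pos', got {polarity!r}")


# Biotransformation classes: 'decoration' covers true enzymatic additions
# on a core structure; 'structural' covers mass gaps between two distinct
# core structures; 'core_transfer' covers coupling of a whole core unit
# onto another molecule; 'multiple_options' covers deltas explainable by
# several distinct reaction combinations.
BT_CLASSES = ("decoration", "structural", "core_transfer", "multiple_options")
_CLASS_FROM_INT = {1: "decoration", 2: "structural", 3: "core_transfer", 4: "multiple_options"}
_CLASS_TO_INT = {v: k for k, v in _CLASS_FROM_INT.items()}

RT_RULES = ("product_earlier", "product_later", "any")


@dataclass(frozen=True)
class Biotransformation:
    """A named mass delta attributed to a (bio)chemical conversion.

    Exactly one of ``formula`` / ``raw_delta`` is set.  ``rt_rule``
    encodes the expected reversed-phase elution order of the product
    relative to the substrate: adding a polar moiety (e.g. a sugar)
    makes the product elute earlier; adding a hydrophobic moiety makes
    it elute later.
    """

    name: str
    short_code: str
    formula: Optional[Formula] = None
    raw_delta: Optional[float] = None
    btclass: str = "decoration"
    rt_rule: str = "any"

    def __post_init__(self) -> None:
        if (self.formula is None) == (self.raw_delta is None):
            raise ValueError(
                f"{self.short_code}: exactly one of formula/raw_delta must be set"
            )
        if self.btclass not in BT_CLASSES:
            raise ValueError(f"{self.short_code}: unknown class {self.btclass!r}")
        if self.rt_rule not in RT_RULES:
            raise ValueError(f"{self.short_code}: unknown rt_rule {self.rt_rule!r}")
        if self.delta_mass <= 0:
            raise ValueError(f"{self.short_code}: delta mass must be positive")

    @property
    def delta_mass(self) -> float:
        if self.formula is not None:
            return monoisotopic_mass(self.formula)
        return float(self.raw_delta)


def _bt(code: str, name: str, formula: str, cls: int, rt: str) -> Biotransformation:
    return Biotransformation(
        name=name,
        short_code=code,
        formula=parse_formula(formula),
        btclass=_CLASS_FROM_INT[cls],
        rt_rule=rt,
    )


# Default catalog of 34 well-known biotransformations (single conversions).
# Elution-order rules follow reversed-phase intuition: polar additions
# (sugars, oxygenations, hydrations, organic acids) shift the product to
# earlier retention times; hydrophobic additions (alkyl groups, aromatic
# acyl/core couplings) shift it later; composite/ambiguous deltas carry
# no constraint. The rules are data and can be overridden via a user
# catalog file.
_DEFAULT_CATALOG: List[Biotransformation] = [
    _bt("RED", "reduction", "H2", 1, "product_later"),
    _bt("MET", "methylation", "CH2", 1, "product_later"),
    _bt("OXY", "oxygenation", "O", 1, "product_earlier"),
    _bt("HYD", "hydration", "H2O", 1, "product_earlier"),
    _bt("ETY", "ethyne addition", "C2H2", 1, "product_later"),
    _bt("ETH", "ethylene addition", "C2H4", 2, "product_later"),
    _bt("MOX", "methoxylation (oxygenation + methylation)", "CH2O", 1, "any"),
    _bt("ACE", "acetylation", "C2H2O", 1, "product_later"),
    _bt("CAR", "carboxylation", "CO2", 1, "product_earlier"),
    _bt("FORM", "formic acid addition", "CH2O2", 1, "product_earlier"),
    _bt("CRC60", "cross ring cleavage (C2H4O2)", "C2H4O2", 1, "product_earlier"),
    _bt("GLY", "glycerol coupling", "C3H6O2", 1, "product_earlier"),
    _bt("GLC", "glyceric acid coupling", "C3H4O3", 1, "product_earlier"),
    _bt("CRC90", "cross ring cleavage (C3H6O3)", "C3H6O3", 1, "product_earlier"),
    _bt("QUL", "phenol coupling", "C6H4O", 3, "product_later"),
    _bt("BEN", "benzoylation", "C7H4O", 3, "product_later"),
    _bt("HQL", "quinone coupling", "C6H4O2", 2, "product_later"),
    _bt("MEV", "mevalonolactone coupling", "C6H8O2", 1, "product_later"),
    _bt("PHA", "phenylacetyl coupling", "C8H6O", 3, "product_later"),
    _bt("HBEN", "hydroxybenzoylation", "C7H4O2", 3, "product_later"),
    _bt("DHBA", "dihydroxybenzyl alcohol coupling", "C7H6O2", 3, "product_later"),
    _bt("PEN", "pentose coupling", "C5H8O4", 1, "product_earlier"),
    _bt("HADI", "hydroxyadipic acid coupling", "C6H8O4", 1, "product_earlier"),
    _bt("RHA", "deoxyhexosylation", "C6H10O4", 1, "product_earlier"),
    _bt("VAN", "vanillic acid coupling", "C8H6O3", 3, "product_later"),
    _bt("HEX", "hexosylation", "C6H10O5", 1, "product_earlier"),
    _bt("QUI", "quinic acid coupling", "C7H10O5", 1, "product_earlier"),
    _bt("FA", "feruloylation", "C10H8O3", 3, "product_later"),
    _bt("GUN8", "condensed guaiacyl coupling", "C10H10O3", 3, "product_later"),
    _bt("SYR", "syringic acid coupling", "C9H8O4", 3, "product_later"),
    _bt("GUN4", "non-condensed guaiacyl coupling", "C10H12O4", 3, "product_later"),
    _bt("SIN", "sinapic acid coupling", "C11H10O4", 3, "product_later"),
    _bt("SUN8", "condensed syringyl coupling", "C11H12O4", 3, "product_later"),
    _bt("SUN4", "non-condensed syringyl coupling", "C11H14O5", 3, "product_later"),
]


def default_catalog() -> List[Biotransformation]:
    """The built-in catalog of 34 well-known single-conversion deltas.

    The exact membership is a documented reconstruction assembled from
    commonly annotated plant biotransformations (reductions, alkylations,
    oxygenations, acylations, glycosylations, phenolic couplings); users
    with a different curated set can load it via :func:`read_catalog`.
    """
    return list(_DEFAULT_CATALOG)


def isotope_entry() -> Biotransformation:
    """Natural 13C isotope spacing (1.003 Da) as a catalog entry.

    Not part of the default catalog of biochemical conversions; add it
    when building networks if the 13C isotopologue sub-network should be
    represented (or stripped) explicitly.
    """
    return Biotransformation(
        name="13C natural isotope",
        short_code="13C",
        raw_delta=C13_C12_DELTA,
        btclass="multiple_options",
        rt_rule="any",
    )


CATALOG_COLUMNS = ["short", "name", "formula", "raw_delta", "class", "rt_rule"]


def read_catalog(path) -> List[Biotransformation]:
    """Read a biotransformation catalog from delimited text.

    Header: ``short,name,formula,raw_delta,class,rt_rule``; exactly one of
    formula (Hill notation) / raw_delta per row; class in {1,2,3,4};
    duplicate short codes are rejected.
    """
    out: List[Biotransformation] = []
    seen = set()
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        missing = set(CATALOG_COLUMNS) - set(reader.fieldnames or [])
        if missing:
            raise ValueError(f"catalog missing columns: {sorted(missing)}")
        for row in reader:
            code = row["short"].strip()
            if code in seen:
                raise ValueError(f"duplicate short_code in catalog: {code!r}")
            seen.add(code)
            formula_txt = (row["formula"] or "").strip()
            raw_txt = (row["raw_delta"] or "").strip()
            cls = row["class"].strip()
            out.append(
                Biotransformation(
                    name=row["name"].strip(),
                    short_code=code,
                    formula=parse_formula(formula_txt) if formula_txt else None,
                    raw_delta=float(raw_txt) if raw_txt else None,
                    btclass=_CLASS_FROM_INT[int(cls)] if cls.isdigit() else cls,
                    rt_rule=row["rt_rule"].strip() or "any",
                )
            )
    return out


def write_catalog(catalog: Iterable[Biotransformation], path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(CATALOG_COLUMNS)
        for bt in catalog:
            writer.writerow(
                [
                    bt.short_code,
                    bt.name,
                    bt.formula.hill() if bt.formula is not None else "",
                    "" if bt.raw_delta is None else repr(bt.raw_delta),
                    _CLASS_TO_INT[bt.btclass],
                    bt.rt_rule,
                ]
            )
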