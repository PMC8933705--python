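"""Glycan composition algebra: residues, monoisotopic masses, adducts, parsing.

A glycan composition is a residue-class count vector (e.g. ``HexNAc(2)Hex(8)``);
no topology or linkage information is carried. Residue classes follow the
conventions of N-glycoproteomics open searches: HexNAc, Hex, Fuc (deoxyhexose),
NeuAc, NeuGc, and the phospho/sulfo modifications of glycans.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

__all__ = [
    "RESIDUE_MASSES",
    "RESIDUE_ORDER",
    "PROTON_MASS",
    "Adduct",
    "AMMONIUM",
    "GlycanComposition",
    "DatabaseEntry",
    "GlycanDatabase",
    "parse_composition",
    "composition_mass",
    "load_glycan_database",
]

#: CODATA monoisotopic atomic masses (Da).
_ATOM = {
    "C": 12.0,
    "H": 1.00782503207,
    "N": 14.0030740048,
    "O": 15.9949146196,
    "P": 30.97376163,
    "S": 31.97207100,
}


def _formula_mass(formula: dict[str, int]) -> float:
    return sum(_ATOM[el] * n for el, n in formula.items())


#: Monoisotopic residue masses in Da, computed from atomic monoisotopic masses
#: so the NeuGc+Fuc == NeuAc+Hex isobaric identity is exact (both are
#: C17H27NO13 in residue form).
RESIDUE_MASSES: dict[str, float] = {
    "HexNAc": _formula_mass({"C": 8, "H": 13, "N": 1, "O": 5}),   # 203.079373
    "Hex": _formula_mass({"C": 6, "H": 10, "O": 5}),              # 162.052824
    "Fuc": _formula_mass({"C": 6, "H": 10, "O": 4}),              # 146.057909
    "NeuAc": _formula_mass({"C": 11, "H": 17, "N": 1, "O": 8}),   # 291.095417
    "NeuGc": _formula_mass({"C": 11, "H": 17, "N": 1, "O": 9}),   # 307.090331
    "Phospho": _formula_mass({"H": 1, "P": 1, "O": 3}),           # 79.966331
    "Sulfo": _formula_mass({"S": 1, "O": 3}),                     # 79.956815
}

#: Canonical residue order used in composition strings.
RESIDUE_ORDER: tuple[str, ...] = (
    "HexNAc",
    "Hex",
    "Fuc",
    "NeuAc",
    "NeuGc",
    "Phospho",
    "Sulfo",
)

PROTON_MASS = 1.00727646688


class CompositionParseError(ValueError):
    """Raised when a composition string cannot be parsed."""


@dataclass(frozen=True)
class Adduct:
    """A noncovalent mass addition that contributes no fragment ions.

    The canonical example is an ammonium ion replacing a proton
    (+NH3, +17.026549 Da): intact mass changes, Y/oxonium ions do not.
    """

    name: str
    mass_delta: float
    max_count: int = 1

    def __post_init__(self) -> None:
        if self.max_count < 0:
            raise ValueError("adduct max_count must be >= 0")


AMMONIUM = Adduct("ammonium", 17.026549, max_count=1)

#: Named adducts accepted on the command line.
KNOWN_ADDUCTS: dict[str, float] = {"ammonium": 17.026549}


@dataclass(frozen=True)
class GlycanComposition:
    """Residue-class count vector with monoisotopic mass.

    Counts are stored sparsely; absent residues count zero. Instances are
    hashable and compare by counts, so they can key dictionaries and sets.
    """

    counts: tuple[tuple[str, int], ...]

    def __init__(self, counts: Mapping[str, int] | Iterable[tuple[str, int]]):
        items = dict(counts)
        for name, count in items.items():
            if name not in RESIDUE_MASSES:
                raise CompositionParseError(f"unknown residue {name!r}")
            if count < 0:
                raise CompositionParseError(
                    f"negative count {count} for residue {name}"
                )
        cleaned = tuple(
            (name, items[name]) for name in RESIDUE_ORDER if items.get(name, 0) > 0
        )
        object.__setattr__(self, "counts", cleaned)

    def __getitem__(self, residue: str) -> int:
        return dict(self.counts).get(residue, 0)

    def __bool__(self) -> bool:
        return bool(self.counts)

    def __str__(self) -> str:
        return self.canonical_string

    @property
    def canonical_string(self) -> str:
        """Text form ``HexNAc(2)Hex(8)`` in canonical residue order."""
        return "".join(f"{name}({count})" for name, count in self.counts)

    @property
    def mass(self) -> float:
        """Monoisotopic mass in Da (sum of residue masses)."""
        return sum(RESIDUE_MASSES[name] * count for name, count in self.counts)

    def total_residues(self) -> int:
        return sum(count for _, count in self.counts)

    def add(self, other: "GlycanComposition") -> "GlycanComposition":
        merged = dict(self.counts)
        for name, count in other.counts:
            merged[name] = merged.get(name, 0) + count
        return GlycanComposition(merged)

    def contains(self, other: "GlycanComposition") -> bool:
        """True if ``other`` is componentwise <= ``self``."""
        return all(self[name] >= count for name, count in other.counts)


_TOKEN_RE = re.compile(r"([A-Za-z]+)\((-?\d+)\)")

# Accepted residue-name aliases in input files (underscore dialect etc.).
_RESIDUE_ALIASES = {
    "hexnac": "HexNAc",
    "hex": "Hex",
    "fuc": "Fuc",
    "dhex": "Fuc",
    "neuac": "NeuAc",
    "neugc": "NeuGc",
    "phospho": "Phospho",
    "phosphate": "Phospho",
    "sulfo": "Sulfo",
    "sulfate": "Sulfo",
}


def _canonical_residue(name: str) -> str:
    try:
        return _RESIDUE_ALIASES[name.lower()]
    except KeyError:
        raise CompositionParseError(f"unknown residue name {name!r}") from None


def parse_composition(text: str) -> GlycanComposition:
    """Parse a composition string such as ``"HexNAc(2)Hex(8)"``.

    The underscore dialect ``"HexNAc-4_Hex-5_NeuAc-1"`` is also accepted.
    Raises :class:`CompositionParseError` on malformed tokens, unknown
    residue names, or negative counts. The empty composition parses (it is
    a valid algebraic identity element) but is rejected as a database entry.
    """
    text = text.strip()
    if not text:
        return GlycanComposition({})
    counts: dict[str, int] = {}
    if "(" in text:
        pos = 0
        for match in _TOKEN_RE.finditer(text):
            if match.start() != pos:
                raise CompositionParseError(
                    f"malformed composition near {text[pos:match.start()]!r}"
                )
            pos = match.end()
            name = _canonical_residue(match.group(1))
            count = int(match.group(2))
            if count < 0:
                raise CompositionParseError(
                    f"negative count in token {match.group(0)!r}"
                )
            counts[name] = counts.get(name, 0) + count
        if pos != len(text):
            raise CompositionParseError(f"malformed composition near {text[pos:]!r}")
    else:
        # underscore dialect: HexNAc-4_Hex-5_NeuAc-1
        for token in text.split("_"):
            if not token:
                continue
            name_part, sep, count_part = token.rpartition("-")
            if not sep or not count_part.lstrip("-").isdigit():
                raise CompositionParseError(f"malformed token {token!r}")
            name = _canonical_residue(name_part)
            count = int(count_part)
            if count < 0:
                raise CompositionParseError(f"negative count in token {token!r}")
            counts[name] = counts.get(name, 0) + count
    return GlycanComposition(counts)


def composition_mass(
    comp: GlycanComposition, adducts: Sequence[Adduct] = ()
) -> float:
    """Intact monoisotopic mass of a composition plus any adducts, in Da."""
    return comp.mass + sum(a.mass_delta for a in adducts)


@dataclass(frozen=True)
class DatabaseEntry:
    """One searchable glycan form: a composition with a specific adduct count."""

    composition: GlycanComposition
    adducts: tuple[Adduct, ...]
    intact_mass: float

    @property
    def label(self) -> str:
        s = self.composition.canonical_string
        if self.adducts:
            s += "".join(f"+{a.name}" for a in self.adducts)
        return s


@dataclass
class GlycanDatabase:
    """A deduplicated list of searchable glycan forms.

    ``n_unique_mass_offsets`` counts distinct intact masses rounded to two
    decimals — the number of mass offsets an open search would consider.
    """

    entries: list[DatabaseEntry]
    source_path: str = "<memory>"

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def n_unique_mass_offsets(self) -> int:
        return len({round(e.intact_mass, 2) for e in self.entries})

    @property
    def compositions(self) -> list[GlycanComposition]:
        seen: dict[GlycanComposition, None] = {}
        for e in self.entries:
            seen.setdefault(e.composition, None)
        return list(seen)


def build_database(
    compositions: Iterable[GlycanComposition],
    adduct: Adduct | None = None,
    max_adducts: int = 0,
    source_path: str = "<memory>",
) -> GlycanDatabase:
    """Expand compositions into entries with 0..max_adducts adducts each."""
    entries: list[DatabaseEntry] = []
    seen: set[tuple[GlycanComposition, int]] = set()
    for comp in compositions:
        if not comp:
            continue
        for k in range(0, max_adducts + 1):
            if k > 0 and adduct is None:
                break
            key = (comp, k)
            if key in seen:
                continue
            seen.add(key)
            ads = tuple([adduct] * k) if adduct is not None else ()
            entries.append(
                DatabaseEntry(comp, ads, composition_mass(comp, ads))
            )
    if not entries:
        raise ValueError("glycan database contains no valid entries")
    return GlycanDatabase(entries, source_path)


def write_glycan_list(
    compositions: Iterable[GlycanComposition], path: str | Path
) -> None:
    """Write a glycan list file (one canonical composition per line)."""
    with open(path, "w", encoding="utf-8") as fh:
        for comp in compositions:
            fh.write(comp.canonical_string + "\n")


def load_glycan_database(
    path: str | Path,
    adduct: Adduct | None = None,
    max_adducts: int = 0,
) -> GlycanDatabase:
    """Load a glycan list: one composition per line, '#' comments allowed.

    Duplicate compositions collapse to one entry (per adduct form). Raises
    ``ValueError`` if no valid entries remain after parsing.
    """
    path = Path(path)
    comps: list[GlycanComposition] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            # allow "name%mass" dialect: mass part ignored, name parsed
            if "%" in line:
                line = line.split("%", 1)[0].strip()
            try:
                comp = parse_composition(line)
            except CompositionParseError as exc:
                raise CompositionParseError(
                    f"{path}:{lineno}: {exc}"
                ) from exc
            if not comp:
                raise CompositionParseError(
                    f"{path}:{lineno}: empty composition is not a valid glycan"
                )
            comps.append(comp)
    return build_database(comps, adduct, max_adducts, source_path=str(path))
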