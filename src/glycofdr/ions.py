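"""Theoretical Y-ion and oxonium-ion enumeration and spectrum matching.

Y-ions retain the intact peptide plus a trimmed glycan remnant and are stored
as the neutral remnant mass to be added to the peptide mass. Oxonium ions are
low-mass glycan fragment cations diagnostic of specific residue classes and
are stored as singly protonated m/z. Y-ions fall in two scoring categories
(fucose-containing or not); oxonium ions in five (NeuAc, NeuGc, Fucose,
Phosphate, Sulfate), each active only when the defining residue is present.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .composition import PROTON_MASS, GlycanComposition
from .spectra import SpectrumPeaks

__all__ = [
    "TheoreticalIon",
    "IonMatch",
    "DEFAULT_OXONIUM_TABLE",
    "OXONIUM_CATEGORY_RESIDUES",
    "enumerate_y_ions",
    "enumerate_oxonium_ions",
    "match_ions",
]

Y_NONFUCOSE = "nonfucose"
Y_FUCOSE = "fucose"

#: Oxonium scoring category -> the residue whose presence activates it.
OXONIUM_CATEGORY_RESIDUES: dict[str, str] = {
    "NeuAc": "NeuAc",
    "NeuGc": "NeuGc",
    "Fucose": "Fuc",
    "Phosphate": "Phospho",
    "Sulfate": "Sulfo",
}

#: Default diagnostic oxonium ions per category: (m/z, expected intensity as
#: fraction of the spectrum base peak). User-overridable via the config file.
DEFAULT_OXONIUM_TABLE: dict[str, tuple[tuple[float, float], ...]] = {
    "NeuAc": ((274.0921, 0.25), (292.1027, 0.25), (657.2349, 0.25)),
    "NeuGc": ((290.0870, 0.25), (308.0976, 0.25), (673.2298, 0.25)),
    "Fucose": ((350.1446, 0.25), (512.1974, 0.25)),
    "Phosphate": ((243.0264, 0.25), (405.0793, 0.25)),
    "Sulfate": ((284.0440, 0.25), (446.0968, 0.25)),
}


@dataclass(frozen=True)
class TheoreticalIon:
    """One theoretical fragment ion of a glycan candidate.

    ``value`` is the neutral remnant mass for Y-ions (added to the peptide
    mass before protonation) or the singly protonated m/z for oxonium ions.
    ``key`` identifies the ion when deciding which ions two candidates share;
    decoy ions carry shifted values and therefore never collide with targets.
    """

    kind: str  # "Y" | "oxonium"
    category: str
    value: float
    expected_intensity: float = 0.25
    label: str = ""

    @property
    def key(self) -> tuple[str, float]:
        return (self.kind, round(self.value, 4))

    def shifted(self, delta: float) -> "TheoreticalIon":
        return TheoreticalIon(
            self.kind,
            self.category,
            self.value + delta,
            self.expected_intensity,
            self.label,
        )


@dataclass(frozen=True)
class IonMatch:
    """Result of searching one theoretical ion against a spectrum."""

    ion: TheoreticalIon
    matched: bool
    observed_intensity: float = 0.0  # fraction of spectrum base peak
    matched_charge: int = 0


def enumerate_y_ions(
    comp: GlycanComposition, max_ions: int = 24
) -> list[TheoreticalIon]:
    """Enumerate the Y-ion trimming ladder of a composition.

    The ladder reflects sequential trimming of an N-glycan from the
    nonreducing end: HexNAc(1), HexNAc(2), then HexNAc(2)Hex(1..h) up to the
    composition's Hex count. When the composition has more than two HexNAc
    and at least three Hex (antenna branches beyond the trimannosyl core),
    HexNAc(k)Hex(3) ions for k = 3..HexNAc count are added. Compositions
    containing Fuc additionally emit each ladder member plus one Fuc in the
    fucose category. Y0 (bare peptide) is excluded; sub-compositions never
    exceed the candidate's residue counts; the list is capped at ``max_ions``.
    """
    n_hexnac = comp["HexNAc"]
    n_hex = comp["Hex"]
    ladder: list[GlycanComposition] = []
    if n_hexnac >= 1:
        ladder.append(GlycanComposition({"HexNAc": 1}))
    if n_hexnac >= 2:
        ladder.append(GlycanComposition({"HexNAc": 2}))
        for h in range(1, n_hex + 1):
            ladder.append(GlycanComposition({"HexNAc": 2, "Hex": h}))
    if n_hexnac > 2 and n_hex >= 3:
        for k in range(3, n_hexnac + 1):
            ladder.append(GlycanComposition({"HexNAc": k, "Hex": 3}))

    ions: list[TheoreticalIon] = []
    for sub in ladder:
        if not comp.contains(sub):
            continue
        ions.append(
            TheoreticalIon("Y", Y_NONFUCOSE, sub.mass, label=sub.canonical_string)
        )
    if comp["Fuc"] >= 1:
        fuc = GlycanComposition({"Fuc": 1})
        for sub in ladder:
            fsub = sub.add(fuc)
            if not comp.contains(fsub):
                continue
            ions.append(
                TheoreticalIon(
                    "Y", Y_FUCOSE, fsub.mass, label=fsub.canonical_string
                )
            )
    return ions[:max_ions]


def enumerate_oxonium_ions(
    comp: GlycanComposition,
    table: Mapping[str, Sequence[tuple[float, float]]] | None = None,
) -> list[TheoreticalIon]:
    """Diagnostic oxonium ions for every category present in ``comp``.

    Compositions containing none of the five category residues return an
    empty list: generic HexNAc/Hex oxonium ions are shared by all candidates
    with the common core and never discriminate, so they are not scored.
    """
    if table is None:
        table = DEFAULT_OXONIUM_TABLE
    ions: list[TheoreticalIon] = []
    for category, residue in OXONIUM_CATEGORY_RESIDUES.items():
        if comp[residue] <= 0:
            continue
        entries = table.get(category, ())
        if not entries:
            raise ValueError(
                f"no oxonium ions configured for category {category}"
            )
        for mz, expected in entries:
            if expected <= 0:
                raise ValueError(
                    f"expected intensity must be > 0 ({category} m/z {mz})"
                )
            ions.append(
                TheoreticalIon(
                    "oxonium", category, mz, expected, f"{category}@{mz:.4f}"
                )
            )
    return ions


def _best_peak_in_window(
    spectrum: SpectrumPeaks, mz: float, tol_ppm: float
) -> float:
    """Most intense peak within tol of mz; -1 if none."""
    tol = mz * tol_ppm * 1e-6
    lo = np.searchsorted(spectrum.mz, mz - tol, side="left")
    hi = np.searchsorted(spectrum.mz, mz + tol, side="right")
    if hi <= lo:
        return -1.0
    return float(spectrum.intensity[lo:hi].max())


def match_ions(
    spectrum: SpectrumPeaks,
    ions: Sequence[TheoreticalIon],
    peptide_mass: float,
    precursor_charge: int,
    frag_tol_ppm: float,
    y_charge_cap: int = 2,
) -> list[IonMatch]:
    """Match theoretical ions against a centroided spectrum.

    Y-ions are searched as ``(peptide_mass + remnant + z*proton)/z`` for
    z = 1..min(precursor charge, charge cap); oxonium ions at their singly
    charged m/z. An ion matches if any peak lies within the ppm tolerance;
    of the peaks in the window, the most intense supplies the observed
    intensity, normalized to the spectrum base peak.
    """
    if frag_tol_ppm <= 0:
        raise ValueError("frag_tol_ppm must be > 0")
    base = spectrum.base_peak
    out: list[IonMatch] = []
    for ion in ions:
        best_int = -1.0
        best_z = 0
        if ion.kind == "Y":
            zmax = max(1, min(precursor_charge, y_charge_cap))
            for z in range(1, zmax + 1):
                mz = (peptide_mass + ion.value + z * PROTON_MASS) / z
                got = _best_peak_in_window(spectrum, mz, frag_tol_ppm)
                if got > best_int:
                    best_int, best_z = got, z
        else:
            best_int = _best_peak_in_window(spectrum, ion.value, frag_tol_ppm)
            best_z = 1
        if best_int >= 0 and base > 0:
            out.append(IonMatch(ion, True, best_int / base, best_z))
        else:
            out.append(IonMatch(ion, False, 0.0, 0))
    return out
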