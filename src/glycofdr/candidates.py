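"""Candidate gathering for an observed delta mass: targets, decoys, isotopes.

For each PSM carrying a glycan-sized delta mass, every target and decoy
glycan whose intact mass matches the delta within tolerance at an allowed
precursor isotope error is a candidate. Decoys are generated one per target
entry by shifting the intact mass within the tolerance, assigning a random
isotope error, and shifting every theoretical fragment ion by a unique value
in [1, 20] Da — so a decoy has the same number of fragment ions of each type
as its target but none of them can match the target's peaks.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .composition import Adduct, GlycanComposition, GlycanDatabase
from .ions import (
    DEFAULT_OXONIUM_TABLE,
    TheoreticalIon,
    enumerate_oxonium_ions,
    enumerate_y_ions,
)

__all__ = [
    "IsotopeSet",
    "GlycanCandidate",
    "CandidateMatch",
    "assign_isotope",
    "generate_decoys",
    "build_candidates",
    "find_candidates",
    "effective_seed",
]

#: Average peptide isotope spacing in Da.
ISOTOPE_SPACING = 1.00235

FRAGMENT_SHIFT_MIN = 1.0
FRAGMENT_SHIFT_MAX = 20.0


@dataclass(frozen=True)
class IsotopeSet:
    """Allowed precursor monoisotopic ("off-by-X") errors.

    Each unit is one isotope spacing (~1.00235 Da); the default set
    (-1, 0, +1, +2, +3) covers typical peak-picking errors.
    """

    allowed: tuple[int, ...] = (-1, 0, 1, 2, 3)
    spacing: float = ISOTOPE_SPACING

    def __post_init__(self) -> None:
        if not (1.0 < self.spacing < 1.01):
            raise ValueError("isotope spacing must be in (1.0, 1.01) Da")
        if 0 not in self.allowed:
            raise ValueError("isotope set must contain 0")


@dataclass(frozen=True)
class GlycanCandidate:
    """A target or decoy glycan form with its theoretical ion set."""

    composition: GlycanComposition
    adducts: tuple[Adduct, ...]
    intact_mass: float  # decoys: shifted mass
    is_decoy: bool = False
    decoy_mass_shift: float = 0.0  # Da; 0 for targets
    decoy_isotope: int | None = None
    y_ions: tuple[TheoreticalIon, ...] = ()
    oxonium_ions: tuple[TheoreticalIon, ...] = ()

    @property
    def label(self) -> str:
        s = self.composition.canonical_string
        if self.adducts:
            s += "".join(f"+{a.name}" for a in self.adducts)
        if self.is_decoy:
            s = "DECOY_" + s
        return s

    @property
    def ions(self) -> tuple[TheoreticalIon, ...]:
        return self.y_ions + self.oxonium_ions


@dataclass(frozen=True)
class CandidateMatch:
    """A candidate matched to an observed delta mass.

    ``corrected_mass_error`` is the ppm residual after removing the isotope
    error mass (isotope integer times the spacing) from the observed delta.
    For decoys the isotope used in scoring is the pre-assigned random one.
    """

    candidate: GlycanCandidate
    isotope_error: int
    corrected_mass_error: float  # signed ppm


def assign_isotope(
    delta_mass: float, candidate_mass: float, iso: IsotopeSet
) -> tuple[int, float] | None:
    """Determine the precursor isotope error and corrected mass error.

    The isotope error is the Da gap rounded to the nearest integer; ties at
    half-integers resolve to the smaller corrected error, then the smaller
    |isotope|. Returns ``None`` when the rounded integer is outside the
    allowed set (the candidate cannot explain the delta mass).
    """
    if candidate_mass <= 0:
        raise ValueError("candidate mass must be > 0")
    gap = delta_mass - candidate_mass
    lo = int(np.floor(gap))
    options = []
    for k in (lo, lo + 1):
        resid_ppm = (gap - k * iso.spacing) / candidate_mass * 1e6
        options.append((abs(resid_ppm), abs(k), k, resid_ppm))
    _, _, k, resid_ppm = min(options)
    if k not in iso.allowed:
        return None
    return k, resid_ppm


def effective_seed(
    db: GlycanDatabase,
    tol_ppm: float,
    iso: IsotopeSet,
    seed: int | None = None,
) -> int:
    """Fixed decoy seed: the user's, else a stable hash of the inputs.

    Hashing the sorted database entries, tolerance and isotope set means the
    same decoys are always generated for the same database and parameters,
    and different ones whenever any of those change.
    """
    if seed is not None:
        return int(seed) % (2**63)
    payload = "\n".join(
        sorted(f"{e.label}\t{e.intact_mass:.6f}" for e in db.entries)
    )
    payload += f"\ntol={tol_ppm!r}\niso={iso.allowed!r}\nspacing={iso.spacing!r}"
    digest = hashlib.sha256(payload.encode()).digest()
    return int.from_bytes(digest[:8], "big") % (2**63)


def _entry_rng(master_seed: int, entry_label: str) -> np.random.Generator:
    # per-entry stream so decoys do not depend on database ordering
    h = hashlib.sha256(f"{master_seed}:{entry_label}".encode()).digest()
    return np.random.default_rng(int.from_bytes(h[:8], "big"))


def build_candidates(
    db: GlycanDatabase,
    tol_ppm: float,
    iso: IsotopeSet,
    seed: int | None = None,
    oxonium_table: Mapping[str, Sequence[tuple[float, float]]] | None = None,
    max_y_ions: int = 24,
) -> list[GlycanCandidate]:
    """Targets plus one decoy per target entry, with theoretical ion sets."""
    targets: list[GlycanCandidate] = []
    for entry in db.entries:
        y = tuple(enumerate_y_ions(entry.composition, max_y_ions))
        oxo = tuple(
            enumerate_oxonium_ions(
                entry.composition, oxonium_table or DEFAULT_OXONIUM_TABLE
            )
        )
        targets.append(
            GlycanCandidate(
                entry.composition,
                entry.adducts,
                entry.intact_mass,
                y_ions=y,
                oxonium_ions=oxo,
            )
        )
    decoys = generate_decoys(db, tol_ppm, iso, seed, oxonium_table, max_y_ions)
    return targets + decoys


def generate_decoys(
    db: GlycanDatabase,
    tol_ppm: float,
    iso: IsotopeSet,
    seed: int | None = None,
    oxonium_table: Mapping[str, Sequence[tuple[float, float]]] | None = None,
    max_y_ions: int = 24,
) -> list[GlycanCandidate]:
    """One decoy per target entry; a pure function of (db, tol, iso, seed).

    The decoy intact mass is the target mass shifted by a uniform draw within
    +/- tol (in ppm of the target mass); the decoy isotope error is uniform
    over the allowed set; each theoretical Y and oxonium ion is shifted by an
    independent uniform value in [1, 20] Da, preserving per-category counts.
    """
    if len(db) == 0:
        raise ValueError("cannot generate decoys from an empty database")
    master = effective_seed(db, tol_ppm, iso, seed)
    table = oxonium_table or DEFAULT_OXONIUM_TABLE
    decoys: list[GlycanCandidate] = []
    for entry in db.entries:
        rng = _entry_rng(master, entry.label)
        shift_ppm = rng.uniform(-tol_ppm, tol_ppm)
        shift_da = entry.intact_mass * shift_ppm * 1e-6
        decoy_iso = int(rng.choice(iso.allowed))
        y = tuple(
            ion.shifted(rng.uniform(FRAGMENT_SHIFT_MIN, FRAGMENT_SHIFT_MAX))
            for ion in enumerate_y_ions(entry.composition, max_y_ions)
        )
        oxo = tuple(
            ion.shifted(rng.uniform(FRAGMENT_SHIFT_MIN, FRAGMENT_SHIFT_MAX))
            for ion in enumerate_oxonium_ions(entry.composition, table)
        )
        decoys.append(
            GlycanCandidate(
                entry.composition,
                entry.adducts,
                entry.intact_mass + shift_da,
                is_decoy=True,
                decoy_mass_shift=shift_da,
                decoy_isotope=decoy_iso,
                y_ions=y,
                oxonium_ions=oxo,
            )
        )
    return decoys


def find_candidates(
    delta_mass: float,
    candidates: Sequence[GlycanCandidate],
    tol_ppm: float,
    iso: IsotopeSet,
) -> list[CandidateMatch]:
    """All candidates whose mass matches the delta within tolerance.

    Each candidate is evaluated at its best allowed isotope error (smallest
    corrected error); decoys are matched on their shifted mass but carry
    their pre-assigned random isotope into scoring. An empty result means
    the PSM has no glycan candidate and is reported unassigned.
    """
    out: list[CandidateMatch] = []
    for cand in candidates:
        assigned = assign_isotope(delta_mass, cand.intact_mass, iso)
        if assigned is None:
            continue
        iso_err, resid_ppm = assigned
        if abs(resid_ppm) > tol_ppm:
            continue
        score_iso = cand.decoy_isotope if cand.is_decoy else iso_err
        assert score_iso is not None
        out.append(CandidateMatch(cand, int(score_iso), resid_ppm))
    return out
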