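"""Composite glycan scoring: pairwise tournament and absolute rescoring.

Candidates for one PSM are compared pairwise on four evidence components —
Y-ions, oxonium ions, corrected mass error, and precursor isotope error —
each expressed as a summed log probability ratio. Only ions unique to one
candidate discriminate; shared ions cancel. The tournament winner is then
rescored absolutely (all of its ions treated as unique, mass error compared
with the typical unmodified-peptide error) to give a score comparable across
PSMs, which drives target-decoy FDR estimation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

from .candidates import CandidateMatch, IsotopeSet
from .ions import (
    DEFAULT_OXONIUM_TABLE,
    IonMatch,
    Y_FUCOSE,
    Y_NONFUCOSE,
    match_ions,
)
from .spectra import SpectrumPeaks

__all__ = [
    "ScoringParams",
    "ScoreBreakdown",
    "score_y_pairwise",
    "score_oxonium_pairwise",
    "pairwise_score",
    "select_best_candidate",
    "absolute_score",
]

Y_CATEGORIES = (Y_NONFUCOSE, Y_FUCOSE)
OXO_CATEGORIES = ("NeuAc", "NeuGc", "Fucose", "Phosphate", "Sulfate")


@dataclass
class ScoringParams:
    """All scoring constants; every value is config-overridable.

    The alpha values are log probability ratios: hits always > 0, misses
    always < 0. Oxonium hits are intensity-weighted by observed/expected
    intensity with a floor at zero, so a barely-detected diagnostic ion
    cannot count against its candidate. ``sigma_unmodified`` is the typical
    absolute mass error (ppm) of unmodified peptides in the analysis, the
    reference scale for the absolute mass-error score.
    """

    alpha_y_hit: dict[str, float] = field(
        default_factory=lambda: {Y_NONFUCOSE: 1.0, Y_FUCOSE: 1.0}
    )
    alpha_y_miss: dict[str, float] = field(
        default_factory=lambda: {Y_NONFUCOSE: -0.5, Y_FUCOSE: -0.5}
    )
    alpha_oxo_hit: dict[str, float] = field(
        default_factory=lambda: {
            "NeuAc": 2.0,
            "NeuGc": 2.0,
            "Fucose": 1.0,
            "Phosphate": 2.0,
            "Sulfate": 2.0,
        }
    )
    alpha_oxo_miss: dict[str, float] = field(
        default_factory=lambda: {
            "NeuAc": -1.0,
            "NeuGc": -1.0,
            "Fucose": -0.5,
            "Phosphate": -0.5,
            "Sulfate": -0.5,
        }
    )
    alpha_isotope: dict[int, float] = field(
        default_factory=lambda: {-1: -1.0, 0: 0.0, 1: -0.5, 2: -1.0, 3: -1.5}
    )
    beta_mass: float = 1.0
    mass_error_floor_ppm: float = 0.01  # epsilon bounding log terms
    sigma_unmodified: float = 3.0  # ppm
    tol_ppm: float = 50.0  # candidate (delta mass) tolerance
    frag_tol_ppm: float = 20.0
    isotopes: IsotopeSet = field(default_factory=IsotopeSet)
    y_charge_cap: int = 2
    max_y_ions: int = 24
    min_glycan_mass: float = 140.0  # Da; smaller deltas are non-glyco
    oxonium_table: Mapping[str, Sequence[tuple[float, float]]] = field(
        default_factory=lambda: DEFAULT_OXONIUM_TABLE
    )

    def validate(self) -> None:
        for cat, v in {**self.alpha_y_hit, **self.alpha_oxo_hit}.items():
            if v <= 0:
                raise ValueError(f"hit alpha for {cat} must be > 0, got {v}")
        for cat, v in {**self.alpha_y_miss, **self.alpha_oxo_miss}.items():
            if v >= 0:
                raise ValueError(f"miss alpha for {cat} must be < 0, got {v}")
        a0 = self.alpha_isotope.get(0, 0.0)
        for k, v in self.alpha_isotope.items():
            if k != 0 and v > a0:
                raise ValueError("alpha_isotope[0] must be the maximum")
        if self.beta_mass < 0:
            raise ValueError("beta_mass must be >= 0")
        if self.sigma_unmodified <= 0:
            raise ValueError("sigma_unmodified must be > 0")
        for k in self.isotopes.allowed:
            if k not in self.alpha_isotope:
                raise ValueError(f"no alpha_isotope entry for isotope {k}")


@dataclass(frozen=True)
class ScoreBreakdown:
    """Score components; ``total`` is their exact sum."""

    s_y: float
    s_oxo: float
    s_mass: float
    s_isotope: float

    @property
    def total(self) -> float:
        return self.s_y + self.s_oxo + self.s_mass + self.s_isotope


def _split_unique(
    matches1: Sequence[IonMatch], matches2: Sequence[IonMatch]
) -> tuple[list[IonMatch], list[IonMatch]]:
    """Drop ions generable by both candidates; they carry no information."""
    keys1 = {m.ion.key for m in matches1}
    keys2 = {m.ion.key for m in matches2}
    shared = keys1 & keys2
    u1 = [m for m in matches1 if m.ion.key not in shared]
    u2 = [m for m in matches2 if m.ion.key not in shared]
    return u1, u2


def score_y_pairwise(
    matches1: Sequence[IonMatch],
    matches2: Sequence[IonMatch],
    params: ScoringParams,
) -> float:
    """Y-ion pairwise score with square-root-normalized counts.

    Per category, hits and misses unique to each candidate are counted,
    square-root normalized (large glycans have more possible Y-ions than
    are typically observed), and differenced with the hit/miss alphas.
    Inputs must already be restricted to unique ions.
    """
    s = 0.0
    for cat in Y_CATEGORIES:
        u1 = sum(1 for m in matches1 if m.ion.category == cat and m.matched)
        v1 = sum(1 for m in matches1 if m.ion.category == cat and not m.matched)
        u2 = sum(1 for m in matches2 if m.ion.category == cat and m.matched)
        v2 = sum(1 for m in matches2 if m.ion.category == cat and not m.matched)
        s += params.alpha_y_hit[cat] * (math.sqrt(u1) - math.sqrt(u2))
        s += params.alpha_y_miss[cat] * (math.sqrt(v1) - math.sqrt(v2))
    return s


def _oxo_hit_term(m: IonMatch, alpha_hit: float) -> float:
    # intensity-weighted, floored at zero: a trace-level hit is neutral
    ratio = m.observed_intensity / m.ion.expected_intensity
    return max(0.0, alpha_hit * ratio)


def score_oxonium_pairwise(
    matches1: Sequence[IonMatch],
    matches2: Sequence[IonMatch],
    params: ScoringParams,
) -> float:
    """Oxonium pairwise score: intensity-weighted hits, no sqrt on counts."""
    s = 0.0
    for cat in OXO_CATEGORIES:
        a_hit = params.alpha_oxo_hit[cat]
        a_miss = params.alpha_oxo_miss[cat]
        v1 = v2 = 0
        for m in matches1:
            if m.ion.category != cat:
                continue
            if m.matched:
                s += _oxo_hit_term(m, a_hit)
            else:
                v1 += 1
        for m in matches2:
            if m.ion.category != cat:
                continue
            if m.matched:
                s -= _oxo_hit_term(m, a_hit)
            else:
                v2 += 1
        s += a_miss * (v1 - v2)
    return s


def pairwise_score(
    match1: CandidateMatch,
    match2: CandidateMatch,
    ion_matches1: Sequence[IonMatch],
    ion_matches2: Sequence[IonMatch],
    params: ScoringParams,
) -> ScoreBreakdown:
    """Composite pairwise score of candidate 1 versus candidate 2.

    Positive total means candidate 1 is preferred. The mass term rewards the
    candidate with the smaller corrected mass error; the isotope term is the
    difference of the isotope-error alphas. Antisymmetric by construction.
    """
    u1, u2 = _split_unique(ion_matches1, ion_matches2)
    y1 = [m for m in u1 if m.ion.kind == "Y"]
    y2 = [m for m in u2 if m.ion.kind == "Y"]
    o1 = [m for m in u1 if m.ion.kind == "oxonium"]
    o2 = [m for m in u2 if m.ion.kind == "oxonium"]
    s_y = score_y_pairwise(y1, y2, params)
    s_oxo = score_oxonium_pairwise(o1, o2, params)
    eps = params.mass_error_floor_ppm
    dm1 = max(abs(match1.corrected_mass_error), eps)
    dm2 = max(abs(match2.corrected_mass_error), eps)
    s_mass = params.beta_mass * math.log(dm2 / dm1)
    s_iso = params.alpha_isotope[match1.isotope_error] - params.alpha_isotope[
        match2.isotope_error
    ]
    return ScoreBreakdown(s_y, s_oxo, s_mass, s_iso)


def _canonical_order(matches: Sequence[CandidateMatch]) -> list[CandidateMatch]:
    """Targets by |corrected error| then mass; decoys after, same order."""
    targets = [m for m in matches if not m.candidate.is_decoy]
    decoys = [m for m in matches if m.candidate.is_decoy]
    key = lambda m: (abs(m.corrected_mass_error), m.candidate.intact_mass)
    return sorted(targets, key=key) + sorted(decoys, key=key)


def select_best_candidate(
    matches: Sequence[CandidateMatch],
    spectrum: SpectrumPeaks,
    peptide_mass: float,
    precursor_charge: int,
    params: ScoringParams,
) -> tuple[CandidateMatch, float, dict[int, list[IonMatch]]]:
    """Sequential pairwise tournament over all candidates.

    Candidates are visited in a canonical deterministic order; the incumbent
    is replaced whenever a challenger scores strictly positive against it
    (exact ties retain the incumbent). Returns the winner, its margin from
    the last comparison, and the per-candidate ion-match cache (keyed by
    ``id(candidate)``) for reuse in absolute rescoring.
    """
    if not matches:
        raise ValueError("select_best_candidate requires >= 1 candidate")
    ordered = _canonical_order(matches)
    cache: dict[int, list[IonMatch]] = {}

    def ion_matches(m: CandidateMatch) -> list[IonMatch]:
        k = id(m.candidate)
        if k not in cache:
            cache[k] = match_ions(
                spectrum,
                m.candidate.ions,
                peptide_mass,
                precursor_charge,
                params.frag_tol_ppm,
                params.y_charge_cap,
            )
        return cache[k]

    best = ordered[0]
    margin = math.inf
    for challenger in ordered[1:]:
        s = pairwise_score(
            challenger, best, ion_matches(challenger), ion_matches(best), params
        ).total
        if s > 0:
            best, margin = challenger, s
        else:
            margin = -s
    ion_matches(best)
    return best, margin, cache


def absolute_score(
    match: CandidateMatch,
    ion_matches: Sequence[IonMatch],
    params: ScoringParams,
) -> ScoreBreakdown:
    """Absolute (total-evidence) score of the tournament winner.

    All of the candidate's theoretical ions are treated as unique; the mass
    error is compared with the typical unmodified-peptide error and the
    isotope error with the no-error baseline. Decoys are scored identically
    through their shifted ions, random isotope, and shifted-mass error.
    """
    s_y = 0.0
    for cat in Y_CATEGORIES:
        u = sum(
            1
            for m in ion_matches
            if m.ion.kind == "Y" and m.ion.category == cat and m.matched
        )
        v = sum(
            1
            for m in ion_matches
            if m.ion.kind == "Y" and m.ion.category == cat and not m.matched
        )
        s_y += params.alpha_y_hit[cat] * math.sqrt(u)
        s_y += params.alpha_y_miss[cat] * math.sqrt(v)
    s_oxo = 0.0
    for cat in OXO_CATEGORIES:
        for m in ion_matches:
            if m.ion.kind != "oxonium" or m.ion.category != cat:
                continue
            if m.matched:
                s_oxo += _oxo_hit_term(m, params.alpha_oxo_hit[cat])
            else:
                s_oxo += params.alpha_oxo_miss[cat]
    dm = max(abs(match.corrected_mass_error), params.mass_error_floor_ppm)
    s_mass = params.beta_mass * math.log(params.sigma_unmodified / dm)
    s_iso = params.alpha_isotope[match.isotope_error]
    return ScoreBreakdown(s_y, s_oxo, s_mass, s_iso)
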