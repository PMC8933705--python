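"""Target-decoy q-value estimation, FDR filtering, entrapment metrics.

FDR at a score threshold is the ratio of decoy-best to target-best PSMs at
or above that score; the q-value of a PSM is the minimum FDR over all
thresholds that accept it. PSMs whose best candidate is a decoy are reported
with the best target composition substituted and q forced to 1, so they
never pass any ordinary filter but stay visible in the full table.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np

from .composition import GlycanComposition, parse_composition

__all__ = [
    "AssignmentResult",
    "EntrapmentReport",
    "qvalues_from_scores",
    "compute_qvalues",
    "apply_fdr_filter",
    "entrapment_rates",
    "entrapment_report_from_counts",
]


@dataclass
class AssignmentResult:
    """Final glycan assignment for one PSM."""

    psm_id: str
    best_target_composition: str | None  # canonical string (+adduct suffix)
    best_is_decoy: bool
    absolute_score: float
    isotope_error: int
    corrected_mass_error: float  # ppm
    q_value: float = float("nan")
    decoy_composition: str | None = None  # decoy label when best is a decoy
    n_candidates: int = 0
    row_index: int = -1  # position in the source PSM table
    score_y: float = 0.0
    score_oxo: float = 0.0
    score_mass: float = 0.0
    score_isotope: float = 0.0


@dataclass(frozen=True)
class EntrapmentReport:
    """Entrapment-search summary: how often absent glycans were assigned."""

    total_glycopsms: int
    counts: dict[str, int]  # per category: NeuAc, NeuGc, Fucose, other
    raw_rate: float  # percent
    adjusted_rate: float  # percent, scaled by true/total list-size ratio

    @property
    def total_entrapment(self) -> int:
        return sum(self.counts.values())


def qvalues_from_scores(
    scores: Sequence[float], is_decoy: Sequence[bool]
) -> np.ndarray:
    """q-values from absolute scores and decoy flags, in input order.

    PSMs are ranked by descending score with decoys preceding targets at
    tied scores (conservative). FDR at rank i is cumulative decoys over
    cumulative targets (capped at 1); q is the running minimum of FDR taken
    from the worst rank upward, making q nonincreasing in score.
    """
    scores = np.asarray(scores, dtype=float)
    decoy = np.asarray(is_decoy, dtype=bool)
    n = scores.size
    if n == 0:
        return np.empty(0)
    # decoys first on ties: sort by (-score, target flag)
    order = np.lexsort((~decoy, -scores))
    cum_decoy = np.cumsum(decoy[order])
    cum_target = np.cumsum(~decoy[order])
    with np.errstate(divide="ignore", invalid="ignore"):
        fdr = np.where(cum_target > 0, cum_decoy / np.maximum(cum_target, 1), 1.0)
    fdr = np.minimum(fdr, 1.0)
    q_sorted = np.minimum.accumulate(fdr[::-1])[::-1]
    q = np.empty(n)
    q[order] = q_sorted
    return q


def compute_qvalues(results: Iterable[AssignmentResult]) -> list[AssignmentResult]:
    """Attach q-values to scored assignments; decoy-best PSMs get q = 1."""
    results = list(results)
    if not any(not r.best_is_decoy for r in results):
        if results:
            warnings.warn("no target-best PSMs: q-values undefined")
        return []
    q = qvalues_from_scores(
        [r.absolute_score for r in results],
        [r.best_is_decoy for r in results],
    )
    out = []
    for r, qv in zip(results, q):
        out.append(replace(r, q_value=1.0 if r.best_is_decoy else float(qv)))
    return out


def apply_fdr_filter(
    results: Sequence[AssignmentResult], q_threshold: float
) -> tuple[list[AssignmentResult], list[AssignmentResult]]:
    """Split into (passing, full) at ``q < q_threshold``.

    The full list always retains every PSM with its q-value; the filtered
    view is what a 1%-glycan-FDR analysis would carry forward.
    """
    if not (0 < q_threshold <= 1):
        raise ValueError("q threshold must be in (0, 1]")
    full = list(results)
    passing = [r for r in full if r.q_value < q_threshold]
    if q_threshold == 1.0:
        passing = [r for r in full if not r.best_is_decoy]
    return passing, full


def _entrapment_category(comp: GlycanComposition) -> str:
    if comp["NeuAc"] > 0:
        return "NeuAc"
    if comp["NeuGc"] > 0:
        return "NeuGc"
    if comp["Fuc"] > 0:
        return "Fucose"
    return "other"


def entrapment_rates(
    assignments: Sequence[AssignmentResult],
    true_glycans: set[str],
    true_size: int,
    total_size: int,
) -> EntrapmentReport:
    """Entrapment rates of FDR-filtered assignments.

    The raw rate is the percentage of assignments to glycans outside the
    true set; the adjusted rate scales it by the ratio of true to total
    glycan-list sizes, giving low and high estimates of realized glycan FDR.
    Adduct suffixes are ignored when matching the true set (adducts do not
    change the glycan).
    """
    if total_size < true_size:
        raise ValueError("total glycan list cannot be smaller than the true list")
    true_canonical = {
        parse_composition(t.split("+")[0]).canonical_string for t in true_glycans
    }
    counts = {"NeuAc": 0, "NeuGc": 0, "Fucose": 0, "other": 0}
    n = 0
    for r in assignments:
        if r.best_is_decoy or r.best_target_composition is None:
            continue
        n += 1
        comp_str = r.best_target_composition.split("+")[0]
        comp = parse_composition(comp_str)
        if comp.canonical_string not in true_canonical:
            counts[_entrapment_category(comp)] += 1
    return entrapment_report_from_counts(n, counts, true_size, total_size)


def entrapment_report_from_counts(
    total_glycopsms: int,
    counts: dict[str, int],
    true_size: int,
    total_size: int,
) -> EntrapmentReport:
    """Build the report from pre-tallied per-category entrapment counts."""
    if total_size < true_size:
        raise ValueError("total glycan list cannot be smaller than the true list")
    n_entrap = sum(counts.values())
    raw = 100.0 * n_entrap / total_glycopsms if total_glycopsms else 0.0
    adjusted = raw * true_size / total_size
    return EntrapmentReport(total_glycopsms, dict(counts), raw, adjusted)
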