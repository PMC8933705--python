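"""Top-level modelling interface: build from data, fit, inspect results.

`GlycanAssignmentModel` bundles a PSM table, the fragment spectra, a glycan
database and scoring parameters; `fit()` runs candidate gathering, the
pairwise tournament, absolute rescoring and target-decoy q-value estimation,
returning a `GlycanAssignmentResults` that carries per-PSM assignments, the
score breakdowns, diagnostics, and writers.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .candidates import (
    GlycanCandidate,
    build_candidates,
    effective_seed,
    find_candidates,
)
from .composition import Adduct, GlycanDatabase, load_glycan_database
from .fdr import (
    AssignmentResult,
    EntrapmentReport,
    apply_fdr_filter,
    compute_qvalues,
    entrapment_rates,
)
from .psmio import PsmRecord, read_psm_table, write_results
from .scoring import ScoringParams, absolute_score, select_best_candidate
from .spectra import SpectrumStore, read_spectra

__all__ = ["GlycanAssignmentModel", "GlycanAssignmentResults"]


class GlycanAssignmentModel:
    """Glycan composition assignment with glycan-level FDR.

    Parameters
    ----------
    psms
        Parsed PSM records from the upstream peptide-first search.
    spectra
        Store of centroided MS2 spectra resolvable by PSM spectrum id.
    database
        Target glycan database (decoys are generated at fit time).
    params
        Scoring parameters; defaults are used when omitted.
    psm_table
        Optional raw table the records came from, preserved for output.
    """

    def __init__(
        self,
        psms: Sequence[PsmRecord],
        spectra: SpectrumStore,
        database: GlycanDatabase,
        params: ScoringParams | None = None,
        psm_table: pd.DataFrame | None = None,
    ) -> None:
        self.psms = list(psms)
        self.spectra = spectra
        self.database = database
        self.params = params or ScoringParams()
        self.params.validate()
        self.psm_table = psm_table

    @classmethod
    def from_files(
        cls,
        psm_path: str | Path,
        spectra_paths: Sequence[str | Path],
        glycan_db_path: str | Path,
        adduct: Adduct | None = None,
        max_adducts: int = 0,
        params: ScoringParams | None = None,
    ) -> "GlycanAssignmentModel":
        params = params or ScoringParams()
        records, df = read_psm_table(psm_path, params.min_glycan_mass)
        store = read_spectra(spectra_paths)
        db = load_glycan_database(glycan_db_path, adduct, max_adducts)
        return cls(records, store, db, params, df)

    # -- sigma_unmodified ---------------------------------------------------

    def estimate_sigma_unmodified(self) -> float:
        """Mean |ppm error| of zero-delta-mass PSMs, else the config default.

        Unmodified peptides (|delta| < 0.1 Da) measure the instrument's
        typical precursor mass error, the reference scale for the absolute
        mass-error score.
        """
        errors = [
            abs(p.delta_mass / p.peptide_mass) * 1e6
            for p in self.psms
            if abs(p.delta_mass) < 0.1 and p.peptide_mass > 0
        ]
        if errors:
            est = float(np.mean(errors))
            return max(est, self.params.mass_error_floor_ppm)
        return self.params.sigma_unmodified

    # -- fitting ------------------------------------------------------------

    def fit(self, seed: int | None = None) -> "GlycanAssignmentResults":
        """Assign glycans to every glyco PSM and estimate q-values."""
        import copy

        params = copy.deepcopy(self.params)
        sigma = self.estimate_sigma_unmodified()
        params.sigma_unmodified = sigma
        master = effective_seed(self.database, params.tol_ppm, params.isotopes, seed)
        candidates = build_candidates(
            self.database,
            params.tol_ppm,
            params.isotopes,
            master,
            params.oxonium_table,
            params.max_y_ions,
        )
        assignments: list[AssignmentResult] = []
        n_unresolved = 0
        for psm in self.psms:
            if not psm.is_glyco:
                continue
            spectrum = self.spectra.get(psm.spectrum_id)
            if spectrum is None:
                n_unresolved += 1
                continue
            matches = find_candidates(
                psm.delta_mass, candidates, params.tol_ppm, params.isotopes
            )
            if not matches:
                continue
            best, _margin, cache = select_best_candidate(
                matches, spectrum, psm.peptide_mass, psm.charge, params
            )
            breakdown = absolute_score(best, cache[id(best.candidate)], params)
            best_target_label: str | None = best.candidate.label
            decoy_label: str | None = None
            if best.candidate.is_decoy:
                decoy_label = best.candidate.label
                targets_only = [m for m in matches if not m.candidate.is_decoy]
                if targets_only:
                    tbest, _, _ = select_best_candidate(
                        targets_only, spectrum, psm.peptide_mass, psm.charge, params
                    )
                    best_target_label = tbest.candidate.label
                else:
                    best_target_label = None
            assignments.append(
                AssignmentResult(
                    psm_id=psm.spectrum_id,
                    best_target_composition=best_target_label,
                    best_is_decoy=best.candidate.is_decoy,
                    absolute_score=breakdown.total,
                    isotope_error=best.isotope_error,
                    corrected_mass_error=best.corrected_mass_error,
                    decoy_composition=decoy_label,
                    n_candidates=len(matches),
                    score_y=breakdown.s_y,
                    score_oxo=breakdown.s_oxo,
                    score_mass=breakdown.s_mass,
                    score_isotope=breakdown.s_isotope,
                    row_index=psm.row_index,
                )
            )
        if n_unresolved:
            warnings.warn(
                f"{n_unresolved} PSMs had unresolvable spectrum ids and were "
                "left unassigned"
            )
        assignments = compute_qvalues(assignments)
        return GlycanAssignmentResults(self, assignments, master, sigma)


@dataclass
class GlycanAssignmentResults:
    """Fitted assignments with q-values, diagnostics and writers."""

    model: GlycanAssignmentModel
    assignments: list[AssignmentResult]
    seed: int
    sigma_unmodified: float

    @property
    def table(self) -> pd.DataFrame:
        """Per-PSM assignment table (one row per scored glyco PSM)."""
        return pd.DataFrame(
            {
                "psm_id": [a.psm_id for a in self.assignments],
                "glycan_composition": [
                    a.best_target_composition for a in self.assignments
                ],
                "glycan_score": [a.absolute_score for a in self.assignments],
                "glycan_q_value": [a.q_value for a in self.assignments],
                "isotope_error": [a.isotope_error for a in self.assignments],
                "mass_error_ppm": [
                    a.corrected_mass_error for a in self.assignments
                ],
                "best_is_decoy": [a.best_is_decoy for a in self.assignments],
                "n_candidates": [a.n_candidates for a in self.assignments],
            }
        )

    def filter(self, q_threshold: float = 0.01) -> list[AssignmentResult]:
        """Assignments passing the glycan FDR filter."""
        passing, _ = apply_fdr_filter(self.assignments, q_threshold)
        return passing

    def entrapment(
        self,
        true_glycans: set[str],
        true_size: int,
        total_size: int,
        q_threshold: float = 0.01,
    ) -> EntrapmentReport:
        """Entrapment rates of the FDR-filtered assignments."""
        return entrapment_rates(
            self.filter(q_threshold), true_glycans, true_size, total_size
        )

    def save(
        self,
        out_prefix: str | Path,
        q_threshold: float = 0.01,
        decoy_report: bool = False,
    ) -> tuple[Path, Path]:
        """Write the full and filtered PSM tables next to ``out_prefix``."""
        df = self.model.psm_table
        if df is None:
            df = pd.DataFrame(
                {
                    "spectrum_id": [p.spectrum_id for p in self.model.psms],
                    "peptide": [p.peptide for p in self.model.psms],
                    "delta_mass": [p.delta_mass for p in self.model.psms],
                }
            )
        return write_results(
            df, self.assignments, out_prefix, q_threshold, decoy_report
        )

    def summary(self, q_threshold: float = 0.01) -> str:
        """Plain-text fit summary."""
        n_glyco = sum(1 for p in self.model.psms if p.is_glyco)
        n_decoy = sum(1 for a in self.assignments if a.best_is_decoy)
        n_pass = len(self.filter(q_threshold))
        lines = [
            "Glycan assignment results",
            "=" * 42,
            f"{'PSMs in table':<32}{len(self.model.psms):>10}",
            f"{'glyco PSMs':<32}{n_glyco:>10}",
            f"{'assigned (candidates found)':<32}{len(self.assignments):>10}",
            f"{'decoy-best PSMs':<32}{n_decoy:>10}",
            f"{'passing q < ' + format(q_threshold, 'g'):<32}{n_pass:>10}",
            f"{'glycan database entries':<32}{len(self.model.database):>10}",
            f"{'unique mass offsets':<32}{self.model.database.n_unique_mass_offsets:>10}",
            f"{'sigma_unmodified (ppm)':<32}{self.sigma_unmodified:>10.3f}",
            f"{'decoy seed':<32}{self.seed:>10}",
        ]
        return "\n".join(lines)

    def plot_score_distributions(self, ax=None):
        """Histogram of target vs decoy absolute scores (requires matplotlib)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        t = [a.absolute_score for a in self.assignments if not a.best_is_decoy]
        d = [a.absolute_score for a in self.assignments if a.best_is_decoy]
        ax.hist(t, bins=40, alpha=0.6, label="target best")
        ax.hist(d, bins=40, alpha=0.6, label="decoy best")
        ax.set_xlabel("absolute glycan score")
        ax.set_ylabel("PSMs")
        ax.legend()
        return ax
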