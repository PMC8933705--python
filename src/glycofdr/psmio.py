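"""PSM table reading/writing and the scoring-parameter config file.

The PSM table is the tab-separated output of a peptide-first glyco search:
one row per spectrum with the identified peptide, its calculated mass, the
observed precursor neutral mass, the delta mass, charge, and a spectrum
identifier. Common search-engine column headers are accepted via aliases.
"""

from __future__ import annotations

import configparser
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import pandas as pd

from .candidates import IsotopeSet
from .fdr import AssignmentResult
from .scoring import ScoringParams

__all__ = [
    "PsmRecord",
    "read_psm_table",
    "write_results",
    "load_params",
    "write_params",
    "PSM_COLUMNS",
]

#: canonical column name -> accepted header aliases (case-insensitive)
PSM_COLUMNS: dict[str, tuple[str, ...]] = {
    "spectrum_id": ("spectrum_id", "spectrum", "spectrumid", "spectrum title"),
    "peptide": ("peptide", "peptide sequence", "modified peptide"),
    "peptide_mass": (
        "peptide_mass",
        "calculated peptide mass",
        "calc_peptide_mass",
        "calc_neutral_pep_mass",
    ),
    "observed_mass": ("observed_mass", "observed mass", "precursor_neutral_mass"),
    "delta_mass": ("delta_mass", "delta mass", "massdiff", "original delta mass"),
    "charge": ("charge", "precursor charge"),
}

_OPTIONAL = {"peptide_probability": ("peptide_probability", "probability", "peptideprophet probability")}


class PsmSchemaError(ValueError):
    """PSM table is missing a required column."""


@dataclass
class PsmRecord:
    """One row of the upstream search output."""

    spectrum_id: str
    peptide: str
    peptide_mass: float
    observed_mass: float
    delta_mass: float
    charge: int
    peptide_probability: float | None = None
    is_glyco: bool = True  # delta mass large enough to be a glycan
    row_index: int = -1


def _resolve_columns(df: pd.DataFrame) -> dict[str, str]:
    lower = {c.lower(): c for c in df.columns}
    resolved: dict[str, str] = {}
    missing: list[str] = []
    for canon, aliases in PSM_COLUMNS.items():
        for alias in aliases:
            if alias in lower:
                resolved[canon] = lower[alias]
                break
        else:
            missing.append(f"{canon} (any of: {', '.join(aliases)})")
    if missing:
        raise PsmSchemaError(
            "PSM table is missing required columns: " + "; ".join(missing)
        )
    for canon, aliases in _OPTIONAL.items():
        for alias in aliases:
            if alias in lower:
                resolved[canon] = lower[alias]
                break
    return resolved


def read_psm_table(
    path: str | Path, min_glycan_mass: float = 140.0
) -> tuple[list[PsmRecord], pd.DataFrame]:
    """Read a TSV PSM table; returns records plus the raw table.

    Rows with missing required fields are rejected with their line numbers.
    Delta masses below ``min_glycan_mass`` are flagged non-glyco and passed
    through unscored. If observed - calculated disagrees with the delta
    column by more than 1 Da a warning is emitted and the delta is trusted.
    """
    df = pd.read_csv(path, sep="\t")
    cols = _resolve_columns(df)
    records: list[PsmRecord] = []
    bad_rows: list[int] = []
    for i, row in df.iterrows():
        required = [cols[c] for c in PSM_COLUMNS]
        if any(pd.isna(row[c]) for c in required):
            bad_rows.append(int(i) + 2)  # 1-based with header line
            continue
        delta = float(row[cols["delta_mass"]])
        obs = float(row[cols["observed_mass"]])
        calc = float(row[cols["peptide_mass"]])
        if abs((obs - calc) - delta) > 1.0:
            warnings.warn(
                f"{path} line {int(i) + 2}: observed-calculated "
                f"({obs - calc:.4f}) disagrees with delta column "
                f"({delta:.4f}); trusting delta"
            )
        prob = None
        if "peptide_probability" in cols and not pd.isna(
            row[cols["peptide_probability"]]
        ):
            prob = float(row[cols["peptide_probability"]])
        records.append(
            PsmRecord(
                spectrum_id=str(row[cols["spectrum_id"]]),
                peptide=str(row[cols["peptide"]]),
                peptide_mass=calc,
                observed_mass=obs,
                delta_mass=delta,
                charge=int(row[cols["charge"]]),
                peptide_probability=prob,
                is_glyco=delta >= min_glycan_mass,
                row_index=int(i),
            )
        )
    if bad_rows:
        warnings.warn(
            f"{path}: rejected {len(bad_rows)} rows with missing fields "
            f"(lines {bad_rows})"
        )
    return records, df


def write_results(
    df: pd.DataFrame,
    assignments: Sequence[AssignmentResult],
    out_prefix: str | Path,
    q_threshold: float = 0.01,
    decoy_report: bool = False,
) -> tuple[Path, Path]:
    """Write the full and FDR-filtered PSM tables with glycan columns.

    Appends glycan_composition, glycan_score, glycan_q_value, isotope_error
    and mass_error_ppm to the input table (row order preserved). In decoy
    diagnostic mode the decoy composition is printed in place of the
    substituted target and a best_is_decoy column is added.
    """
    out_prefix = Path(out_prefix)
    by_row = {a.row_index: a for a in assignments}
    comp, score, qval, iso, merr, isdec = [], [], [], [], [], []
    for i in range(len(df)):
        a = by_row.get(i)
        if a is None:
            comp.append("")
            score.append("")
            qval.append("")
            iso.append("")
            merr.append("")
            isdec.append("")
            continue
        shown = a.best_target_composition or ""
        if decoy_report and a.best_is_decoy and a.decoy_composition:
            shown = a.decoy_composition
        comp.append(shown)
        score.append(f"{a.absolute_score:.4f}")
        qval.append(f"{a.q_value:.6g}")
        iso.append(str(a.isotope_error))
        merr.append(f"{a.corrected_mass_error:.4f}")
        isdec.append(str(a.best_is_decoy))
    out = df.copy()
    out["glycan_composition"] = comp
    out["glycan_score"] = score
    out["glycan_q_value"] = qval
    out["isotope_error"] = iso
    out["mass_error_ppm"] = merr
    if decoy_report:
        out["best_is_decoy"] = isdec
    full_path = out_prefix.with_name(out_prefix.name + ".psms.tsv")
    out.to_csv(full_path, sep="\t", index=False)
    keep = [
        i
        for i in range(len(df))
        if i in by_row
        and not by_row[i].best_is_decoy
        and by_row[i].q_value < q_threshold
    ]
    filt_path = out_prefix.with_name(out_prefix.name + ".filtered.psms.tsv")
    out.iloc[keep].to_csv(filt_path, sep="\t", index=False)
    return full_path, filt_path


# ---------------------------------------------------------------------------
# config file


def load_params(path: str | Path) -> ScoringParams:
    """Load scoring parameters from a flat key-value config with sections.

    Sections: [scoring] scalar knobs; [alpha] per-category probability-ratio
    logs (keys like y_hit_nonfucose, oxo_miss_NeuAc); [isotope] allowed set,
    spacing and per-error alphas (alpha_-1 ... alpha_3); [oxonium] one key
    per category with comma-separated mz:expected_intensity pairs. Any key
    left out keeps its default.
    """
    cp = configparser.ConfigParser()
    cp.optionxform = str  # keep case of category names
    with open(path, encoding="utf-8") as fh:
        cp.read_file(fh)
    params = ScoringParams()
    if cp.has_section("scoring"):
        sec = cp["scoring"]
        for key in (
            "beta_mass",
            "mass_error_floor_ppm",
            "sigma_unmodified",
            "tol_ppm",
            "frag_tol_ppm",
            "min_glycan_mass",
        ):
            if key in sec:
                setattr(params, key, sec.getfloat(key))
        for key in ("y_charge_cap", "max_y_ions"):
            if key in sec:
                setattr(params, key, sec.getint(key))
    if cp.has_section("alpha"):
        for key, raw in cp["alpha"].items():
            value = float(raw)
            kind, rest = key.split("_", 1)
            which, cat = rest.split("_", 1)
            table = {
                ("y", "hit"): params.alpha_y_hit,
                ("y", "miss"): params.alpha_y_miss,
                ("oxo", "hit"): params.alpha_oxo_hit,
                ("oxo", "miss"): params.alpha_oxo_miss,
            }.get((kind, which))
            if table is None:
                raise ValueError(f"unrecognized alpha key {key!r}")
            table[cat] = value
    if cp.has_section("isotope"):
        sec = cp["isotope"]
        allowed = params.isotopes.allowed
        spacing = params.isotopes.spacing
        if "allowed" in sec:
            allowed = tuple(int(x) for x in sec["allowed"].split(","))
        if "spacing" in sec:
            spacing = float(sec["spacing"])
        params.isotopes = IsotopeSet(allowed, spacing)
        for key, raw in sec.items():
            if key.startswith("alpha_"):
                params.alpha_isotope[int(key[6:])] = float(raw)
    if cp.has_section("oxonium"):
        table = dict(params.oxonium_table)
        for cat, raw in cp["oxonium"].items():
            entries = []
            for pair in raw.split(","):
                mz, expected = pair.split(":")
                entries.append((float(mz), float(expected)))
            table[cat] = tuple(entries)
        params.oxonium_table = table
    params.validate()
    return params


def write_params(params: ScoringParams, path: str | Path) -> None:
    """Write a config file round-trippable through :func:`load_params`."""
    cp = configparser.ConfigParser()
    cp.optionxform = str
    cp["scoring"] = {
        "beta_mass": repr(params.beta_mass),
        "mass_error_floor_ppm": repr(params.mass_error_floor_ppm),
        "sigma_unmodified": repr(params.sigma_unmodified),
        "tol_ppm": repr(params.tol_ppm),
        "frag_tol_ppm": repr(params.frag_tol_ppm),
        "min_glycan_mass": repr(params.min_glycan_mass),
        "y_charge_cap": str(params.y_charge_cap),
        "max_y_ions": str(params.max_y_ions),
    }
    alpha: dict[str, str] = {}
    for cat, v in params.alpha_y_hit.items():
        alpha[f"y_hit_{cat}"] = repr(v)
    for cat, v in params.alpha_y_miss.items():
        alpha[f"y_miss_{cat}"] = repr(v)
    for cat, v in params.alpha_oxo_hit.items():
        alpha[f"oxo_hit_{cat}"] = repr(v)
    for cat, v in params.alpha_oxo_miss.items():
        alpha[f"oxo_miss_{cat}"] = repr(v)
    cp["alpha"] = alpha
    iso = {
        "allowed": ",".join(str(k) for k in params.isotopes.allowed),
        "spacing": repr(params.isotopes.spacing),
    }
    for k, v in params.alpha_isotope.items():
        iso[f"alpha_{k}"] = repr(v)
    cp["isotope"] = iso
    cp["oxonium"] = {
        cat: ",".join(f"{mz}:{exp}" for mz, exp in entries)
        for cat, entries in params.oxonium_table.items()
    }
    with open(path, "w", encoding="utf-8") as fh:
        cp.write(fh)
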