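"""Synthetic glycoproteomics fixtures: glycan lists, spectra, PSM tables.

The generator emulates what the assignment method consumes: precursor delta
masses equal to a glycan mass plus isotope and Gaussian mass errors, spectra
with Y-ion trimming ladders, category-specific oxonium ions, noise peaks,
and optional cofragmentation contamination (oxonium ions of a second glycan
leaking into a spectrum). Everything is driven by one seeded generator so
datasets are byte-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from pyteomics import mgf as mgf_writer

from .composition import PROTON_MASS, GlycanComposition, parse_composition
from .ions import DEFAULT_OXONIUM_TABLE, enumerate_oxonium_ions, enumerate_y_ions
from .psmio import PsmRecord
from .spectra import SpectrumPeaks

__all__ = [
    "SimulationConfig",
    "make_glycan_series",
    "make_entrapment_list",
    "synth_spectrum",
    "synth_dataset",
]

ISOTOPE_SPACING = 1.00235


def make_glycan_series(
    hexnac: int, hex_min: int, hex_max: int
) -> list[GlycanComposition]:
    """High-mannose-style series HexNAc(n)Hex(h) for h in [hex_min, hex_max].

    ``make_glycan_series(2, 4, 20)`` reproduces the 17-composition series
    typical of fission-yeast N-glycosylation.
    """
    if hex_min > hex_max:
        raise ValueError("hex_min must be <= hex_max")
    return [
        GlycanComposition({"HexNAc": hexnac, "Hex": h})
        for h in range(hex_min, hex_max + 1)
    ]


def make_entrapment_list() -> list[GlycanComposition]:
    """Deterministic mammalian-style entrapment compositions.

    Disjoint from the HexNAc(2)Hex(4..20) series; includes hybrid/complex
    HexNAc-rich forms (several within one or two isotope spacings of series
    members, e.g. HexNAc(6)Hex(3) vs HexNAc(2)Hex(8)), plus fucosylated and
    sialylated variants that produce category-specific oxonium ions.
    """
    comps: list[GlycanComposition] = []
    for n in (3, 4, 5, 6):
        for h in range(3, 10):
            comps.append(GlycanComposition({"HexNAc": n, "Hex": h}))
    for h in range(4, 10):
        comps.append(GlycanComposition({"HexNAc": 2, "Hex": h, "Fuc": 1}))
        comps.append(GlycanComposition({"HexNAc": 4, "Hex": h, "NeuAc": 1}))
    for h in range(5, 8):
        comps.append(GlycanComposition({"HexNAc": 4, "Hex": h, "NeuGc": 1}))
        comps.append(GlycanComposition({"HexNAc": 4, "Hex": h, "Fuc": 1, "NeuAc": 1}))
    return comps


@dataclass
class SimulationConfig:
    """Generative model for synthetic glycoPSM datasets.

    ``true_glycans`` receive spectra according to ``glycan_freqs`` (uniform
    when omitted); ``entrapment_glycans`` never generate spectra but are
    meant to be included in the searched database. ``cofrag_rate`` is the
    probability that a spectrum gains the oxonium ions of a second random
    glycan, mimicking chimeric precursor windows.
    """

    true_glycans: list[GlycanComposition] = field(
        default_factory=lambda: make_glycan_series(2, 4, 20)
    )
    glycan_freqs: Sequence[float] | None = None
    entrapment_glycans: list[GlycanComposition] = field(default_factory=list)
    peptide_mass_range: tuple[float, float] = (800.0, 3000.0)
    mass_error_ppm_sigma: float = 2.0
    isotope_probs: dict[int, float] = field(
        default_factory=lambda: {-1: 0.03, 0: 0.80, 1: 0.10, 2: 0.05, 3: 0.02}
    )
    charge_probs: dict[int, float] = field(
        default_factory=lambda: {2: 0.5, 3: 0.4, 4: 0.1}
    )
    y_decay: float = 0.7  # geometric intensity decay along the ladder
    oxonium_jitter_sigma: float = 0.3  # lognormal sigma on oxonium intensity
    frag_jitter_ppm: float = 2.0  # fragment m/z measurement error
    n_noise_peaks: int = 30
    noise_intensity_scale: float = 0.05  # exponential, fraction of base peak
    cofrag_rate: float = 0.0
    nonglyco_fraction: float = 0.1  # zero-delta PSMs for sigma estimation
    oxonium_table: dict = field(
        default_factory=lambda: dict(DEFAULT_OXONIUM_TABLE)
    )
    max_y_ions: int = 24

    def __post_init__(self) -> None:
        if not (0.0 <= self.cofrag_rate <= 1.0):
            raise ValueError("cofrag_rate must be in [0, 1]")
        if self.mass_error_ppm_sigma < 0:
            raise ValueError("mass_error_ppm_sigma must be >= 0")
        if self.glycan_freqs is not None:
            freqs = np.asarray(self.glycan_freqs, dtype=float)
            if len(freqs) != len(self.true_glycans):
                raise ValueError("glycan_freqs length must match true_glycans")
            if not np.isclose(freqs.sum(), 1.0):
                raise ValueError("glycan_freqs must sum to 1")

    @property
    def all_glycans(self) -> list[GlycanComposition]:
        return list(self.true_glycans) + list(self.entrapment_glycans)


def _choice(rng: np.random.Generator, probs: dict) -> object:
    keys = list(probs)
    p = np.asarray([probs[k] for k in keys], dtype=float)
    return keys[rng.choice(len(keys), p=p / p.sum())]


def synth_spectrum(
    peptide_mass: float,
    glycan: GlycanComposition,
    cfg: SimulationConfig,
    rng: np.random.Generator,
    spectrum_id: str = "sim.1.1.2",
    charge: int | None = None,
) -> tuple[SpectrumPeaks, PsmRecord]:
    """One glycopeptide spectrum plus its PSM row.

    Deposits the glycan's Y-ladder at charges 1-2 with geometric intensity
    decay, its diagnostic oxonium ions near expected intensity with
    lognormal jitter, uniform noise peaks, and — with probability
    ``cofrag_rate`` — the oxonium ions of a second random glycan. The
    precursor delta is the glycan mass plus the drawn isotope error times
    1.00235 Da plus a Gaussian ppm error.
    """
    if charge is None:
        charge = int(_choice(rng, cfg.charge_probs))
    isotope = int(_choice(rng, cfg.isotope_probs))
    err_ppm = rng.normal(0.0, cfg.mass_error_ppm_sigma) if cfg.mass_error_ppm_sigma else 0.0
    delta = glycan.mass + isotope * ISOTOPE_SPACING + glycan.mass * err_ppm * 1e-6
    observed = peptide_mass + delta

    mzs: list[float] = []
    intens: list[float] = []

    def deposit(mz: float, frac: float) -> None:
        if cfg.frag_jitter_ppm:
            mz += mz * rng.normal(0.0, cfg.frag_jitter_ppm) * 1e-6
        mzs.append(mz)
        intens.append(max(frac, 1e-6))

    y_ions = enumerate_y_ions(glycan, cfg.max_y_ions)
    for i, ion in enumerate(y_ions):
        frac = cfg.y_decay**i
        for z in range(1, min(charge, 2) + 1):
            mz = (peptide_mass + ion.value + z * PROTON_MASS) / z
            deposit(mz, frac * (1.0 if z == 1 else 0.5))

    for ion in enumerate_oxonium_ions(glycan, cfg.oxonium_table):
        jitter = (
            np.exp(rng.normal(0.0, cfg.oxonium_jitter_sigma))
            if cfg.oxonium_jitter_sigma
            else 1.0
        )
        deposit(ion.value, ion.expected_intensity * jitter)

    if cfg.cofrag_rate and rng.random() < cfg.cofrag_rate:
        pool = [g for g in cfg.all_glycans if g != glycan]
        if pool:
            contaminant = pool[rng.integers(len(pool))]
            for ion in enumerate_oxonium_ions(contaminant, cfg.oxonium_table):
                jitter = np.exp(rng.normal(0.0, cfg.oxonium_jitter_sigma))
                deposit(ion.value, 0.5 * ion.expected_intensity * jitter)

    if cfg.n_noise_peaks:
        top_mz = max(mzs) if mzs else 2000.0
        for _ in range(cfg.n_noise_peaks):
            deposit(
                rng.uniform(150.0, top_mz),
                rng.exponential(cfg.noise_intensity_scale),
            )

    mz_arr = np.asarray(mzs)
    int_arr = np.asarray(intens)
    scale = 1e5 / int_arr.max()
    spectrum = SpectrumPeaks(
        spectrum_id,
        mz_arr,
        int_arr * scale,
        precursor_mz=(observed + charge * PROTON_MASS) / charge,
        precursor_charge=charge,
    )
    psm = PsmRecord(
        spectrum_id=spectrum_id,
        peptide="SIMULATEDPEPTIDE",
        peptide_mass=peptide_mass,
        observed_mass=observed,
        delta_mass=delta,
        charge=charge,
        is_glyco=True,
    )
    return spectrum, psm


def synth_dataset(
    n_psms: int,
    cfg: SimulationConfig,
    out_dir: str | Path,
    seed: int = 0,
    run_name: str = "sim",
) -> dict[str, Path]:
    """Write a fully seeded dataset: MGF spectra, PSM TSV, and truth table.

    Returns paths keyed ``psm``, ``mgf``, ``truth``. The truth table maps
    each glyco PSM to its generating glycan so calibration tests never
    re-derive ground truth from identifiers. A ``nonglyco_fraction`` of the
    rows are unmodified peptides (near-zero delta) used downstream to
    estimate the typical precursor mass error.
    """
    if n_psms < 1:
        raise ValueError("n_psms must be >= 1")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    freqs = cfg.glycan_freqs
    if freqs is None:
        freqs = np.full(len(cfg.true_glycans), 1.0 / len(cfg.true_glycans))
    freqs = np.asarray(freqs, dtype=float)

    spectra_entries = []
    psm_rows = []
    truth_rows = []
    for i in range(1, n_psms + 1):
        peptide_mass = rng.uniform(*cfg.peptide_mass_range)
        if rng.random() < cfg.nonglyco_fraction:
            charge = int(_choice(rng, cfg.charge_probs))
            err_ppm = rng.normal(0.0, cfg.mass_error_ppm_sigma)
            delta = peptide_mass * err_ppm * 1e-6
            sid = f"{run_name}.{i}.{i}.{charge}"
            psm_rows.append(
                (sid, "SIMULATEDPEPTIDE", peptide_mass, peptide_mass + delta,
                 delta, charge)
            )
            truth_rows.append((sid, ""))
            continue
        glycan = cfg.true_glycans[rng.choice(len(freqs), p=freqs)]
        charge = int(_choice(rng, cfg.charge_probs))
        sid = f"{run_name}.{i}.{i}.{charge}"
        spectrum, psm = synth_spectrum(
            peptide_mass, glycan, cfg, rng, spectrum_id=sid, charge=charge
        )
        spectra_entries.append(
            {
                "m/z array": spectrum.mz,
                "intensity array": spectrum.intensity,
                "params": {
                    "title": sid,
                    "pepmass": spectrum.precursor_mz,
                    "charge": charge,
                    "scans": str(i),
                },
            }
        )
        psm_rows.append(
            (sid, psm.peptide, psm.peptide_mass, psm.observed_mass,
             psm.delta_mass, charge)
        )
        truth_rows.append((sid, glycan.canonical_string))

    mgf_path = out_dir / f"{run_name}.mgf"
    mgf_writer.write(spectra_entries, output=str(mgf_path), file_mode="w")
    psm_path = out_dir / f"{run_name}.psm.tsv"
    with open(psm_path, "w", encoding="utf-8") as fh:
        fh.write(
            "spectrum_id\tpeptide\tpeptide_mass\tobserved_mass\t"
            "delta_mass\tcharge\n"
        )
        for row in psm_rows:
            fh.write(
                f"{row[0]}\t{row[1]}\t{row[2]:.6f}\t{row[3]:.6f}\t"
                f"{row[4]:.6f}\t{row[5]}\n"
            )
    truth_path = out_dir / f"{run_name}.truth.tsv"
    with open(truth_path, "w", encoding="utf-8") as fh:
        fh.write("psm_id\ttrue_glycan\n")
        for sid, glycan_str in truth_rows:
            fh.write(f"{sid}\t{glycan_str}\n")
    return {"psm": psm_path, "mgf": mgf_path, "truth": truth_path}
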