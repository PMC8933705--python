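# glycofdr

Glycan composition assignment and glycan-level FDR control for
peptide-first glycoproteomics open searches.

## The problem

Modern glyco search engines can identify the peptide portion of an
N-glycopeptide first, reporting each spectrum as a peptide plus a *delta
mass* — the difference between the observed precursor neutral mass and the
calculated peptide mass, i.e. the putative intact mass of the attached
glycan. Converting that delta mass to a specific glycan composition is not
straightforward: many residue combinations are close or identical in mass
(NeuGc + Fuc is exactly isobaric with NeuAc + Hex), and precursor
monoisotopic ("off-by-X") peak-picking errors shift the delta by integer
multiples of ~1.00235 Da, creating further confusions such as
HexNAc(6)Hex(3) vs HexNAc(2)Hex(8), which differ by 2.05 Da — almost
exactly two isotope spacings.

`glycofdr` resolves the delta mass to a composition using multiple sources
of spectral evidence and controls the error rate of those assignments with
a glycan-specific target-decoy FDR:

1. **Candidate gathering** — every target and decoy glycan whose intact
   mass lies within a ppm tolerance of the delta mass at an allowed isotope
   error (default −1…+3) is a candidate. The isotope error is the Da gap
   rounded to the nearest integer; the mass error used in scoring is
   computed after removing the isotope mass (error × 1.00235 Da).
2. **Pairwise tournament** — candidates are compared two at a time on four
   log-probability-ratio components, keeping the incumbent unless the
   challenger scores positive:

   S_pairwise = S_Y + S_oxo + β·log|Δm₂/Δm₁| + (α_iso(i₁) − α_iso(i₂))

   S_Y counts Y-ions (peptide + trimmed glycan remnant) unique to each
   candidate, square-root-normalized, per fucose/non-fucose category;
   S_oxo counts diagnostic oxonium ions per residue category (NeuAc,
   NeuGc, Fucose, Phosphate, Sulfate), intensity-weighted by
   observed/expected ratio with a floor at zero so a trace-level hit is
   never penalized. Ions generable by both candidates carry no information
   and are removed.
3. **Absolute rescoring** — the winner is rescored treating all of its
   theoretical ions as unique, with the mass term β·log(σ_unmod/|Δm|)
   referenced to the typical mass error of unmodified peptides in the
   analysis:

   S_absolute = S_abs,Y + S_abs,oxo + β·log|σ_unmod/Δm| + α_iso
4. **FDR estimation** — one decoy per target is generated by shifting the
   intact mass randomly within the tolerance, drawing a random isotope
   error, and shifting every theoretical fragment by a unique 1–20 Da
   offset (so a decoy has exactly the same number of ions of each type as
   its target but matches none of its peaks). FDR at a score threshold is
   decoys/targets above it; each PSM gets the minimum such FDR among
   thresholds that accept it (its q-value). Decoy-best PSMs are reported
   with the best target composition and q = 1. The decoy random seed is
   fixed (derived from the database and parameters, or set explicitly) so
   identical inputs always produce identical outputs.

## Worked example

The bundled simulator writes a complete synthetic analysis — an MGF of
glycopeptide spectra with Y-ion ladders, oxonium ions, noise, and 10%
cofragmentation contamination; the matching PSM table; and a truth table:

```python
from pathlib import Path
from glycofdr.composition import write_glycan_list
from glycofdr.simulate import SimulationConfig, make_entrapment_list, synth_dataset

out = Path("demo")
cfg = SimulationConfig(cofrag_rate=0.1, mass_error_ppm_sigma=2.0,
                       entrapment_glycans=make_entrapment_list())
paths = synth_dataset(500, cfg, out, seed=42, run_name="demo")
write_glycan_list(cfg.all_glycans, out / "glycans.txt")
write_glycan_list(cfg.true_glycans, out / "true_glycans.txt")
```

```bash
glycofdr --psm demo/demo.psm.tsv --spectra demo/demo.mgf \
         --glycan-db demo/glycans.txt --true-glycans demo/true_glycans.txt \
         --seed 42 --out demo/run
```

prints

```
Glycan assignment results
==========================================
PSMs in table                          500
glyco PSMs                             449
assigned (candidates found)            449
decoy-best PSMs                          0
passing q < 0.01                       449
glycan database entries                 63
unique mass offsets                     63
sigma_unmodified (ppm)               1.721
decoy seed                              42
candidate tolerance (ppm)             50.0
fragment tolerance (ppm)              20.0
isotope errors                  (-1, 0, 1, 2, 3)
...
entrapment PSMs                          0
raw entrapment rate (%)              0.000
adjusted entrapment rate (%)        0.0000
```

Of the 500 simulated PSMs, 449 carry a glycan-sized delta mass (the rest
are unmodified peptides, used to estimate the 1.7 ppm typical mass error);
all 449 are assigned, none to a decoy, and at 1% glycan FDR none are
assigned to any of the 46 entrapment glycans that were searched but never
generated. The output `demo/run.psms.tsv` is the input table with appended
columns `glycan_composition`, `glycan_score`, `glycan_q_value`,
`isotope_error`, `mass_error_ppm`; `demo/run.filtered.psms.tsv` keeps rows
with q < 0.01. The first assigned row:

```
spectrum_id  ...  glycan_composition  glycan_score  glycan_q_value  isotope_error
demo.1.1.3   ...  HexNAc(2)Hex(18)    4.0577        0               0
```

The same analysis is available programmatically:

```python
from glycofdr import GlycanAssignmentModel
model = GlycanAssignmentModel.from_files("demo/demo.psm.tsv", ["demo/demo.mgf"],
                                         "demo/glycans.txt")
results = model.fit(seed=42)
print(results.summary())
results.table          # per-PSM DataFrame
results.filter(0.01)   # assignments passing 1% glycan FDR
```

## Input formats

- **PSM table** — TSV with header; required columns (aliases accepted):
  `spectrum_id`, `peptide`, `peptide_mass`, `observed_mass`, `delta_mass`,
  `charge`. Spectrum ids follow `<run>.<scan>.<scan>.<charge>`; MGF titles
  also resolve.
- **Spectra** — mzML or MGF (centroided; profile scans are peak-picked
  with a warning).
- **Glycan list** — one composition per line, `HexNAc(2)Hex(8)` or
  `HexNAc-2_Hex-8` dialect, `#` comments.
- **Config** — INI-style file overriding any scoring constant
  (see `glycofdr.psmio.write_params` for a template of every key).
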