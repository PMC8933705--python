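# Methods

## Scope and model

`glycofdr` assigns a glycan composition — a residue-class count vector,
never a topology — to the delta mass of each PSM produced by a
peptide-first glyco search, and estimates a glycan-level FDR for those
assignments by target-decoy competition. The peptide identification and
peptide-level FDR are upstream concerns: this package consumes their
output (a PSM table) and the fragment spectra.

## Composition algebra

Residue classes are HexNAc, Hex, Fuc, NeuAc, NeuGc, Phospho, Sulfo.
Monoisotopic residue masses are computed from atomic monoisotopic masses
(HexNAc C8H13NO5, Hex C6H10O5, Fuc C6H10O4, NeuAc C11H17NO8, NeuGc
C11H17NO9, Phospho HPO3, Sulfo SO3) rather than stored as rounded
constants, which makes the NeuGc+Fuc ↔ NeuAc+Hex isobaric identity exact
to machine precision — the motivating example of why delta mass alone
cannot identify a composition. Adducts (ammonium, +17.026549 Da)
contribute intact mass but no fragment ions, since the noncovalent adduct
is not retained on fragments. A glycan database is a deduplicated list of
(composition, adduct multiset) forms; the number of distinct intact masses
rounded to two decimals is reported because it is what an open search
would enumerate as mass offsets.

## Candidate gathering and isotope correction

For a delta mass Δ and candidate intact mass m, the precursor isotope
error is round(Δ − m), accepted only if it lies in the allowed set
(default −1…+3; half-integer ties resolve to the smaller corrected error,
then the smaller |isotope|). The corrected mass error is
(Δ − m − k·1.00235)/m in ppm, with 1.00235 Da the average peptide isotope
spacing. Candidates within the tolerance (default 50 ppm) at some allowed
isotope are scored. Delta masses below 140 Da (smaller than any residue)
are classed non-glyco and passed through unscored.

## Decoy generation

One decoy is generated per target entry (per adduct form): the intact mass
is shifted by a uniform draw within ±tolerance (in ppm of the target mass,
because the tolerance is specified in ppm); an isotope error is drawn
uniformly from the allowed set; and each theoretical Y and oxonium ion is
shifted by an independent uniform value in [1, 20] Da, applied in the
positive direction to keep shifted ions inside typical scan ranges (the
magnitude range is the modelled quantity; the direction was an open
choice). A decoy therefore has the same number of ions of each category as
its target but none of them coincide with target ions. Decoy candidacy is
evaluated on the shifted mass; scoring uses the pre-assigned random
isotope and the mass error against the shifted mass.

Determinism: the decoy stream is a pure function of (database, tolerance,
isotope set, seed). When no seed is given, one is derived from a SHA-256
hash of the sorted database entries and the parameters, so identical
inputs always yield identical decoys while any change to the database or
parameters changes them. Each entry gets its own hashed substream, making
decoys independent of database ordering.

## Theoretical ions

*Y-ions* (peptide + trimmed glycan remnant) follow a reconstruction of the
sequential trimming ladder of an N-glycan: HexNAc(1), HexNAc(2),
HexNAc(2)Hex(1..h); when the composition has >2 HexNAc and ≥3 Hex,
branch ions HexNAc(k)Hex(3) for k = 3..HexNAc count are added; if Fuc is
present each ladder member is also emitted with one Fuc (the
fucose-containing category). Sub-compositions never exceed the candidate,
and the list is capped (default 24). The rule and cap are configurable
because the generated set is a modelling choice, not a measured fact.

*Oxonium ions* are diagnostic low-mass fragments emitted per residue
category, active only when the defining residue is present: NeuAc
(274.0921, 292.1027, 657.2349), NeuGc (290.0870, 308.0976, 673.2298),
Fucose (350.1446, 512.1974), Phosphate (243.0264, 405.0793), Sulfate
(284.0440, 446.0968), each with a default expected intensity of 0.25 of
the base peak. These defaults are standard diagnostic series from the
glycoproteomics literature and are fully user-overridable in the config —
analyses of unusual samples should recalibrate them. Generic HexNAc/Hex
oxonium ions are not scored: all candidates sharing the core generate
them, so they never discriminate.

Matching: Y-ions are searched at charges 1..min(precursor charge, 2) —
the charge cap reflects typical HCD glycopeptide behaviour and is
configurable — oxonium ions at their singly protonated m/z. Within the
fragment tolerance (default 20 ppm) the most intense peak supplies the
observed intensity, normalized to the spectrum base peak.

## Scoring

Both scores are sums of log probability ratios; hit alphas are positive,
miss alphas negative, enforced at validation.

**Pairwise** (candidate 1 vs 2, only ions unique to one side):

- Y term, per category t ∈ {nonfucose, fucose}:
  α_hit,t(√U₁ − √U₂) + α_miss,t(√V₁ − √V₂), where U are unique hits and V
  unique misses. The square root compensates for large glycans having more
  possible Y-ions than are typically observed; it is applied to each count
  before differencing, the minimal reading consistent with the additive
  form.
- Oxonium term, per category: each unique hit contributes
  max(0, α_hit·I_obs/I_exp) (signed + for candidate 1, − for candidate 2);
  misses contribute α_miss(V₁ − V₂). The zero floor means a hit at
  negligible intensity cannot count against a candidate — it is simply
  uninformative. No square-root normalization.
- Mass term: β·log(|Δm₂|/|Δm₁|) with β = 1 by default and |Δm| floored at
  ε = 0.01 ppm to bound the logarithm on near-exact matches. Errors are in
  ppm throughout, matching how the tolerances are specified.
- Isotope term: α_iso(i₁) − α_iso(i₂), defaults 0 → 0, +1 → −0.5,
  +2 → −1.0, +3 → −1.5, −1 → −1.0 (a −1 error is rarer than +1 in
  practice, hence the asymmetry).

Every term is antisymmetric, so score(c1,c2) = −score(c2,c1) exactly.

The tournament visits candidates in a canonical order — targets by
|corrected error| then mass, decoys after — replacing the incumbent only
on a strictly positive challenger score (exact ties retain the incumbent).
A fixed order makes the in-principle order-dependent tournament
reproducible.

**Absolute** (the winner, all ions treated as unique): Y term
α_hit√U + α_miss√V per category; oxonium term Σ max(0, α_hit·I_obs/I_exp)
+ α_miss·V; mass term β·log(σ_unmod/max(|Δm|, ε)), oriented so a
smaller-than-typical error scores positive (the orientation of this log is
the one design point where the source material is ambiguous; this
direction is consistent with the pairwise term's reward structure);
isotope term α_iso(i). σ_unmod is estimated as the mean |ppm error| of
PSMs with |delta| < 0.1 Da when any are present, else a 3 ppm default.

Default alphas (all config-overridable): Y hit +1.0 / miss −0.5 in both
categories; oxonium NeuAc/NeuGc hit +2.0 / miss −1.0; Fucose hit +1.0 /
miss −0.5 (fucose oxonium ions are weaker evidence); Phosphate/Sulfate
hit +2.0 / miss −0.5. These preserve the ordering constraints the method
requires (hits > 0 > misses, strong sialic-acid evidence, weak fucose
evidence); tools calibrated on large annotated corpora should replace
them via the config file.

## q-values and reporting

PSMs are ranked by descending absolute score, decoys before targets at
ties (the conservative convention; no pseudocount is added to the plain
decoys/targets ratio). FDR at rank i is cumulative decoys over cumulative
targets capped at 1; q is the running minimum of FDR taken from the worst
rank upward, making q nonincreasing in score and equal to the minimum FDR
over all thresholds that accept the PSM. Decoy-best PSMs are then forced
to q = 1 with the best target composition (tournament over targets only)
substituted, so every row remains interpretable while never passing a
filter; a diagnostic mode prints the decoy identity instead. The full
table is always written; the filtered view applies q < threshold.

Entrapment metrics: raw rate = % of FDR-passing assignments outside the
declared true glycan set; adjusted rate = raw × (true list size / total
list size). The two bracket the realized glycan FDR from above and below
when the search list is much larger than the sample's glycome.

## Synthetic data

The generator emulates the features the scorer consumes: a Y-ion ladder
at charges 1–2 with geometric intensity decay (ratio 0.7 from the core,
charge-2 peaks at half intensity), category oxonium ions at expected
intensity with lognormal jitter (σ = 0.3), uniform-m/z noise peaks with
exponential intensities (default 30 peaks, scale 0.05 of base peak),
2 ppm fragment m/z jitter, a precursor delta equal to the glycan mass
plus isotope error × 1.00235 Da plus Gaussian ppm error, and — with
probability ρ — the oxonium ions of a second random glycan at half
intensity (cofragmentation of co-isolated glycopeptides, the mechanism by
which foreign diagnostic ions mislead assignment). A configurable fraction
(default 10%) of rows are unmodified peptides with near-zero delta,
exercising the σ_unmod estimate. Default condition values (2 ppm precursor
σ, ρ = 0.1 for the calibration runs, the 17-member HexNAc(2)Hex(4..20)
true list) reflect a well-characterized high-mannose benchmark sample
measured on a modern Orbitrap.

What the generator does **not** model: peptide backbone fragmentation
(b/y ions), retention time, charge-dependent fragmentation efficiency,
correlated noise, or realistic glycan abundance tails. Passing calibration
tests therefore demonstrates the correctness and internal calibration of
the scoring and FDR machinery under the stated generative model, not
performance on real instrument data, where the supplementary-calibrated
probability ratios matter.

The bundled entrapment list (46 compositions: HexNAc-rich hybrid/complex
forms plus fucosylated and sialylated variants, several within one or two
isotope spacings of true-series members) is deterministic and disjoint
from the true list by construction.

## Problem sizes and numerical choices

The calibration analyses run at 2,000 simulated PSMs (and 300 for the
noise-free recovery check), sizes at which binomial envelopes around a 1%
nominal rate are already informative while a full run completes in
seconds. Tolerances: candidate 50 ppm, fragment 20 ppm, ε floor 0.01 ppm,
composition masses exact to < 1e-9 Da additivity. Degenerate inputs:
empty spectra score all-miss; PSMs with no candidate in tolerance are
reported unassigned; an empty database or an all-decoy result set is an
error/warning rather than silent output.

## Known limitations

- Single glycosylation event per peptide; multiply glycosylated peptides
  and O-glycan site localization are out of scope.
- All fragment ions of a category share one probability ratio; no
  per-glycan or per-ion calibration.
- The Y-ladder rule is a reconstruction and may differ from any specific
  search engine's internal set; it is deliberately configurable.
- Default probability ratios and oxonium expected intensities are
  order-preserving placeholders, not empirically fitted values.
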