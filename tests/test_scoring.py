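"""Pairwise scoring, tournament selection, and absolute rescoring."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from glycofdr.candidates import (
    CandidateMatch,
    GlycanCandidate,
    IsotopeSet,
    build_candidates,
    find_candidates,
)
from glycofdr.composition import PROTON_MASS, build_database, parse_composition
from glycofdr.ions import IonMatch, TheoreticalIon, Y_NONFUCOSE, match_ions
from glycofdr.scoring import (
    ScoringParams,
    absolute_score,
    pairwise_score,
    score_oxonium_pairwise,
    score_y_pairwise,
    select_best_candidate,
)
from glycofdr.simulate import SimulationConfig, synth_spectrum


def y_matches(n_hit, n_miss, category=Y_NONFUCOSE, start_mass=500.0):
    out = []
    for i in range(n_hit + n_miss):
        ion = TheoreticalIon("Y", category, start_mass + i * 10.0)
        out.append(IonMatch(ion, matched=i < n_hit, observed_intensity=0.5 if i < n_hit else 0.0))
    return out


def oxo_match(category, observed, expected=0.25, mz=300.0):
    ion = TheoreticalIon("oxonium", category, mz, expected)
    return IonMatch(ion, matched=observed > 0, observed_intensity=observed)


def make_match(mass=1000.0, err_ppm=1.0, isotope=0, is_decoy=False, comp="HexNAc(2)Hex(4)"):
    cand = GlycanCandidate(
        parse_composition(comp), (), mass, is_decoy=is_decoy,
        decoy_isotope=isotope if is_decoy else None,
    )
    return CandidateMatch(cand, isotope, err_ppm)


class TestYPairwise:
    def test_hand_evaluated_example(self, default_params):
        """4 unique hits vs 4 unique misses: 1.0*(2-0) + (-0.5)*(0-2) = 3."""
        m1 = y_matches(4, 0)
        m2 = y_matches(0, 4, start_mass=900.0)
        assert score_y_pairwise(m1, m2, default_params) == pytest.approx(3.0)

    def test_no_unique_ions_scores_zero(self, default_params):
        assert score_y_pairwise([], [], default_params) == 0.0

    def test_role_swap_negates(self, default_params):
        m1, m2 = y_matches(3, 2), y_matches(1, 4, start_mass=900.0)
        assert score_y_pairwise(m1, m2, default_params) == pytest.approx(
            -score_y_pairwise(m2, m1, default_params)
        )


class TestOxoniumPairwise:
    def test_hit_at_expected_intensity(self, default_params):
        m = oxo_match("NeuAc", observed=0.25, expected=0.25)
        assert score_oxonium_pairwise([m], [], default_params) == pytest.approx(2.0)

    def test_trace_hit_is_neutral_not_negative(self, default_params):
        m = oxo_match("NeuAc", observed=0.25e-6, expected=0.25)
        s = score_oxonium_pairwise([m], [], default_params)
        assert s == pytest.approx(2.0 * 1e-6)
        assert s >= 0.0

    def test_rivals_missing_ion_helps(self, default_params):
        """A Fucose ion unique to the rival but absent scores +1 for us."""
        rival_miss = oxo_match("Fucose", observed=0.0)
        assert score_oxonium_pairwise([], [rival_miss], default_params) == pytest.approx(0.5)

    def test_hit_floor_property(self, default_params):
        rng = np.random.default_rng(0)
        for _ in range(500):
            m = oxo_match("NeuAc", observed=float(rng.uniform(0, 1e-3)))
            assert score_oxonium_pairwise([m], [], default_params) >= 0.0


class TestPairwiseScore:
    def test_symmetric_inputs_score_zero(self, default_params):
        m1 = make_match(err_ppm=2.0)
        m2 = make_match(mass=1000.1, err_ppm=-2.0)
        s = pairwise_score(m1, m2, [], [], default_params)
        assert s.total == pytest.approx(0.0)

    def test_mass_term_alone(self, default_params):
        m1 = make_match(err_ppm=1.0)
        m2 = make_match(mass=1000.1, err_ppm=10.0)
        s = pairwise_score(m1, m2, [], [], default_params)
        assert s.total == pytest.approx(math.log(10.0))

    def test_shared_ions_cancel(self, default_params):
        shared = y_matches(2, 0)
        s = pairwise_score(
            make_match(), make_match(mass=1000.1), shared, shared, default_params
        )
        assert s.s_y == 0.0

    @given(
        st.integers(0, 5), st.integers(0, 5), st.integers(0, 5), st.integers(0, 5),
        st.floats(0.01, 50), st.floats(0.01, 50),
        st.sampled_from([-1, 0, 1, 2, 3]), st.sampled_from([-1, 0, 1, 2, 3]),
    )
    @settings(max_examples=300, deadline=None)
    def test_antisymmetry(self, u1, v1, u2, v2, e1, e2, i1, i2):
        params = ScoringParams()
        m1 = make_match(err_ppm=e1, isotope=i1)
        m2 = make_match(mass=1000.1, err_ppm=e2, isotope=i2)
        im1 = y_matches(u1, v1)
        im2 = y_matches(u2, v2, start_mass=900.0)
        a = pairwise_score(m1, m2, im1, im2, params).total
        b = pairwise_score(m2, m1, im2, im1, params).total
        assert a == pytest.approx(-b, abs=1e-12)

    def test_extra_matched_ion_never_hurts(self, default_params):
        base = y_matches(2, 1)
        better = y_matches(3, 1)
        m1 = make_match()
        m2 = make_match(mass=1000.1)
        rival = y_matches(1, 2, start_mass=900.0)
        s_base = pairwise_score(m1, m2, base, rival, default_params).total
        s_more = pairwise_score(m1, m2, better, rival, default_params).total
        assert s_more >= s_base

    def test_larger_mass_error_never_helps(self, default_params):
        m2 = make_match(mass=1000.1, err_ppm=5.0)
        s_small = pairwise_score(make_match(err_ppm=1.0), m2, [], [], default_params).total
        s_large = pairwise_score(make_match(err_ppm=8.0), m2, [], [], default_params).total
        assert s_large <= s_small


class TestTournament:
    def _spectrum_for(self, comp_str, pep=1500.0, charge=2):
        cfg = SimulationConfig(
            mass_error_ppm_sigma=0.0, frag_jitter_ppm=0.0,
            n_noise_peaks=0, cofrag_rate=0.0, oxonium_jitter_sigma=0.0,
            isotope_probs={0: 1.0},
        )
        rng = np.random.default_rng(1)
        comp = parse_composition(comp_str)
        return synth_spectrum(pep, comp, cfg, rng, charge=charge)

    def test_single_candidate_returned(self, default_params, yeast_db, iso_set):
        cands = [c for c in build_candidates(yeast_db, 50.0, iso_set, seed=1)
                 if not c.is_decoy]
        spectrum, psm = self._spectrum_for("HexNAc(2)Hex(4)")
        matches = find_candidates(psm.delta_mass, cands[:1], 50.0, iso_set)
        best, _, _ = select_best_candidate(
            matches, spectrum, psm.peptide_mass, psm.charge, default_params
        )
        assert best.candidate.label == "HexNAc(2)Hex(4)"

    def test_supported_candidate_wins(self, default_params, iso_set):
        """The candidate whose Y-ladder is in the spectrum beats a rival."""
        db = build_database(
            [parse_composition("HexNAc(2)Hex(8)"), parse_composition("HexNAc(6)Hex(3)")]
        )
        cands = [c for c in build_candidates(db, 50.0, iso_set, seed=1)
                 if not c.is_decoy]
        spectrum, psm = self._spectrum_for("HexNAc(2)Hex(8)")
        # +2 isotope-shifted delta makes both candidates eligible
        delta = psm.delta_mass + 2 * 1.00235
        matches = find_candidates(delta, cands, 50.0, iso_set)
        assert len(matches) == 2
        best, margin, _ = select_best_candidate(
            matches, spectrum, psm.peptide_mass, psm.charge, default_params
        )
        assert best.candidate.label == "HexNAc(2)Hex(8)"
        assert margin > 0

    def test_deterministic_winner(self, default_params, yeast_db, iso_set):
        cands = build_candidates(yeast_db, 50.0, iso_set, seed=1)
        spectrum, psm = self._spectrum_for("HexNAc(2)Hex(10)")
        matches = find_candidates(psm.delta_mass, cands, 50.0, iso_set)
        winners = set()
        for _ in range(3):
            best, _, _ = select_best_candidate(
                matches, spectrum, psm.peptide_mass, psm.charge, default_params
            )
            winners.add(best.candidate.label)
        assert winners == {"HexNAc(2)Hex(10)"}

    def test_true_glycan_recovery_noise_free(self, default_params, yeast_db, iso_set):
        """On noise-free spectra the generating glycan wins >= 95% of cases."""
        cfg = SimulationConfig(
            mass_error_ppm_sigma=0.5, frag_jitter_ppm=0.0, n_noise_peaks=0,
            cofrag_rate=0.0, oxonium_jitter_sigma=0.0,
        )
        rng = np.random.default_rng(42)
        cands = build_candidates(yeast_db, 50.0, iso_set, seed=7)
        wins = total = 0
        for _ in range(100):
            comp = cfg.true_glycans[rng.integers(len(cfg.true_glycans))]
            pep = rng.uniform(800, 2500)
            spectrum, psm = synth_spectrum(pep, comp, cfg, rng)
            matches = find_candidates(psm.delta_mass, cands, 50.0, iso_set)
            if not matches:
                continue
            total += 1
            best, _, _ = select_best_candidate(
                matches, spectrum, psm.peptide_mass, psm.charge, default_params
            )
            wins += best.candidate.label == comp.canonical_string
        assert total >= 95
        assert wins / total >= 0.95


class TestAbsoluteScore:
    def test_all_ions_matched_closed_form(self, default_params, iso_set, make_spectrum):
        """Full ladder at expected intensity, |dm| = sigma/e, isotope 0."""
        comp = parse_composition("HexNAc(2)Hex(2)")
        db = build_database([comp])
        cand = [c for c in build_candidates(db, 50.0, iso_set, seed=1)
                if not c.is_decoy][0]
        pep = 1200.0
        peaks = [(pep + ion.value + PROTON_MASS, 100.0) for ion in cand.y_ions]
        spectrum = make_spectrum(peaks, charge=1)
        ion_matches = match_ions(spectrum, cand.ions, pep, 1, 20.0)
        err = default_params.sigma_unmodified / math.e
        match = CandidateMatch(cand, 0, err)
        s = absolute_score(match, ion_matches, default_params)
        n_y = len(cand.y_ions)
        assert s.s_y == pytest.approx(1.0 * math.sqrt(n_y))
        assert s.s_oxo == 0.0
        assert s.s_mass == pytest.approx(1.0)
        assert s.s_isotope == 0.0
        assert s.total == s.s_y + s.s_oxo + s.s_mass + s.s_isotope

    def test_no_ions_matched_miss_penalties_only(self, default_params, iso_set, make_spectrum):
        comp = parse_composition("HexNAc(2)Hex(2)")
        db = build_database([comp])
        cand = [c for c in build_candidates(db, 50.0, iso_set, seed=1)
                if not c.is_decoy][0]
        spectrum = make_spectrum([(100.0, 10.0)])
        ion_matches = match_ions(spectrum, cand.ions, 1200.0, 1, 20.0)
        match = CandidateMatch(cand, 0, default_params.sigma_unmodified)
        s = absolute_score(match, ion_matches, default_params)
        assert s.s_mass == pytest.approx(0.0)  # log(sigma/sigma) = 0
        assert s.s_y == pytest.approx(-0.5 * math.sqrt(len(cand.y_ions)))
        assert s.s_oxo == 0.0
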