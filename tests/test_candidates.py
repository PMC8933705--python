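"""Isotope assignment, decoy generation, and candidate gathering."""

import numpy as np
import pytest
from scipy import stats

from glycofdr.candidates import (
    ISOTOPE_SPACING,
    IsotopeSet,
    assign_isotope,
    build_candidates,
    effective_seed,
    find_candidates,
    generate_decoys,
)
from glycofdr.composition import build_database, parse_composition
from glycofdr.simulate import make_glycan_series

HEX8 = parse_composition("HexNAc(2)Hex(8)")
HEX6_3 = parse_composition("HexNAc(6)Hex(3)")


class TestAssignIsotope:
    def test_plus_one_isotope(self, iso_set):
        iso, err = assign_isotope(1703.5837, 1702.5813, iso_set)
        assert iso == 1
        # residual: 1.0024 - 1.00235 = 5e-5 Da on 1702.58 Da ~ 0.03 ppm
        assert err == pytest.approx(5e-5 / 1702.5813 * 1e6, abs=1e-3)

    def test_exact_match_is_isotope_zero(self, iso_set):
        iso, err = assign_isotope(1702.5813, 1702.5813, iso_set)
        assert iso == 0 and err == 0.0

    def test_plus_two_isotope(self, iso_set):
        iso, err = assign_isotope(1704.6346, 1702.5813, iso_set)
        assert iso == 2
        assert err == pytest.approx(28.5, abs=0.2)

    def test_disallowed_isotope_is_no_match(self, iso_set):
        # the 2.05 Da gap between HexNAc(6)Hex(3) and HexNAc(2)Hex(8)
        # rounds to -2, which the default set does not allow
        assert assign_isotope(HEX8.mass, HEX6_3.mass, iso_set) is None


class TestDecoys:
    def test_determinism_same_seed(self, yeast_db, iso_set):
        d1 = generate_decoys(yeast_db, 50.0, iso_set, seed=11)
        d2 = generate_decoys(yeast_db, 50.0, iso_set, seed=11)
        assert d1 == d2

    def test_determinism_without_user_seed(self, yeast_db, iso_set):
        assert generate_decoys(yeast_db, 50.0, iso_set) == generate_decoys(
            yeast_db, 50.0, iso_set
        )

    def test_changed_database_changes_decoys(self, iso_set):
        db1 = build_database(make_glycan_series(2, 4, 20))
        db2 = build_database(
            make_glycan_series(2, 4, 19) + [parse_composition("HexNAc(3)Hex(4)")]
        )
        d1 = {d.label: d for d in generate_decoys(db1, 50.0, iso_set)}
        d2 = {d.label: d for d in generate_decoys(db2, 50.0, iso_set)}
        assert d1 != d2

    def test_mass_shift_within_tolerance(self, yeast_db, iso_set):
        for d in generate_decoys(yeast_db, 50.0, iso_set, seed=3):
            target_mass = d.intact_mass - d.decoy_mass_shift
            assert abs(d.decoy_mass_shift / target_mass * 1e6) <= 50.0

    def test_decoy_isotope_in_allowed_set(self, yeast_db, iso_set):
        for d in generate_decoys(yeast_db, 50.0, iso_set, seed=3):
            assert d.decoy_isotope in iso_set.allowed

    def test_fragment_shifts_in_range(self, yeast_db, iso_set):
        targets = {
            c.label: c
            for c in build_candidates(yeast_db, 50.0, iso_set, seed=3)
            if not c.is_decoy
        }
        for d in generate_decoys(yeast_db, 50.0, iso_set, seed=3):
            t = targets[d.label.removeprefix("DECOY_")]
            for dion, tion in zip(d.ions, t.ions):
                shift = dion.value - tion.value
                assert 1.0 <= shift <= 20.0

    def test_per_category_ion_counts_preserved(self, iso_set):
        db = build_database(
            [parse_composition("HexNAc(4)Hex(5)Fuc(1)NeuAc(1)")]
        )
        target = build_candidates(db, 50.0, iso_set, seed=5)[0]
        decoy = generate_decoys(db, 50.0, iso_set, seed=5)[0]

        def counts(cand):
            out = {}
            for ion in cand.ions:
                out[(ion.kind, ion.category)] = out.get((ion.kind, ion.category), 0) + 1
            return out

        assert counts(target) == counts(decoy)

    def test_empty_database_rejected(self, iso_set):
        from glycofdr.composition import GlycanDatabase

        with pytest.raises(ValueError):
            generate_decoys(GlycanDatabase([]), 50.0, iso_set, seed=1)


class TestFindCandidates:
    def test_isotope_gap_excludes_candidate(self, iso_set):
        db = build_database([HEX8, HEX6_3])
        cands = [c for c in build_candidates(db, 50.0, iso_set, seed=1)
                 if not c.is_decoy]
        matches = find_candidates(HEX8.mass, cands, 50.0, iso_set)
        labels = {m.candidate.label for m in matches}
        assert "HexNAc(2)Hex(8)" in labels
        assert "HexNAc(6)Hex(3)" not in labels  # would need isotope -2

    def test_both_match_at_plus_two(self, iso_set):
        db = build_database([HEX8, HEX6_3])
        cands = [c for c in build_candidates(db, 50.0, iso_set, seed=1)
                 if not c.is_decoy]
        delta = HEX8.mass + 2 * ISOTOPE_SPACING + HEX8.mass * 5e-6
        matches = {m.candidate.label: m for m in
                   find_candidates(delta, cands, 50.0, iso_set)}
        assert matches["HexNAc(2)Hex(8)"].isotope_error == 2
        assert matches["HexNAc(6)Hex(3)"].isotope_error == 0

    def test_far_delta_returns_empty(self, yeast_db, iso_set):
        cands = build_candidates(yeast_db, 50.0, iso_set, seed=1)
        assert find_candidates(500.0, cands, 50.0, iso_set) == []

    def test_agrees_with_bruteforce_scan(self, yeast_db, iso_set):
        """Recall oracle: exhaustive (entry x isotope) scan finds the same set."""
        cands = build_candidates(yeast_db, 50.0, iso_set, seed=9)
        rng = np.random.default_rng(4)
        for _ in range(200):
            delta = rng.uniform(800, 3600)
            got = {m.candidate.label for m in
                   find_candidates(delta, cands, 50.0, iso_set)}
            brute = set()
            for c in cands:
                for k in iso_set.allowed:
                    resid = (delta - c.intact_mass - k * iso_set.spacing)
                    if abs(resid / c.intact_mass * 1e6) <= 50.0:
                        brute.add(c.label)
            assert got == brute

    def test_decoy_error_distribution_uniform(self, iso_set):
        """Decoy corrected errors look uniform across +/- tol; targets near 0."""
        comps = []
        for n in range(1, 7):
            for h in range(0, 16):
                for f in range(0, 3):
                    for s in range(0, 2):
                        comps.append(
                            parse_composition(
                                f"HexNAc({n})Hex({h})Fuc({f})NeuAc({s})"
                            )
                        )
        comps = [c for c in comps if c.mass > 200]
        db = build_database(comps)
        cands = build_candidates(db, 50.0, iso_set, seed=2)
        decoys = {c.label.removeprefix("DECOY_"): c for c in cands if c.is_decoy}
        rng = np.random.default_rng(8)
        target_errs, decoy_errs = [], []
        for c in cands:
            if c.is_decoy:
                continue
            delta = c.intact_mass * (1 + rng.normal(0, 0.5) * 1e-6)
            for m in find_candidates(delta, [c, decoys[c.label]], 50.0, iso_set):
                (decoy_errs if m.candidate.is_decoy else target_errs).append(
                    m.corrected_mass_error
                )
        assert len(decoy_errs) >= 500
        assert abs(np.mean(target_errs)) < 0.5
        p = stats.kstest(decoy_errs, "uniform", args=(-50.0, 100.0)).pvalue
        assert p > 0.01


class TestSeedPolicy:
    def test_effective_seed_stable(self, yeast_db, iso_set):
        assert effective_seed(yeast_db, 50.0, iso_set) == effective_seed(
            yeast_db, 50.0, iso_set
        )

    def test_effective_seed_tracks_parameters(self, yeast_db, iso_set):
        assert effective_seed(yeast_db, 50.0, iso_set) != effective_seed(
            yeast_db, 20.0, iso_set
        )
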