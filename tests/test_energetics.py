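import numpy as np
import pytest

from mirspan.energetics import (
    EnergyParams,
    SiteWindow,
    duplex_energy,
    extract_window,
    fold_mfe,
    opening_energy,
    site_energies,
)
from mirspan.seedscan import SeedSite, SeedType
from mirspan.seqmodel import RegionKind

from tests.oracles import oracle_duplex, oracle_fold


def _site(start, end, stype=SeedType.T2t8A1):
    return SeedSite("g", RegionKind.UTR3, start, end, stype)


class TestWindowExtraction:
    def test_interior_site_gets_58nt_window(self):
        seq = "A" * 300
        w = extract_window(seq, _site(100, 108))
        assert len(w.sequence) == 58
        assert (w.site_start, w.site_end) == (30, 38)
        assert w.region_offset == 70

    def test_site_at_start_truncates_5p_flank(self):
        seq = "A" * 100
        w = extract_window(seq, _site(0, 8))
        assert len(w.sequence) == 28  # site + 20 nt 3' flank only
        assert (w.site_start, w.site_end) == (0, 8)

    def test_six_nt_site_gets_56nt_window(self):
        seq = "A" * 300
        w = extract_window(seq, _site(100, 106, SeedType.T2t7))
        assert len(w.sequence) == 56

    def test_site_past_region_end_is_error(self):
        with pytest.raises(ValueError):
            extract_window("A" * 10, _site(5, 13))


class TestDuplexEnergy:
    def test_three_stacked_gc_pairs(self, toy_params):
        # four G:C pairs -> three stack terms of -3 each
        assert duplex_energy("GGGG", "CCCC", toy_params) == pytest.approx(-9.0)

    def test_no_possible_pair_scores_zero(self, toy_params, default_params):
        for p in (toy_params, default_params):
            assert duplex_energy("GGGG", "AAAA", p) == 0.0

    def test_strand_role_symmetry_for_palindrome(self, toy_params):
        a, b = "GGAA", "UUCC"
        assert duplex_energy(a, b, toy_params) == pytest.approx(
            duplex_energy(b, a, toy_params)
        )

    def test_n_is_unpairable(self, toy_params):
        assert duplex_energy("GGGG", "NNNN", toy_params) == 0.0

    def test_too_short_strand_is_error(self, toy_params):
        with pytest.raises(ValueError):
            duplex_energy("G", "CCCC", toy_params)

    def test_matches_enumeration_on_random_pairs(self, default_params, toy_params):
        rng = np.random.default_rng(21)
        for _ in range(60):
            x = "".join(rng.choice(list("ACGU"), rng.integers(4, 11)))
            y = "".join(rng.choice(list("ACGU"), rng.integers(4, 11)))
            for p in (default_params, toy_params):
                assert duplex_energy(x, y, p) == pytest.approx(
                    oracle_duplex(x, y, p), abs=1e-9
                )

    def test_appending_nonpairing_flank_never_raises_energy(self, toy_params):
        rng = np.random.default_rng(22)
        for _ in range(30):
            x = "".join(rng.choice(list("ACGU"), 8))
            y = "".join(rng.choice(list("ACGU"), 10))
            base = duplex_energy(x, y, toy_params)
            assert duplex_energy(x, y + "NNNN", toy_params) <= base + 1e-12


class TestFolding:
    def test_hairpin_mfe(self, toy_params):
        # GGGG-AAAA-CCCC: 3 stacks (-9) + 4-nt loop (1 nt beyond minimum, +4)
        assert fold_mfe("GGGGAAAACCCC", toy_params) == pytest.approx(-5.0)

    def test_unfoldable_sequence_scores_zero(self, toy_params, default_params):
        for p in (toy_params, default_params):
            assert fold_mfe("AAAAAAAAAAAA", p) == 0.0

    def test_matches_enumeration_on_random_windows(self, default_params, toy_params):
        rng = np.random.default_rng(23)
        for _ in range(40):
            s = "".join(rng.choice(list("ACGU"), rng.integers(8, 15)))
            for p in (default_params, toy_params):
                assert fold_mfe(s, p) == pytest.approx(oracle_fold(s, p), abs=1e-9)

    def test_constrained_fold_matches_enumeration(self, default_params):
        rng = np.random.default_rng(24)
        for _ in range(20):
            s = "".join(rng.choice(list("ACGU"), 12))
            span = tuple(range(3, 7))
            assert fold_mfe(s, default_params, forced_unpaired=span) == pytest.approx(
                oracle_fold(s, default_params, forced_unpaired=span), abs=1e-9
            )


class TestOpeningEnergy:
    def test_no_self_complementarity_costs_nothing(self, toy_params):
        w = SiteWindow(sequence="AAAACCCCAAAA", site_start=4, site_end=8)
        assert opening_energy(w, toy_params) == 0.0

    def test_blocking_a_hairpin_arm_costs_its_stability(self, toy_params):
        w = SiteWindow(sequence="GGGGAAAACCCC", site_start=8, site_end=12)
        assert opening_energy(w, toy_params) == pytest.approx(5.0)

    def test_inactive_constraint_costs_nothing(self, toy_params):
        # the site lies in the hairpin loop, already unpaired in the MFE
        w = SiteWindow(sequence="GGGGAAAACCCC", site_start=4, site_end=8)
        assert opening_energy(w, toy_params) == 0.0

    def test_nonnegative_on_random_windows(self, default_params):
        rng = np.random.default_rng(25)
        for _ in range(15):
            seq = "".join(rng.choice(list("ACGU"), 40))
            w = SiteWindow(sequence=seq, site_start=16, site_end=24)
            assert opening_energy(w, default_params) >= 0.0


class TestSiteEnergies:
    def test_ddg_is_duplex_minus_open(self, toy_params):
        w = SiteWindow(sequence="GGGGAAAACCCC", site_start=8, site_end=12)
        e = site_energies("GGGG", w, toy_params)
        assert e.ddG == pytest.approx(e.dG_duplex - e.dG_open)
        assert e.dG_open == pytest.approx(5.0)

    def test_zero_opening_cost_means_ddg_equals_duplex(self, toy_params):
        w = SiteWindow(sequence="AAAACCCCAAAA", site_start=4, site_end=8)
        e = site_energies("GGGG", w, toy_params)
        assert e.dG_open == 0.0 and e.ddG == e.dG_duplex


class TestParams:
    def test_param_file_round_trip(self, tmp_path, default_params):
        assert default_params.version == "reduced-v1"
        # every legal pair quartet has a finite stacking term
        finite = [
            default_params.stack[a][b][c][d]
            for a in range(4)
            for b in range(4)
            for c in range(4)
            for d in range(4)
            if default_params.stack[a][b][c][d] != float("inf")
        ]
        assert len(finite) == 36 and all(e < 0 for e in finite)

    def test_external_engine_contract(self):
        """The ViennaRNA adapter satisfies the same sign contracts as the
        bundled engine."""
        pytest.importorskip("RNA")
        from mirspan.external import ViennaEngine

        eng = ViennaEngine()
        w = SiteWindow(
            sequence="GCGCGCAAAAAAAGCGCGCAAAAAAGGGCAUGCCAAAA",
            site_start=27,
            site_end=35,
        )
        e = eng.site_energies("UGGCAUGCAAGGAUCCAAGGAA", w)
        assert e.dG_duplex <= 0.0
        assert e.dG_open >= 0.0
        assert e.ddG == pytest.approx(e.dG_duplex - e.dG_open)
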