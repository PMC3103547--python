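"""Titration thermodynamics: curves, pKas, shifts, ionization flags."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from mutscan.structio import Chain, Structure
from mutscan.synthdata import make_titration_fixture
from mutscan.titration import (
    MODEL_PKA, PkaResult, TitratableSite, TitrationSystem,
    build_titration_system, compute_pkas, find_titratable,
    flag_ionization_discrepancy, intrinsic_pka, ionized_fraction,
    pka_shift_report, titration_curve,
)


def single_site(aa="ASP", pka=4.0):
    charge = -1 if aa in ("ASP", "GLU", "TYR", "CYS") else +1
    site = TitratableSite("C", 1, aa, pka, charge, pka)
    return TitrationSystem([site], np.zeros((1, 1)))


def result(aa, number, pka, charge=None):
    if charge is None:
        charge = -1 if aa in ("ASP", "GLU", "TYR", "CYS") else +1
    return PkaResult(TitratableSite("C", number, aa, pka, charge, pka), pka)


class TestFindTitratable:
    def test_poly_ala_has_none(self):
        from test_structio import make_chain

        s = Structure([make_chain("A", [1, 2, 3], "AAA")])
        assert find_titratable(s) == []

    def test_counts_and_order(self):
        from test_structio import make_chain

        s = Structure([make_chain("A", [1, 2, 3, 4], "DKDA")])
        sites = find_titratable(s)
        assert [t.aa for t in sites] == ["ASP", "LYS", "ASP"]
        assert [t.residue_number for t in sites] == [1, 2, 3]

    def test_model_pkas_from_table(self, toy_dimer):
        for t in find_titratable(toy_dimer):
            assert t.model_pka == MODEL_PKA[t.aa]

    def test_toy_monomer_documented_count(self, toy_dimer):
        mono = Structure([toy_dimer.chain("C").copy()])
        sites = find_titratable(mono)
        assert [t.label for t in sites] == [
            "C:ASP12", "C:GLU14", "C:GLU18", "C:HIS21"
        ]


class TestIntrinsicPka:
    def test_isolated_exposed_site_recovers_model_value(self, toy_dimer):
        res = toy_dimer.chain("C").residue(18).copy()  # GLU
        iso = Structure([Chain("C", [res])])
        site = find_titratable(iso)[0]
        assert intrinsic_pka(site, iso) == pytest.approx(4.4, abs=1e-9)

    def test_acid_near_negative_charge_shifts_up(self, toy_dimer, ffa):
        """Fixed -1 background charge next to an acid penalizes ionization."""
        from conftest import make_ion
        from dataclasses import replace

        res = toy_dimer.chain("C").residue(18).copy()  # GLU
        tip = res.atom("CD").pos
        ion = make_ion("NEG", 50, tip + np.array([3.0, 0.0, 0.0]))
        iso = Structure([Chain("C", [res, ion])])
        p = replace(
            ffa,
            charges={**ffa.charges, ("NEG", "Q1"): (-1.0, "ION")},
            classes={**ffa.classes, "ION": (3.0, 0.0, 2.0)},
        )
        site = find_titratable(iso)[0]
        assert intrinsic_pka(site, iso, p) > 4.4

    def test_base_near_negative_charge_shifts_up(self, toy_dimer, ffa):
        from conftest import make_ion
        from dataclasses import replace

        res = toy_dimer.chain("C").residue(21).copy()  # HIS
        tip = res.atom("NE2").pos
        ion = make_ion("NEG", 50, tip + np.array([3.0, 0.0, 0.0]))
        iso = Structure([Chain("C", [res, ion])])
        p = replace(
            ffa,
            charges={**ffa.charges, ("NEG", "Q1"): (-1.0, "ION")},
            classes={**ffa.classes, "ION": (3.0, 0.0, 2.0)},
        )
        site = find_titratable(iso)[0]
        assert intrinsic_pka(site, iso, p) > MODEL_PKA["HIS"]

    def test_burial_raises_acid_pka(self, toy_dimer):
        """Desolvation: the buried-flanked Glu18 pays more than exposed Glu14
        in the monomer; both desolvation shifts are non-negative."""
        mono = Structure([toy_dimer.chain("C").copy()])
        sys_ = build_titration_system(mono)
        by = {t.label: t.intrinsic_pka for t in sys_.sites}
        assert by["C:GLU18"] >= 4.4 - 0.05
        assert by["C:GLU14"] >= 4.4 - 0.05


class TestTitrationCurve:
    def test_single_acid_midpoint(self):
        sys_ = single_site("ASP", 4.0)
        frac = titration_curve(sys_, [4.0], method="enumerate")
        assert frac[0, 0] == pytest.approx(0.5, abs=1e-12)

    def test_single_site_follows_henderson_hasselbalch(self):
        sys_ = single_site("LYS", 10.4)
        grid = np.array([8.0, 9.0, 10.4, 11.0, 12.0])
        frac = titration_curve(sys_, grid, method="enumerate")[:, 0]
        expected = 1.0 / (1.0 + 10.0 ** (grid - 10.4))
        np.testing.assert_allclose(frac, expected, atol=1e-12)

    def test_uncoupled_sites_factorize(self):
        a = single_site("ASP", 4.0)
        b = single_site("LYS", 10.4)
        sites = a.sites + [TitratableSite("C", 2, "LYS", 10.4, +1, 10.4)]
        both = TitrationSystem(sites, np.zeros((2, 2)))
        grid = [3.0, 5.0, 8.0, 11.0]
        joint = titration_curve(both, grid, method="enumerate")
        fa = titration_curve(a, grid, method="enumerate")[:, 0]
        fb = titration_curve(b, grid, method="enumerate")[:, 0]
        np.testing.assert_allclose(joint[:, 0], fa, atol=1e-12)
        np.testing.assert_allclose(joint[:, 1], fb, atol=1e-12)

    def test_mc_matches_enumeration_six_sites(self):
        sys_ = make_titration_fixture(6, 0.8, seed=3)
        grid = [3.0, 5.0, 7.0, 9.0, 11.0]
        exact = titration_curve(sys_, grid, method="enumerate")
        mc = titration_curve(sys_, grid, method="monte_carlo", seed=11,
                             mc_sweeps=100_000)
        assert np.abs(exact - mc).max() < 0.01

    def test_enumeration_size_guard(self):
        sys_ = make_titration_fixture(6, 0.0, seed=1)
        sites = sys_.sites * 4  # 24 sites
        big = TitrationSystem(list(sites), np.zeros((24, 24)))
        with pytest.raises(ValueError, match="monte_carlo"):
            titration_curve(big, [7.0], method="enumerate")

    def test_mc_requires_seed(self):
        sys_ = single_site()
        with pytest.raises(ValueError, match="seed"):
            titration_curve(sys_, [7.0], method="monte_carlo")

    @given(pka=st.floats(min_value=2.0, max_value=12.0))
    def test_single_site_protonation_monotone_in_ph(self, pka):
        sys_ = single_site("GLU", pka)
        grid = np.arange(0.0, 14.0, 0.5)
        frac = titration_curve(sys_, grid, method="enumerate")[:, 0]
        assert np.all(np.diff(frac) <= 1e-12)


class TestComputePkas:
    def test_isolated_sites_recover_model_values(self):
        sys_ = make_titration_fixture(8, 0.0, seed=2)
        for r in compute_pkas(sys_, method="enumerate"):
            assert r.pka == pytest.approx(r.site.intrinsic_pka, abs=0.05)

    def test_coupled_identical_acids_split_macroscopically(self):
        """Two equivalent acids with 1 pK of repulsive coupling: by symmetry
        each site's half-protonation point shifts up by about W/2, while the
        stepwise (macroscopic) midpoints — where total protonation crosses
        1.5 and 0.5 — split to either side of the model value."""
        sites = [
            TitratableSite("C", 1, "ASP", 4.0, -1, 4.0),
            TitratableSite("C", 2, "ASP", 4.0, -1, 4.0),
        ]
        w = np.array([[0.0, 1.364], [1.364, 0.0]])
        sys_ = TitrationSystem(sites, w)
        per_site = compute_pkas(sys_, method="enumerate")
        assert per_site[0].pka == pytest.approx(per_site[1].pka, abs=1e-6)
        assert per_site[0].pka == pytest.approx(4.0 + 0.5, abs=0.1)
        grid = np.arange(2.0, 8.0, 0.01)
        total = titration_curve(sys_, grid, method="enumerate").sum(axis=1)
        pk1 = grid[np.argmin(np.abs(total - 1.5))]
        pk2 = grid[np.argmin(np.abs(total - 0.5))]
        assert pk1 < 4.0 < pk2
        assert pk2 - pk1 > 1.0

    def test_out_of_range_sites_get_sentinels(self):
        low = single_site("ASP", -3.0)
        r = compute_pkas(low, method="enumerate")[0]
        assert r.pka == -1.0 and "below-range" in r.flags
        high = single_site("LYS", 20.0)
        r = compute_pkas(high, method="enumerate")[0]
        assert r.pka == 15.0 and "above-range" in r.flags

    def test_structure_input_accepted(self, toy_dimer):
        mono = Structure([toy_dimer.chain("C").copy()])
        res = compute_pkas(mono, method="enumerate")
        assert len(res) == 4
        assert all(np.isfinite(r.pka) for r in res)


class TestPkaShiftReport:
    def test_identity_gives_zero(self):
        wt = [result("ASP", 1, 4.1), result("LYS", 2, 10.0)]
        rep = pka_shift_report(wt, wt)
        assert rep.sum_abs == 0.0
        assert all(v == 0.0 for v in rep.shifts.values())

    def test_hand_computed_sum(self):
        wt = [result("ASP", 1, 4.0), result("LYS", 2, 10.0)]
        mut = [result("ASP", 1, 4.7), result("LYS", 2, 9.5)]
        rep = pka_shift_report(wt, mut)
        assert rep.sum_abs == pytest.approx(1.2, abs=1e-12)
        assert rep.n_sites == 2

    def test_mutated_site_excluded_from_pairing(self):
        wt = [result("ASP", 1, 4.0), result("GLU", 5, 4.5)]
        mut = [result("ASP", 1, 4.3)]  # position 5 lost its titratable group
        rep = pka_shift_report(wt, mut)
        assert rep.n_sites == 1
        assert rep.unpaired == [("C", 5)]
        assert rep.sum_abs == pytest.approx(0.3)

    def test_empty_overlap_rejected(self):
        with pytest.raises(ValueError):
            pka_shift_report([result("ASP", 1, 4.0)], [result("GLU", 2, 4.4)])

    @given(
        shifts=st.lists(
            st.floats(min_value=-5, max_value=5, allow_nan=False), min_size=2,
            max_size=10,
        )
    )
    def test_sum_additive_under_partition(self, shifts):
        wt = [result("ASP", i + 1, 4.0) for i in range(len(shifts))]
        mut = [result("ASP", i + 1, 4.0 + s) for i, s in enumerate(shifts)]
        whole = pka_shift_report(wt, mut).sum_abs
        k = len(shifts) // 2
        part = (
            pka_shift_report(wt[:k], mut[:k]).sum_abs
            + pka_shift_report(wt[k:], mut[k:]).sum_abs
        )
        assert whole == pytest.approx(part, abs=1e-9)
        assert whole >= max(abs(s) for s in shifts) - 1e-9


class TestIonizationDiscrepancy:
    def test_same_pka_not_flagged(self):
        mono = [result("ASP", 1, 4.0)]
        dim = [result("ASP", 1, 4.0)]
        assert not flag_ionization_discrepancy(mono, dim, ("C", 1)).flagged

    def test_acid_shifted_across_contexts_flagged(self):
        mono = [result("ASP", 1, 4.0)]
        dim = [result("ASP", 1, 9.0)]
        rec = flag_ionization_discrepancy(mono, dim, ("C", 1), ph=7.0)
        assert rec.flagged
        assert rec.fraction_monomer == pytest.approx(1.0, abs=1e-2)
        assert rec.fraction_dimer == pytest.approx(0.01, abs=0.01)

    def test_his_ionized_in_monomer_neutral_in_dimer(self):
        """Monomer pKa 7.1 -> mostly ionized at pH 7; dimer pKa well below 7
        -> neutral: the discrepancy is flagged."""
        mono = [result("HIS", 56, 7.1)]
        dim = [result("HIS", 56, 4.9)]
        rec = flag_ionization_discrepancy(mono, dim, ("C", 56), ph=7.0)
        assert rec.flagged
        assert rec.fraction_monomer > 0.5 > rec.fraction_dimer

    def test_missing_site_rejected(self):
        with pytest.raises(KeyError):
            flag_ionization_discrepancy(
                [result("ASP", 1, 4.0)], [result("ASP", 1, 4.0)], ("C", 9)
            )

    def test_ionized_fraction_conventions(self):
        assert ionized_fraction(4.0, -1, 7.0) > 0.99   # acid above its pKa
        assert ionized_fraction(10.4, +1, 7.0) > 0.99  # base below its pKa
        assert ionized_fraction(7.0, -1, 7.0) == pytest.approx(0.5)
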