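"""Binding/folding free-energy protocols and the saturation-scan driver."""

import numpy as np
import pytest

from conftest import ion_params, ion_structure
from mutscan.energy import load_param_set, total_energy
from mutscan.structio import Chain, Structure, split_monomers
from mutscan.thermo import (
    BindingResult, ScanConfig, binding_effect, binding_energy,
    folding_effect, folding_energy, scan_site,
)


def ion_dimer(q_c: float, q_d: float, r: float):
    """One ion per chain, Coulomb only (no LJ, no GB: eps_solv = eps_int)."""
    c = ion_structure([("IC", [0.0, 0.0, 0.0])], chain_id="C").chains[0]
    d = ion_structure([("ID", [r, 0.0, 0.0])], chain_id="D").chains[0]
    for res in c.residues + d.residues:
        res.is_hetero = False  # count as protein chains for split_monomers
    p = ion_params({"IC": q_c, "ID": q_d}, eps_solv=1.0)
    return Structure([c, d]), p


class TestBindingEnergy:
    def test_dg_bind_identity_exact(self):
        r = BindingResult(g_dimer=-12.5, g_c=-4.25, g_d=-3.5)
        assert r.dg_bind == -12.5 - (-4.25) - (-3.5)

    def test_salt_bridge_dimer(self):
        s, p = ion_dimer(+1.0, -1.0, 3.32)
        res = binding_energy(s, p)
        assert res.dg_bind == pytest.approx(-332.0636 / 3.32, rel=1e-12)
        assert res.g_c == 0.0 and res.g_d == 0.0

    def test_zero_interaction_gives_zero(self, toy_dimer):
        """All charges and epsilons zeroed: every pair energy vanishes."""
        from dataclasses import replace

        base = load_param_set("ff_a")
        zeroed = replace(
            base,
            charges={k: (0.0, cls) for k, (_, cls) in base.charges.items()},
            classes={k: (sig, 0.0, gbr) for k, (sig, _, gbr) in base.classes.items()},
        )
        res = binding_energy(toy_dimer, zeroed)
        assert res.dg_bind == pytest.approx(0.0, abs=1e-9)

    def test_invariant_under_chain_relabelling(self, toy_dimer, ffa):
        res = binding_energy(toy_dimer, ffa)
        flipped = Structure(
            [toy_dimer.chains[1].copy(), toy_dimer.chains[0].copy()],
            toy_dimer.title,
        )
        res2 = binding_energy(flipped, ffa)
        assert res2.dg_bind == pytest.approx(res.dg_bind, abs=1e-9)

    def test_monomers_taken_rigid(self, toy_dimer, ffa):
        c, d = split_monomers(toy_dimer)
        res = binding_energy(toy_dimer, ffa)
        assert res.g_c == total_energy(c, ffa).total
        assert res.g_d == total_energy(d, ffa).total


class TestBindingEffect:
    def test_identity_mutation_is_zero(self, toy_dimer):
        p = [load_param_set("ff_a")]
        assert binding_effect(toy_dimer, toy_dimer.copy(), p) == 0.0

    def test_removing_salt_bridge_is_destabilizing(self):
        """Losing the only inter-chain salt bridge weakens binding: the
        effect is negative under the default sign convention."""
        wt, p_wt = ion_dimer(+1.0, -1.0, 3.32)
        mut, p_mut = ion_dimer(0.0, -1.0, 3.32)  # charge removed
        dg_wt = binding_energy(wt, p_wt).dg_bind
        dg_mut = binding_energy(mut, p_mut).dg_bind
        assert dg_wt == pytest.approx(-100.02, abs=0.01)
        assert dg_mut == 0.0
        assert dg_wt - dg_mut < 0

    def test_single_set_average_equals_raw(self, toy_dimer):
        from mutscan.mutator import MutationSpec, mutate_residue

        mut = mutate_residue(toy_dimer, MutationSpec("C", 6, "ASP"))
        p = [load_param_set("ff_a")]
        eff = binding_effect(toy_dimer, mut, p)
        dg_wt = binding_energy(toy_dimer, p[0]).dg_bind
        dg_mut = binding_energy(mut, p[0]).dg_bind
        assert eff == pytest.approx(dg_wt - dg_mut, abs=1e-9)

    def test_sign_convention_switch_flips(self, toy_dimer):
        from mutscan.mutator import MutationSpec, mutate_residue

        mut = mutate_residue(toy_dimer, MutationSpec("C", 6, "ASP"))
        p = [load_param_set("ff_a")]
        a = binding_effect(toy_dimer, mut, p, sign_convention="destabilizing_negative")
        b = binding_effect(toy_dimer, mut, p, sign_convention="raw_difference")
        assert a == pytest.approx(-b, abs=1e-12)

    def test_mismatched_chains_rejected(self, toy_dimer):
        truncated = Structure([toy_dimer.chains[0].copy()])
        with pytest.raises(ValueError, match="mismatched"):
            binding_effect(toy_dimer, truncated, [load_param_set("ff_a")])


class TestFoldingEnergy:
    def test_segment_only_monomer_scores_zero(self, toy_dimer, ffa):
        from mutscan.structio import extract_segment

        mono, _ = split_monomers(toy_dimer)
        seg = extract_segment(mono, "C", 19, 7)
        res = folding_energy(seg, 19, ffa, 7)
        assert res.dg_fold == pytest.approx(0.0, abs=1e-9)

    @pytest.mark.parametrize("seg_len", [5, 7, 9])
    def test_segment_lengths_all_run(self, toy_dimer, ffa, seg_len):
        mono, _ = split_monomers(toy_dimer)
        res = folding_energy(mono, 19, ffa, seg_len)
        assert np.isfinite(res.dg_fold)
        assert res.segment_length == seg_len

    def test_lengths_give_different_values(self, toy_dimer, ffa):
        mono, _ = split_monomers(toy_dimer)
        vals = {L: folding_energy(mono, 19, ffa, L).dg_fold for L in (5, 7, 9)}
        assert len(set(vals.values())) == 3

    def test_chain_end_site_truncates_consistently(self, toy_dimer, ffa):
        mono, _ = split_monomers(toy_dimer)
        res = folding_energy(mono, 2, ffa, 7)  # window clipped at N-terminus
        assert res.segment_length == 5
        assert np.isfinite(res.dg_fold)

    def test_dimer_input_rejected(self, toy_dimer, ffa):
        with pytest.raises(ValueError, match="one protein chain"):
            folding_energy(toy_dimer, 19, ffa, 7)


class TestFoldingEffect:
    def test_identity_mutation_is_zero_under_all_sets(self, toy_dimer):
        from mutscan.energy import load_default_sets

        assert folding_effect(toy_dimer, toy_dimer.copy(), 19,
                              load_default_sets()) == 0.0

    def test_result_is_mean_of_per_chain_values(self, toy_dimer):
        from mutscan.mutator import MutationSpec, mutate_residue

        p = [load_param_set("ff_a")]
        mut = mutate_residue(
            mutate_residue(toy_dimer, MutationSpec("C", 19, "ASP")),
            MutationSpec("D", 19, "ASP"),
        )
        both = folding_effect(toy_dimer, mut, 19, p)
        per_chain = []
        for cid in ("C", "D"):
            wt_m = Structure([toy_dimer.chain(cid).copy()])
            mut_m = Structure([mut.chain(cid).copy()])
            per_chain.append(folding_effect(wt_m, mut_m, 19, p))
        assert both == pytest.approx(np.mean(per_chain), abs=1e-9)

    def test_burying_charge_in_acidic_pocket_destabilizes(self, toy_dimer):
        """Glu into the buried site flanked by acids: negative folding effect."""
        from mutscan.mutator import MutationSpec, mutate_residue

        p = [load_param_set("ff_a")]
        mut = mutate_residue(toy_dimer, MutationSpec("C", 19, "GLU"))
        wt_m = Structure([toy_dimer.chain("C").copy()])
        mut_m = Structure([mut.chain("C").copy()])
        assert folding_effect(wt_m, mut_m, 19, p) < 0


@pytest.fixture(scope="module")
def small_cfg():
    return ScanConfig(param_set_names=("ff_a",), max_sweeps=1)


@pytest.fixture(scope="module")
def scan(toy_dimer, small_cfg):
    return scan_site(toy_dimer, ("C", 19), small_cfg)


class TestScanSite:
    def test_nineteen_records_no_wild_type(self, scan, toy_dimer):
        assert len(scan) == 19
        wt = toy_dimer.chain("C").residue(19).aa
        assert wt not in {e.spec.target_aa for e in scan}

    def test_no_failures_and_finite_effects(self, scan):
        for e in scan:
            assert e.error is None
            assert np.isfinite(e.ddg_fold) and np.isfinite(e.dddg_bind)

    def test_averages_match_raw_values(self, scan):
        for e in scan:
            assert e.ddg_fold == pytest.approx(
                np.mean(list(e.per_ff_fold.values())), abs=1e-12
            )
            assert e.dddg_bind == pytest.approx(
                np.mean(list(e.per_ff_bind.values())), abs=1e-12
            )

    def test_bit_exact_rerun(self, toy_dimer, small_cfg, scan):
        again = scan_site(toy_dimer, ("C", 19), small_cfg)
        assert [e.ddg_fold for e in again] == [e.ddg_fold for e in scan]
        assert [e.dddg_bind for e in again] == [e.dddg_bind for e in scan]

    def test_acids_destabilize_buried_site(self, scan):
        by_aa = {e.spec.target_aa: e for e in scan}
        assert by_aa["ASP"].ddg_fold < 0
        assert by_aa["GLU"].ddg_fold < 0


class TestPkaEffect:
    def test_cumulative_shift_for_introduced_base(self, toy_dimer):
        """Putting Arg at the buried site near the acid cluster perturbs the
        titratable network: the chain-averaged cumulative |pKa shift| is
        positive and finite."""
        from mutscan.mutator import load_rotamer_library
        from mutscan.thermo import _pka_effect

        cfg = ScanConfig()
        val = _pka_effect(
            toy_dimer, ["C", "D"], 19, "ARG", load_param_set("ff_a"), cfg,
            load_rotamer_library(),
        )
        assert np.isfinite(val)
        assert val > 0.0
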