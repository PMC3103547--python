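"""Folding and binding free-energy change protocols.

Binding: dG_bind = G(dimer) - G(C) - G(D), with monomer coordinates taken
rigid from the relaxed dimer (no re-relaxation) and the association entropy
assumed equal for wild type and mutant, so it cancels in differences.

Folding: dG_fold = G(folded monomer) - G(segment), where the segment is a
short window (default 7 residues, odd, 5-9) centred at the mutation site
and scored in isolation at its monomer coordinates.  The remainder of the
unfolded-state energy is mutation independent and cancels in differences.

Mutation effects are averaged over the bundled parameter sets and over the
two chains.  Under the default sign convention an effect is reported as
value(WT) - value(mutant): negative means the mutation destabilizes the
monomer (folding) or weakens the dimer (binding).  ``raw_difference``
reports mutant - WT instead.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import energy as energy_mod
from .energy import EnergyModel, ForceFieldParams, load_default_sets, relax
from .mutator import MutationSpec, RotamerLibrary, load_rotamer_library, mutate_residue
from .geometry import AA3
from .structio import Structure, extract_segment, split_monomers

SIGN_CONVENTIONS = ("destabilizing_negative", "raw_difference")


@dataclass
class BindingResult:
    g_dimer: float
    g_c: float
    g_d: float

    @property
    def dg_bind(self) -> float:
        return self.g_dimer - self.g_c - self.g_d


@dataclass
class FoldingResult:
    g_folded: float
    g_seg: float
    segment_length: int

    @property
    def dg_fold(self) -> float:
        # up to the mutation-independent unfolded-state constant
        return self.g_folded - self.g_seg


@dataclass
class MutationEffect:
    spec: MutationSpec
    ddg_fold: float | None = None        # kcal/mol, averaged
    dddg_bind: float | None = None       # kcal/mol, averaged
    sum_dpka: float | None = None        # pK units, averaged over chains
    per_ff_fold: dict = field(default_factory=dict)    # (ff, chain) -> value
    per_ff_bind: dict = field(default_factory=dict)    # (ff, chain) -> value
    error: str | None = None


def binding_energy(dimer: Structure, p: ForceFieldParams) -> BindingResult:
    """Total-energy binding free energy of an (already relaxed) dimer."""
    mono_c, mono_d = split_monomers(dimer)
    return BindingResult(
        g_dimer=EnergyModel(dimer, p).total(),
        g_c=EnergyModel(mono_c, p).total(),
        g_d=EnergyModel(mono_d, p).total(),
    )


def _apply_sign(wt: float, mut: float, sign_convention: str) -> float:
    if sign_convention == "destabilizing_negative":
        return wt - mut
    if sign_convention == "raw_difference":
        return mut - wt
    raise ValueError(f"unknown sign convention {sign_convention!r}")


def binding_effect(
    wt: Structure,
    mut: Structure,
    param_sets: list[ForceFieldParams] | None = None,
    sign_convention: str = "destabilizing_negative",
) -> float:
    """Mean over parameter sets of the binding free-energy change."""
    param_sets = param_sets or load_default_sets()
    _check_matched(wt, mut)
    vals = []
    for p in param_sets:
        vals.append(
            _apply_sign(
                binding_energy(wt, p).dg_bind, binding_energy(mut, p).dg_bind,
                sign_convention,
            )
        )
    return float(np.mean(vals))


def folding_energy(
    monomer: Structure,
    site: int,
    p: ForceFieldParams,
    seg_len: int = 7,
) -> FoldingResult:
    """Folding free energy of a relaxed single-chain monomer."""
    chains = monomer.protein_chains()
    if len(chains) != 1:
        raise ValueError(f"monomer must have one protein chain, got {len(chains)}")
    chain_id = chains[0].id
    seg = extract_segment(monomer, chain_id, site, seg_len)
    return FoldingResult(
        g_folded=EnergyModel(monomer, p).total(),
        g_seg=EnergyModel(seg, p).total(),
        segment_length=len(seg.chain(chain_id).residues),
    )


def folding_effect(
    wt: Structure,
    mut: Structure,
    site: int,
    param_sets: list[ForceFieldParams] | None = None,
    seg_len: int = 7,
    sign_convention: str = "destabilizing_negative",
) -> float:
    """Mean over parameter sets and chains of the folding-energy change.

    `wt` and `mut` may be dimers (both chains averaged) or single-chain
    monomers.
    """
    param_sets = param_sets or load_default_sets()
    _check_matched(wt, mut)
    chain_ids = [c.id for c in wt.protein_chains()]
    vals = []
    for p in param_sets:
        for cid in chain_ids:
            wt_mono = _as_monomer(wt, cid)
            mut_mono = _as_monomer(mut, cid)
            vals.append(
                _apply_sign(
                    folding_energy(wt_mono, site, p, seg_len).dg_fold,
                    folding_energy(mut_mono, site, p, seg_len).dg_fold,
                    sign_convention,
                )
            )
    return float(np.mean(vals))


def _as_monomer(s: Structure, chain_id: str) -> Structure:
    if len(s.protein_chains()) == 1:
        return s
    return Structure([s.chain(chain_id).copy()], s.title, s.numbering_offset)


def _check_matched(wt: Structure, mut: Structure) -> None:
    wc = [(c.id, len(c.residues)) for c in wt.chains]
    mc = [(c.id, len(c.residues)) for c in mut.chains]
    if wc != mc:
        raise ValueError(f"mismatched chains: {wc} vs {mc}")


@dataclass
class ScanConfig:
    seg_len: int = 7
    param_set_names: tuple = energy_mod.DEFAULT_SETS
    relax_radius: float = 6.0            # scope shell around the site, A
    relax_tol: float = 0.01              # kcal/mol per sweep
    max_sweeps: int = 2
    sign_convention: str = "destabilizing_negative"
    include_pka: bool = False
    pka_method: str = "enumerate"
    seed: int = 1

    def param_sets(self) -> list[ForceFieldParams]:
        return load_default_sets(self.param_set_names)


def relax_scope(s: Structure, chain_id: str, residue_number: int,
                radius: float) -> list[tuple[str, int]]:
    """The mutated residue plus neighbours whose side chains sit within
    `radius` of the site's side chain (CA for glycine)."""
    from .geometry import BACKBONE_ATOMS

    site = s.chain(chain_id).residue(residue_number)
    site_pos = np.array(
        [a.pos for a in site.atoms if a.name not in BACKBONE_ATOMS]
        or [site.atom("CA").pos]
    )
    scope = []
    for c in s.chains:
        for r in c.residues:
            if r.is_hetero:
                continue
            pos = np.array(
                [a.pos for a in r.atoms if a.name not in BACKBONE_ATOMS]
                or [r.atom("CA").pos]
            )
            d = np.linalg.norm(pos[:, None, :] - site_pos[None, :, :], axis=-1)
            if (c.id, r.number) == (chain_id, residue_number) or d.min() <= radius:
                scope.append((c.id, r.number))
    return scope


def _relaxed_variants(
    dimer: Structure,
    spec: MutationSpec | None,
    chain_id: str,
    site: int,
    p: ForceFieldParams,
    config: ScanConfig,
    lib: RotamerLibrary,
) -> Structure:
    """Mutate (optionally) in one chain, then relax the site neighbourhood.

    The identical relaxation protocol is applied to the WT re-scored
    structure (spec=None) so protocol noise cancels in differences.
    """
    work = dimer if spec is None else mutate_residue(dimer, spec, lib)
    scope = relax_scope(work, chain_id, site, config.relax_radius)
    return relax(
        work, p, scope=scope, tol=config.relax_tol, max_sweeps=config.max_sweeps
    ).structure


def scan_site(
    dimer: Structure,
    chain_site: tuple[str, int] | int,
    config: ScanConfig | None = None,
) -> list[MutationEffect]:
    """Saturation scan of one site: 19 substitutions, folding and binding
    effects averaged over parameter sets and both chains.

    `chain_site` is (chain_id, residue_number) or a bare residue number
    (mutated in each chain in turn; the homologous site must share the
    number in both chains).  Per-mutation failures are recorded in the
    effect's ``error`` field, not raised.
    """
    config = config or ScanConfig()
    lib = load_rotamer_library()
    if isinstance(chain_site, tuple):
        site_chains = [chain_site[0]]
        site = chain_site[1]
    else:
        site = chain_site
        site_chains = [c.id for c in dimer.protein_chains()]
    param_sets = config.param_sets()
    wt_aa = dimer.chain(site_chains[0]).residue(site).aa

    # WT baselines under the identical relax protocol, per (ff, chain)
    wt_bind: dict = {}
    wt_fold: dict = {}
    wt_relaxed: dict = {}
    for p in param_sets:
        for cid in site_chains:
            wt_rel = _relaxed_variants(dimer, None, cid, site, p, config, lib)
            wt_relaxed[(p.name, cid)] = wt_rel
            wt_bind[(p.name, cid)] = binding_energy(wt_rel, p).dg_bind
            mono = _as_monomer(wt_rel, cid)
            wt_fold[(p.name, cid)] = folding_energy(mono, site, p, config.seg_len).dg_fold

    effects = []
    for one in sorted(AA3):
        target = AA3[one]
        if target == wt_aa:
            continue
        eff = MutationEffect(spec=MutationSpec(site_chains[0], site, target))
        try:
            for p in param_sets:
                for cid in site_chains:
                    spec = MutationSpec(cid, site, target)
                    mut_rel = _relaxed_variants(dimer, spec, cid, site, p, config, lib)
                    dg_bind = binding_energy(mut_rel, p).dg_bind
                    eff.per_ff_bind[(p.name, cid)] = _apply_sign(
                        wt_bind[(p.name, cid)], dg_bind, config.sign_convention
                    )
                    mono = _as_monomer(mut_rel, cid)
                    dg_fold = folding_energy(mono, site, p, config.seg_len).dg_fold
                    eff.per_ff_fold[(p.name, cid)] = _apply_sign(
                        wt_fold[(p.name, cid)], dg_fold, config.sign_convention
                    )
            eff.ddg_fold = float(np.mean(list(eff.per_ff_fold.values())))
            eff.dddg_bind = float(np.mean(list(eff.per_ff_bind.values())))
            if config.include_pka:
                eff.sum_dpka = _pka_effect(
                    dimer, site_chains, site, target, param_sets[0], config, lib
                )
        except Exception as exc:  # per-mutation failures are not fatal
            eff.error = f"{type(exc).__name__}: {exc}"
        effects.append(eff)
    return effects


def _pka_effect(
    dimer: Structure,
    site_chains: list[str],
    site: int,
    target: str,
    p: ForceFieldParams,
    config: ScanConfig,
    lib: RotamerLibrary,
) -> float:
    """Cumulative |pKa shift| over titratable sites, averaged over chains.

    Computed on monomers (the WT-vs-mutant comparison the shift metric is
    defined on); the mutated position is excluded from pairing when its
    titratability changes.
    """
    from .titration import compute_pkas, pka_shift_report

    sums = []
    for cid in site_chains:
        wt_mono = _as_monomer(dimer, cid)
        mut_mono = _as_monomer(mutate_residue(dimer, MutationSpec(cid, site, target), lib), cid)
        wt_pkas = compute_pkas(wt_mono, p, method=config.pka_method, seed=config.seed)
        mut_pkas = compute_pkas(mut_mono, p, method=config.pka_method, seed=config.seed)
        sums.append(pka_shift_report(wt_pkas, mut_pkas).sum_abs)
    return float(np.mean(sums))
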