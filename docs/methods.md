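# Methods

This note documents the models behind `mutscan`, the choices made where the
design was genuinely open, and what the synthetic test system does and does
not establish about real proteins.

## Energy model

The potential is pairwise nonbonded only:

* **Lennard-Jones**, 4ε[(σ/r)¹² − (σ/r)⁶] with Lorentz–Berthelot
  combination (σ arithmetic mean, ε geometric mean);
* **Coulomb**, k_e q_i q_j /(ε_int r) with k_e = 332.0636 kcal·Å/(mol·e²)
  and interior dielectric ε_int = 1.0;
* **Generalized Born** solvation in the Still functional form,
  −½(1/ε_int − 1/ε_solv) Σ_ij k_e q_i q_j / f_GB, with
  f_GB = √(r² + B_iB_j·exp(−r²/4B_iB_j)), solvent dielectric 78.5, and
  effective Born radii B_i from Hawkins–Cramer–Truhlar pairwise
  descreening with scaling factor 0.8. For overlapping sphere pairs the
  descreening integral is clamped to its contact value — a deterministic
  simplification that preserves the single-ion limit (an isolated atom's
  Born radius equals its intrinsic radius exactly, which the tests assert
  against the analytic Born energy).

Bonded terms are deliberately absent. All structural perturbations the
package performs are side-chain χ rotations on ideal internal geometry, so
bond lengths and angles never change; the folding and binding protocols
only consume energy *differences* under a rigid backbone, in which any
constant bonded contribution cancels. Exclusions: 1-2 and 1-3 pairs are
removed, 1-4 pairs scaled by 0.5 (LJ and Coulomb); the GB sum runs over all
pairs plus self terms. No cutoff is applied — intended system sizes are a
few hundred atoms.

Atoms are heavy atoms with implicit hydrogens. Three bundled parameter sets
(`ff_a`, `ff_b`, `ff_c`, plain text under `src/mutscan/data/`) share the
topology and differ in charges (±5%) and LJ parameters (σ ±2%, ε ±10%);
effects are averaged over the three so that no single parameterization
dominates. They are simplified in-repo sets, with no claim of equivalence
to any published force field. Titratable side chains carry fully ionized
charges (Asp⁻, Glu⁻, Lys⁺, Arg⁺, His⁺); Tyr and Cys are neutral, since at
the physiological comparison pH their neutral forms dominate. Protonation
discrepancies are the titration module's job and are never folded back into
the potential.

## Side-chain placement and relaxation

Mutants are built by deleting the side chain and regrowing the target
residue's heavy atoms from ideal bond lengths/angles at candidate rotamers
(a small backbone-independent library, χ ∈ {−60°, 60°, 180°} and
combinations, stored as plain text). The rotamer minimizing a steric
overlap score — Σ max(0, 0.8·(r_i + r_j) − d)² over side-chain/environment
pairs — wins; ties break by library order, so placement is bit-for-bit
deterministic. Backbone atoms of the site never move. Proline targets are
built open-chain (the ring closure to the backbone nitrogen is recorded in
the bond table but not geometrically enforced) and flagged.

Relaxation is coordinate descent over the χ angles of a scope (the mutated
residue plus residues whose side chains lie within 6 Å of its side chain):
each χ in turn tries a fixed proposal grid (±30°, ±60°, ±120°), and a full
sweep that improves the total energy by less than 0.01 kcal/mol terminates
the loop (default at most 2 sweeps during scans). For speed, proposals are
screened with an exact LJ/Coulomb delta plus a GB pair delta at Born radii
frozen at the sweep start; every screened winner is then re-verified
against the full energy and accepted only if it genuinely lowers it, so
the published contract — energy is monotone non-increasing and the
backbone is untouched — holds on the true total energy. The 0.01
convergence criterion is interpreted as an energy-improvement tolerance
per sweep.

## Folding and binding protocols

**Binding.** ΔG_bind = G(dimer) − G(C) − G(D), the monomers cut rigidly
out of the relaxed dimer. This rigid-body convention makes the three terms
share one conformation, which empirically stabilizes differences across
parameter sets; the association entropy is assumed equal for wild type and
mutant and cancels.

**Folding.** ΔG_fold = G(folded monomer) − G(segment), the segment being a
window of 5–9 residues (default 7, always odd) centred on the mutation
site, scored in isolation at its in-monomer coordinates. It models the part
of the unfolded chain that differs between wild type and mutant; everything
further from the site is assumed identical in both unfolded states and
cancels in ΔΔG. Windows at chain termini are truncated to the available
residues, identically for wild type and mutant.

**Effects and signs.** A mutation's effect is value(WT) − value(mutant),
averaged over the three parameter sets and over the two chains (each chain
is mutated in turn; the wild type is re-scored under the identical
mutate-free relax protocol so protocol noise differences out). Since more
negative potential energy means more stable, this orientation makes
*negative = destabilizing / weaker dimer*. Note the sign: the raw
difference mutant − wild-type would be *positive* for a destabilizing
mutation, so the reported quantity is its negation; `raw_difference` in
the configuration restores the unflipped arithmetic for interoperability
with tools using the opposite convention.

## Titration

Each titratable residue (Asp, Glu, His, Lys, Arg, Tyr, Cys; configurable)
is a two-state site. A microstate x ∈ {0,1}ⁿ (1 = ionized) has energy

    E(x; pH) = Σ_i x_i·1.364·g_i·(pH − pKa_int,i) + Σ_{i<j} x_i x_j W_ij

with g = −1 for acids, +1 for bases and 1.364 kcal/mol per pK unit at
298 K. Boltzmann averages come from exact enumeration (≤ 20 sites) or
single-site Metropolis Monte Carlo (all pH values propagated in parallel,
default 10⁵ sweeps, 10% burn-in, seed mandatory); a site's pKa is the pH
where its protonation fraction crosses ½ on a 0.1-pH grid with linear
interpolation. Sites whose midpoint falls outside pH 0–14 are reported with
sentinels (−1 / 15) and flagged.

Intrinsic pKas follow the standard continuum decomposition: model value
(Asp 4.0, Glu 4.4, His 6.3, Lys 10.4, Arg 12.0, Tyr 9.6, Cys 8.3) plus a
Born desolvation term and a background-charge term, both divided by
±1.364 per acid/base convention. Two reference choices keep the limits
honest: the desolvation penalty is measured against the Born radius of the
*residue taken alone* (the solvated model compound the model pKa refers
to), and a site's own residue is excluded from its background sum — so a
fully isolated, fully exposed residue recovers its model pKa exactly.
Site–site couplings W_ij are screened interactions between unit charges at
representative charged-group atoms. Because the heavy-atom geometry is
rigid (no conformer search, no hydrogen-bond network optimization — a
deliberate simplification), the titration electrostatics use a protein
dielectric of 8, the conventional continuum-pKa choice that absorbs the
missing conformational relaxation; the potential-energy model keeps
ε_int = 1 independently.

One subtlety the tests document: for two *symmetric* coupled acids, the
per-site half-protonation pKas do not split — both shift up by ≈ W/2 —
while the macroscopic stepwise midpoints (total protonation crossing 1.5
and 0.5) split to either side of the model value. The per-site definition
is the operation's contract; the stepwise splitting is asserted on the
total titration curve.

The cumulative shift metric for a mutation is Σ_i |pKa_i(mut) − pKa_i(WT)|
over all titratable residues paired between the two structures, computed
with |·| per chain and then averaged over chains. When a mutation adds or
removes a titratable residue, the mutated position is excluded from the
pairing and recorded as unpaired; N counts paired sites only. The
monomer-versus-dimer ionization flag compares Henderson–Hasselbalch
ionized fractions at pH 7.0 (physiological default) and fires when they
differ by more than 0.5.

## Classification

For 19 effects with population mean µ and standard deviation σ (÷n, since
the 19 substitutions are the whole population; sample mode available),
HSTD = σ/2 exactly and Z = (x − µ)/σ:

* tolerance: `non-tolerable` iff |µ| > HSTD (strict; |µ| makes the rule
  symmetric under sign conventions);
* specificity: `specific` iff more than 20% of substitutions satisfy
  |effect| > HSTD *and* the exceeding set contains both favorable and
  unfavorable effects. This is one reading of an ambiguous ">20% cause
  different effects … larger than HSTD" rule (the alternative counts
  direction changes); the chosen reading is logged in every report;
* pKa: `sensitive` iff mean cumulative shift > 2 pK units; `specific` iff
  max − min > 2 pK units. The 2-pK cut-off is an empirical threshold
  applied to the mean over substitutions.

The classifier implements only these rules. Judgement overrides — e.g.
calling a site tolerable although its mean formally exceeds HSTD because
most substitutions do nothing, or calling a quiet site specific on the
magnitude of individual changes — can be attached to reports as
annotations but are never computed, so the formal label and the override
remain distinguishable.

## Synthetic test system

Each monomer is a β-hairpin: two 11-residue antiparallel extended strands
(φ/ψ = −135°/135°) paired in-plane at 5 Å, joined by a two-residue turn
placed rigidly beyond the strand ends. The two junctions are spacers a few
Å long; since the energy model has no bonded terms, this costs nothing and
keeps every piece at ideal internal geometry. The dimer stacks a second,
differently-sequenced copy along the sheet normal (9.5 Å, side chains
interdigitating), rotated half a turn so the two hairpin turns sit at
opposite ends — the interface is therefore not symmetric. Side chains are
grown sequentially at the least-clashing rotamer; 0.05 Å of seeded uniform
jitter breaks exact degeneracies. Defaults: 24 residues per chain,
327 atoms total.

Three archetypal sites per chain mirror the mechanisms the scans probe:
the turn glycine (residue 13) is solvent-exposed with acidic neighbours;
the strand-1 valine (residue 6) points across the interface and can be
ringed with Asp/Glu to form a negative pocket (`build_negative_pocket`
verifies the Coulomb potential at the site goes negative); the strand-2
isoleucine (residue 19) packs against the partner sheet with Glu/His
flanking it. Burial is audited by a neighbour-count proxy (atoms within
8 Å of the side-chain centroid; buried > 55, exposed < 40) and interface
contact by a 5 Å inter-chain distance audit.

Effect-table fixtures generate 19-substitution vectors whose shapes encode
the qualitative regimes of the three site types — buried core: almost all
substitutions strongly destabilizing, acids worst, mean ≪ −HSTD; interface
pocket: near-zero mean with charged substitutions splitting both ways
beyond HSTD; exposed turn: most substitutions inert but a few strongly
stabilizing, pushing the mean just past HSTD (≈2.2 vs ≈1.9 kcal/mol) —
plus matching cumulative-pKa-shift vectors. Values are canonical levels
with N(0, 0.2) seeded noise; classification of these regimes is stable for
≥95% of seeds by construction and verified over 100 seeds.

**What passing tests do not show.** The toy dimer has ideal secondary
structure, complete heavy atoms, no ligands, no long-range domain
architecture, and ~300 atoms; the bundled parameter sets are simplified.
Tests therefore establish the *protocol* — identities, sign conventions,
averaging contracts, oracle agreement, determinism — not the accuracy of
absolute kcal/mol or pK values for any real protein, which depend on the
energy engine and structure quality.

## Problem sizes and determinism

Default scans relax the 6 Å scope for at most 2 sweeps under 3 parameter
sets and both chains (~20 s per chain-site on one core); titration uses
exact enumeration below 20 sites and seeded Monte Carlo above; all
generators, scans and reports are bit-reproducible given the seed, which
every stochastic stage requires explicitly. Degenerate inputs fail loudly:
σ = 0 effect tables, empty truncations, even segment lengths, >20-site
enumeration, coincident atoms in a nonbonded pair, and identity mutations
are errors, not silent results.

## Known limitations

* Backbone response to mutation is ignored (rigid-backbone χ relaxation
  only); proline and glycine substitutions that would reshape the backbone
  are built but their strain is not scored.
* The GB overlap clamp slightly overestimates descreening for tightly
  bonded neighbours; adequate for differences, not for absolute solvation
  energies.
* The unfolded-state segment model ignores residual structure and
  segment–remainder interactions beyond the cancellation assumption.
* Titration ignores conformer relaxation; the effective dielectric absorbs
  it in the mean.
* Ligand handling is structural only (HETATM groups are carried and
  flagged); no ligand parameters ship with the package.
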