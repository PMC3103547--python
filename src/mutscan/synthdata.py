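"""Synthetic structures and titration systems for desk-scale testing.

The toy dimer emulates the structural motifs the scanning protocols assume:
a homodimer of two beta-hairpin monomers (two antiparallel extended strands
joined by a tight two-residue turn), stacked along the sheet normal so the
interface is non-symmetric, with three archetypal sites per monomer:

* ``loop_site``   -- solvent-exposed glycine at the apex of the sharp turn,
  acidic residues adjacent (exposed turn archetype);
* ``interface_site`` -- mid-strand residue whose side chain points across
  the dimer interface and can be ringed with acids (interfacial
  negative-pocket archetype);
* ``buried_site`` -- mid-strand residue whose side chain points into the
  packed region between the monomers' sheets, flanked by titratable
  residues (buried core archetype).

Backbones are grown with ideal peptide geometry from a phi/psi program;
all generators are deterministic given the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import geometry
from .geometry import AA3, rotation_x, rotation_y, rotation_z
from .structio import Atom, Chain, Residue, Structure

_EXT = (-135.0, 135.0)                     # extended-strand phi/psi
_TURN = ((-60.0, -30.0), (-90.0, 0.0))     # tight two-residue turn
_PAIR_SEP = 5.0                            # in-plane strand pairing distance, A
_TURN_OFFSET = 4.5                         # turn clearance beyond strand end, A


@dataclass
class ToySpec:
    """Parameters of the toy dimer generator.

    n_residues is per chain and must fit two strands plus a 4-residue turn.
    """

    n_residues: int = 24
    interface_gap: float = 9.5              # sheet-normal offset of chain D, A
    asym_shift: float = 2.0                 # x-shift of chain D, away from the turn
    loop_site: int = 13
    interface_site: int = 6
    buried_site: int = 19
    # (chain_id, residue_number, one- or three-letter aa)
    charge_decorations: list[tuple] = field(default_factory=list)
    jitter: float = 0.05                    # coordinate noise amplitude, A
    seed: int = 1

    def __post_init__(self):
        if self.n_residues < 18 or self.n_residues % 2:
            raise ValueError("n_residues must be even and >= 18")
        for name in ("loop_site", "interface_site", "buried_site"):
            v = getattr(self, name)
            if not 1 <= v <= self.n_residues:
                raise ValueError(f"{name}={v} outside chain range")
        self.n_strand = (self.n_residues - 2) // 2


# Default per-chain sequences (one-letter).  The turn carries Asp-Gly (the
# glycine is the loop site); Glu/His flank the buried Ile; chain D differs
# from chain C so the homodimer interface is not symmetric in detail.
_SEQ_C = "AVSLAVVLAVA" + "DG" + "ELVSEITHAVS"
_SEQ_D = "AVTLAVVLAVA" + "DG" + "ELVAEITQAVS"


def _default_sequence(chain_id: str, n: int) -> str:
    base = _SEQ_C if chain_id == "C" else _SEQ_D
    seq = (base * (n // len(base) + 1))[:n]
    return seq


def _canonical_piece(program):
    """NeRF backbone piece oriented with strand axis -> +x and the pleat
    (CB alternation) direction -> z, centred on its CA centroid."""
    res = geometry.build_backbone_chain(program)
    ca = np.array([r["CA"] for r in res])
    center = ca.mean(axis=0)
    _, _, vt = np.linalg.svd(ca - center)
    x = vt[0]
    if np.dot(ca[-1] - ca[0], x) < 0:
        x = -x
    bb = res[min(1, len(res) - 1)]
    cb = geometry.place_atom(bb["N"], bb["C"], bb["CA"], 1.53, 110.5, 122.7)
    v = cb - bb["CA"]
    z = v - np.dot(v, x) * x
    z = z / np.linalg.norm(z)
    y = np.cross(z, x)
    rot = np.vstack([x, y, z])
    return [{k: rot @ (p - center) for k, p in r.items()} for r in res]


def _monomer_backbone(spec: ToySpec) -> list[dict]:
    """Two paired antiparallel strands joined by a rigidly placed turn.

    The pieces have ideal internal peptide geometry; the two junctions are
    spacers a few Angstroms long, which the nonbonded-only energy model
    tolerates by construction.
    """
    strand = _canonical_piece([_EXT] * spec.n_strand)
    turn = _canonical_piece(list(_TURN))
    x_end = strand[-1]["CA"][0]
    out = [{k: v.copy() for k, v in r.items()} for r in strand]
    rot90 = rotation_z(90.0)
    for r in turn:
        out.append(
            {
                k: rot90 @ v + np.array([x_end + _TURN_OFFSET, _PAIR_SEP / 2, 0.0])
                for k, v in r.items()
            }
        )
    rot180 = rotation_z(180.0)
    for r in strand:
        out.append({k: rot180 @ v + np.array([0.0, _PAIR_SEP, 0.0]) for k, v in r.items()})
    return out


def _build_chain(chain_id: str, spec: ToySpec, seq: str, rng: np.random.Generator,
                 transform) -> Chain:
    """Backbone under a rigid transform; side chains start as Ala stubs and
    are grown clash-aware afterwards (see build_toy_dimer)."""
    backbone = _monomer_backbone(spec)
    rot_g, t_g = transform
    chain = Chain(chain_id)
    for i, bb_local in enumerate(backbone):
        aa = AA3[seq[i]]
        bb = {n: rot_g @ xyz + t_g for n, xyz in bb_local.items()}
        res = Residue(number=i + 1, aa="GLY" if aa == "GLY" else "ALA")
        for n in ("N", "CA", "C", "O"):
            res.atoms.append(
                Atom(name=n, element=geometry.element_of(n), pos=bb[n].copy())
            )
        if res.aa == "ALA":
            sc = geometry.build_side_chain({k: bb[k] for k in ("N", "CA", "C")}, "ALA", [])
            for n, p in sc.items():
                res.atoms.append(Atom(name=n, element=geometry.element_of(n), pos=p))
        for a in res.atoms:
            a.pos = a.pos + rng.uniform(-spec.jitter, spec.jitter, 3)
        chain.residues.append(res)
    return chain


def build_toy_dimer(spec: ToySpec | None = None) -> Structure:
    """Deterministic two-chain toy structure (chains C and D).

    Chain D is the same fold rotated half a turn about the sheet normal and
    offset along it, so the two turns sit at opposite ends and the interface
    is not symmetric.  Side chains are placed sequentially at the least-
    clashing library rotamer.
    """
    spec = spec or ToySpec()
    rng = np.random.default_rng(spec.seed)
    ident = (np.eye(3), np.zeros(3))
    seq_c = _default_sequence("C", spec.n_residues)
    seq_d = _default_sequence("D", spec.n_residues)
    chain_c = _build_chain("C", spec, seq_c, rng, ident)
    center = np.array([0.0, _PAIR_SEP / 2, 0.0])
    rot_d = rotation_z(180.0)
    t_d = center - rot_d @ center + np.array([-spec.asym_shift, 0.0, spec.interface_gap])
    chain_d = _build_chain("D", spec, seq_d, rng, (rot_d, t_d))
    s = Structure(chains=[chain_c, chain_d], title="mutscan toy dimer")
    # grow final side chains clash-aware, in chain order
    for cid, seq in (("C", seq_c), ("D", seq_d)):
        for i, one in enumerate(seq):
            _replace_residue(s, cid, i + 1, AA3[one])
    for chain_id, number, aa in spec.charge_decorations:
        aa3 = AA3.get(aa, aa)
        _replace_residue(s, chain_id, number, aa3)
    s.validate()
    _check_chain_overlap(s)
    return s


def _check_chain_overlap(s: Structure) -> None:
    c_atoms = np.array([a.pos for r in s.chain("C").residues for a in r.atoms])
    d_atoms = np.array([a.pos for r in s.chain("D").residues for a in r.atoms])
    d = np.linalg.norm(c_atoms[:, None, :] - d_atoms[None, :, :], axis=-1)
    if d.min() < 1.0:
        raise ValueError(
            f"chains overlap (min inter-chain distance {d.min():.2f} A); "
            "increase interface_gap"
        )


def _replace_residue(s: Structure, chain_id: str, number: int, aa3: str) -> None:
    from .mutator import MutationSpec, mutate_residue  # local import, no cycle

    res = s.chain(chain_id).residue(number)
    if res.aa == aa3:
        return
    mutated = mutate_residue(s, MutationSpec(chain_id, number, aa3))
    s.chains = mutated.chains


def neighbour_count(s: Structure, chain_id: str, residue_number: int,
                    radius: float = 8.0) -> int:
    """Burial proxy: atoms of other residues within `radius` of the site's
    side-chain centroid (CA if glycine)."""
    res = s.chain(chain_id).residue(residue_number)
    side = [a.pos for a in res.atoms if a.name not in geometry.BACKBONE_ATOMS]
    center = np.mean(side, axis=0) if side else res.atom("CA").pos
    count = 0
    for c in s.chains:
        for r in c.residues:
            if c.id == chain_id and r.number == residue_number:
                continue
            for a in r.atoms:
                if np.linalg.norm(a.pos - center) <= radius:
                    count += 1
    return count


def min_interchain_distance(s: Structure, chain_id: str, residue_number: int) -> float:
    res = s.chain(chain_id).residue(residue_number)
    other_atoms = [
        a.pos for c in s.chains if c.id != chain_id for r in c.residues for a in r.atoms
    ]
    own = np.array([a.pos for a in res.atoms])
    other = np.array(other_atoms)
    d = np.linalg.norm(own[:, None, :] - other[None, :, :], axis=-1)
    return float(d.min())


def coulomb_potential_at_site(s: Structure, chain_id: str, residue_number: int) -> float:
    """Coulomb potential (kcal/mol/e, eps=1) at the site's CB (CA if Gly),
    from ionized-form charges of all other residues."""
    from .energy import KE, load_param_set

    p = load_param_set("ff_a")
    res = s.chain(chain_id).residue(residue_number)
    probe = res.atom("CB").pos if res.has_atom("CB") else res.atom("CA").pos
    pot = 0.0
    for c in s.chains:
        for r in c.residues:
            if c.id == chain_id and r.number == residue_number:
                continue
            for a in r.atoms:
                q, *_ = p.lookup(r.aa, a.name)
                d = float(np.linalg.norm(a.pos - probe))
                if d > 1e-6:
                    pot += KE * q / d
    return pot


def build_negative_pocket(
    s: Structure, around: tuple[str, int], n_acids: int, radius: float = 10.0
) -> Structure:
    """Replace `n_acids` nearby residues with Asp/Glu (alternating).

    Candidates are non-site residues with CA within `radius` of the site CA,
    nearest first, skipping residues that are already acidic.
    """
    if n_acids == 0:
        return s.copy()
    chain_id, number = around
    site_ca = s.chain(chain_id).residue(number).atom("CA").pos
    candidates = []
    for c in s.chains:
        for r in c.residues:
            if (c.id, r.number) == (chain_id, number) or r.aa in ("ASP", "GLU", "GLY", "PRO"):
                continue
            d = float(np.linalg.norm(r.atom("CA").pos - site_ca))
            if d <= radius:
                candidates.append((d, c.id, r.number))
    candidates.sort()
    if len(candidates) < n_acids:
        raise ValueError(
            f"only {len(candidates)} candidate residues within {radius} A, "
            f"need {n_acids}"
        )
    out = s.copy()
    for k, (_, cid, rnum) in enumerate(candidates[:n_acids]):
        _replace_residue(out, cid, rnum, "ASP" if k % 2 == 0 else "GLU")
    return out


# ---------------------------------------------------------------------------
# Titration fixtures


def make_titration_fixture(n_sites: int, coupling_scale: float, seed: int):
    """Random TitrationSystem: model pKas in [3, 12], couplings ~ |N(0, s)|."""
    from .titration import TitratableSite, TitrationSystem

    if n_sites < 1:
        raise ValueError("n_sites must be >= 1")
    rng = np.random.default_rng(seed)
    aas = ["ASP", "GLU", "HIS", "LYS", "ARG", "TYR", "CYS"]
    sites = []
    for i in range(n_sites):
        aa = aas[i % len(aas)]
        pka = float(rng.uniform(3.0, 12.0))
        charge = -1 if aa in ("ASP", "GLU", "TYR", "CYS") else +1
        sites.append(
            TitratableSite(
                chain_id="C",
                residue_number=i + 1,
                aa=aa,
                model_pka=pka,
                ionized_charge=charge,
                intrinsic_pka=pka,
            )
        )
    w = np.abs(rng.normal(0.0, coupling_scale, (n_sites, n_sites)))
    w = np.triu(w, 1)
    w = w + w.T
    return TitrationSystem(sites=sites, coupling=w)


# ---------------------------------------------------------------------------
# Effect-table fixtures: canonical 19-substitution effect vectors per site
# archetype, in the qualitative regimes the toy analysis targets.  Values are
# per-substitution canonical levels plus a small seeded jitter.

_OTHER = 0.0

# keyed by substitution one-letter code; missing keys take the default level
_ARCHETYPES: dict[tuple[str, str], tuple[float, dict[str, float]]] = {
    # exposed sharp-turn site, folding: most substitutions near zero, a few
    # strongly stabilizing (Lys/Arg/Tyr ~ +10, Met bends inward) -> formal
    # mean above HSTD although many substitutions do nothing
    ("g56", "folding"): (0.3, {"K": 11.0, "R": 10.5, "Y": 10.0, "M": 6.5}),
    # interface pocket site, folding: near-zero mean, charged residues split
    # in both directions beyond HSTD
    ("v132", "folding"): (0.0, {"D": -8.0, "E": -7.0, "H": 6.5, "K": 6.0, "R": 4.5}),
    # buried packed site, folding: almost everything strongly destabilizing,
    # acids worst; His/Arg mildly stabilizing but below threshold
    ("i150", "folding"): (
        -6.0,
        {"D": -14.8, "E": -14.2, "H": 1.0, "R": 0.8, "T": -4.0, "S": -4.5,
         "N": -5.0, "Q": -5.0, "W": -9.0, "F": -8.0, "Y": -8.0},
    ),
    # peripheral interface site, binding: most substitutions weaken the dimer
    ("g56", "binding"): (
        -4.0,
        {"D": -12.0, "H": 0.6, "W": -0.3, "A": -6.0, "E": -3.0, "S": -5.0},
    ),
    # central interface site, binding: charge-dominated, positives strengthen
    ("v132", "binding"): (
        1.5,
        {"D": -6.0, "E": -5.0, "K": 14.0, "R": 13.0, "H": 10.0, "W": 8.0},
    ),
    # distant-from-interface site, binding: tiny effects, Gly artifact spike
    ("i150", "binding"): (
        0.0,
        {"G": 6.0, "D": -2.0, "E": -1.8, "K": 1.2, "R": 1.2, "H": 0.8},
    ),
    # cumulative |dpKa| per substitution (pK units, non-negative)
    ("g56", "pka"): (0.25, {"R": 2.9, "K": 1.6, "D": 1.0, "E": 0.9}),
    ("v132", "pka"): (0.15, {"R": 2.9, "K": 1.2, "D": 0.8, "E": 0.7}),
    ("i150", "pka"): (2.6, {"R": 8.0, "K": 7.0, "D": 4.5, "E": 4.2, "H": 3.5}),
}

_WT = {"g56": "G", "v132": "V", "i150": "I"}


def effect_table_fixture(archetype: str, metric: str, seed: int) -> list[float]:
    """19 canonical effect values (alphabetical by substitution one-letter
    code, wild type excluded) with small seeded noise.

    Energy metrics are kcal/mol with negative = destabilizing; the pka
    metric is a non-negative cumulative |pKa shift| in pK units.
    """
    key = (archetype.lower(), metric.lower())
    if key not in _ARCHETYPES:
        raise KeyError(f"unknown archetype/metric {key}")
    default, special = _ARCHETYPES[key]
    rng = np.random.default_rng(seed)
    wt = _WT[archetype.lower()]
    values = []
    for one in sorted(AA3):
        if one == wt:
            continue
        v = special.get(one, default) + float(rng.normal(0.0, 0.2))
        if metric.lower() == "pka":
            v = max(v, 0.0)
        values.append(v)
    assert len(values) == 19
    return values
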