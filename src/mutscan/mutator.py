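"""Backbone-preserving in-silico mutagenesis.

Side chains are rebuilt from ideal internal geometry at candidate rotamers
from a small backbone-independent library; the rotamer with the lowest
steric clash score wins, ties broken by library order.  Backbone atoms of
the site never move, so every mutant of a site shares the wild-type
backbone bit-exactly — energies are re-relaxed downstream, placement only
needs to be deterministic and clash-aware.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np

from . import geometry
from .geometry import AA1, AA3, CANONICAL_AA
from .structio import Atom, Structure

# Heavy-atom contact radius used for clash scoring (LJ-like proxy), Angstrom.
_CLASH_RADIUS = {"C": 1.75, "N": 1.62, "O": 1.48, "S": 1.78}
_CLASH_OVERLAP_FACTOR = 0.8


@dataclass
class MutationSpec:
    chain_id: str
    residue_number: int
    target_aa: str  # three-letter code

    def __post_init__(self):
        if self.target_aa not in CANONICAL_AA:
            if self.target_aa.upper() in AA3:
                self.target_aa = AA3[self.target_aa.upper()]
            else:
                raise ValueError(f"unknown amino acid {self.target_aa!r}")

    @property
    def label(self) -> str:
        return f"{self.chain_id}:{self.residue_number}{AA1[self.target_aa]}"


@dataclass
class RotamerLibrary:
    """Chi-angle tuples per amino acid, in library (tie-break) order."""

    rotamers_by_aa: dict[str, list[tuple[float, ...]]] = field(default_factory=dict)

    def rotamers(self, aa: str) -> list[tuple[float, ...]]:
        if aa == "GLY":
            return [()]
        return self.rotamers_by_aa[aa]


def load_rotamer_library() -> RotamerLibrary:
    text = resources.files("mutscan.data").joinpath("rotamers.txt").read_text()
    lib: dict[str, list[tuple[float, ...]]] = {}
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        aa = parts[0]
        chis = tuple(float(x) for x in parts[1:] if x != "-")
        lib.setdefault(aa, []).append(chis)
    return RotamerLibrary(lib)


def clash_score(s: Structure, chain_id: str, residue_number: int) -> float:
    """Steric overlap of a residue's side chain with the rest of the structure.

    Sum over pairs (side-chain atom of the site, any atom at graph distance
    >= 3 bonds — approximated as: any atom of another residue, or side-chain
    atoms of the same residue more than two recipe steps away are ignored)
    of max(0, r_overlap - d)^2 with r_overlap = 0.8 x sum of contact radii.
    """
    res = s.chain(chain_id).residue(residue_number)
    side = [a for a in res.atoms if a.name not in geometry.BACKBONE_ATOMS]
    if not side:
        return 0.0
    others: list[Atom] = []
    for c in s.chains:
        for r in c.residues:
            if c.id == chain_id and r.number == residue_number:
                continue
            # backbone of sequence neighbours is within 3 bonds of CB; skip it
            if c.id == chain_id and abs(r.number - residue_number) == 1:
                others.extend(
                    a for a in r.atoms if a.name not in geometry.BACKBONE_ATOMS
                )
            else:
                others.extend(r.atoms)
    if not others:
        return 0.0
    sp = np.array([a.pos for a in side])
    op = np.array([a.pos for a in others])
    sr = np.array([_CLASH_RADIUS[a.element] for a in side])
    orr = np.array([_CLASH_RADIUS[a.element] for a in others])
    d = np.linalg.norm(sp[:, None, :] - op[None, :, :], axis=-1)
    r_overlap = _CLASH_OVERLAP_FACTOR * (sr[:, None] + orr[None, :])
    pen = np.maximum(0.0, r_overlap - d)
    return float((pen * pen).sum())


def mutate_residue(
    s: Structure,
    spec: MutationSpec,
    lib: RotamerLibrary | None = None,
) -> Structure:
    """Replace the side chain of one residue, keeping its backbone fixed.

    Among library rotamers the one with the lowest clash score is chosen
    (first on tie).  If every rotamer clashes, the least-bad one is still
    returned and the residue is flagged ``clash``; Pro targets are flagged
    ``proline-open-ring``.
    """
    lib = lib or load_rotamer_library()
    res = s.chain(spec.chain_id).residue(spec.residue_number)
    if res.aa == spec.target_aa:
        raise ValueError(
            f"identity mutation {res.aa}{spec.residue_number} -> {spec.target_aa}"
        )
    for n in ("N", "CA", "C"):
        if not res.has_atom(n):
            raise ValueError(f"incomplete backbone at {res.aa}{spec.residue_number}")

    out = s.copy()
    new_res = out.chain(spec.chain_id).residue(spec.residue_number)
    backbone_atoms = [a for a in new_res.atoms if a.name in geometry.BACKBONE_ATOMS]
    backbone = {a.name: a.pos for a in backbone_atoms}
    new_res.aa = spec.target_aa
    new_res.flags = [f for f in new_res.flags if f not in ("clash", "proline-open-ring")]

    best = None  # (score, rotamer_index, positions)
    for i, chis in enumerate(lib.rotamers(spec.target_aa)):
        sc = geometry.build_side_chain(backbone, spec.target_aa, chis)
        new_res.atoms = backbone_atoms + [
            Atom(name=n, element=geometry.element_of(n), pos=np.array(p))
            for n, p in sc.items()
        ]
        score = clash_score(out, spec.chain_id, spec.residue_number)
        if best is None or score < best[0] - 1e-12:
            best = (score, i, {n: np.array(p) for n, p in sc.items()})
    assert best is not None
    score, _, sc = best
    new_res.atoms = backbone_atoms + [
        Atom(name=n, element=geometry.element_of(n), pos=p) for n, p in sc.items()
    ]
    if score > 0.0:
        new_res.flags.append("clash")
    if spec.target_aa == "PRO":
        new_res.flags.append("proline-open-ring")
    return out


def saturation_scan(
    s: Structure,
    chain_id: str,
    residue_number: int,
    lib: RotamerLibrary | None = None,
) -> list[tuple[MutationSpec, Structure]]:
    """All 19 non-wild-type substitutions at a site, one-letter alphabetical."""
    lib = lib or load_rotamer_library()
    wt = s.chain(chain_id).residue(residue_number).aa
    out = []
    for one in sorted(AA3):
        aa = AA3[one]
        if aa == wt:
            continue
        spec = MutationSpec(chain_id, residue_number, aa)
        out.append((spec, mutate_residue(s, spec, lib)))
    return out
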