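"""Hierarchical protein structure container and PDB I/O.

The container is deliberately small: atoms carry coordinate, element and
slots for the partial charge / radii that the energy module fills in.
Fixed-column PDB parsing and writing are delegated to gemmi; alternate
conformations are collapsed to the highest-occupancy conformer (first on
tie) and HETATM groups are retained but flagged non-protein.

A single integer ``numbering_offset`` maps file numbering to reporting
numbering, for structures whose deposited residue numbers are shifted
relative to the numbering used in the literature on the protein; all
residue numbers handled here are file numbering.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import gemmi
import numpy as np

from .geometry import AA1, BACKBONE_ATOMS, CANONICAL_AA


class PDBFormatError(ValueError):
    """Malformed or unusable PDB content."""


@dataclass
class Atom:
    name: str
    element: str
    pos: np.ndarray
    charge: float = 0.0          # partial charge, e (set by energy module)
    radius: float = 0.0          # LJ sigma/2-like radius slot, Angstrom
    sigma: float = 0.0           # LJ sigma, Angstrom
    epsilon: float = 0.0         # LJ well depth, kcal/mol
    gb_radius: float = 0.0       # intrinsic Born radius, Angstrom

    def copy(self) -> "Atom":
        a = copy.copy(self)
        a.pos = np.array(self.pos, dtype=float)
        return a


@dataclass
class Residue:
    number: int
    aa: str                      # three-letter code (canonical, or ligand id)
    atoms: list[Atom] = field(default_factory=list)
    insertion_code: str = ""
    is_hetero: bool = False      # HETATM group (ligand, water, ...)
    flags: list[str] = field(default_factory=list)

    def atom(self, name: str) -> Atom:
        for a in self.atoms:
            if a.name == name:
                return a
        raise KeyError(f"atom {name} not in residue {self.aa}{self.number}")

    def has_atom(self, name: str) -> bool:
        return any(a.name == name for a in self.atoms)

    @property
    def one_letter(self) -> str:
        return AA1.get(self.aa, "X")

    def positions(self) -> dict[str, np.ndarray]:
        return {a.name: a.pos for a in self.atoms}

    def copy(self) -> "Residue":
        r = copy.copy(self)
        r.atoms = [a.copy() for a in self.atoms]
        r.flags = list(self.flags)
        return r


@dataclass
class Chain:
    id: str
    residues: list[Residue] = field(default_factory=list)

    def residue(self, number: int) -> Residue:
        for r in self.residues:
            if r.number == number:
                return r
        raise KeyError(f"residue {number} not in chain {self.id}")

    def has_residue(self, number: int) -> bool:
        return any(r.number == number for r in self.residues)

    def protein_residues(self) -> list[Residue]:
        return [r for r in self.residues if not r.is_hetero]

    def copy(self) -> "Chain":
        return Chain(self.id, [r.copy() for r in self.residues])


@dataclass
class Structure:
    chains: list[Chain] = field(default_factory=list)
    title: str = ""
    numbering_offset: int = 0

    def chain(self, chain_id: str) -> Chain:
        for c in self.chains:
            if c.id == chain_id:
                return c
        raise KeyError(f"chain {chain_id} not in structure")

    def protein_chains(self) -> list[Chain]:
        return [c for c in self.chains if c.protein_residues()]

    def atoms(self) -> list[Atom]:
        return [a for c in self.chains for r in c.residues for a in r.atoms]

    def n_atoms(self) -> int:
        return len(self.atoms())

    def coords(self) -> np.ndarray:
        return np.array([a.pos for a in self.atoms()], dtype=float)

    def set_coords(self, xyz: np.ndarray) -> None:
        for a, p in zip(self.atoms(), np.asarray(xyz, dtype=float)):
            a.pos = np.array(p)

    def report_number(self, file_number: int) -> int:
        """Map file numbering to reporting (literature) numbering."""
        return file_number - self.numbering_offset

    def file_number(self, report_number: int) -> int:
        return report_number + self.numbering_offset

    def copy(self) -> "Structure":
        return Structure(
            [c.copy() for c in self.chains], self.title, self.numbering_offset
        )

    def validate(self) -> None:
        ids = [c.id for c in self.chains]
        if len(set(ids)) != len(ids):
            raise PDBFormatError(f"duplicate chain ids: {ids}")
        for c in self.chains:
            numbers = [r.number for r in c.residues]
            if any(b <= a for a, b in zip(numbers, numbers[1:])):
                raise PDBFormatError(
                    f"residue numbers not strictly increasing in chain {c.id}"
                )
            for r in c.protein_residues():
                if r.aa not in CANONICAL_AA:
                    raise PDBFormatError(f"non-canonical residue {r.aa}{r.number}")
                missing = [n for n in BACKBONE_ATOMS if not r.has_atom(n)]
                if missing:
                    raise PDBFormatError(
                        f"residue {r.aa}{r.number} chain {c.id} missing backbone {missing}"
                    )


def read_pdb(path, numbering_offset: int = 0) -> Structure:
    """Read a PDB file into a Structure.

    Altlocs are collapsed to the highest-occupancy conformer (first on tie);
    HETATM groups are kept with ``is_hetero`` set.
    """
    import os

    if not os.path.exists(str(path)):
        raise FileNotFoundError(f"no such PDB file: {path}")
    st = gemmi.read_pdb(str(path))
    if len(st) == 0 or st[0].count_atom_sites() == 0:
        raise PDBFormatError(f"no ATOM records in {path}")
    out = Structure(title=st.name, numbering_offset=numbering_offset)
    model = st[0]
    for ch in model:
        chain = Chain(id=ch.name or "A")
        for res in ch:
            is_het = res.het_flag == "H"
            residue = Residue(
                number=res.seqid.num,
                aa=res.name,
                insertion_code=(res.seqid.icode or "").strip(),
                is_hetero=is_het or res.name not in CANONICAL_AA,
            )
            def _alt(a: gemmi.Atom) -> str:
                return (a.altloc or "").strip("\x00 ").strip()

            best: dict[str, gemmi.Atom] = {}
            for at in res:
                prev = best.get(at.name)
                if prev is None:
                    best[at.name] = at
                elif not _alt(at) and not _alt(prev):
                    raise PDBFormatError(
                        f"duplicate atom {at.name} in residue {res.name}{res.seqid.num}"
                    )
                elif at.occ > prev.occ:
                    best[at.name] = at  # higher-occupancy conformer wins
                # equal or lower occupancy: keep first
            for at in best.values():
                residue.atoms.append(
                    Atom(
                        name=at.name,
                        element=at.element.name or at.name[0],
                        pos=np.array([at.pos.x, at.pos.y, at.pos.z]),
                    )
                )
            chain.residues.append(residue)
        if chain.residues:
            out.chains.append(chain)
    if not out.chains:
        raise PDBFormatError(f"no chains parsed from {path}")
    return out


def write_pdb(s: Structure, path) -> None:
    """Write fixed-column PDB ATOM/HETATM records (occ 1.00, B 0.00)."""
    if not s.chains or all(not c.residues for c in s.chains):
        raise ValueError("refusing to write empty structure")
    st = gemmi.Structure()
    st.name = s.title or "mutscan"
    model = gemmi.Model("1")
    for c in s.chains:
        ch = gemmi.Chain(c.id)
        for r in c.residues:
            res = gemmi.Residue()
            res.name = r.aa
            res.seqid = gemmi.SeqId(r.number, r.insertion_code or " ")
            res.het_flag = "H" if r.is_hetero else "A"
            for a in r.atoms:
                at = gemmi.Atom()
                at.name = a.name
                at.element = gemmi.Element(a.element)
                at.pos = gemmi.Position(*[float(x) for x in a.pos])
                at.occ = 1.0
                at.b_iso = 0.0
                res.add_atom(at)
            ch.add_residue(res)
        model.add_chain(ch)
    st.add_model(model)
    st.setup_entities()
    st.write_pdb(str(path))


def truncate_domain(s: Structure, chain_id: str, start: int, end: int) -> Structure:
    """Restrict one chain to the closed residue interval [start, end].

    Other chains are dropped; numbering is file numbering.
    """
    if start > end:
        raise ValueError(f"invalid range: start {start} > end {end}")
    chain = s.chain(chain_id)
    kept = [r.copy() for r in chain.residues if start <= r.number <= end]
    if not kept:
        raise ValueError(f"no residues in range [{start}, {end}] of chain {chain_id}")
    return Structure(
        chains=[Chain(chain_id, kept)],
        title=s.title,
        numbering_offset=s.numbering_offset,
    )


def extract_segment(s: Structure, chain_id: str, center: int, length: int = 7) -> Structure:
    """Contiguous segment of odd `length` centred at residue `center`.

    At chain termini the window is truncated to the available residues; the
    same truncation is applied to wild type and mutant so folding-energy
    differences stay consistent.
    """
    if length % 2 == 0:
        raise ValueError(f"segment length must be odd, got {length}")
    if not 5 <= length <= 9:
        raise ValueError(f"segment length must be in [5, 9], got {length}")
    chain = s.chain(chain_id)
    if not chain.has_residue(center):
        raise KeyError(f"center residue {center} not in chain {chain_id}")
    half = (length - 1) // 2
    return truncate_domain(
        s,
        chain_id,
        max(center - half, chain.residues[0].number),
        min(center + half, chain.residues[-1].number),
    )


def split_monomers(dimer: Structure) -> tuple[Structure, Structure]:
    """Split a two-chain structure into its monomers, coordinates untouched.

    This is the rigid-body contract: monomer coordinates are bit-identical
    to those in the (already relaxed) dimer.
    """
    chains = dimer.protein_chains()
    if len(chains) != 2:
        raise ValueError(f"expected exactly 2 protein chains, got {len(chains)}")
    out = []
    for c in chains:
        out.append(
            Structure([c.copy()], dimer.title, dimer.numbering_offset)
        )
    return out[0], out[1]


def clash_report(s: Structure, overlap_factor: float = 0.6) -> list[tuple]:
    """Pairs of non-bonded atoms from different residues closer than
    ``overlap_factor`` x sum of heavy-atom contact radii (1.7 A proxy).

    Exposed as a report only; structures are never auto-rejected.
    """
    atoms = []
    for c in s.chains:
        for r in c.residues:
            for a in r.atoms:
                atoms.append((c.id, r.number, a))
    hits = []
    cutoff = overlap_factor * 3.4
    for i in range(len(atoms)):
        ci, ri, ai = atoms[i]
        for j in range(i + 1, len(atoms)):
            cj, rj, aj = atoms[j]
            if ci == cj and abs(ri - rj) <= 1:
                continue
            d = float(np.linalg.norm(ai.pos - aj.pos))
            if d < cutoff:
                hits.append((ci, ri, ai.name, cj, rj, aj.name, round(d, 3)))
    return hits
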