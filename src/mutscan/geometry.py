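"""Ideal-geometry construction of amino-acid residues.

Backbone atoms are taken from a planar template positioned by a rigid
transform; side-chain heavy atoms are grown with the natural extension
reference frame (NeRF) from bond length / bond angle / torsion recipes.
Only heavy atoms are built — the nonbonded energy model is parameterized
for heavy atoms with implicit hydrogens.

Torsion recipes reference chi angles (chi1..chi4) or fixed values; ring
closures (Phe/Tyr/Trp/His, Pro) are approximate: the closing bond is
recorded in the connectivity table but not geometrically constrained.
"""

from __future__ import annotations

import math
from typing import Sequence

import numpy as np

AA3 = {
    "A": "ALA", "R": "ARG", "N": "ASN", "D": "ASP", "C": "CYS",
    "Q": "GLN", "E": "GLU", "G": "GLY", "H": "HIS", "I": "ILE",
    "L": "LEU", "K": "LYS", "M": "MET", "F": "PHE", "P": "PRO",
    "S": "SER", "T": "THR", "W": "TRP", "Y": "TYR", "V": "VAL",
}
AA1 = {v: k for k, v in AA3.items()}
CANONICAL_AA = sorted(AA3.values())

BACKBONE_ATOMS = ("N", "CA", "C", "O")

# Elements by leading character of the (heavy-atom) PDB name.
_ELEMENT_BY_INITIAL = {"C": "C", "N": "N", "O": "O", "S": "S"}


def element_of(atom_name: str) -> str:
    return _ELEMENT_BY_INITIAL[atom_name.strip()[0]]


def normalize(v: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(v)
    if n == 0.0:
        raise ValueError("zero-length vector")
    return v / n


def dihedral(p0, p1, p2, p3) -> float:
    """Signed dihedral angle p0-p1-p2-p3 in degrees, IUPAC convention."""
    b0 = np.asarray(p0) - np.asarray(p1)
    b1 = np.asarray(p2) - np.asarray(p1)
    b2 = np.asarray(p3) - np.asarray(p2)
    b1u = normalize(b1)
    v = b0 - np.dot(b0, b1u) * b1u
    w = b2 - np.dot(b2, b1u) * b1u
    x = np.dot(v, w)
    y = np.dot(np.cross(b1u, v), w)
    return math.degrees(math.atan2(y, x))


def place_atom(a, b, c, bond: float, angle: float, torsion: float) -> np.ndarray:
    """Position atom D with |CD| = bond, angle(B,C,D) and dihedral(A,B,C,D).

    Angles in degrees.  NeRF construction.
    """
    ang = math.radians(angle)
    tor = math.radians(torsion)
    d_local = np.array(
        [
            -bond * math.cos(ang),
            bond * math.sin(ang) * math.cos(tor),
            bond * math.sin(ang) * math.sin(tor),
        ]
    )
    bc = normalize(np.asarray(c) - np.asarray(b))
    n = normalize(np.cross(np.asarray(b) - np.asarray(a), bc))
    m = np.column_stack([bc, np.cross(n, bc), n])
    return np.asarray(c) + m @ d_local


# Backbone template in a local frame: CA at origin, C on +x, peptide plane
# ~ the xy-plane.  Ideal bond lengths/angles (Engh-Huber-like, rounded).
_N_ANGLE = math.radians(111.0)
BACKBONE_TEMPLATE = {
    "N": np.array([1.458 * math.cos(_N_ANGLE), 1.458 * math.sin(_N_ANGLE), 0.0]),
    "CA": np.array([0.0, 0.0, 0.0]),
    "C": np.array([1.525, 0.0, 0.0]),
    "O": np.array(
        [1.525 + 1.231 * math.cos(math.radians(59.2)),
         -1.231 * math.sin(math.radians(59.2)), 0.0]
    ),
}

# Side-chain recipes.  Each entry: (atom, refA, refB, refC, bond, angle, tors)
# where tors is ("chi", k, offset_deg) or ("fix", value_deg).  Atom is bonded
# to refC.
_chi = lambda k, off=0.0: ("chi", k, off)
_fix = lambda v: ("fix", v)

SIDE_CHAIN_RECIPES: dict[str, list[tuple]] = {
    "GLY": [],
    "ALA": [("CB", "N", "C", "CA", 1.53, 110.5, _fix(122.7))],
}


def _with_cb(rest: list[tuple]) -> list[tuple]:
    return SIDE_CHAIN_RECIPES["ALA"] + rest


SIDE_CHAIN_RECIPES.update(
    {
        "SER": _with_cb([("OG", "N", "CA", "CB", 1.42, 110.5, _chi(1))]),
        "CYS": _with_cb([("SG", "N", "CA", "CB", 1.81, 114.4, _chi(1))]),
        "THR": _with_cb(
            [
                ("OG1", "N", "CA", "CB", 1.43, 109.6, _chi(1)),
                ("CG2", "N", "CA", "CB", 1.53, 110.5, _chi(1, -122.0)),
            ]
        ),
        "VAL": _with_cb(
            [
                ("CG1", "N", "CA", "CB", 1.53, 110.5, _chi(1)),
                ("CG2", "N", "CA", "CB", 1.53, 110.5, _chi(1, 122.0)),
            ]
        ),
        "LEU": _with_cb(
            [
                ("CG", "N", "CA", "CB", 1.53, 116.3, _chi(1)),
                ("CD1", "CA", "CB", "CG", 1.53, 110.7, _chi(2)),
                ("CD2", "CA", "CB", "CG", 1.53, 110.7, _chi(2, 122.0)),
            ]
        ),
        "ILE": _with_cb(
            [
                ("CG1", "N", "CA", "CB", 1.53, 110.4, _chi(1)),
                ("CG2", "N", "CA", "CB", 1.53, 110.5, _chi(1, -122.0)),
                ("CD1", "CA", "CB", "CG1", 1.53, 113.9, _chi(2)),
            ]
        ),
        "MET": _with_cb(
            [
                ("CG", "N", "CA", "CB", 1.52, 114.1, _chi(1)),
                ("SD", "CA", "CB", "CG", 1.80, 112.7, _chi(2)),
                ("CE", "CB", "CG", "SD", 1.79, 100.9, _chi(3)),
            ]
        ),
        "PRO": _with_cb(
            [
                ("CG", "N", "CA", "CB", 1.49, 104.5, _fix(30.0)),
                ("CD", "CA", "CB", "CG", 1.50, 106.1, _fix(-35.0)),
            ]
        ),
        "PHE": _with_cb(
            [
                ("CG", "N", "CA", "CB", 1.51, 113.8, _chi(1)),
                ("CD1", "CA", "CB", "CG", 1.39, 120.8, _chi(2)),
                ("CD2", "CA", "CB", "CG", 1.39, 120.8, _chi(2, 180.0)),
                ("CE1", "CB", "CG", "CD1", 1.39, 121.0, _fix(180.0)),
                ("CE2", "CB", "CG", "CD2", 1.39, 121.0, _fix(180.0)),
                ("CZ", "CG", "CD1", "CE1", 1.39, 120.0, _fix(0.0)),
            ]
        ),
        "TRP": _with_cb(
            [
                ("CG", "N", "CA", "CB", 1.50, 114.0, _chi(1)),
                ("CD1", "CA", "CB", "CG", 1.37, 127.0, _chi(2)),
                ("CD2", "CA", "CB", "CG", 1.43, 126.6, _chi(2, 180.0)),
                ("NE1", "CB", "CG", "CD1", 1.38, 110.1, _fix(180.0)),
                ("CE2", "CB", "CG", "CD2", 1.41, 107.2, _fix(180.0)),
                ("CE3", "CB", "CG", "CD2", 1.40, 133.9, _fix(0.0)),
                ("CZ2", "CG", "CD2", "CE2", 1.40, 122.4, _fix(180.0)),
                ("CZ3", "CG", "CD2", "CE3", 1.39, 118.6, _fix(180.0)),
                ("CH2", "CD2", "CE2", "CZ2", 1.37, 117.5, _fix(0.0)),
            ]
        ),
        "ASP": _with_cb(
            [
                ("CG", "N", "CA", "CB", 1.52, 113.0, _chi(1)),
                ("OD1", "CA", "CB", "CG", 1.25, 118.4, _chi(2)),
                ("OD2", "CA", "CB", "CG", 1.25, 118.4, _chi(2, 180.0)),
            ]
        ),
        "ASN": _with_cb(
            [
                ("CG", "N", "CA", "CB", 1.52, 112.7, _chi(1)),
                ("OD1", "CA", "CB", "CG", 1.23, 120.8, _chi(2)),
                ("ND2", "CA", "CB", "CG", 1.33, 116.4, _chi(2, 180.0)),
            ]
        ),
        "GLU": _with_cb(
            [
                ("CG", "N", "CA", "CB", 1.52, 114.1, _chi(1)),
                ("CD", "CA", "CB", "CG", 1.52, 112.6, _chi(2)),
                ("OE1", "CB", "CG", "CD", 1.25, 118.4, _chi(3)),
                ("OE2", "CB", "CG", "CD", 1.25, 118.4, _chi(3, 180.0)),
            ]
        ),
        "GLN": _with_cb(
            [
                ("CG", "N", "CA", "CB", 1.52, 114.1, _chi(1)),
                ("CD", "CA", "CB", "CG", 1.52, 112.6, _chi(2)),
                ("OE1", "CB", "CG", "CD", 1.23, 120.8, _chi(3)),
                ("NE2", "CB", "CG", "CD", 1.33, 116.4, _chi(3, 180.0)),
            ]
        ),
        "LYS": _with_cb(
            [
                ("CG", "N", "CA", "CB", 1.52, 114.1, _chi(1)),
                ("CD", "CA", "CB", "CG", 1.52, 111.3, _chi(2)),
                ("CE", "CB", "CG", "CD", 1.52, 111.7, _chi(3)),
                ("NZ", "CG", "CD", "CE", 1.49, 112.0, _chi(4)),
            ]
        ),
        "ARG": _with_cb(
            [
                ("CG", "N", "CA", "CB", 1.52, 114.1, _chi(1)),
                ("CD", "CA", "CB", "CG", 1.52, 111.3, _chi(2)),
                ("NE", "CB", "CG", "CD", 1.46, 112.0, _chi(3)),
                ("CZ", "CG", "CD", "NE", 1.33, 124.2, _chi(4)),
                ("NH1", "CD", "NE", "CZ", 1.33, 120.0, _fix(0.0)),
                ("NH2", "CD", "NE", "CZ", 1.33, 120.0, _fix(180.0)),
            ]
        ),
        "HIS": _with_cb(
            [
                ("CG", "N", "CA", "CB", 1.49, 113.8, _chi(1)),
                ("ND1", "CA", "CB", "CG", 1.38, 122.7, _chi(2)),
                ("CD2", "CA", "CB", "CG", 1.36, 131.1, _chi(2, 180.0)),
                ("CE1", "CB", "CG", "ND1", 1.32, 109.2, _fix(180.0)),
                ("NE2", "CB", "CG", "CD2", 1.37, 107.2, _fix(180.0)),
            ]
        ),
    }
)

# Ring-closure / extra bonds not implied by the recipes (atom bonded to refC).
_EXTRA_BONDS = {
    "PHE": [("CE2", "CZ")],
    "TYR": [("CE2", "CZ")],
    "TRP": [("NE1", "CE2"), ("CZ3", "CH2")],
    "HIS": [("CE1", "NE2")],
    "PRO": [("CD", "N")],
}

SIDE_CHAIN_RECIPES["TYR"] = SIDE_CHAIN_RECIPES["PHE"] + [
    ("OH", "CD1", "CE1", "CZ", 1.38, 119.9, _fix(180.0))
]

# Number of variable chi angles per residue.
N_CHI = {
    aa: max([r[6][1] for r in recipe if r[6][0] == "chi"], default=0)
    for aa, recipe in SIDE_CHAIN_RECIPES.items()
}


def side_chain_atom_names(aa: str) -> list[str]:
    return [r[0] for r in SIDE_CHAIN_RECIPES[aa]]


def residue_bonds(aa: str) -> list[tuple[str, str]]:
    """Intra-residue heavy-atom bonds (pairs of atom names)."""
    bonds = [("N", "CA"), ("CA", "C"), ("C", "O")]
    for atom, _a, _b, ref_c, *_ in SIDE_CHAIN_RECIPES[aa]:
        bonds.append((ref_c, atom))
    bonds.extend(_EXTRA_BONDS.get(aa, []))
    return bonds


def build_side_chain(
    backbone: dict[str, np.ndarray], aa: str, chis: Sequence[float]
) -> dict[str, np.ndarray]:
    """Grow side-chain heavy atoms of `aa` onto backbone coordinates.

    `backbone` must contain N, CA, C.  `chis` supplies chi1..chiK (missing
    angles default to 180 deg).  Returns atom-name -> position.
    """
    pos = {k: np.asarray(v, dtype=float) for k, v in backbone.items()}
    chis = list(chis)
    out: dict[str, np.ndarray] = {}
    for atom, a, b, c, bond, angle, tors in SIDE_CHAIN_RECIPES[aa]:
        kind = tors[0]
        if kind == "chi":
            k, off = tors[1], tors[2]
            base = chis[k - 1] if k <= len(chis) else 180.0
            t = base + off
        else:
            t = tors[1]
        p = place_atom(pos[a], pos[b], pos[c], bond, angle, t)
        pos[atom] = p
        out[atom] = p
    return out


def backbone_at(rotation: np.ndarray, translation: np.ndarray) -> dict[str, np.ndarray]:
    """Backbone template atoms under a rigid transform."""
    return {
        name: rotation @ xyz + translation for name, xyz in BACKBONE_TEMPLATE.items()
    }


def rotation_x(deg: float) -> np.ndarray:
    c, s = math.cos(math.radians(deg)), math.sin(math.radians(deg))
    return np.array([[1, 0, 0], [0, c, -s], [0, s, c]], dtype=float)


def rotation_y(deg: float) -> np.ndarray:
    c, s = math.cos(math.radians(deg)), math.sin(math.radians(deg))
    return np.array([[c, 0, s], [0, 1, 0], [-s, 0, c]], dtype=float)


def rotation_z(deg: float) -> np.ndarray:
    c, s = math.cos(math.radians(deg)), math.sin(math.radians(deg))
    return np.array([[c, -s, 0], [s, c, 0], [0, 0, 1]], dtype=float)


def build_backbone_chain(program: Sequence[tuple[float, float]]) -> list[dict[str, np.ndarray]]:
    """Backbone (N, CA, C, O per residue) from a (phi, psi) program.

    The first residue sits at the template; each next residue is grown with
    ideal peptide geometry (omega = 180).  O is placed anti to the next N.
    """
    res: list[dict[str, np.ndarray]] = [
        {k: np.array(v) for k, v in BACKBONE_TEMPLATE.items() if k != "O"}
    ]
    for i, (phi, psi) in enumerate(program):
        cur = res[i]
        if i + 1 < len(program):
            n2 = place_atom(cur["N"], cur["CA"], cur["C"], 1.33, 116.2, psi)
            ca2 = place_atom(cur["CA"], cur["C"], n2, 1.458, 121.7, 180.0)
            c2 = place_atom(cur["C"], n2, ca2, 1.525, 111.0, program[i + 1][0])
            res.append({"N": n2, "CA": ca2, "C": c2})
        cur["O"] = place_atom(cur["N"], cur["CA"], cur["C"], 1.231, 120.8, psi + 180.0)
    return res


def measure_chis(positions: dict[str, np.ndarray], aa: str) -> list[float]:
    """Chi angles (degrees) of a residue given its atom positions."""
    chis: list[float] = []
    for atom, a, b, c, _bond, _angle, tors in SIDE_CHAIN_RECIPES[aa]:
        if tors[0] == "chi" and tors[2] == 0.0 and tors[1] == len(chis) + 1:
            chis.append(dihedral(positions[a], positions[b], positions[c], positions[atom]))
    return chis
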