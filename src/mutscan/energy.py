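"""Simplified molecular-mechanics potential with implicit solvent.

The potential is pairwise nonbonded only: Lennard-Jones (Lorentz-Berthelot
combination), Coulomb electrostatics with interior dielectric, and a
Still-type Generalized-Born solvation term with Hawkins-Cramer-Truhlar
(HCT) pairwise-descreening Born radii.  Bonded terms are absent by design:
the downstream folding/binding protocols only use energy differences under
a rigid backbone, and side-chain relaxation operates in torsion space where
ideal bond lengths and angles are preserved by construction.

Nonbonded exclusions: 1-2 and 1-3 pairs excluded, 1-4 pairs scaled by 0.5
(LJ and Coulomb); the GB sum runs over all pairs, including self terms.

Three bundled parameter sets (ff_a, ff_b, ff_c) provide the multi-force-
field averaging used by the scanning protocols.  They share the topology
and differ in charges and LJ parameters; titratable side chains carry
their fully ionized charges (Asp-, Glu-, Lys+, Arg+, His+).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources

import numpy as np

from . import geometry
from .structio import Structure

KE = 332.0636          # Coulomb constant, kcal*A/(mol*e^2)
DEFAULT_EPS_INT = 1.0
DEFAULT_EPS_SOLV = 78.5
HCT_SCALE = 0.8        # descreening scaling factor
ONE_FOUR_SCALE = 0.5

DEFAULT_SETS = ("ff_a", "ff_b", "ff_c")


class ParameterError(ValueError):
    """Atom or residue without parameters."""


@dataclass
class ForceFieldParams:
    """A named nonbonded parameter set.

    charges: (residue, atom) -> partial charge (e) with the atom's LJ class;
    classes: class -> (sigma A, epsilon kcal/mol, gb_radius A).
    """

    name: str
    charges: dict[tuple[str, str], tuple[float, str]]
    classes: dict[str, tuple[float, float, float]]
    interior_dielectric: float = DEFAULT_EPS_INT
    solvent_dielectric: float = DEFAULT_EPS_SOLV

    def lookup(self, aa: str, atom: str) -> tuple[float, float, float, float]:
        """(charge, sigma, epsilon, gb_radius) for an atom."""
        try:
            q, cls = self.charges[(aa, atom)]
            sig, eps, gbr = self.classes[cls]
        except KeyError:
            raise ParameterError(
                f"no parameters for atom {atom} of residue {aa} in set {self.name}"
            ) from None
        return q, sig, eps, gbr


def load_param_set(name: str) -> ForceFieldParams:
    """Load a bundled plain-text parameter set by name."""
    text = resources.files("mutscan.data").joinpath(f"{name}.txt").read_text()
    charges: dict[tuple[str, str], tuple[float, str]] = {}
    classes: dict[str, tuple[float, float, float]] = {}
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        if parts[0] == "CHG":
            _, aa, atom, q, cls = parts
            charges[(aa, atom)] = (float(q), cls)
        elif parts[0] == "CLS":
            _, cls, sig, eps, gbr = parts
            classes[cls] = (float(sig), float(eps), float(gbr))
    return ForceFieldParams(name=name, charges=charges, classes=classes)


def load_default_sets(names=DEFAULT_SETS) -> list[ForceFieldParams]:
    return [load_param_set(n) for n in names]


def assign_parameters(s: Structure, p: ForceFieldParams) -> Structure:
    """Return a copy of `s` with charge/sigma/epsilon/gb_radius on every atom."""
    out = s.copy()
    for c in out.chains:
        for r in c.residues:
            for a in r.atoms:
                q, sig, eps, gbr = p.lookup(r.aa, a.name)
                a.charge, a.sigma, a.epsilon, a.gb_radius = q, sig, eps, gbr
                a.radius = sig / 2.0
    return out


@dataclass
class EnergyBreakdown:
    lj: float
    coulomb: float
    gb: float

    @property
    def total(self) -> float:
        return self.lj + self.coulomb + self.gb


def _bond_graph(s: Structure) -> list[list[int]]:
    """Adjacency lists over the flat atom order of `s`.

    Intra-residue bonds from the residue templates, peptide bonds C(i)-N(i+1)
    within each chain.  Hetero groups contribute no bonds (treated as free
    nonbonded particles).
    """
    index: dict[tuple[str, int, str], int] = {}
    k = 0
    for c in s.chains:
        for r in c.residues:
            for a in r.atoms:
                index[(c.id, r.number, a.name)] = k
                k += 1
    adj: list[list[int]] = [[] for _ in range(k)]

    def link(i: int, j: int) -> None:
        adj[i].append(j)
        adj[j].append(i)

    for c in s.chains:
        prev = None
        for r in c.residues:
            if r.is_hetero or r.aa not in geometry.SIDE_CHAIN_RECIPES:
                prev = None  # free nonbonded particle (ion, ligand)
                continue
            for a_name, b_name in geometry.residue_bonds(r.aa):
                ia = index.get((c.id, r.number, a_name))
                ib = index.get((c.id, r.number, b_name))
                if ia is not None and ib is not None:
                    link(ia, ib)
            if prev is not None:
                ic = index.get((c.id, prev.number, "C"))
                inn = index.get((c.id, r.number, "N"))
                if ic is not None and inn is not None and r.number == prev.number + 1:
                    link(ic, inn)
            prev = r
    return adj


def _pair_scale_matrix(adj: list[list[int]]) -> np.ndarray:
    """n x n matrix: 0 for self/1-2/1-3, ONE_FOUR_SCALE for 1-4, 1 otherwise."""
    n = len(adj)
    scale = np.ones((n, n))
    np.fill_diagonal(scale, 0.0)
    for i in range(n):
        # BFS to depth 3
        dist = {i: 0}
        frontier = [i]
        for d in (1, 2, 3):
            nxt = []
            for u in frontier:
                for v in adj[u]:
                    if v not in dist:
                        dist[v] = d
                        nxt.append(v)
            frontier = nxt
        for j, d in dist.items():
            if j == i:
                continue
            scale[i, j] = 0.0 if d <= 2 else ONE_FOUR_SCALE
    return scale


class EnergyModel:
    """Vectorized nonbonded energy for one structure under one parameter set.

    Topology (parameters, exclusions) is computed once; coordinates may be
    swapped with ``set_coords`` during relaxation.
    """

    def __init__(self, s: Structure, p: ForceFieldParams):
        self.params = p
        self.structure = assign_parameters(s, p)
        atoms = self.structure.atoms()
        self.n = len(atoms)
        self.q = np.array([a.charge for a in atoms])
        sig = np.array([a.sigma for a in atoms])
        eps = np.array([a.epsilon for a in atoms])
        self.rho = np.array([a.gb_radius for a in atoms])
        # Lorentz-Berthelot combination
        self.sig_ij = 0.5 * (sig[:, None] + sig[None, :])
        self.eps_ij = np.sqrt(np.outer(eps, eps))
        self.scale = _pair_scale_matrix(_bond_graph(self.structure))
        self.qq = np.outer(self.q, self.q)
        self.xyz = self.structure.coords()
        self._iu = np.triu_indices(self.n, k=1)

    def set_coords(self, xyz: np.ndarray) -> None:
        self.xyz = np.asarray(xyz, dtype=float)

    def _distances(self) -> np.ndarray:
        d = self.xyz[:, None, :] - self.xyz[None, :, :]
        r = np.sqrt(np.einsum("ijk,ijk->ij", d, d))
        return r

    def _check_coincident(self, r: np.ndarray) -> None:
        ru = r[self._iu]
        su = self.scale[self._iu]
        if np.any((ru == 0.0) & (su > 0.0)):
            raise ValueError("coincident atoms in nonbonded pair")

    def _nonbonded_r(self, r: np.ndarray) -> np.ndarray:
        """Distances with excluded pairs sent to infinity (zero energy)."""
        return np.where(self.scale > 0.0, r, np.inf)

    def coulomb(self, r: np.ndarray | None = None) -> float:
        r = self._distances() if r is None else r
        self._check_coincident(r)
        e = self.scale * KE * self.qq / (
            self.params.interior_dielectric * self._nonbonded_r(r)
        )
        return float(e[self._iu].sum())

    def lj(self, r: np.ndarray | None = None) -> float:
        r = self._distances() if r is None else r
        self._check_coincident(r)
        sr6 = (self.sig_ij / self._nonbonded_r(r)) ** 6
        e = self.scale * 4.0 * self.eps_ij * (sr6 * sr6 - sr6)
        return float(e[self._iu].sum())

    def born_radii(self, r: np.ndarray | None = None) -> np.ndarray:
        """Effective Born radii via HCT pairwise descreening.

        1/B_i = 1/rho_i - sum_j H(r_ij, s*rho_j); isolated atoms recover
        their intrinsic radii exactly.
        """
        r = self._distances() if r is None else r
        rho = self.rho
        if np.any(rho <= 0.0):
            raise ValueError("nonpositive intrinsic Born radius")
        sj = HCT_SCALE * rho[None, :]
        rij = np.where(r > 0.0, r, 1.0)  # diagonal placeholder, zeroed below
        # HCT integral for non-overlapping spheres; overlapping case clamped
        # to the non-overlap branch evaluated at contact (deterministic,
        # smooth enough for toy systems).
        rr = np.maximum(rij, rho[:, None] + sj)
        lij = rr - sj
        uij = rr + sj
        term = (
            0.5
            * (
                1.0 / lij
                - 1.0 / uij
                + (rr * rr - sj * sj) / (4.0 * rr) * (1.0 / (uij * uij) - 1.0 / (lij * lij))
                + np.log(lij / uij) / (2.0 * rr)
            )
        )
        np.fill_diagonal(term, 0.0)
        inv_b = 1.0 / rho - term.sum(axis=1)
        inv_b = np.maximum(inv_b, 1e-8)
        return 1.0 / inv_b

    def gb(self, r: np.ndarray | None = None) -> float:
        r = self._distances() if r is None else r
        b = self.born_radii(r)
        tau = 1.0 / self.params.interior_dielectric - 1.0 / self.params.solvent_dielectric
        bb = np.outer(b, b)
        with np.errstate(over="ignore", under="ignore"):
            f = np.sqrt(r * r + bb * np.exp(-(r * r) / (4.0 * bb)))
        e = KE * self.qq / f
        # all pairs once + self terms
        total = e[self._iu].sum() + 0.5 * np.trace(e)
        return float(-tau * total)

    def breakdown(self) -> EnergyBreakdown:
        r = self._distances()
        return EnergyBreakdown(lj=self.lj(r), coulomb=self.coulomb(r), gb=self.gb(r))

    def total(self) -> float:
        return self.breakdown().total

    def _moved_terms(self, xyz: np.ndarray, idx: np.ndarray, born: np.ndarray) -> float:
        """LJ + Coulomb + GB-pair energy of all pairs involving atoms `idx`,
        with frozen Born radii.

        Exact for LJ/Coulomb; the GB part neglects the Born-radius response
        to the move.  Used only to screen relaxation proposals — accepted
        moves are re-verified with the full energy.
        """
        sub = xyz[idx]
        d = np.sqrt(
            np.maximum(((sub[:, None, :] - xyz[None, :, :]) ** 2).sum(axis=-1), 1e-6)
        )
        tau = 1.0 / self.params.interior_dielectric - 1.0 / self.params.solvent_dielectric

        def pair_terms(dd, scale, qq, sig, eps, bb):
            sr6 = (sig / dd) ** 6
            lj_coul = scale * (
                4.0 * eps * (sr6 * sr6 - sr6)
                + KE * qq / (self.params.interior_dielectric * dd)
            )
            f = np.sqrt(dd * dd + bb * np.exp(-(dd * dd) / (4.0 * bb)))
            return lj_coul - tau * KE * qq / f

        rows = pair_terms(
            d, self.scale[idx], self.qq[idx], self.sig_ij[idx], self.eps_ij[idx],
            np.outer(born[idx], born),
        )
        mask = np.ones((len(idx), self.n))
        mask[np.arange(len(idx)), idx] = 0.0  # drop self pairs
        total = (rows * mask).sum()
        # idx-idx pairs appear in two rows each: subtract one copy
        ii = np.ix_(idx, idx)
        inner = pair_terms(
            np.maximum(d[:, idx], 1e-3), self.scale[ii], self.qq[ii],
            self.sig_ij[ii], self.eps_ij[ii], np.outer(born[idx], born[idx]),
        )
        total -= 0.5 * (inner * (1.0 - np.eye(len(idx)))).sum()
        return float(total)


def coulomb_energy(s: Structure, p: ForceFieldParams | None = None) -> float:
    p = p or load_param_set("ff_a")
    return EnergyModel(s, p).coulomb()


def lj_energy(s: Structure, p: ForceFieldParams | None = None) -> float:
    p = p or load_param_set("ff_a")
    return EnergyModel(s, p).lj()


def gb_energy(s: Structure, p: ForceFieldParams | None = None) -> float:
    p = p or load_param_set("ff_a")
    return EnergyModel(s, p).gb()


def total_energy(s: Structure, p: ForceFieldParams) -> EnergyBreakdown:
    return EnergyModel(s, p).breakdown()


@dataclass
class RelaxResult:
    structure: Structure
    energy: float
    sweeps: int
    converged: bool


CHI_PROPOSALS = (-120.0, -60.0, -30.0, 30.0, 60.0, 120.0)


def _residue_atom_slice(s: Structure, chain_id: str, number: int) -> tuple[int, int]:
    """(start, stop) indices of a residue's atoms in the flat atom order."""
    k = 0
    for c in s.chains:
        for r in c.residues:
            if c.id == chain_id and r.number == number:
                return k, k + len(r.atoms)
            k += len(r.atoms)
    raise KeyError((chain_id, number))


def relax(
    s: Structure,
    p: ForceFieldParams,
    scope: list[tuple[str, int]] | None = None,
    tol: float = 0.01,
    max_sweeps: int = 5,
) -> RelaxResult:
    """Coordinate descent over side-chain chi angles of `scope` residues.

    Backbone is fixed.  Each sweep visits every chi angle of every scope
    residue and keeps the best of the current value and a fixed proposal
    grid.  Terminates when a full sweep improves total energy by less than
    `tol` (kcal/mol) or after `max_sweeps`; energy never increases.
    """
    model = EnergyModel(s, p)
    work = model.structure
    atom_names = [a.name for a in work.atoms()]
    if scope is None:
        scope = [
            (c.id, r.number)
            for c in work.protein_chains()
            for r in c.residues
            if geometry.N_CHI[r.aa] > 0
        ]
    if math.isinf(tol):
        return RelaxResult(work.copy(), model.total(), 0, True)

    coords = work.coords()          # accepted state
    model.set_coords(coords)
    current = model.total()
    sweeps = 0
    converged = False
    for _ in range(max_sweeps):
        sweeps += 1
        start_energy = current
        born = model.born_radii()   # frozen during the sweep, for screening
        for chain_id, number in scope:
            res = work.chain(chain_id).residue(number)
            nchi = geometry.N_CHI[res.aa]
            if nchi == 0:
                continue
            lo, hi = _residue_atom_slice(work, chain_id, number)
            side_idx = np.array(
                [i for i in range(lo, hi) if atom_names[i] not in geometry.BACKBONE_ATOMS]
            )
            if len(side_idx) == 0:
                continue
            backbone = {n: res.atom(n).pos for n in ("N", "CA", "C")}

            def apply_chis(base: np.ndarray, trial_chis) -> np.ndarray:
                sc = geometry.build_side_chain(backbone, res.aa, trial_chis)
                xyz = base.copy()
                for i in range(lo, hi):
                    if atom_names[i] in sc:
                        xyz[i] = sc[atom_names[i]]
                return xyz

            for k in range(1, nchi + 1):
                chis = geometry.measure_chis(res.positions(), res.aa)
                base_terms = model._moved_terms(coords, side_idx, born)
                best_delta, best_chis = -1e-9, None
                for step in CHI_PROPOSALS:
                    trial = list(chis)
                    trial[k - 1] = chis[k - 1] + step
                    delta = (
                        model._moved_terms(apply_chis(coords, trial), side_idx, born)
                        - base_terms
                    )
                    if delta < best_delta:
                        best_delta, best_chis = delta, trial
                if best_chis is not None:
                    # verify the screened winner against the full energy
                    trial_coords = apply_chis(coords, best_chis)
                    model.set_coords(trial_coords)
                    e = model.total()
                    if e < current - 1e-12:
                        coords = trial_coords
                        current = e
                        sc = geometry.build_side_chain(backbone, res.aa, best_chis)
                        for a in res.atoms:
                            if a.name in sc:
                                a.pos = np.array(sc[a.name])
                    else:
                        model.set_coords(coords)
        model.set_coords(coords)
        if start_energy - current < tol:
            converged = True
            break
    return RelaxResult(work.copy(), current, sweeps, converged)
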