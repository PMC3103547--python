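"""Continuum-electrostatics titration and pKa-shift analysis.

Sites titrate on a two-state (neutral/ionized) lattice.  A microstate is a
vector x with x_i = 1 when site i is ionized; its energy at a given pH is

    E(x) = sum_i x_i * 1.364 * g_i * (pH - pKa_int_i) + sum_{i<j} x_i x_j W_ij

with g_i = -1 for acids, +1 for bases, 1.364 kcal/mol per pK unit at 298 K,
and W the pairwise interaction between ionized forms.  Boltzmann averages
come from exact enumeration (<= 20 sites) or single-site Metropolis Monte
Carlo; a site's pKa is the pH where its protonation fraction crosses 1/2.

Intrinsic pKas are the model value shifted by Born desolvation and the
interaction with non-titratable background charges — the standard
decomposition underlying continuum pKa methods, with conformational
hydrogen-bond optimization deliberately simplified out (fixed heavy-atom
geometry, mean-field charges).  Because the structure is rigid, these
electrostatic terms are evaluated with a protein dielectric of 8 (the
usual continuum-pKa choice that absorbs the missing conformational
relaxation), independent of the interior dielectric of 1 used by the
potential-energy model.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .energy import KE, EnergyModel, ForceFieldParams, load_param_set
from .structio import Structure

PK_TO_KCAL = 1.364          # kcal/mol per pK unit at 298 K
KT = PK_TO_KCAL / math.log(10.0)

TITRATION_DIELECTRIC = 8.0   # protein dielectric for pKa electrostatics

MODEL_PKA = {
    "ASP": 4.0, "GLU": 4.4, "HIS": 6.3, "LYS": 10.4,
    "ARG": 12.0, "TYR": 9.6, "CYS": 8.3,
}
IONIZED_CHARGE = {
    "ASP": -1, "GLU": -1, "TYR": -1, "CYS": -1,
    "HIS": +1, "LYS": +1, "ARG": +1,
}
# representative charged-group atom per titratable residue
_TIP_ATOM = {
    "ASP": "CG", "GLU": "CD", "HIS": "NE2", "LYS": "NZ",
    "ARG": "CZ", "TYR": "OH", "CYS": "SG",
}
DEFAULT_TITRATABLE = tuple(MODEL_PKA)


@dataclass
class TitratableSite:
    chain_id: str
    residue_number: int
    aa: str
    model_pka: float
    ionized_charge: int          # -1 acid, +1 base
    intrinsic_pka: float

    @property
    def key(self) -> tuple[str, int]:
        return (self.chain_id, self.residue_number)

    @property
    def sign(self) -> int:
        """g_i in the microstate energy: -1 acid, +1 base."""
        return -1 if self.ionized_charge < 0 else +1

    @property
    def label(self) -> str:
        return f"{self.chain_id}:{self.aa}{self.residue_number}"


@dataclass
class TitrationSystem:
    sites: list[TitratableSite]
    coupling: np.ndarray         # symmetric, zero diagonal, kcal/mol

    def __post_init__(self):
        w = np.asarray(self.coupling, dtype=float)
        n = len(self.sites)
        if w.shape != (n, n):
            raise ValueError(f"coupling shape {w.shape} != ({n}, {n})")
        if not np.allclose(w, w.T):
            raise ValueError("coupling matrix must be symmetric")
        w = w.copy()
        np.fill_diagonal(w, 0.0)
        self.coupling = w

    @property
    def n(self) -> int:
        return len(self.sites)


def find_titratable(s: Structure, aa_set=DEFAULT_TITRATABLE) -> list[TitratableSite]:
    """Titratable sites of a structure, ordered by (chain, residue number)."""
    out = []
    for c in s.chains:
        for r in c.protein_residues():
            if r.aa in aa_set:
                out.append(
                    TitratableSite(
                        chain_id=c.id,
                        residue_number=r.number,
                        aa=r.aa,
                        model_pka=MODEL_PKA[r.aa],
                        ionized_charge=IONIZED_CHARGE[r.aa],
                        intrinsic_pka=MODEL_PKA[r.aa],
                    )
                )
    out.sort(key=lambda t: (t.chain_id, t.residue_number))
    return out


def _tip_index(model: EnergyModel, chain_id: str, number: int, aa: str) -> int:
    k = 0
    for c in model.structure.chains:
        for r in c.residues:
            for a in r.atoms:
                if c.id == chain_id and r.number == number and a.name == _TIP_ATOM[aa]:
                    return k
                k += 1
    raise KeyError(f"tip atom {_TIP_ATOM[aa]} of {aa}{number} chain {chain_id}")


def _side_chain_mask(model: EnergyModel, titratable: list[TitratableSite]) -> np.ndarray:
    """True for side-chain atoms of titratable residues (excluded from the
    fixed background so site-site terms are not double counted)."""
    from .geometry import BACKBONE_ATOMS

    keys = {t.key for t in titratable}
    mask = np.zeros(model.n, dtype=bool)
    k = 0
    for c in model.structure.chains:
        for r in c.residues:
            for a in r.atoms:
                if (c.id, r.number) in keys and a.name not in BACKBONE_ATOMS:
                    mask[k] = True
                k += 1
    return mask


def _own_residue_mask(model: EnergyModel) -> np.ndarray:
    """Integer label of the (chain, residue) owning each atom."""
    labels = np.empty(model.n, dtype=int)
    k = 0
    tag = 0
    for c in model.structure.chains:
        for r in c.residues:
            for _ in r.atoms:
                labels[k] = tag
                k += 1
            tag += 1
    return labels


def _model_compound_born(s: Structure, site: TitratableSite, p) -> float:
    """Born radius of the site's charged-group atom in the residue taken
    alone (the solvated model compound the model pKa refers to)."""
    from .structio import Chain as _Chain, Structure as _Structure

    res = s.chain(site.chain_id).residue(site.residue_number)
    iso = _Structure([_Chain(site.chain_id, [res.copy()])])
    model = EnergyModel(iso, p)
    tip = _tip_index(model, site.chain_id, site.residue_number, site.aa)
    return float(model.born_radii()[tip])


def _screened_pair(r: float, bi: float, bj: float, eps_int: float, tau: float) -> float:
    """ke-scaled screened interaction kernel 1/(eps*r) - tau/f_GB."""
    f = math.sqrt(r * r + bi * bj * math.exp(-(r * r) / (4.0 * bi * bj)))
    direct = 1.0 / (eps_int * r) if r > 0 else 0.0
    return direct - tau / f


def build_titration_system(
    s: Structure,
    p: ForceFieldParams | None = None,
    aa_set=DEFAULT_TITRATABLE,
    dielectric: float = TITRATION_DIELECTRIC,
) -> TitrationSystem:
    """Titration system of a structure: intrinsic pKas + coupling matrix."""
    p = p or load_param_set("ff_a")
    sites = find_titratable(s, aa_set)
    model = EnergyModel(s, p)
    r_all = model._distances()
    born = model.born_radii(r_all)
    eps_int = dielectric
    tau = 1.0 / eps_int - 1.0 / p.solvent_dielectric
    xyz = model.xyz
    bg_mask = ~_side_chain_mask(model, sites)

    tips = [_tip_index(model, t.chain_id, t.residue_number, t.aa) for t in sites]
    own_residue = _own_residue_mask(model)
    for t, tip in zip(sites, tips):
        q = float(t.ionized_charge)
        b = float(born[tip])
        # model-compound reference: the same residue isolated in solvent
        b_model = _model_compound_born(model.structure, t, p)
        dg_desolv = -0.5 * tau * KE * q * q * (1.0 / b - 1.0 / b_model)
        dg_bg = 0.0
        for j in np.nonzero(bg_mask & (own_residue != own_residue[tip]))[0]:
            qj = float(model.q[j])
            if qj == 0.0:
                continue
            r = float(np.linalg.norm(xyz[tip] - xyz[j]))
            dg_bg += KE * q * qj * _screened_pair(r, b, float(born[j]), eps_int, tau)
        t.intrinsic_pka = t.model_pka + (dg_desolv + dg_bg) / (PK_TO_KCAL * t.sign * -1)

    n = len(sites)
    w = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            r = float(np.linalg.norm(xyz[tips[i]] - xyz[tips[j]]))
            w[i, j] = w[j, i] = (
                KE
                * sites[i].ionized_charge
                * sites[j].ionized_charge
                * _screened_pair(r, float(born[tips[i]]), float(born[tips[j]]), eps_int, tau)
            )
    return TitrationSystem(sites=sites, coupling=w)


def intrinsic_pka(
    site: TitratableSite, s: Structure, p: ForceFieldParams | None = None
) -> float:
    """Intrinsic pKa of one site in a structure (model + desolvation +
    background shifts; no site-site coupling)."""
    sys_ = build_titration_system(s, p)
    for t in sys_.sites:
        if t.key == site.key:
            return t.intrinsic_pka
    raise KeyError(f"site {site.key} not titratable in structure")


def _field_terms(sys_: TitrationSystem, ph: float) -> np.ndarray:
    return np.array(
        [PK_TO_KCAL * t.sign * (ph - t.intrinsic_pka) for t in sys_.sites]
    )


def titration_curve(
    sys_: TitrationSystem,
    ph_grid,
    method: str = "enumerate",
    seed: int | None = None,
    mc_sweeps: int = 100_000,
    burn_in_fraction: float = 0.1,
) -> np.ndarray:
    """Per-site protonation fraction over `ph_grid`.

    Returns an array of shape (len(ph_grid), n_sites).  `enumerate` is exact
    Boltzmann averaging over all 2^n microstates (n <= 20); `monte_carlo`
    runs seeded single-site Metropolis flips, all pH values in parallel.
    """
    ph_grid = np.asarray(ph_grid, dtype=float)
    n = sys_.n
    signs = np.array([t.sign for t in sys_.sites], dtype=float)
    if method == "enumerate":
        if n > 20:
            raise ValueError(
                f"enumeration infeasible for {n} sites; use method='monte_carlo'"
            )
        states = (
            (np.arange(2**n)[:, None] >> np.arange(n)[None, :]) & 1
        ).astype(float)
        pair = 0.5 * np.einsum("si,ij,sj->s", states, sys_.coupling, states)
        out = np.empty((len(ph_grid), n))
        for k, ph in enumerate(ph_grid):
            e = pair + states @ _field_terms(sys_, ph)
            w = np.exp(-(e - e.min()) / KT)
            x_mean = (w @ states) / w.sum()
            out[k] = np.where(signs < 0, 1.0 - x_mean, x_mean)
        return out
    if method != "monte_carlo":
        raise ValueError(f"unknown method {method!r}")
    if seed is None:
        raise ValueError("monte_carlo titration requires a seed")
    rng = np.random.default_rng(seed)
    n_ph = len(ph_grid)
    h = np.stack([_field_terms(sys_, ph) for ph in ph_grid])  # (n_ph, n)
    x = np.zeros((n_ph, n))
    f = np.zeros((n_ph, n))          # coupling field sum_j W_ij x_j
    accum = np.zeros((n_ph, n))
    n_acc = 0
    burn = int(burn_in_fraction * mc_sweeps)
    w = sys_.coupling
    order = rng.integers(0, n, size=(mc_sweeps, n))
    u = rng.random((mc_sweeps, n, n_ph))
    for sweep in range(mc_sweeps):
        for step in range(n):
            i = int(order[sweep, step])
            flip = 1.0 - 2.0 * x[:, i]                 # +1 turn on, -1 turn off
            de = flip * (h[:, i] + f[:, i])
            acc = u[sweep, step] < np.exp(np.minimum(-de / KT, 0.0))
            if acc.any():
                delta = np.where(acc, flip, 0.0)
                x[:, i] += delta
                f += delta[:, None] * w[i][None, :]
        if sweep >= burn:
            accum += x
            n_acc += 1
    x_mean = accum / max(n_acc, 1)
    return np.where(signs[None, :] < 0, 1.0 - x_mean, x_mean)


@dataclass
class PkaResult:
    site: TitratableSite
    pka: float
    flags: list[str] = field(default_factory=list)


DEFAULT_PH_GRID = np.round(np.arange(0.0, 14.0 + 1e-9, 0.1), 10)
SENTINEL_LOW = -1.0
SENTINEL_HIGH = 15.0


def pka_from_curve(ph_grid, fractions) -> tuple[float, list[str]]:
    """pH of the first downward 0.5 crossing, linear interpolation."""
    ph_grid = np.asarray(ph_grid)
    fr = np.asarray(fractions)
    flags: list[str] = []
    if fr[0] < 0.5:
        return SENTINEL_LOW, ["below-range"]
    crossings = np.nonzero((fr[:-1] >= 0.5) & (fr[1:] < 0.5))[0]
    if len(crossings) == 0:
        return SENTINEL_HIGH, ["above-range"]
    if len(crossings) > 1 or np.any(np.diff(fr) > 0.02):
        flags.append("non-monotonic")
    k = crossings[0]
    x0, x1 = ph_grid[k], ph_grid[k + 1]
    y0, y1 = fr[k], fr[k + 1]
    pka = x0 + (0.5 - y0) * (x1 - x0) / (y1 - y0)
    return float(pka), flags


def compute_pkas(
    system,
    p: ForceFieldParams | None = None,
    method: str = "enumerate",
    seed: int | None = None,
    ph_grid=DEFAULT_PH_GRID,
    mc_sweeps: int = 100_000,
) -> list[PkaResult]:
    """Half-protonation pKas of all sites of a structure or TitrationSystem."""
    if isinstance(system, Structure):
        system = build_titration_system(system, p)
    curve = titration_curve(system, ph_grid, method=method, seed=seed,
                            mc_sweeps=mc_sweeps)
    out = []
    for i, site in enumerate(system.sites):
        pka, flags = pka_from_curve(ph_grid, curve[:, i])
        out.append(PkaResult(site=site, pka=pka, flags=flags))
    return out


@dataclass
class PkaShiftReport:
    """Per-site pKa shifts of a mutant relative to wild type and their
    cumulative absolute sum over all paired titratable residues."""

    shifts: dict[tuple[str, int], float]
    sum_abs: float
    n_sites: int
    unpaired: list[tuple[str, int]] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "sum_abs": self.sum_abs,
            "n_sites": self.n_sites,
            "shifts": {f"{c}:{n}": v for (c, n), v in self.shifts.items()},
            "unpaired": [f"{c}:{n}" for c, n in self.unpaired],
        }


def pka_shift_report(
    wt_pkas: list[PkaResult], mut_pkas: list[PkaResult]
) -> PkaShiftReport:
    """Per-site pKa(mut) - pKa(WT) and the cumulative absolute shift.

    Sites present in only one list (e.g. a mutation that adds or removes a
    titratable residue) are excluded from the sum and recorded as unpaired;
    N counts paired sites only.
    """
    wt = {r.site.key: r for r in wt_pkas}
    mut = {r.site.key: r for r in mut_pkas}
    paired = sorted(set(wt) & set(mut))
    if not paired:
        raise ValueError("no overlapping titratable sites between WT and mutant")
    unpaired = sorted(set(wt) ^ set(mut))
    shifts = {k: mut[k].pka - wt[k].pka for k in paired}
    return PkaShiftReport(
        shifts=shifts,
        sum_abs=float(sum(abs(v) for v in shifts.values())),
        n_sites=len(paired),
        unpaired=unpaired,
    )


def ionized_fraction(pka: float, ionized_charge: int, ph: float) -> float:
    """Henderson-Hasselbalch ionized fraction of an acid or base."""
    if ionized_charge < 0:
        return 1.0 / (1.0 + 10.0 ** (pka - ph))
    return 1.0 / (1.0 + 10.0 ** (ph - pka))


@dataclass
class IonizationFlag:
    site_key: tuple[str, int]
    pka_monomer: float
    pka_dimer: float
    fraction_monomer: float
    fraction_dimer: float
    ph: float
    flagged: bool


def flag_ionization_discrepancy(
    monomer_pkas: list[PkaResult],
    dimer_pkas: list[PkaResult],
    site: tuple[str, int],
    ph: float = 7.0,
    threshold: float = 0.5,
) -> IonizationFlag:
    """Flag a site whose ionized fraction differs across monomer/dimer
    contexts by more than `threshold` at the given pH."""
    mono = {r.site.key: r for r in monomer_pkas}
    dim = {r.site.key: r for r in dimer_pkas}
    if site not in mono or site not in dim:
        raise KeyError(f"site {site} missing from monomer or dimer pKa set")
    fm = ionized_fraction(mono[site].pka, mono[site].site.ionized_charge, ph)
    fd = ionized_fraction(dim[site].pka, dim[site].site.ionized_charge, ph)
    return IonizationFlag(
        site_key=site,
        pka_monomer=mono[site].pka,
        pka_dimer=dim[site].pka,
        fraction_monomer=fm,
        fraction_dimer=fd,
        ph=ph,
        flagged=abs(fm - fd) > threshold,
    )
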