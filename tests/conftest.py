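import warnings

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from mutscan.energy import ForceFieldParams, load_param_set
from mutscan.structio import Atom, Chain, Residue, Structure
from mutscan.synthdata import ToySpec, build_toy_dimer

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

warnings.filterwarnings("ignore", category=RuntimeWarning)


@pytest.fixture(scope="session")
def toy_dimer() -> Structure:
    return build_toy_dimer(ToySpec())


@pytest.fixture(scope="session")
def toy_spec() -> ToySpec:
    return ToySpec()


@pytest.fixture(scope="session")
def ffa():
    return load_param_set("ff_a")


def make_ion(name: str, number: int, pos, chain_id: str = "C") -> Residue:
    """Single-atom pseudo-residue for closed-form energy fixtures."""
    r = Residue(number=number, aa=name, is_hetero=True)
    r.atoms.append(Atom(name="Q1", element="C", pos=np.array(pos, dtype=float)))
    return r


def ion_params(
    charges, sigma=0.0, epsilon=0.0, gb_radius=2.0,
    eps_int=1.0, eps_solv=78.5,
) -> ForceFieldParams:
    """Parameter set for `make_ion` fixtures: one atom class per ion name."""
    chg = {}
    cls = {}
    for name, q in charges.items():
        chg[(name, "Q1")] = (q, name)
        cls[name] = (sigma, epsilon, gb_radius)
    return ForceFieldParams(
        name="ions", charges=chg, classes=cls,
        interior_dielectric=eps_int, solvent_dielectric=eps_solv,
    )


def ion_structure(ions: list[tuple[str, list]], chain_id: str = "C") -> Structure:
    """Structure of free single-atom particles (no bonds, no exclusions)."""
    chain = Chain(chain_id)
    for k, (name, pos) in enumerate(ions):
        chain.residues.append(make_ion(name, k + 1, pos, chain_id))
    return Structure([chain])
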