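import numpy as np
import pytest

from vinakit import FixtureSpec, make_toy_pocket, vina_params, vinardo_params
from vinakit.atomtypes import InteractionClass, TypedAtom
from vinakit.pdbqt import parse_pdbqt
from vinakit.synth import make_chain_ligand


@pytest.fixture(scope="session")
def vina():
    return vina_params()


@pytest.fixture(scope="session")
def vinardo():
    return vinardo_params()


@pytest.fixture(scope="session")
def single_pair_pocket():
    """One aromatic-carbon receptor atom + one aromatic-carbon ligand atom."""
    return make_toy_pocket(FixtureSpec(seed=3, n_receptor=1))


@pytest.fixture(scope="session")
def cage_pocket():
    """Six-atom contact cage around a single-atom ligand at the origin."""
    return make_toy_pocket(FixtureSpec(seed=11, n_receptor=6))


@pytest.fixture(scope="session")
def flexible_complex():
    """Six-atom, three-torsion chain ligand in a six-atom pocket."""
    return make_toy_pocket(
        FixtureSpec(seed=5, n_receptor=6, ligand_atoms=6, ligand_torsions=3)
    )


@pytest.fixture(scope="session")
def chain_ligand():
    return parse_pdbqt(make_chain_ligand(6, 3), role="ligand")


def make_atom(
    ad_type: str,
    cls: InteractionClass,
    coords=(0.0, 0.0, 0.0),
    element: str | None = None,
    serial: int = 1,
) -> TypedAtom:
    """Hand-built atom with an explicitly assigned interaction class."""
    elements = {"A": "C", "NA": "N", "OA": "O", "HD": "H", "SA": "S"}
    return TypedAtom(
        serial=serial,
        name=ad_type,
        element=element or elements.get(ad_type, ad_type),
        coords=np.asarray(coords, float),
        partial_charge=0.0,
        ad_type=ad_type,
        interaction_class=cls,
    )
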