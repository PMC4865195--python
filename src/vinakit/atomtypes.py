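"""AutoDock atom typing: elements, interaction classes, bond perception.

The Vina family of scoring functions assigns every heavy atom to one of a
handful of interaction classes that gate the non-steric terms: the
hydrophobic bonus requires both partners to be hydrophobic, and the
non-directional hydrogen-bond bonus requires a donor paired with an
acceptor.  Class membership is a pure function of the AutoDock atom type
plus the atom's covalently bonded neighbors (a carbon is hydrophobic only
if it is bonded to nothing but carbon and hydrogen; an N or O becomes a
donor only if it carries a polar hydrogen).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from enum import Enum

import numpy as np

__all__ = [
    "InteractionClass",
    "TypedAtom",
    "element_of_ad_type",
    "perceive_bonds",
    "assign_interaction_classes",
    "is_donor",
    "is_acceptor",
    "hbond_pair",
    "hydrophobic_pair",
]


class InteractionClass(str, Enum):
    HYDROPHOBIC = "hydrophobic"
    DONOR = "donor"
    ACCEPTOR = "acceptor"
    DONOR_ACCEPTOR = "donor_acceptor"
    POLAR_NONHB = "polar_nonhb"
    HYDROGEN = "hydrogen"
    METAL = "metal"


# AutoDock type token -> chemical element.  Tokens cover the standard
# AutoGrid map set plus the common metals emitted by prepare_receptor4.
_AD_TO_ELEMENT = {
    "C": "C", "A": "C",
    "N": "N", "NA": "N", "NS": "N",
    "O": "O", "OA": "O", "OS": "O",
    "S": "S", "SA": "S",
    "H": "H", "HD": "H", "HS": "H",
    "P": "P", "F": "F", "CL": "Cl", "BR": "Br", "I": "I",
    "ZN": "Zn", "MN": "Mn", "MG": "Mg", "CA": "Ca", "FE": "Fe",
    "NI": "Ni", "CU": "Cu", "CO": "Co", "K": "K", "NA+": "Na", "CD": "Cd",
}

_METALS = {"Zn", "Mn", "Mg", "Ca", "Fe", "Ni", "Cu", "Co", "K", "Na", "Cd", "V"}
_HALOGENS = {"F", "Cl", "Br", "I"}

# Single-bond covalent radii (angstrom) for distance-based bond perception.
_COVALENT_RADIUS = {
    "H": 0.31, "C": 0.76, "N": 0.71, "O": 0.66, "S": 1.05, "P": 1.07,
    "F": 0.57, "Cl": 1.02, "Br": 1.20, "I": 1.39,
}
_COVALENT_DEFAULT = 1.3  # metals and anything exotic

#: Factor applied to the sum of covalent radii when inferring bonds.
BOND_TOLERANCE = 1.2

_ACCEPTOR_TYPES = {"NA", "NS", "OA", "OS", "SA"}


@dataclass(frozen=True)
class TypedAtom:
    """One atom with coordinates, AutoDock type and scoring attributes.

    ``radius`` is the scoring-function radius (parameter-set dependent) and
    is only meaningful for heavy atoms; hydrogens never enter pair sums.
    """

    serial: int
    name: str
    element: str
    coords: np.ndarray  # shape (3,), angstrom
    partial_charge: float
    ad_type: str
    interaction_class: InteractionClass = InteractionClass.POLAR_NONHB
    radius: float = 0.0

    @property
    def is_heavy(self) -> bool:
        return self.element != "H"

    @property
    def is_metal(self) -> bool:
        return self.element in _METALS


def element_of_ad_type(token: str) -> str:
    """Chemical element for an AutoDock type token.

    Vanadium is not supported by the AutoDock preparation tools and is
    conventionally typed as sulfur; the substitution is applied here.
    """
    tok = token.strip()
    if tok.upper() == "V":
        return "S"
    try:
        return _AD_TO_ELEMENT[tok.upper()]
    except KeyError:
        raise ValueError(f"unknown AutoDock atom type token: {token!r}") from None


def normalize_ad_type(token: str) -> str:
    """Canonical AutoDock type; vanadium maps to sulfur (type 'S')."""
    tok = token.strip()
    if tok.upper() == "V":
        return "S"
    if tok.upper() not in _AD_TO_ELEMENT:
        raise ValueError(f"unknown AutoDock atom type token: {token!r}")
    # preserve conventional capitalization (Cl, Br, Zn...)
    elem = _AD_TO_ELEMENT[tok.upper()]
    if tok.upper() in {"CL", "BR", "ZN", "MN", "MG", "FE", "NI", "CU", "CO", "CD"}:
        return elem
    return tok.upper()


def covalent_radius(element: str) -> float:
    return _COVALENT_RADIUS.get(element, _COVALENT_DEFAULT)


def perceive_bonds(atoms: list[TypedAtom]) -> list[set[int]]:
    """Distance-based covalent connectivity.

    Atoms i, j are bonded when their distance is below
    ``BOND_TOLERANCE * (rcov_i + rcov_j)``.  PDBQT carries no explicit
    connectivity for receptors, so this inference is the only source of
    neighbor information.  Returns adjacency as a list of neighbor-index
    sets, parallel to ``atoms``.
    """
    n = len(atoms)
    adj: list[set[int]] = [set() for _ in range(n)]
    if n < 2:
        return adj
    xyz = np.array([a.coords for a in atoms])
    rcov = np.array([covalent_radius(a.element) for a in atoms])
    d = np.linalg.norm(xyz[:, None, :] - xyz[None, :, :], axis=-1)
    thresh = BOND_TOLERANCE * (rcov[:, None] + rcov[None, :])
    ii, jj = np.nonzero((d < thresh) & (d > 1e-6))
    for i, j in zip(ii.tolist(), jj.tolist()):
        if i < j:
            adj[i].add(j)
            adj[j].add(i)
    return adj


def assign_interaction_classes(
    atoms: list[TypedAtom],
    adjacency: list[set[int]] | None = None,
    *,
    fluorine_hydrophobic: bool = True,
) -> list[TypedAtom]:
    """Assign each atom its interaction class from type plus neighbors.

    Rules (heavy atoms):

    * carbon bonded only to carbon/hydrogen -> hydrophobic; carbon bonded
      to any heteroatom -> polar (no hydrophobic bonus);
    * AutoDock acceptor types (NA/NS/OA/OS/SA) -> acceptor;
    * N/O carrying a bonded polar hydrogen (type HD) -> donor, or
      donor_acceptor if also an acceptor type;
    * halogens -> hydrophobic (fluorine configurable);
    * metals -> metal, which pairs as a donor in the H-bond term.

    The assignment is order-independent: it depends only on the multiset of
    bonded-neighbor elements, never on record order.
    """
    if adjacency is None:
        adjacency = perceive_bonds(atoms)
    out: list[TypedAtom] = []
    for i, a in enumerate(atoms):
        if a.element == "H":
            out.append(replace(a, interaction_class=InteractionClass.HYDROGEN))
            continue
        if a.is_metal:
            out.append(replace(a, interaction_class=InteractionClass.METAL))
            continue
        neigh = [atoms[j] for j in adjacency[i]]
        cls: InteractionClass
        if a.element == "C":
            if all(nb.element in ("C", "H") for nb in neigh):
                cls = InteractionClass.HYDROPHOBIC
            else:
                cls = InteractionClass.POLAR_NONHB
        elif a.element in _HALOGENS:
            if a.element == "F" and not fluorine_hydrophobic:
                cls = InteractionClass.POLAR_NONHB
            else:
                cls = InteractionClass.HYDROPHOBIC
        else:
            acceptor = a.ad_type.upper() in _ACCEPTOR_TYPES
            donor = a.element in ("N", "O", "S") and any(
                nb.ad_type.upper() == "HD" for nb in neigh
            )
            if donor and acceptor:
                cls = InteractionClass.DONOR_ACCEPTOR
            elif donor:
                cls = InteractionClass.DONOR
            elif acceptor:
                cls = InteractionClass.ACCEPTOR
            else:
                cls = InteractionClass.POLAR_NONHB
        out.append(replace(a, interaction_class=cls))
    return out


def is_donor(cls: InteractionClass) -> bool:
    return cls in (
        InteractionClass.DONOR,
        InteractionClass.DONOR_ACCEPTOR,
        InteractionClass.METAL,
    )


def is_acceptor(cls: InteractionClass) -> bool:
    return cls in (InteractionClass.ACCEPTOR, InteractionClass.DONOR_ACCEPTOR)


def hbond_pair(a: InteractionClass, b: InteractionClass) -> bool:
    """True when the pair qualifies for the non-directional H-bond term."""
    return (is_donor(a) and is_acceptor(b)) or (is_donor(b) and is_acceptor(a))


def hydrophobic_pair(a: InteractionClass, b: InteractionClass) -> bool:
    return a is InteractionClass.HYDROPHOBIC and b is InteractionClass.HYDROPHOBIC
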