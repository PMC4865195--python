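"""PDBQT reading and writing (AutoDock dialect).

A receptor PDBQT is a flat list of ATOM/HETATM records carrying partial
charges and AutoDock atom types in the two trailing columns.  A ligand
PDBQT additionally encodes a torsion tree: a rigid ROOT fragment and
nested BRANCH blocks, one per rotatable bond, plus a TORSDOF record.
Atoms are parsed, typed (element, interaction class) and given their
scoring radii by a parameter set at scoring time.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import shortest_path
from scipy.spatial import cKDTree

from .atomtypes import (
    InteractionClass,
    TypedAtom,
    assign_interaction_classes,
    element_of_ad_type,
    normalize_ad_type,
    perceive_bonds,
)

__all__ = [
    "PdbqtError",
    "TorsionEdge",
    "LigandModel",
    "ReceptorModel",
    "parse_pdbqt",
    "parse_pdbqt_models",
    "write_poses",
]


class PdbqtError(ValueError):
    """Malformed PDBQT content (names the offending line)."""


@dataclass(frozen=True)
class TorsionEdge:
    """One rotatable bond: axis atom pair and the atoms it moves.

    ``parent``/``child`` are atom indices (0-based, in record order) of the
    bond axis; ``moved`` is the index set of every atom in the child
    subtree, which rotates rigidly about the axis.
    """

    parent: int
    child: int
    moved: tuple[int, ...]


@dataclass
class LigandModel:
    """Ligand atoms plus torsion tree (rigid root + rotatable branches)."""

    atoms: list[TypedAtom]
    fragments: list[tuple[int, ...]]  # atom indices per rigid fragment
    torsion_edges: list[TorsionEdge]  # preorder: parents before children
    torsdof: int | None = None  # TORSDOF record, if present

    @property
    def n_rot(self) -> int:
        """Number of rotatable bonds (BRANCH records)."""
        return len(self.torsion_edges)

    @property
    def coords(self) -> np.ndarray:
        return np.array([a.coords for a in self.atoms])

    @property
    def heavy_indices(self) -> np.ndarray:
        return np.array([i for i, a in enumerate(self.atoms) if a.is_heavy], dtype=int)

    def with_coords(self, xyz: np.ndarray) -> "LigandModel":
        if xyz.shape != (len(self.atoms), 3):
            raise ValueError("coordinate array shape mismatch")
        atoms = [replace(a, coords=np.asarray(c, float)) for a, c in zip(self.atoms, xyz)]
        return LigandModel(atoms, self.fragments, self.torsion_edges, self.torsdof)

    def fragment_of(self) -> np.ndarray:
        """Fragment index per atom."""
        frag = np.empty(len(self.atoms), dtype=int)
        for k, members in enumerate(self.fragments):
            frag[list(members)] = k
        return frag

    def bond_distances(self) -> np.ndarray:
        """All-pairs bond-graph path lengths (inferred connectivity).

        Branch axis bonds are added explicitly in case distance-based
        perception misses a stretched rotatable bond.
        """
        n = len(self.atoms)
        adj = perceive_bonds(self.atoms)
        for e in self.torsion_edges:
            adj[e.parent].add(e.child)
            adj[e.child].add(e.parent)
        rows, cols = [], []
        for i, neigh in enumerate(adj):
            for j in neigh:
                rows.append(i)
                cols.append(j)
        m = csr_matrix((np.ones(len(rows)), (rows, cols)), shape=(n, n))
        return shortest_path(m, method="D", unweighted=True)


@dataclass
class ReceptorModel:
    """Rigid receptor: typed atoms plus a neighbor index for cutoff queries."""

    atoms: list[TypedAtom]
    _tree: cKDTree | None = field(default=None, repr=False, compare=False)
    _heavy: np.ndarray | None = field(default=None, repr=False, compare=False)

    @property
    def coords(self) -> np.ndarray:
        return np.array([a.coords for a in self.atoms])

    @property
    def heavy_indices(self) -> np.ndarray:
        if self._heavy is None:
            self._heavy = np.array(
                [i for i, a in enumerate(self.atoms) if a.is_heavy], dtype=int
            )
        return self._heavy

    def spatial_index(self) -> cKDTree:
        """KD-tree over heavy-atom coordinates, built lazily."""
        if self._tree is None:
            self._tree = cKDTree(self.coords[self.heavy_indices])
        return self._tree

    def atoms_within(self, center: np.ndarray, radius: float) -> np.ndarray:
        """Indices (into ``atoms``) of heavy atoms within ``radius`` of ``center``.

        Exact: the tree query is followed by no approximation, so results
        equal brute-force distance filtering.
        """
        idx = self.spatial_index().query_ball_point(np.asarray(center, float), radius)
        return self.heavy_indices[np.asarray(idx, dtype=int)]


def _parse_atom_line(line: str, lineno: int) -> TypedAtom:
    try:
        serial = int(line[6:11])
        name = line[12:16].strip()
        x = float(line[30:38])
        y = float(line[38:46])
        z = float(line[46:54])
    except ValueError as exc:
        raise PdbqtError(f"line {lineno}: malformed ATOM/HETATM record: {exc}") from None
    tail = line[66:].split()
    if len(tail) < 2:
        raise PdbqtError(f"line {lineno}: missing partial charge / AutoDock type columns")
    try:
        charge = float(tail[-2])
    except ValueError:
        raise PdbqtError(f"line {lineno}: malformed partial charge {tail[-2]!r}") from None
    token = tail[-1]
    try:
        ad_type = normalize_ad_type(token)
        element = element_of_ad_type(token)
    except ValueError as exc:
        raise PdbqtError(f"line {lineno}: {exc}") from None
    return TypedAtom(
        serial=serial,
        name=name,
        element=element,
        coords=np.array([x, y, z]),
        partial_charge=charge,
        ad_type=ad_type,
    )


def parse_pdbqt(path_or_text: str, role: str = "receptor"):
    """Parse PDBQT content into a ReceptorModel or LigandModel.

    ``path_or_text`` may be a filesystem path or the raw text itself
    (anything containing a newline is treated as text).  ``role`` selects
    the dialect: receptors are flat atom lists; ligands require
    ROOT/ENDROOT and may nest BRANCH blocks.
    """
    if role not in ("receptor", "ligand"):
        raise ValueError(f"role must be 'receptor' or 'ligand', got {role!r}")
    text = path_or_text
    if "\n" not in path_or_text:
        with open(path_or_text) as fh:
            text = fh.read()
    lines = text.splitlines()

    atoms: list[TypedAtom] = []
    fragments: list[list[int]] = []
    edges: list[TorsionEdge] = []
    torsdof: int | None = None

    if role == "receptor":
        for lineno, line in enumerate(lines, 1):
            if line.startswith(("ATOM", "HETATM")):
                atoms.append(_parse_atom_line(line, lineno))
        if not atoms:
            raise PdbqtError("no ATOM/HETATM records found")
        atoms = assign_interaction_classes(atoms)
        return ReceptorModel(atoms)

    # --- ligand: walk the torsion-tree records ---
    serial_to_index: dict[int, int] = {}
    # stack entries: (fragment_index, branch_parent_serial, branch_child_serial, lineno)
    stack: list[tuple[int, int | None, int | None, int]] = []
    seen_root = False
    current_frag: int | None = None
    # subtree membership is resolved after parsing from fragment parenthood
    frag_parent: list[int | None] = []
    frag_axis: list[tuple[int, int] | None] = []  # serial pair per fragment

    for lineno, line in enumerate(lines, 1):
        rec = line.split()[0] if line.split() else ""
        if rec == "ROOT":
            if seen_root:
                raise PdbqtError(f"line {lineno}: duplicate ROOT record")
            seen_root = True
            fragments.append([])
            frag_parent.append(None)
            frag_axis.append(None)
            current_frag = 0
        elif rec == "ENDROOT":
            if current_frag != 0:
                raise PdbqtError(f"line {lineno}: ENDROOT outside ROOT block")
            current_frag = None
        elif rec == "BRANCH":
            parts = line.split()
            if len(parts) < 3:
                raise PdbqtError(f"line {lineno}: BRANCH requires two atom serials")
            pa, ch = int(parts[1]), int(parts[2])
            parent_frag = current_frag
            if parent_frag is None:
                # branch opened after parent block closed: parent is the
                # fragment owning the parent-axis atom
                if pa not in serial_to_index:
                    raise PdbqtError(f"line {lineno}: BRANCH parent atom {pa} not yet defined")
                parent_frag = _owning_fragment(fragments, serial_to_index[pa])
            fragments.append([])
            frag_parent.append(parent_frag)
            frag_axis.append((pa, ch))
            stack.append((len(fragments) - 1, pa, ch, lineno))
            current_frag = len(fragments) - 1
        elif rec == "ENDBRANCH":
            if not stack:
                raise PdbqtError(f"line {lineno}: ENDBRANCH without matching BRANCH")
            stack.pop()
            current_frag = stack[-1][0] if stack else None
        elif rec == "TORSDOF":
            torsdof = int(line.split()[1])
        elif line.startswith(("ATOM", "HETATM")):
            if current_frag is None:
                raise PdbqtError(f"line {lineno}: atom record outside ROOT/BRANCH block")
            atom = _parse_atom_line(line, lineno)
            serial_to_index[atom.serial] = len(atoms)
            fragments[current_frag].append(len(atoms))
            atoms.append(atom)

    if not seen_root:
        raise PdbqtError("ligand PDBQT requires a ROOT record")
    if stack:
        raise PdbqtError(f"line {stack[-1][3]}: unclosed BRANCH block")
    if not atoms:
        raise PdbqtError("no ATOM/HETATM records found")

    # resolve torsion edges in fragment order (preorder by construction)
    children: dict[int, list[int]] = {}
    for k, par in enumerate(frag_parent):
        if par is not None:
            children.setdefault(par, []).append(k)

    def subtree_atoms(k: int) -> list[int]:
        out = list(fragments[k])
        for c in children.get(k, []):
            out.extend(subtree_atoms(c))
        return out

    for k in range(1, len(fragments)):
        pa, ch = frag_axis[k]  # type: ignore[misc]
        for serial, label in ((pa, "parent"), (ch, "child")):
            if serial not in serial_to_index:
                raise PdbqtError(f"BRANCH {label} atom serial {serial} not found")
        edges.append(
            TorsionEdge(
                parent=serial_to_index[pa],
                child=serial_to_index[ch],
                moved=tuple(sorted(subtree_atoms(k))),
            )
        )

    atoms = assign_interaction_classes(atoms)
    return LigandModel(
        atoms=atoms,
        fragments=[tuple(f) for f in fragments],
        torsion_edges=edges,
        torsdof=torsdof,
    )


def _owning_fragment(fragments: list[list[int]], atom_index: int) -> int:
    for k, members in enumerate(fragments):
        if atom_index in members:
            return k
    raise PdbqtError(f"atom index {atom_index} belongs to no fragment")


def _format_atom_line(a: TypedAtom, coords: np.ndarray, serial: int) -> str:
    name = a.name if len(a.name) >= 4 else f" {a.name:<3s}"
    return (
        f"ATOM  {serial:5d} {name:<4.4s} LIG A   1    "
        f"{coords[0]:8.3f}{coords[1]:8.3f}{coords[2]:8.3f}"
        f"{1.00:6.2f}{0.00:6.2f}    {a.partial_charge:6.3f} {a.ad_type:<2s}"
    )


def _ligand_records(model: LigandModel, coords: np.ndarray) -> list[str]:
    """Ligand atom records with torsion-tree markup, in fragment structure."""
    lines: list[str] = ["ROOT"]
    for i in model.fragments[0]:
        lines.append(_format_atom_line(model.atoms[i], coords[i], model.atoms[i].serial))
    lines.append("ENDROOT")
    # emit branches in preorder; close in reverse (valid nesting for chains
    # and star topologies alike because children directly follow parents)
    frag_of = model.fragment_of()
    open_stack: list[TorsionEdge] = []

    def close_until(frag_needed: int):
        while open_stack:
            top = open_stack[-1]
            if frag_of[top.child] == frag_needed or frag_needed in [
                frag_of[m] for m in top.moved
            ]:
                break
            e = open_stack.pop()
            lines.append(
                f"ENDBRANCH {model.atoms[e.parent].serial:3d} {model.atoms[e.child].serial:3d}"
            )

    for e in model.torsion_edges:
        close_until(frag_of[e.parent])
        lines.append(
            f"BRANCH {model.atoms[e.parent].serial:3d} {model.atoms[e.child].serial:3d}"
        )
        open_stack.append(e)
        k = frag_of[e.child]
        for i in model.fragments[k]:
            lines.append(_format_atom_line(model.atoms[i], coords[i], model.atoms[i].serial))
    while open_stack:
        e = open_stack.pop()
        lines.append(
            f"ENDBRANCH {model.atoms[e.parent].serial:3d} {model.atoms[e.child].serial:3d}"
        )
    lines.append(f"TORSDOF {model.torsdof if model.torsdof is not None else model.n_rot}")
    return lines


def write_poses(
    model: LigandModel,
    poses: list[np.ndarray],
    scores: list[float] | None = None,
) -> str:
    """Multi-model ligand PDBQT text, one MODEL block per pose.

    Poses are written in the given (score) order; each block carries the
    predicted affinity as a REMARK line.  Round-trips through
    :func:`parse_pdbqt` to 3-decimal coordinate precision.
    """
    if not poses:
        raise ValueError("empty pose list")
    if scores is not None and len(scores) != len(poses):
        raise ValueError("pose/score count mismatch")
    blocks: list[str] = []
    for k, pose in enumerate(poses):
        pose = np.asarray(pose, float)
        if pose.shape != (len(model.atoms), 3):
            raise ValueError(
                f"pose {k}: expected {len(model.atoms)} coordinate triples, got {pose.shape}"
            )
        blocks.append(f"MODEL {k + 1}")
        if scores is not None:
            blocks.append(f"REMARK VINAKIT RESULT: {scores[k]:10.4f}")
        blocks.extend(_ligand_records(model, pose))
        blocks.append("ENDMDL")
    return "\n".join(blocks) + "\n"


def parse_pdbqt_models(text_or_path: str) -> list[LigandModel]:
    """Parse a multi-model ligand PDBQT into one LigandModel per MODEL."""
    text = text_or_path
    if "\n" not in text_or_path:
        with open(text_or_path) as fh:
            text = fh.read()
    models: list[LigandModel] = []
    current: list[str] = []
    in_model = False
    for line in text.splitlines():
        if line.startswith("MODEL"):
            in_model = True
            current = []
        elif line.startswith("ENDMDL"):
            models.append(parse_pdbqt("\n".join(current) + "\n", role="ligand"))
            in_model = False
        elif in_model:
            current.append(line)
    if not models and text.strip():
        models.append(parse_pdbqt(text, role="ligand"))
    return models
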