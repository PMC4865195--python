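"""Deterministic synthetic fixtures: pockets, decoy poses, screening tables.

Every generator is a pure function of its spec and seed, so the whole
test surface runs without external structure files.  Receptors are small
shells of atoms around a binding site; ligands use idealized geometry
(1.5 A bonds, tetrahedral angles) - plausible, not chemically exact.
Pockets are built so the global minimum pose is known analytically: every
receptor atom sits exactly at contact distance (surface distance d = 0)
from the ligand's crystal position, which for a single-minimum function
makes the crystal pose the global optimum by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .minimize import PoseDOF, apply_dof
from .params import TermParameterSet, vinardo_params
from .pdbqt import LigandModel, ReceptorModel, parse_pdbqt
from .rmsd import hungarian_rmsd

__all__ = [
    "FixtureSpec",
    "make_toy_pocket",
    "make_chain_ligand",
    "make_pose_decoys",
    "make_screening_table",
]


@dataclass
class FixtureSpec:
    """Parameters of the synthetic study system.

    Pocket: ``n_receptor`` atoms on a shell at contact distance around the
    ligand, full sphere or one hemisphere (an asymmetric pocket).  Ligand:
    a carbon chain with ``ligand_atoms`` atoms and ``ligand_torsions``
    rotatable bonds.  Screening: actives and decoys drawn from two normal
    score distributions separated by ``separation`` (0 = the random-
    selection null).
    """

    seed: int = 0
    n_receptor: int = 6
    receptor_type: str = "A"
    ligand_type: str = "A"
    ligand_atoms: int = 1
    ligand_torsions: int = 0
    hemisphere: bool = False
    n_shell2: int = 0  # second-shell receptor atoms (outside contact)
    shell2_offset: float = 1.5  # surface distance of the second shell, A
    n_active: int = 100
    n_decoy: int = 2000
    separation: float = 0.0


def _atom_line(serial: int, name: str, xyz, charge: float, ad_type: str) -> str:
    pname = name if len(name) >= 4 else f" {name:<3s}"
    return (
        f"ATOM  {serial:5d} {pname:<4.4s} LIG A   1    "
        f"{xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}{1.00:6.2f}{0.00:6.2f}"
        f"    {charge:6.3f} {ad_type:<2s}"
    )


def _unit_vectors(n: int, rng: np.random.Generator, hemisphere: bool) -> np.ndarray:
    """Well-spread random unit vectors (minimum pairwise angle enforced)."""
    dirs: list[np.ndarray] = []
    max_dot, attempts = 0.85, 0
    while len(dirs) < n:
        attempts += 1
        if attempts % 2000 == 0:  # relax spacing if the cap is infeasible
            max_dot = min(max_dot + 0.05, 0.999)
        v = rng.normal(size=3)
        v /= np.linalg.norm(v)
        if hemisphere and v[2] < 0.25:
            continue
        if any(float(v @ u) > max_dot for u in dirs):
            continue
        dirs.append(v)
    return np.array(dirs)


def make_toy_pocket(
    spec: FixtureSpec, params: TermParameterSet | None = None
) -> tuple[ReceptorModel, LigandModel, dict]:
    """Receptor shell + single-site ligand with a known optimum.

    Receptor atoms are placed at exactly ``Ri + Rj`` (contact, d = 0) from
    the origin; the ligand's crystal pose puts its anchor atom at the
    origin.  For a single-minimum parameterization every pair sits at its
    pairwise optimum there, so the crystal pose is the global minimum.
    Returns (receptor, ligand, info) where info carries the optimum
    position and contact distance.  Identical spec + seed give identical
    models (byte-identical PDBQT text).
    """
    params = params or vinardo_params()
    rng = np.random.default_rng(spec.seed)
    ri = params.radius_of(spec.ligand_type, "C")
    rj = params.radius_of(spec.receptor_type, "C")
    contact = ri + rj
    dirs = _unit_vectors(spec.n_receptor + spec.n_shell2, rng, spec.hemisphere)
    radii_by_shell = [contact] * spec.n_receptor + [
        contact + spec.shell2_offset
    ] * spec.n_shell2
    rec_lines = [
        _atom_line(i + 1, f"C{i + 1}", rho * v, 0.0, spec.receptor_type)
        for i, (v, rho) in enumerate(zip(dirs, radii_by_shell))
    ]
    receptor = parse_pdbqt("\n".join(rec_lines) + "\n", role="receptor")
    if spec.ligand_atoms == 1:
        lig_text = "\n".join(
            ["ROOT", _atom_line(1, "C1", np.zeros(3), 0.0, spec.ligand_type), "ENDROOT", "TORSDOF 0"]
        ) + "\n"
    else:
        lig_text = make_chain_ligand(
            spec.ligand_atoms, spec.ligand_torsions, ad_type=spec.ligand_type
        )
    ligand = parse_pdbqt(lig_text, role="ligand")
    info = {
        "optimum": np.zeros(3),
        "contact_distance": contact,
        "receptor_directions": dirs,
    }
    return receptor, ligand, info


def make_chain_ligand(n_atoms: int, n_torsions: int, ad_type: str = "C") -> str:
    """PDBQT text for an idealized zigzag carbon chain.

    Bond length 1.5 A, tetrahedral angles, the first atom at the origin.
    The last ``n_torsions`` bonds are declared rotatable as nested BRANCH
    blocks; ``n_torsions`` must leave at least two atoms in the root.
    """
    if n_atoms < 2:
        raise ValueError("chain needs at least 2 atoms")
    if n_torsions < 0 or (n_torsions > 0 and n_torsions > n_atoms - 3):
        # each rotatable bond must move at least one off-axis atom, so the
        # terminal branch keeps two atoms and the root keeps two
        raise ValueError("torsion count must be <= n_atoms - 3")
    # zigzag in the xz plane: bond 1.5 A, angle 109.47 deg
    step, half_angle = 1.5, np.deg2rad(180.0 - 109.47) / 2.0
    xyz = np.zeros((n_atoms, 3))
    for i in range(1, n_atoms):
        direction = np.array(
            [np.cos(half_angle), 0.0, np.sin(half_angle) * (-1) ** i]
        )
        xyz[i] = xyz[i - 1] + step * direction
    n_root = n_atoms - 1 - n_torsions if n_torsions else n_atoms
    lines = ["ROOT"]
    for i in range(n_root):
        lines.append(_atom_line(i + 1, f"C{i + 1}", xyz[i], 0.0, ad_type))
    lines.append("ENDROOT")
    for i in range(n_root, n_atoms - 1):
        lines.append(f"BRANCH {i:3d} {i + 1:3d}")
        lines.append(_atom_line(i + 1, f"C{i + 1}", xyz[i], 0.0, ad_type))
        if i == n_atoms - 2:  # terminal branch carries the last two atoms
            lines.append(_atom_line(i + 2, f"C{i + 2}", xyz[i + 1], 0.0, ad_type))
    for i in range(n_atoms - 1, n_root, -1):
        lines.append(f"ENDBRANCH {i - 1:3d} {i:3d}")
    lines.append(f"TORSDOF {n_torsions}")
    return "\n".join(lines) + "\n"


def make_pose_decoys(
    ligand: LigandModel,
    n: int,
    rmsd_bins: list[tuple[float, float]],
    seed: int,
    max_attempts: int = 2000,
) -> tuple[list[np.ndarray], list[float]]:
    """Seeded decoy pose set with exact RMSD annotations.

    Poses are generated by rigid perturbation (translation targeted at the
    bin midpoint plus a small rotation) and torsion jitter, then
    rejection-sampled so every requested RMSD bin is populated; the ``n``
    poses are assigned to bins round-robin.  Annotated RMSDs are the
    symmetry-corrected values against the input pose.  A bin that cannot
    be reached raises a diagnostic error.
    """
    if n < 1:
        raise ValueError("need at least one pose")
    rng = np.random.default_rng(seed)
    poses: list[np.ndarray] = []
    rmsds: list[float] = []
    crystal = ligand.coords
    for k in range(n):
        lo, hi = rmsd_bins[k % len(rmsd_bins)]
        if lo <= 0.0 and not poses:
            poses.append(crystal.copy())
            rmsds.append(0.0)
            continue
        mid = 0.5 * (lo + hi)
        for attempt in range(max_attempts):
            direction = rng.normal(size=3)
            direction /= np.linalg.norm(direction)
            shift = direction * rng.uniform(max(lo, 0.05), max(hi, 0.1))
            rotvec = rng.normal(size=3) * (0.05 + 0.1 * mid)
            torsions = rng.normal(size=ligand.n_rot) * (0.05 + 0.2 * mid)
            quat = np.concatenate([
                np.sin(np.linalg.norm(rotvec) / 2.0)
                * rotvec
                / max(np.linalg.norm(rotvec), 1e-12),
                [np.cos(np.linalg.norm(rotvec) / 2.0)],
            ])
            xyz = apply_dof(ligand, PoseDOF(shift, quat, torsions))
            r = hungarian_rmsd(ligand, ligand, probe_coords=xyz).rmsd
            if lo <= r < hi:
                poses.append(xyz)
                rmsds.append(r)
                break
        else:
            raise ValueError(
                f"could not generate a pose in RMSD bin [{lo}, {hi}) "
                f"after {max_attempts} attempts (ligand too small?)"
            )
    return poses, rmsds


def make_screening_table(
    n_active: int,
    n_decoy: int,
    separation: float,
    seed: int,
    protein_id: str = "P1",
) -> pd.DataFrame:
    """Labeled active/decoy score table.

    Decoy scores are N(-6, 1); active scores are N(-6 - separation, 1)
    (more negative = better).  ``separation = 0`` gives the
    label-independent random-ranking null; large separation drives the
    AUC toward 1.  Deterministic per seed.
    """
    if n_active < 1 or n_decoy < 1:
        raise ValueError("need at least one active and one decoy")
    rng = np.random.default_rng(seed)
    scores = np.concatenate(
        [rng.normal(-6.0 - separation, 1.0, n_active), rng.normal(-6.0, 1.0, n_decoy)]
    )
    labels = ["active"] * n_active + ["decoy"] * n_decoy
    order = rng.permutation(n_active + n_decoy)
    return pd.DataFrame(
        {
            "complex_id": [f"cmp{i + 1}" for i in range(n_active + n_decoy)],
            "protein_id": protein_id,
            "predicted": scores[order],
            "experimental": np.nan,
            "label": np.array(labels)[order],
            "pose_rmsd": np.nan,
        }
    )
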