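"""Symmetry-corrected RMSD via optimal within-type atom assignment.

Chemically equivalent atoms (the two oxygens of a carboxylate, symmetric
ring atoms) can be recorded in either order, so the naive
index-by-index RMSD between two conformations of the same molecule can be
badly inflated.  The corrected value minimizes the root-mean-square
deviation over all assignments that pair atoms of identical element and
AutoDock type, solved exactly per type block with the Hungarian
algorithm.  Poses are compared in a common (receptor) frame: no
superposition is performed, as in re-docking evaluation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import linear_sum_assignment

from .atomtypes import TypedAtom
from .pdbqt import LigandModel

__all__ = ["RmsdResult", "hungarian_rmsd", "docking_success"]


@dataclass
class RmsdResult:
    rmsd: float  # angstrom, symmetry-corrected
    mapping: np.ndarray  # probe index assigned to each ref index
    naive_rmsd: float  # identity mapping


def _heavy_key_blocks(atoms: list[TypedAtom]) -> dict[tuple[str, str], list[int]]:
    blocks: dict[tuple[str, str], list[int]] = {}
    for i, a in enumerate(atoms):
        if a.is_heavy:
            blocks.setdefault((a.element, a.ad_type), []).append(i)
    return blocks


def hungarian_rmsd(
    ref: LigandModel | list[TypedAtom],
    probe: LigandModel | list[TypedAtom],
    ref_coords: np.ndarray | None = None,
    probe_coords: np.ndarray | None = None,
) -> RmsdResult:
    """Symmetry-corrected heavy-atom RMSD between two conformations.

    ``ref``/``probe`` must carry the same multiset of (element, AutoDock
    type); hydrogens are excluded.  The cost matrix within each type block
    is the squared interatomic distance; the optimal assignment per block
    minimizes the overall RMSD because blocks are disjoint.
    """
    ref_atoms = ref.atoms if isinstance(ref, LigandModel) else ref
    probe_atoms = probe.atoms if isinstance(probe, LigandModel) else probe
    rxyz = (
        np.asarray(ref_coords, float)
        if ref_coords is not None
        else np.array([a.coords for a in ref_atoms])
    )
    pxyz = (
        np.asarray(probe_coords, float)
        if probe_coords is not None
        else np.array([a.coords for a in probe_atoms])
    )
    rblocks = _heavy_key_blocks(ref_atoms)
    pblocks = _heavy_key_blocks(probe_atoms)
    if {k: len(v) for k, v in rblocks.items()} != {k: len(v) for k, v in pblocks.items()}:
        raise ValueError("atom type multisets differ between ref and probe")

    n_heavy = sum(len(v) for v in rblocks.values())
    mapping = -np.ones(len(ref_atoms), dtype=int)
    sq_total = 0.0
    naive_sq = 0.0
    for key, ridx in rblocks.items():
        pidx = pblocks[key]
        cost = (
            ((rxyz[ridx][:, None, :] - pxyz[pidx][None, :, :]) ** 2).sum(axis=-1)
        )
        rows, cols = linear_sum_assignment(cost)
        sq_total += float(cost[rows, cols].sum())
        for a, b in zip(rows, cols):
            mapping[ridx[a]] = pidx[b]
        naive_sq += float(
            ((rxyz[ridx] - pxyz[ridx]) ** 2).sum()
        )
    return RmsdResult(
        rmsd=float(np.sqrt(sq_total / n_heavy)),
        mapping=mapping,
        naive_rmsd=float(np.sqrt(naive_sq / n_heavy)),
    )


def docking_success(rmsd: float, threshold: float = 2.0) -> bool:
    """Re-docking success: RMSD equal to, or less than, the threshold."""
    if rmsd < 0:
        raise ValueError("RMSD must be non-negative")
    return rmsd <= threshold
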