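"""Ligand pose minimization over rigid-body and torsional degrees of freedom.

A pose is parameterized by a rigid translation, a unit-quaternion
orientation, and one dihedral angle per rotatable bond
(:class:`PoseDOF`).  Torsions are applied first (rotating each branch
subtree about its bond axis, root outward), then the whole ligand is
rotated about the centroid of its input conformation and translated.

The objective is the intermolecular plus intramolecular energy of the
posed ligand.  Gradients are analytic: per-pair de/dr is chained into
per-atom Cartesian gradients, which project onto the translation (sum),
the orientation tangent space (torque about the rotation center) and each
torsion (torque component along the bond axis).  The potential is only
piecewise-smooth (the repulsion, hydrophobic and H-bond terms have
kinks), so the optimizer is L-BFGS-B - its backtracking line search only
needs sufficient decrease, never curvature across a joint.  The
orientation chart (rotation vector composed onto the current quaternion)
is re-centered between L-BFGS rounds to stay away from the chart
singularity at angle pi.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize as _scipy_minimize
from scipy.spatial.transform import Rotation

from .atomtypes import hbond_pair, hydrophobic_pair
from .params import TermParameterSet
from .pdbqt import LigandModel, ReceptorModel
from .scoring import ScoreBreakdown, intermolecular_energy, intra_pairs, predicted_affinity

__all__ = [
    "PoseDOF",
    "apply_dof",
    "energy_and_gradient",
    "local_minimize",
    "random_restart_search",
    "PoseResult",
]


@dataclass
class PoseDOF:
    """Minimization variable: translation, orientation, torsion angles."""

    translation: np.ndarray  # (3,) angstrom
    orientation: np.ndarray  # unit quaternion, scipy (x, y, z, w) convention
    torsions: np.ndarray  # (n_rot,) radians

    def __post_init__(self):
        self.translation = np.asarray(self.translation, float).reshape(3)
        q = np.asarray(self.orientation, float).reshape(4)
        self.orientation = q / np.linalg.norm(q)
        self.torsions = np.atleast_1d(np.asarray(self.torsions, float))

    @classmethod
    def identity(cls, n_rot: int = 0) -> "PoseDOF":
        return cls(np.zeros(3), np.array([0.0, 0.0, 0.0, 1.0]), np.zeros(n_rot))

    def perturbed(self, delta: np.ndarray) -> "PoseDOF":
        """Compose a flat increment [dt(3), rotvec(3), dtorsions] onto this DOF."""
        delta = np.asarray(delta, float)
        q = (Rotation.from_rotvec(delta[3:6]) * Rotation.from_quat(self.orientation)).as_quat()
        return PoseDOF(self.translation + delta[:3], q, self.torsions + delta[6:])


def _rotation_center(model: LigandModel) -> np.ndarray:
    return model.coords.mean(axis=0)


def apply_dof(model: LigandModel, dof: PoseDOF) -> np.ndarray:
    """Coordinates of the ligand posed by ``dof``.

    Rigid fragments move rigidly; each torsion rotates exactly its
    moved-atom set about the (current) branch axis; the zero DOF vector
    reproduces the input coordinates exactly.
    """
    if len(dof.torsions) != model.n_rot:
        raise ValueError(
            f"torsion count mismatch: DOF has {len(dof.torsions)}, model has {model.n_rot}"
        )
    xyz = model.coords.copy()
    for angle, edge in zip(dof.torsions, model.torsion_edges):
        axis = xyz[edge.child] - xyz[edge.parent]
        norm = np.linalg.norm(axis)
        if norm < 1e-12:
            continue
        rot = Rotation.from_rotvec(axis / norm * angle)
        moved = list(edge.moved)
        pivot = xyz[edge.child].copy()
        xyz[moved] = rot.apply(xyz[moved] - pivot) + pivot
    center = _rotation_center(model)
    rot = Rotation.from_quat(dof.orientation)
    return rot.apply(xyz - center) + center + dof.translation


# --- vectorized energy/gradient over precomputed pair tables ---

@dataclass
class _PairTable:
    i: np.ndarray  # ligand atom index
    j: np.ndarray  # partner atom index (receptor, or ligand for intra)
    rsum: np.ndarray  # Ri + Rj
    hydro: np.ndarray  # bool mask
    hb: np.ndarray  # bool mask


@dataclass
class _EnergyModel:
    """Precomputed pair metadata for fast repeated evaluation of one complex."""

    model: LigandModel
    receptor: ReceptorModel
    params: TermParameterSet
    inter: _PairTable = field(init=False)
    intra: _PairTable = field(init=False)
    rec_xyz: np.ndarray = field(init=False)

    def __post_init__(self):
        p = self.params
        lig, rec = self.model, self.receptor
        self.rec_xyz = rec.coords
        lh = lig.heavy_indices
        rh = rec.heavy_indices
        li, rj = np.meshgrid(lh, rh, indexing="ij")
        self.inter = self._table(lig, rec, li.ravel(), rj.ravel())
        ip = intra_pairs(lig)
        if ip:
            ii, jj = np.array(ip, dtype=int).T
        else:
            ii = jj = np.zeros(0, dtype=int)
        self.intra = self._table(lig, lig, ii, jj)

    def _table(self, a_model, b_model, ii, jj) -> _PairTable:
        p = self.params
        radius = lambda atom: p.radius_of(atom.ad_type, atom.element)
        rsum = np.array(
            [radius(a_model.atoms[i]) + radius(b_model.atoms[j]) for i, j in zip(ii, jj)]
        )
        hydro = np.array(
            [
                hydrophobic_pair(
                    a_model.atoms[i].interaction_class, b_model.atoms[j].interaction_class
                )
                for i, j in zip(ii, jj)
            ],
            dtype=bool,
        )
        hb = np.array(
            [
                hbond_pair(
                    a_model.atoms[i].interaction_class, b_model.atoms[j].interaction_class
                )
                for i, j in zip(ii, jj)
            ],
            dtype=bool,
        )
        return _PairTable(np.asarray(ii), np.asarray(jj), rsum, hydro, hb)

    def _eval_table(self, t: _PairTable, xa: np.ndarray, xb: np.ndarray, grad_b: bool):
        """Energy and per-atom gradient contributions for one pair table."""
        p = self.params
        if t.i.size == 0:
            return 0.0, np.zeros((len(self.model.atoms), 3))
        dx = xa[t.i] - xb[t.j]
        r = np.linalg.norm(dx, axis=1)
        r = np.maximum(r, 1e-12)
        d = r - t.rsum
        live = d < p.cutoff
        z1 = (d - p.o1) / p.s1
        g1 = np.exp(-(z1 * z1))
        e = p.w1 * g1
        de = p.w1 * (-2.0 * z1 / p.s1) * g1
        if p.gauss2_enabled:
            z2 = (d - p.o2) / p.s2
            g2 = np.exp(-(z2 * z2))
            e = e + p.w2 * g2
            de = de + p.w2 * (-2.0 * z2 / p.s2) * g2
        rep = d <= 0.0
        e = e + p.w3 * np.where(rep, d * d, 0.0)
        de = de + p.w3 * np.where(rep, 2.0 * d, 0.0)
        if t.hydro.any():
            hv = np.clip((p.p2 - d) / (p.p2 - p.p1), 0.0, 1.0)
            hd = np.where((d > p.p1) & (d < p.p2), -1.0 / (p.p2 - p.p1), 0.0)
            e = e + p.w4 * t.hydro * hv
            de = de + p.w4 * t.hydro * hd
        if t.hb.any():
            bv = np.clip(d / p.h1, 0.0, 1.0)
            bd = np.where((d > p.h1) & (d < 0.0), 1.0 / p.h1, 0.0)
            e = e + p.w5 * t.hb * bv
            de = de + p.w5 * t.hb * bd
        if p.lj_weight != 0.0:
            q = t.rsum / r
            m, n = p.lj_m, p.lj_n
            e = e + p.lj_weight / (n - m) * (m * q**n - n * q**m)
            de = de + p.lj_weight / (n - m) * (n * m * (q**m - q**n)) / r
        e = np.where(live, e, 0.0)
        de = np.where(live, de, 0.0)
        grad = np.zeros((len(self.model.atoms), 3))
        gvec = (de / r)[:, None] * dx
        np.add.at(grad, t.i, gvec)
        if grad_b:  # intra: partner atoms feel the opposite force
            np.add.at(grad, t.j, -gvec)
        return float(e.sum()), grad

    def energy_and_atom_grad(self, lig_xyz: np.ndarray) -> tuple[float, np.ndarray]:
        e1, g1 = self._eval_table(self.inter, lig_xyz, self.rec_xyz, grad_b=False)
        e2, g2 = self._eval_table(self.intra, lig_xyz, lig_xyz, grad_b=True)
        return e1 + e2, g1 + g2


def _dof_gradient(
    model: LigandModel, dof: PoseDOF, lig_xyz: np.ndarray, atom_grad: np.ndarray
) -> np.ndarray:
    """Project Cartesian atom gradients onto the DOF tangent space."""
    center = _rotation_center(model) + dof.translation
    g_trans = atom_grad.sum(axis=0)
    g_rot = np.cross(lig_xyz - center, atom_grad).sum(axis=0)
    g_tors = np.zeros(model.n_rot)
    for k, edge in enumerate(model.torsion_edges):
        axis = lig_xyz[edge.child] - lig_xyz[edge.parent]
        norm = np.linalg.norm(axis)
        if norm < 1e-12:
            continue
        u = axis / norm
        moved = list(edge.moved)
        torque = np.cross(lig_xyz[moved] - lig_xyz[edge.child], atom_grad[moved]).sum(axis=0)
        g_tors[k] = float(u @ torque)
    return np.concatenate([g_trans, g_rot, g_tors])


def energy_and_gradient(
    model: LigandModel,
    receptor: ReceptorModel,
    dof: PoseDOF,
    params: TermParameterSet,
    _cache: _EnergyModel | None = None,
) -> tuple[float, np.ndarray]:
    """Total energy (inter + intra) and its gradient over the DOF.

    The gradient is taken in the chart centered at ``dof``: components are
    [translation (3), orientation tangent / rotation-vector increment (3),
    torsions (n_rot)], i.e. the directional derivatives of the energy
    under ``dof.perturbed(delta)`` at ``delta = 0``.
    """
    em = _cache or _EnergyModel(model, receptor, params)
    xyz = apply_dof(model, dof)
    e, atom_grad = em.energy_and_atom_grad(xyz)
    return e, _dof_gradient(model, dof, xyz, atom_grad)


def _skew(w: np.ndarray) -> np.ndarray:
    return np.array([[0, -w[2], w[1]], [w[2], 0, -w[0]], [-w[1], w[0], 0]])


def _so3_left_jacobian(w: np.ndarray) -> np.ndarray:
    """J_l with exp((w + dw)^) ~ exp((J_l dw)^) exp(w^)."""
    phi = np.linalg.norm(w)
    K = _skew(w)
    if phi < 1e-6:
        return np.eye(3) + 0.5 * K + K @ K / 6.0
    return (
        np.eye(3)
        + (1.0 - np.cos(phi)) / phi**2 * K
        + (phi - np.sin(phi)) / phi**3 * (K @ K)
    )


def local_minimize(
    model: LigandModel,
    receptor: ReceptorModel,
    start: PoseDOF,
    params: TermParameterSet,
    tol: float = 1e-6,
    max_iter: int = 10000,
) -> tuple[PoseDOF, ScoreBreakdown, list[float]]:
    """Quasi-Newton local minimization from ``start``.

    Runs L-BFGS-B in the chart around the current pose, re-centers the
    orientation chart between rounds, and terminates on the
    gradient-norm tolerance or the iteration budget.  Returns the final
    DOF, the intermolecular breakdown at the final pose, and the
    trajectory of accepted energies (monotone non-increasing).
    Deterministic given identical inputs.
    """
    em = _EnergyModel(model, receptor, params)
    n_rot = model.n_rot
    current = start
    if not np.isfinite(apply_dof(model, current)).all():
        raise ValueError("non-finite coordinates at the starting pose")
    e0, _ = energy_and_gradient(model, receptor, current, params, _cache=em)
    if not np.isfinite(e0):
        raise ValueError("non-finite energy at the starting pose")
    trajectory = [e0]
    best_e = e0
    iters_left = max_iter
    for _round in range(40):
        base_q = Rotation.from_quat(current.orientation)
        base_t = current.translation
        base_phi = current.torsions

        def fun(z):
            dof = PoseDOF(base_t + z[:3], (Rotation.from_rotvec(z[3:6]) * base_q).as_quat(), base_phi + z[6:])
            xyz = apply_dof(model, dof)
            e, atom_grad = em.energy_and_atom_grad(xyz)
            g = _dof_gradient(model, dof, xyz, atom_grad)
            g[3:6] = _so3_left_jacobian(z[3:6]).T @ g[3:6]
            return e, g

        res = _scipy_minimize(
            fun,
            np.zeros(6 + n_rot),
            jac=True,
            method="L-BFGS-B",
            options={"maxiter": min(iters_left, 200), "gtol": tol, "ftol": 1e-12},
        )
        iters_left -= max(res.nit, 1)
        candidate = PoseDOF(
            base_t + res.x[:3],
            (Rotation.from_rotvec(res.x[3:6]) * base_q).as_quat(),
            base_phi + res.x[6:],
        )
        if res.fun <= best_e + 1e-15:
            if res.fun < best_e - 1e-15:
                trajectory.append(float(res.fun))
            current = candidate
            best_e = min(best_e, float(res.fun))
        grad_norm = float(np.linalg.norm(res.jac))
        if grad_norm <= tol or iters_left <= 0:
            break
        if res.fun >= trajectory[-1] - 1e-12 and np.linalg.norm(res.x) < 1e-10:
            break
    final_xyz = apply_dof(model, current)
    breakdown = intermolecular_energy(model, receptor, params, ligand_coords=final_xyz)
    return current, breakdown, trajectory


@dataclass
class PoseResult:
    """One ranked pose from a restart search."""

    dof: PoseDOF
    coords: np.ndarray
    breakdown: ScoreBreakdown
    affinity: float


def random_restart_search(
    model: LigandModel,
    receptor: ReceptorModel,
    n_starts: int,
    seed: int,
    params: TermParameterSet,
    box: tuple[np.ndarray, np.ndarray] | None = None,
    tol: float = 1e-6,
    max_iter: int = 2000,
) -> list[PoseResult]:
    """Random-restart local search: a desk-scale stand-in for docking.

    Samples ``n_starts`` starting poses uniformly (ligand centroid in the
    box, orientation uniform on the rotation group, torsions uniform in
    (-pi, pi]), minimizes each, and returns poses sorted by predicted
    affinity (best first).  Reproducible given ``seed``.
    """
    if n_starts < 1:
        raise ValueError("n_starts must be >= 1")
    if box is None:
        rec_xyz = receptor.coords
        lo, hi = rec_xyz.min(axis=0), rec_xyz.max(axis=0)
        box = (0.5 * (lo + hi), hi - lo + 2.0)
    center, size = (np.asarray(box[0], float), np.asarray(box[1], float))
    if np.any(size <= 0):
        raise ValueError("empty search box")
    rng = np.random.default_rng(seed)
    lig_centroid = _rotation_center(model)
    results = []
    for _ in range(n_starts):
        target = center + (rng.random(3) - 0.5) * size
        quat = rng.normal(size=4)
        quat /= np.linalg.norm(quat)
        torsions = rng.uniform(-np.pi, np.pi, size=model.n_rot)
        start = PoseDOF(target - lig_centroid, quat, torsions)
        dof, breakdown, _ = local_minimize(model, receptor, start, params, tol=tol, max_iter=max_iter)
        affinity = predicted_affinity(breakdown.total, model.n_rot, params)
        results.append(PoseResult(dof, apply_dof(model, dof), breakdown, affinity))
    results.sort(key=lambda p: p.affinity)
    return results
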