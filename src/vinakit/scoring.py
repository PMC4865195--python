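"""Vina-family pairwise scoring terms and energy sums.

The predicted binding energy is a sum over heavy-atom pairs of a
distance-dependent pair potential evaluated on the *surface distance*

    d = r - Ri - Rj,

the interatomic distance minus the two scoring radii.  Each pair feels a
steric interaction (one or two attractive Gaussians plus a quadratic
overlap repulsion); hydrophobic pairs additionally feel a piecewise-linear
hydrophobic bonus, and donor-acceptor pairs a piecewise-linear
non-directional hydrogen-bond bonus:

    e(d) = w1*Gauss1(d) + w2*Gauss2(d) + w3*Repulsion(d)
         + w4*Hydrophobic(d) + w5*HBond(d)

The piecewise-linear terms are implemented in their *normalized* form
(value 1 at the onset, 0 at the offset, linear in between) so the
potential is continuous for every parameterization - with the Vina
parameters (p2 - p1 = 1) the normalized hydrophobic term coincides with
the unnormalized one.

The Vinardo parameterization disables the second Gaussian, which removes
the long-range steric minimum: its steric profile has a single minimum at
d = 0 (atoms in contact), whereas Vina's has a second, outer minimum 3 A
beyond contact (6.8 A between two aromatic carbons).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .atomtypes import TypedAtom, hbond_pair, hydrophobic_pair
from .params import TermParameterSet
from .pdbqt import LigandModel, ReceptorModel

__all__ = [
    "surface_distance",
    "gauss_term",
    "repulsion_term",
    "hydrophobic_term",
    "hbond_term",
    "lj_mn_term",
    "pair_energy",
    "steric_profile",
    "ScoreBreakdown",
    "intermolecular_energy",
    "intramolecular_energy",
    "predicted_affinity",
    "term_contributions",
]

TERM_NAMES = ("gauss1", "gauss2", "repulsion", "hydrophobic", "hbond", "lj")


# --- elementary terms (all vectorized in d) ---

def surface_distance(r, ri, rj):
    """Surface distance d = r - Ri - Rj (negative when shells overlap)."""
    return np.asarray(r) - ri - rj


def gauss_term(d, o, s):
    """Attractive Gaussian exp(-((d-o)/s)^2), maximum 1 at d = o."""
    d = np.asarray(d, float)
    return np.exp(-(((d - o) / s) ** 2))


def repulsion_term(d):
    """Quadratic overlap repulsion: d^2 for d <= 0, else 0."""
    d = np.asarray(d, float)
    return np.where(d <= 0.0, d * d, 0.0)


def hydrophobic_term(d, p1, p2):
    """Hydrophobic bonus: 1 below p1, 0 above p2, linear in between."""
    d = np.asarray(d, float)
    return np.clip((p2 - d) / (p2 - p1), 0.0, 1.0)


def hbond_term(d, h1):
    """H-bond bonus: 1 below h1 (< 0), 0 above 0, linear in between."""
    d = np.asarray(d, float)
    return np.clip(d / h1, 0.0, 1.0)


def lj_mn_term(r, m, n, well_depth=1.0, r_min=1.0):
    """Generic m-n Lennard-Jones potential (n > m > 0).

    Minimum of depth ``well_depth`` at ``r_min``:
        e(r) = depth/(n-m) * [m*(r_min/r)^n - n*(r_min/r)^m]
    """
    if not 0 < m < n:
        raise ValueError("Lennard-Jones exponents require n > m > 0")
    r = np.asarray(r, float)
    q = r_min / r
    return well_depth / (n - m) * (m * q**n - n * q**m)


# --- analytic derivatives in d (needed for pose gradients) ---

def _gauss_deriv(d, o, s):
    z = (np.asarray(d, float) - o) / s
    return -2.0 * z / s * np.exp(-(z * z))


def _repulsion_deriv(d):
    d = np.asarray(d, float)
    return np.where(d <= 0.0, 2.0 * d, 0.0)


def _hydrophobic_deriv(d, p1, p2):
    d = np.asarray(d, float)
    return np.where((d > p1) & (d < p2), -1.0 / (p2 - p1), 0.0)


def _hbond_deriv(d, h1):
    d = np.asarray(d, float)
    return np.where((d > h1) & (d < 0.0), 1.0 / h1, 0.0)


def _lj_deriv(r, m, n, well_depth, r_min):
    r = np.asarray(r, float)
    q = r_min / r
    return well_depth / (n - m) * (-n * m * q**n + n * m * q**m) / r


# --- pair evaluation ---

def _pair_terms(d, hydrophobic: bool, hbond: bool, p: TermParameterSet):
    """Raw (unweighted) term values for surface distance(s) d."""
    vals = {
        "gauss1": gauss_term(d, p.o1, p.s1),
        "gauss2": gauss_term(d, p.o2, p.s2) if p.gauss2_enabled else np.zeros_like(np.asarray(d, float)),
        "repulsion": repulsion_term(d),
        "hydrophobic": hydrophobic_term(d, p.p1, p.p2) if hydrophobic else np.zeros_like(np.asarray(d, float)),
        "hbond": hbond_term(d, p.h1) if hbond else np.zeros_like(np.asarray(d, float)),
    }
    return vals


def pair_energy(a: TypedAtom, b: TypedAtom, r: float, params: TermParameterSet) -> float:
    """Weighted pair interaction energy at interatomic distance ``r``.

    Steric terms apply to every heavy pair; the hydrophobic bonus only when
    both atoms are hydrophobic; the H-bond bonus only for donor-acceptor
    pairings (metals count as donors).
    """
    ri = params.radius_of(a.ad_type, a.element)
    rj = params.radius_of(b.ad_type, b.element)
    d = float(surface_distance(r, ri, rj))
    hydro = hydrophobic_pair(a.interaction_class, b.interaction_class)
    hb = hbond_pair(a.interaction_class, b.interaction_class)
    vals = _pair_terms(d, hydro, hb, params)
    e = (
        params.w1 * vals["gauss1"]
        + params.w2 * vals["gauss2"]
        + params.w3 * vals["repulsion"]
        + params.w4 * vals["hydrophobic"]
        + params.w5 * vals["hbond"]
    )
    if params.lj_weight != 0.0:
        e += params.lj_weight * lj_mn_term(r, params.lj_m, params.lj_n, r_min=ri + rj)
    return float(e)


def steric_profile(r, ri: float, rj: float, params: TermParameterSet):
    """Weighted steric energy (Gaussians + repulsion) over distances ``r``."""
    d = surface_distance(np.asarray(r, float), ri, rj)
    e = params.w1 * gauss_term(d, params.o1, params.s1) + params.w3 * repulsion_term(d)
    if params.gauss2_enabled:
        e = e + params.w2 * gauss_term(d, params.o2, params.s2)
    return e


# --- energy sums with breakdown ---

@dataclass
class ScoreBreakdown:
    """Total energy plus per-term raw sums and weighted contributions."""

    total: float
    per_term_raw: dict
    per_term_weighted: dict
    n_pairs_evaluated: int

    @property
    def per_term_percent(self) -> dict:
        if self.total == 0.0:
            raise ZeroDivisionError("per-term percentages undefined for zero total")
        return {k: 100.0 * v / self.total for k, v in self.per_term_weighted.items()}


def _accumulate(
    lig_atoms: list[TypedAtom],
    lig_xyz: np.ndarray,
    rec_atoms: list[TypedAtom],
    rec_xyz: np.ndarray,
    pair_iter,
    params: TermParameterSet,
) -> ScoreBreakdown:
    raw = {t: 0.0 for t in TERM_NAMES}
    weights = {
        "gauss1": params.w1,
        "gauss2": params.w2,
        "repulsion": params.w3,
        "hydrophobic": params.w4,
        "hbond": params.w5,
        "lj": params.lj_weight,
    }
    n_pairs = 0
    for i, j in pair_iter:
        a, b = lig_atoms[i], rec_atoms[j]
        ri = params.radius_of(a.ad_type, a.element)
        rj = params.radius_of(b.ad_type, b.element)
        r = float(np.linalg.norm(lig_xyz[i] - rec_xyz[j]))
        d = r - ri - rj
        if d >= params.cutoff:
            continue
        n_pairs += 1
        vals = _pair_terms(
            d,
            hydrophobic_pair(a.interaction_class, b.interaction_class),
            hbond_pair(a.interaction_class, b.interaction_class),
            params,
        )
        for t in ("gauss1", "gauss2", "repulsion", "hydrophobic", "hbond"):
            raw[t] += float(vals[t])
        if params.lj_weight != 0.0:
            raw["lj"] += float(lj_mn_term(r, params.lj_m, params.lj_n, r_min=ri + rj))
    weighted = {t: weights[t] * raw[t] for t in TERM_NAMES}
    return ScoreBreakdown(
        total=float(sum(weighted.values())),
        per_term_raw=raw,
        per_term_weighted=weighted,
        n_pairs_evaluated=n_pairs,
    )


def intermolecular_energy(
    ligand: LigandModel,
    receptor: ReceptorModel,
    params: TermParameterSet,
    ligand_coords: np.ndarray | None = None,
) -> ScoreBreakdown:
    """Sum of pair energies over all heavy ligand-receptor pairs within cutoff.

    Uses the receptor's spatial index to restrict candidate pairs; the
    cutoff filter itself is exact, so the result equals the brute-force
    double loop.
    """
    if not ligand.atoms or not receptor.atoms:
        raise ValueError("empty ligand or receptor")
    lig_xyz = ligand.coords if ligand_coords is None else np.asarray(ligand_coords, float)
    rec_xyz = receptor.coords
    rmax = max(
        params.radius_of(receptor.atoms[j].ad_type, receptor.atoms[j].element)
        for j in receptor.heavy_indices
    )

    def pairs():
        for i in ligand.heavy_indices:
            a = ligand.atoms[i]
            ri = params.radius_of(a.ad_type, a.element)
            for j in receptor.atoms_within(lig_xyz[i], params.cutoff + ri + rmax):
                yield i, j

    return _accumulate(ligand.atoms, lig_xyz, receptor.atoms, rec_xyz, pairs(), params)


def intramolecular_energy(
    ligand: LigandModel,
    params: TermParameterSet,
    ligand_coords: np.ndarray | None = None,
    _pair_cache: list | None = None,
) -> ScoreBreakdown:
    """Ligand self-interaction over flexibility-separated heavy pairs.

    Only pairs in *different* rigid fragments and at least 4 bonds apart
    contribute; everything else is fixed by the torsion tree or dominated
    by bonded terms and is excluded.  A rigid ligand therefore has zero
    intramolecular energy.
    """
    lig_xyz = ligand.coords if ligand_coords is None else np.asarray(ligand_coords, float)
    pairs = intra_pairs(ligand) if _pair_cache is None else _pair_cache
    return _accumulate(ligand.atoms, lig_xyz, ligand.atoms, lig_xyz, pairs, params)


def intra_pairs(ligand: LigandModel) -> list[tuple[int, int]]:
    """Eligible intramolecular heavy-atom pairs (cross-fragment, >= 4 bonds)."""
    if ligand.n_rot == 0:
        return []
    frag = ligand.fragment_of()
    dist = ligand.bond_distances()
    heavy = ligand.heavy_indices
    out = []
    for ii, i in enumerate(heavy):
        for j in heavy[ii + 1:]:
            if frag[i] != frag[j] and dist[i, j] >= 4:
                out.append((int(i), int(j)))
    return out


def predicted_affinity(inter: float, n_rot: int, params: TermParameterSet) -> float:
    """Entropy-scaled affinity: inter / (1 + torsion_coeff * n_rot).

    With ``torsion_coeff = 0`` this is the identity; the default
    coefficient follows the Vina lineage.
    """
    if n_rot < 0:
        raise ValueError("rotatable-bond count must be non-negative")
    return inter / (1.0 + params.torsion_coeff * n_rot)


def term_contributions(breakdowns: list[ScoreBreakdown]) -> dict:
    """Average per-term contribution as percent of the average total.

    Mirrors a per-term decomposition over a dataset of complexes: the mean
    weighted sum of each term divided by the mean total, times 100.
    """
    if not breakdowns:
        raise ValueError("empty breakdown list")
    mean_total = float(np.mean([b.total for b in breakdowns]))
    if mean_total == 0.0:
        raise ZeroDivisionError("term contributions undefined: average total is zero")
    return {
        t: 100.0 * float(np.mean([b.per_term_weighted[t] for b in breakdowns])) / mean_total
        for t in TERM_NAMES
    }


def pair_energy_and_deriv(
    a: TypedAtom, b: TypedAtom, r: float, params: TermParameterSet
) -> tuple[float, float]:
    """(e, de/dr) for one pair - used by the pose-gradient machinery."""
    ri = params.radius_of(a.ad_type, a.element)
    rj = params.radius_of(b.ad_type, b.element)
    d = r - ri - rj
    hydro = hydrophobic_pair(a.interaction_class, b.interaction_class)
    hb = hbond_pair(a.interaction_class, b.interaction_class)
    vals = _pair_terms(d, hydro, hb, params)
    e = (
        params.w1 * vals["gauss1"]
        + params.w2 * vals["gauss2"]
        + params.w3 * vals["repulsion"]
        + params.w4 * vals["hydrophobic"]
        + params.w5 * vals["hbond"]
    )
    de = params.w1 * _gauss_deriv(d, params.o1, params.s1) + params.w3 * _repulsion_deriv(d)
    if params.gauss2_enabled:
        de += params.w2 * _gauss_deriv(d, params.o2, params.s2)
    if hydro:
        de += params.w4 * _hydrophobic_deriv(d, params.p1, params.p2)
    if hb:
        de += params.w5 * _hbond_deriv(d, params.h1)
    if params.lj_weight != 0.0:
        e += params.lj_weight * lj_mn_term(r, params.lj_m, params.lj_n, r_min=ri + rj)
        de += params.lj_weight * _lj_deriv(r, params.lj_m, params.lj_n, 1.0, ri + rj)
    return float(e), float(de)
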