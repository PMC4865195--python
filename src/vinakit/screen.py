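"""Scoring-function development screen.

The development strategy implemented here: enumerate a constrained grid
of candidate parameter sets, rank them by the average symmetry-corrected
RMSD between each crystal ligand pose and its energy-minimized pose
(cheap), re-dock the short list (expensive), and diagnose how well either
proxy - scoring correlation or post-minimization RMSD - predicts docking
success.  The screen is dataset-agnostic: it consumes any list of
(receptor, ligand crystal pose) complexes, such as the synthetic pockets
from :mod:`vinakit.synth`.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .minimize import PoseDOF, apply_dof, local_minimize, random_restart_search
from .params import TermParameterSet
from .pdbqt import LigandModel, ReceptorModel
from .rmsd import docking_success, hungarian_rmsd
from .scoring import intermolecular_energy, predicted_affinity

__all__ = [
    "GridSpec",
    "Complex",
    "generate_grid",
    "minimization_screen",
    "docking_screen",
    "predictor_diagnostics",
]


def _radius_constraints(values: dict) -> bool:
    """Default radii constraints: C >= C_A, N > O, N - O <= 0.10 A."""
    c, ca = values.get("radius_C"), values.get("radius_A")
    n, o = values.get("radius_N"), values.get("radius_O")
    if c is not None and ca is not None and not c >= ca:
        return False
    if n is not None and o is not None:
        if not n > o + 1e-9:
            return False
        if not n - o <= 0.10 + 1e-12:
            return False
    return True


@dataclass
class GridSpec:
    """Per-parameter (start, stop, step) axes plus constraints.

    Axis names are parameter-set attributes (``w1``..``w5``, ``o1``,
    ``s1``, ``p1``, ``p2``, ``h1``, ...) or ``radius_<TYPE>``.  The
    default constraint enforces the radii conditions C >= C_A, N > O and
    N - O <= 0.10 A; additional constraints are predicates over the
    axis-value dict.
    """

    axes: dict  # name -> (start, stop, step)
    constraints: list = field(default_factory=lambda: [_radius_constraints])
    base: str = "vinardo"

    def axis_values(self, name: str) -> np.ndarray:
        start, stop, step = self.axes[name]
        if step <= 0:
            raise ValueError(f"axis {name!r}: step must be positive")
        if start > stop:
            raise ValueError(f"axis {name!r}: start must not exceed stop")
        n = int(round((stop - start) / step)) + 1
        # round away accumulation noise so grid points compare cleanly
        vals = np.round(start + step * np.arange(n), 9)
        return vals[vals <= stop + 1e-9]


def generate_grid(spec: GridSpec, base: TermParameterSet):
    """Yield every constrained grid combination exactly once.

    Candidates are ``base`` with the axis values overridden; tuples
    violating any constraint are dropped.  An infeasible constraint set
    simply yields nothing.
    """
    names = list(spec.axes)
    grids = [spec.axis_values(n) for n in names]
    count = 0
    for combo in itertools.product(*grids):
        values = dict(zip(names, (float(v) for v in combo)))
        if not all(ok(values) for ok in spec.constraints):
            continue
        count += 1
        yield base.with_overrides(name=f"{base.name}-grid-{count}", **values)


@dataclass
class Complex:
    """One training complex: rigid receptor + crystal ligand pose."""

    complex_id: str
    receptor: ReceptorModel
    ligand: LigandModel  # coordinates = crystal pose
    experimental: float | None = None  # affinity (higher = stronger), optional


def minimization_screen(
    candidates: list[TermParameterSet],
    dataset: list[Complex],
    top_k: int = 20,
    tol: float = 1e-6,
    max_iter: int = 2000,
) -> pd.DataFrame:
    """Rank candidate functions by average post-minimization RMSD.

    For each candidate, every crystal ligand is locally minimized in its
    receptor and the symmetry-corrected RMSD to the crystal pose is
    averaged over the dataset.  Candidates are reported ascending by that
    average (low = the candidate keeps a local minimum near every crystal
    geometry), truncated to ``top_k``.  Scoring correlation on crystal
    poses is reported alongside when experimental affinities are present.
    Per-complex failures are recorded, never silently dropped.
    """
    if not dataset:
        raise ValueError("empty dataset")
    rows = []
    for ci, params in enumerate(candidates):
        rmsds, scores, exps, failures = [], [], [], []
        for cx in dataset:
            try:
                dof, _, _ = local_minimize(
                    cx.ligand, cx.receptor, PoseDOF.identity(cx.ligand.n_rot),
                    params, tol=tol, max_iter=max_iter,
                )
                minimized = apply_dof(cx.ligand, dof)
                rmsds.append(
                    hungarian_rmsd(cx.ligand, cx.ligand, probe_coords=minimized).rmsd
                )
            except Exception as exc:  # noqa: BLE001 - recorded, not dropped
                failures.append(f"{cx.complex_id}: {exc}")
            if cx.experimental is not None:
                e = intermolecular_energy(cx.ligand, cx.receptor, params).total
                scores.append(predicted_affinity(e, cx.ligand.n_rot, params))
                exps.append(cx.experimental)
        scoring_r = np.nan
        if len(scores) >= 3 and np.std(scores) > 0 and np.std(exps) > 0:
            scoring_r = float(stats.pearsonr(-np.array(scores), exps).statistic)
        rows.append(
            {
                "candidate": params.name,
                "candidate_index": ci,
                "avg_rmsd": float(np.mean(rmsds)) if rmsds else np.nan,
                "scoring_r": scoring_r,
                "n_failed": len(failures),
                "failures": "; ".join(failures),
            }
        )
    report = pd.DataFrame(rows).sort_values("avg_rmsd", kind="stable").reset_index(drop=True)
    return report.head(top_k)


def docking_screen(
    candidates: list[TermParameterSet],
    dataset: list[Complex],
    n_starts: int = 8,
    seed: int = 0,
    threshold: float = 2.0,
    box: tuple | None = None,
) -> pd.DataFrame:
    """Re-docking success rate per candidate.

    Each complex is re-docked with a seeded random-restart search; success
    means the best-scored pose lies within ``threshold`` of the crystal
    pose.  Deterministic per seed (per-complex seeds are derived from
    ``seed`` and the complex index).
    """
    if not dataset:
        raise ValueError("empty dataset")
    rows = []
    for ci, params in enumerate(candidates):
        wins, total, failures = 0, 0, []
        for k, cx in enumerate(dataset):
            sub_seed = (seed * 100003 + ci * 1009 + k) % (2**31 - 1)
            try:
                poses = random_restart_search(
                    cx.ligand, cx.receptor, n_starts, sub_seed, params, box=box
                )
                best = poses[0]
                r = hungarian_rmsd(cx.ligand, cx.ligand, probe_coords=best.coords).rmsd
                total += 1
                if docking_success(r, threshold):
                    wins += 1
            except Exception as exc:  # noqa: BLE001
                failures.append(f"{cx.complex_id}: {exc}")
        rows.append(
            {
                "candidate": params.name,
                "candidate_index": ci,
                "docking_pct": 100.0 * wins / total if total else np.nan,
                "n_failed": len(failures),
                "failures": "; ".join(failures),
            }
        )
    return pd.DataFrame(rows)


def predictor_diagnostics(report: pd.DataFrame) -> dict:
    """How well scoring R vs average RMSD predict docking success.

    ``report`` needs columns ``docking_pct``, ``scoring_r`` and
    ``avg_rmsd`` for at least 3 candidates.  Returns both Pearson
    coefficients and the fitted linear trends (slope, intercept).
    """
    df = report.dropna(subset=["docking_pct", "scoring_r", "avg_rmsd"])
    if len(df) < 3:
        raise ValueError("diagnostics require at least 3 complete candidates")
    dock = df["docking_pct"].to_numpy(float)
    out = {}
    for key, col in (("scoring_r", "scoring_r"), ("avg_rmsd", "avg_rmsd")):
        x = df[col].to_numpy(float)
        r = float(stats.pearsonr(dock, x).statistic) if np.std(x) > 0 else np.nan
        slope, intercept = np.polyfit(x, dock, 1) if np.std(x) > 0 else (np.nan, np.nan)
        out[f"r_docking_vs_{key}"] = r
        out[f"trend_docking_vs_{key}"] = (float(slope), float(intercept))
    return out
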