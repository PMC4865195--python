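"""Scoring-function evaluation metrics over score tables.

Implements the four CASF-style aptitude tests (scoring, ranking, docking
and screening power) and the virtual-screening enrichment metrics (ROC
AUC for overall enrichment, BEDROC for early enrichment) on delimited
score tables.

Sign convention, declared once for the whole module: a *lower* (more
negative) predicted energy means a *better* rank, while a *higher*
experimental affinity value (e.g. pKd) means a *stronger* binder.
Ties in predicted scores are broken deterministically by input order
(stable sorts throughout).
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import roc_auc_score

__all__ = [
    "read_score_table",
    "scoring_power",
    "ranking_power",
    "docking_power",
    "screening_power",
    "roc_auc",
    "bedroc",
]

#: canonical score-table columns
COLUMNS = ["complex_id", "protein_id", "predicted", "experimental", "label", "pose_rmsd"]


def read_score_table(path_or_buf, sep: str = "\t") -> pd.DataFrame:
    """Read a delimited score table; missing optional columns become NaN."""
    df = pd.read_csv(path_or_buf, sep=sep)
    for col in COLUMNS:
        if col not in df.columns:
            df[col] = np.nan
    return df


def scoring_power(records: pd.DataFrame) -> float:
    """Pearson correlation between predicted and experimental affinity.

    Predicted energies are negated before correlating so that "more
    negative predicted = stronger experimental" counts as positive R.
    """
    df = records.dropna(subset=["predicted", "experimental"])
    if len(df) < 3:
        raise ValueError("scoring power requires at least 3 records")
    pred = -df["predicted"].to_numpy(float)
    exp = df["experimental"].to_numpy(float)
    if np.std(pred) == 0 or np.std(exp) == 0:
        raise ValueError("zero variance in predicted or experimental affinities")
    return float(stats.pearsonr(pred, exp).statistic)


def ranking_power(records: pd.DataFrame) -> tuple[float, float]:
    """(high success %, low success %) over per-protein triplets.

    Each protein contributes exactly three ligands with distinct
    experimental affinities.  High success: all three correctly ordered by
    predicted score.  Low success: the strongest experimental binder is
    ranked first.
    """
    highs = lows = n_groups = 0
    for pid, grp in records.groupby("protein_id", sort=False):
        if len(grp) != 3:
            raise ValueError(f"protein {pid!r}: ranking groups must have exactly 3 ligands")
        if grp["experimental"].nunique() != 3:
            raise ValueError(f"protein {pid!r}: experimental affinities must be distinct")
        by_pred = grp.sort_values("predicted", kind="stable")  # best (lowest) first
        exp_sorted = by_pred["experimental"].to_numpy(float)
        n_groups += 1
        if exp_sorted[0] == grp["experimental"].max():
            lows += 1
            if exp_sorted[0] > exp_sorted[1] > exp_sorted[2]:
                highs += 1
    return 100.0 * highs / n_groups, 100.0 * lows / n_groups


def docking_power(
    records: pd.DataFrame, threshold: float = 2.0
) -> tuple[float, float, float]:
    """(top1 %, top2 %, top3 %) success over per-complex decoy pose sets.

    Success at level N: among the N best-scored poses of a complex there
    is one within ``threshold`` of the crystal pose.  Ties are broken by
    input order (stable sort).
    """
    if records["pose_rmsd"].isna().any():
        raise ValueError("docking power requires pose_rmsd for every record")
    wins = np.zeros(3)
    n = 0
    for cid, grp in records.groupby("complex_id", sort=False):
        if len(grp) < 3:
            raise ValueError(f"complex {cid!r}: need at least 3 scored poses")
        rmsds = grp.sort_values("predicted", kind="stable")["pose_rmsd"].to_numpy(float)
        n += 1
        for k in range(3):
            if (rmsds[: k + 1] <= threshold).any():
                wins[k] += 1
    return tuple(100.0 * wins / n)  # type: ignore[return-value]


def screening_power(
    records: pd.DataFrame,
    true_binders: dict[str, str],
    levels: tuple[float, ...] = (0.01, 0.03, 0.05),
) -> tuple[float, ...]:
    """Success rates at each pool fraction for true-binder retrieval.

    For each protein the full compound pool is scored (best pose per
    compound); success at level x when the known true binder ranks within
    ceil(x * pool size).  With a 195-compound pool, the top 1% means rank
    1 or 2.
    """
    wins = np.zeros(len(levels))
    n = 0
    for pid, grp in records.groupby("protein_id", sort=False):
        if pid not in true_binders:
            raise ValueError(f"no true binder declared for protein {pid!r}")
        best = grp.groupby("complex_id", sort=False)["predicted"].min()
        ranked = best.sort_values(kind="stable")
        binder = true_binders[pid]
        if binder not in ranked.index:
            raise ValueError(f"true binder {binder!r} absent from pool for {pid!r}")
        rank = int(np.nonzero(ranked.index.to_numpy() == binder)[0][0]) + 1
        pool = len(ranked)
        n += 1
        for k, x in enumerate(levels):
            if rank <= math.ceil(x * pool):
                wins[k] += 1
    return tuple(100.0 * wins / n)


def _labels_and_scores(records: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    df = records[records["label"].isin(["active", "decoy"])]
    y = (df["label"] == "active").to_numpy()
    # better (more negative) predicted energy -> higher classifier score
    s = -df["predicted"].to_numpy(float)
    return y, s


def roc_auc(records: pd.DataFrame) -> float:
    """Area under the ROC curve for active/decoy discrimination.

    Equals the Mann-Whitney statistic: the fraction of (active, decoy)
    pairs ranked correctly, counting ties as 1/2.  0.5 is the random
    expectation.
    """
    y, s = _labels_and_scores(records)
    if y.all() or not y.any():
        raise ValueError("ROC AUC requires both actives and decoys")
    return float(roc_auc_score(y, s))


def bedroc(records: pd.DataFrame, alpha: float = 20.0) -> float:
    """Boltzmann-enhanced discrimination of ROC (early enrichment).

    Exponentially up-weights early recognition with parameter ``alpha``;
    bounded in [0, 1].  The random expectation approaches 1/alpha (0.05
    for the default alpha = 20) as the active fraction goes to zero.
    """
    if alpha <= 0:
        raise ValueError("alpha must be positive")
    y, s = _labels_and_scores(records)
    if not y.any():
        raise ValueError("BEDROC requires at least one active")
    order = np.argsort(-s, kind="stable")
    ranks = np.nonzero(y[order])[0] + 1  # 1-based ranks of actives
    n, big_n = len(ranks), len(y)
    ra = n / big_n
    rie_num = np.exp(-alpha * ranks / big_n).sum() / n
    rie_den = (1.0 / big_n) * (1.0 - math.exp(-alpha)) / (math.exp(alpha / big_n) - 1.0)
    rie = rie_num / rie_den
    factor = ra * math.sinh(alpha / 2.0) / (
        math.cosh(alpha / 2.0) - math.cosh(alpha / 2.0 - alpha * ra)
    )
    const = 1.0 / (1.0 - math.exp(alpha * (1.0 - ra)))
    return float(rie * factor + const)


def bedroc_random_expectation(n_active: int, n_total: int, alpha: float = 20.0) -> float:
    """Closed-form expected BEDROC under label-independent ranking.

    E[RIE] = 1 for a random ranking, so the expectation is the
    BEDROC transform evaluated at RIE = 1; it converges to 1/alpha as the
    active fraction n_active/n_total goes to zero.
    """
    ra = n_active / n_total
    factor = ra * math.sinh(alpha / 2.0) / (
        math.cosh(alpha / 2.0) - math.cosh(alpha / 2.0 - alpha * ra)
    )
    const = 1.0 / (1.0 - math.exp(alpha * (1.0 - ra)))
    return factor + const
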