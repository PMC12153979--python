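"""Coupling aggregation and comparison with fibril-structure distances.

The interaction score of a pair of positions is the mean absolute energetic
coupling over all mutation combinations at that pair (16 for two positions
with four alternatives each). Scores are compared with mature-fibril
geometry by rank-correlating them against inverse scHA_min distances; top
interacting pairs are extracted at a percentile of the score distribution.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.stats import rankdata, spearmanr

from amynuc.energy_model import EnergyModel
from amynuc.library_design import Mutation
from amynuc.structure import DistanceMatrix

__all__ = [
    "DistanceCorrelationResult",
    "correlate_with_distance",
    "interaction_scores",
    "position_summary",
    "spearman_with_exact_p",
    "top_pairs",
]

log = logging.getLogger(__name__)


def interaction_scores(
    couplings: Mapping[tuple[str, str], float],
) -> pd.DataFrame:
    """Mean absolute coupling per unordered position pair.

    Returns columns ``pos_i``, ``pos_j`` (pos_i < pos_j), ``score``,
    ``n_couplings`` and ``percentile`` (rank of the score within the
    empirical distribution, in percent).
    """
    if not couplings:
        raise ValueError("no couplings given")
    acc: dict[tuple[int, int], list[float]] = {}
    for (a, b), val in couplings.items():
        pa, pb = Mutation.parse(a).position, Mutation.parse(b).position
        key = (min(pa, pb), max(pa, pb))
        acc.setdefault(key, []).append(abs(float(val)))
    rows = [
        {"pos_i": i, "pos_j": j, "score": float(np.mean(v)), "n_couplings": len(v)}
        for (i, j), v in sorted(acc.items())
    ]
    df = pd.DataFrame(rows)
    df["percentile"] = rankdata(df["score"], method="average") / len(df) * 100.0
    return df


def top_pairs(scores: pd.DataFrame, percentile: float = 90.0) -> pd.DataFrame:
    """Pairs whose score reaches the given percentile of the score distribution.

    The threshold is the linearly interpolated empirical percentile; pairs
    with score >= threshold are returned, so ties at the threshold are all
    kept. For 40 pairs at the 90th percentile this yields the top 4.
    """
    if scores.empty:
        raise ValueError("empty score table")
    thr = float(np.percentile(scores["score"].to_numpy(), percentile))
    out = scores[scores["score"] >= thr].copy()
    return out.sort_values("score", ascending=False, kind="stable").reset_index(drop=True)


@dataclass(frozen=True)
class DistanceCorrelationResult:
    structure_id: str
    rho: float
    p_value: float
    n: int
    mode: str = "monomer"
    defined: bool = True


def spearman_with_exact_p(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Spearman rho with an exact permutation p-value for small samples.

    For n < 10 the two-sided p is computed by full enumeration of rank
    permutations (|rho_perm| >= |rho_obs|); for n >= 10 the usual
    t-approximation is used.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    rho = float(spearmanr(x, y).statistic)
    if n >= 10:
        return rho, float(spearmanr(x, y).pvalue)
    rx = rankdata(x) - (n + 1) / 2.0
    ry = rankdata(y) - (n + 1) / 2.0
    denom = math.sqrt(float((rx * rx).sum() * (ry * ry).sum()))
    if denom == 0:
        return rho, float("nan")
    obs = float((rx * ry).sum() / denom)
    perms = np.array(list(itertools.permutations(range(n))), dtype=np.intp)
    stats = (ry[perms] @ rx) / denom
    p = float(np.mean(np.abs(stats) >= abs(obs) - 1e-12))
    return rho, p


def correlate_with_distance(
    scores: pd.DataFrame, distances: DistanceMatrix
) -> DistanceCorrelationResult:
    """Spearman correlation of interaction score with inverse scHA_min.

    Pairs without a distance in the matrix are dropped with a log entry;
    constant scores or distances yield a flagged undefined result.
    """
    xs, ys, dropped = [], [], []
    pos_set = set(distances.positions)
    for _, row in scores.iterrows():
        i, j = int(row["pos_i"]), int(row["pos_j"])
        if i not in pos_set or j not in pos_set:
            dropped.append((i, j))
            continue
        d = distances.get(i, j)
        if d <= 0:
            dropped.append((i, j))
            continue
        xs.append(float(row["score"]))
        ys.append(1.0 / d)
    if dropped:
        log.info("correlate_with_distance: dropped %d pairs without distances", len(dropped))
    n = len(xs)
    if n < 3:
        raise ValueError(f"need >= 3 shared pairs for a correlation; have {n}")
    x = np.array(xs)
    y = np.array(ys)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return DistanceCorrelationResult(
            distances.structure_id, float("nan"), float("nan"), n, distances.mode, defined=False
        )
    rho, p = spearman_with_exact_p(x, y)
    return DistanceCorrelationResult(distances.structure_id, rho, p, n, distances.mode)


def position_summary(model: EnergyModel) -> pd.DataFrame:
    """Per-position arithmetic mean of first-order activation-energy terms."""
    if not model.first_order:
        raise ValueError("model has no first-order terms")
    rows: dict[int, list[float]] = {}
    for key, val in model.first_order.items():
        rows.setdefault(Mutation.parse(key).position, []).append(float(val))
    return pd.DataFrame(
        [
            {"position": p, "mean_ddg_act": float(np.mean(v)), "n_terms": len(v)}
            for p, v in sorted(rows.items())
        ]
    )
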