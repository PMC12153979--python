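"""Phi-like ratio analysis: activation-energy changes vs fibril stability.

For each fibril polymorph, predicted assembly stability changes are divided
by the chain count to give per-monomer values, filtered to moderate effects
(0.6 < |ddG| < 10 kcal/mol by default: large enough to be meaningful,
small enough not to perturb the fibril fold), and combined with inferred
activation-energy changes into ratios R = ddG_act / ddG_stability. A ratio
near 1 suggests the mutated residue is as structured in the transition state
as in the mature fibril; near 0, unstructured. Polymorphs are ranked by the
root-mean-square distance of their ratios to 1.
"""

from __future__ import annotations

import logging
from typing import Mapping

import numpy as np
import pandas as pd

from amynuc.library_design import Mutation

__all__ = [
    "compute_ratios",
    "filter_moderate",
    "per_monomer_ddg",
    "position_mean_ratios",
    "rank_polymorphs",
]

log = logging.getLogger(__name__)

DEFAULT_LOWER = 0.6
DEFAULT_UPPER = 10.0


def per_monomer_ddg(assembly_ddg: float | np.ndarray, chain_count: int) -> float | np.ndarray:
    """Per-monomer stability change from a stacked-filament assembly value."""
    if chain_count < 1:
        raise ValueError("chain_count must be >= 1")
    out = np.asarray(assembly_ddg, dtype=float) / chain_count
    return float(out) if out.ndim == 0 else out


def filter_moderate(
    values: pd.Series | np.ndarray,
    lower: float = DEFAULT_LOWER,
    upper: float = DEFAULT_UPPER,
) -> pd.DataFrame:
    """Moderate-effect filter on per-monomer stability changes.

    Pass iff lower < |ddG| < upper (absolute-value rule, both bounds strict):
    below the lower bound a ratio is dominated by noise, above the upper the
    mutation likely perturbs the fibril structure itself. Fail reasons are
    recorded per mutation.
    """
    v = np.asarray(values, dtype=float)
    absv = np.abs(v)
    passed = (absv > lower) & (absv < upper)
    reason = np.where(
        passed, "", np.where(absv <= lower, "too_small", "structure_perturbing")
    )
    return pd.DataFrame({"value": v, "passed": passed, "reason": reason})


def compute_ratios(
    ddg_act: Mapping[str, float],
    stability: pd.DataFrame,
    lower: float = DEFAULT_LOWER,
    upper: float = DEFAULT_UPPER,
) -> pd.DataFrame:
    """Per-mutation activation/stability ratios per structure, with filtering.

    ``stability`` needs columns ``structure``, ``mutation``, ``assembly_ddg``,
    ``n_chains``. Only mutations present in both inputs and passing the
    moderate-effect filter on per-monomer stability contribute ratios.
    """
    stab = stability.copy()
    stab["per_monomer_ddg"] = stab["assembly_ddg"] / stab["n_chains"]
    stab = stab[stab["mutation"].isin(ddg_act.keys())].copy()
    if stab.empty:
        raise ValueError("no shared mutations between activation and stability tables")
    flt = filter_moderate(stab["per_monomer_ddg"], lower, upper)
    stab["passed"] = flt["passed"].to_numpy()
    stab["fail_reason"] = flt["reason"].to_numpy()
    stab["ddg_act"] = stab["mutation"].map(ddg_act)
    stab["position"] = stab["mutation"].map(lambda m: Mutation.parse(m).position)
    stab["ratio"] = np.where(
        stab["passed"], stab["ddg_act"] / stab["per_monomer_ddg"], np.nan
    )
    return stab.reset_index(drop=True)


def position_mean_ratios(ratios: pd.DataFrame) -> pd.DataFrame:
    """Per-position mean ratio (and mean energies) over passing mutations only."""
    passing = ratios[ratios["passed"]]
    grp = passing.groupby(["structure", "position"])
    out = grp.agg(
        mean_ratio=("ratio", "mean"),
        mean_ddg_act=("ddg_act", "mean"),
        mean_ddg_stab=("per_monomer_ddg", "mean"),
        n=("ratio", "size"),
    ).reset_index()
    return out


def rank_polymorphs(
    ratios: pd.DataFrame, region: tuple[int, int] | None = None
) -> pd.DataFrame:
    """Rank structures by RMSD of passing ratios to 1 (ascending; best first).

    ``region`` optionally restricts to a 1-based inclusive position range
    (e.g. the C-terminal aggregation-prone region, residues 29-42).
    Structures with no passing ratios in the region are excluded with a
    warning.
    """
    df = ratios[ratios["passed"]]
    if region is not None:
        df = df[(df["position"] >= region[0]) & (df["position"] <= region[1])]
    rows = []
    for struct, grp in df.groupby("structure"):
        r = grp["ratio"].to_numpy(dtype=float)
        if r.size == 0:
            log.warning("structure %s has no passing ratios in region; excluded", struct)
            continue
        rows.append(
            {"structure": struct, "rmsd_to_1": float(np.sqrt(np.mean((r - 1.0) ** 2))), "n": r.size}
        )
    if not rows:
        raise ValueError("no structure has passing ratios to rank")
    out = pd.DataFrame(rows).sort_values("rmsd_to_1", kind="stable").reset_index(drop=True)
    out["rank"] = np.arange(1, len(out) + 1)
    return out
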