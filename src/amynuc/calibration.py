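"""Kinetic calibration of trait units to kcal/mol via transition-state theory.

Transition-state theory gives k = A * exp(-dG_act / RT) with a
mutation-invariant pre-factor A, so the change in free energy of activation
for a variant relative to WT is RT * ln(k_WT / k_var): a slower variant has a
positive activation-energy change. Regressing the model's additive trait
values on these experimentally derived energies yields a slope whose inverse
converts every model term to kcal/mol. A second affine regression maps
combinatorial-library energy scales (anchored by an artificial reference)
onto the double-mutant scale.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import linregress

from amynuc.constants import R_KCAL, T_KELVIN
from amynuc.energy_model import EnergyModel

__all__ = [
    "CalibrationFit",
    "apply_calibration",
    "ddg_from_rates",
    "fit_calibration",
    "recenter_combinatorial",
]


@dataclass(frozen=True)
class CalibrationFit:
    slope: float
    intercept: float
    rate_type: str = "secondary"
    r_value: float = float("nan")
    n: int = 0


def ddg_from_rates(
    k_wt: float | np.ndarray, k_var: float | np.ndarray, temperature: float = T_KELVIN
) -> float | np.ndarray:
    """Activation-energy change (kcal/mol) from WT and variant rate constants.

    ddG_act = R*T*ln(k_WT / k_var); halving the rate at 303 K gives
    +RT*ln2 ~ +0.417 kcal/mol. Multiplicative rate terms (e.g. elongation x
    nucleation products) may be passed directly: a mutation-invariant factor
    cancels in the ratio.
    """
    k_wt = np.asarray(k_wt, dtype=float)
    k_var = np.asarray(k_var, dtype=float)
    if np.any(k_wt <= 0) or np.any(k_var <= 0):
        raise ValueError("rate constants must be positive")
    out = R_KCAL * temperature * np.log(k_wt / k_var)
    return float(out) if out.ndim == 0 else out


def fit_calibration(
    traits: Sequence[float],
    ddg_experimental: Sequence[float],
    rate_type: str = "secondary",
) -> CalibrationFit:
    """OLS of model trait values on experimentally derived activation energies.

    The regression is trait ~ ddG_exp (that orientation), so dividing model
    terms by the slope converts them to kcal/mol.
    """
    t = np.asarray(traits, dtype=float)
    d = np.asarray(ddg_experimental, dtype=float)
    if t.shape != d.shape or t.size < 2:
        raise ValueError("need >= 2 paired (trait, ddG) observations")
    if np.ptp(d) == 0:
        raise ValueError("experimental ddG values have zero variance")
    res = linregress(d, t)
    return CalibrationFit(
        slope=float(res.slope),
        intercept=float(res.intercept),
        rate_type=rate_type,
        r_value=float(res.rvalue),
        n=t.size,
    )


def apply_calibration(model: EnergyModel, fit: CalibrationFit) -> EnergyModel:
    """Convert a trait-unit model to kcal/mol by dividing terms by the slope.

    Only energy *differences* (terms) are rescaled; the regression intercept
    plays no role because differences are intercept-free.
    """
    if fit.slope == 0:
        raise ValueError("calibration slope must be nonzero")
    return replace(
        model,
        first_order={k: v / fit.slope for k, v in model.first_order.items()},
        couplings={k: v / fit.slope for k, v in model.couplings.items()},
        units="kcal/mol",
    )


def recenter_combinatorial(
    combinatorial_terms: Mapping[str, float],
    double_terms: Mapping[str, float],
) -> tuple[dict[str, float], CalibrationFit]:
    """Affine-map combinatorial-scale energies onto the double-mutant scale.

    Regresses double-mutant-scale energies on combinatorial-scale energies
    over the shared terms and applies slope and intercept to every
    combinatorial term (the artificial reference used to anchor combinatorial
    fits shifts and scales that dataset's energies; shared terms identify the
    map). Rejects if fewer than two shared terms or zero variance.
    """
    shared = sorted(set(combinatorial_terms) & set(double_terms))
    if len(shared) < 2:
        raise ValueError(
            f"need >= 2 shared terms to recenter; found {len(shared)}: {shared}"
        )
    x = np.array([combinatorial_terms[k] for k in shared])
    y = np.array([double_terms[k] for k in shared])
    if np.ptp(x) == 0:
        raise ValueError("combinatorial terms constant over the shared set")
    res = linregress(x, y)
    mapped = {
        k: float(res.slope * v + res.intercept) for k, v in combinatorial_terms.items()
    }
    fit = CalibrationFit(
        slope=float(res.slope),
        intercept=float(res.intercept),
        rate_type="recenter",
        r_value=float(res.rvalue),
        n=len(shared),
    )
    return mapped, fit


def rates_table_to_ddg(
    rates: pd.DataFrame, rate_column: str = "k2", temperature: float = T_KELVIN
) -> pd.DataFrame:
    """Per-variant activation energies from a rates table containing a WT row.

    Expects columns ``variant`` and the chosen rate column (``k2`` secondary,
    ``kn`` primary, or multiplicative equivalents).
    """
    wt_rows = rates.loc[rates["variant"] == "WT", rate_column]
    if wt_rows.empty:
        raise ValueError("rates table must contain a WT row")
    k_wt = float(wt_rows.iloc[0])
    out = rates.loc[rates["variant"] != "WT", ["variant", rate_column]].copy()
    out["ddg_exp"] = ddg_from_rates(k_wt, out[rate_column].to_numpy(), temperature)
    return out
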