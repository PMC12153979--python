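"""Global-epistasis energy model for nucleation growth rates.

The measured relative growth rate of a variant is modelled as a bounded,
monotonically decreasing sigmoid of an additive latent trait:

    GR(v) = L + (U - L) / (1 + exp(phi(v))),    phi(v) = sum_i theta_i x_i(v)

where x(v) is a binary encoding of the variant's substitutions (and, at
order 2, of its substitution pairs), and theta are the activation-energy
terms. The sigmoid captures the upper and lower bounds of the selection
assay (global nonlinearity); phi is in trait units until kinetic calibration
converts it to kcal/mol. The trait scale of the sigmoid is fixed at 1: a free
scale would trade off exactly against the norm of theta, and the absolute
scale is recovered by calibration against in vitro rate constants.

Fitting minimizes the inverse-variance weighted squared error plus an
elastic-net penalty lambda*(||theta||_1 + ||theta||_2^2) on the energy terms
(the L1 part uses the smooth approximation |t| ~ sqrt(t^2 + 1e-12)).
Cross-validation refits the model on each training fold; per-term standard
errors are the across-fold standard deviations of the terms.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import expit
from scipy.stats import norm
from sklearn.model_selection import KFold
from statsmodels.stats.multitest import multipletests

from amynuc.library_design import Mutation, parse_mutation_str

__all__ = [
    "EnergyModel",
    "FitReport",
    "add_reference_variant",
    "encode_variants",
    "fit_energy_model",
    "predict_growth",
    "significance_terms",
]

log = logging.getLogger(__name__)

_SMOOTH_EPS = 1e-12


@dataclass
class EnergyModel:
    """Fitted energy landscape in trait units (or kcal/mol after calibration)."""

    first_order: dict[str, float]
    couplings: dict[tuple[str, str], float]
    sigmoid: tuple[float, float, float]  # (L, U, scale); scale fixed at 1
    order: int
    lam: float
    link: str = "sigmoid"
    units: str = "trait"
    temperature: float = 303.0

    @property
    def term_names(self) -> list[str]:
        return list(self.first_order) + [f"{a}:{b}" for a, b in self.couplings]

    def trait(self, mutations_str: str) -> float:
        muts = parse_mutation_str(mutations_str)
        phi = sum(self.first_order[str(m)] for m in muts)
        for a, b in itertools.combinations(muts, 2):
            key = _pair_key(a, b)
            phi += self.couplings.get(key, 0.0)
        return phi

    def predict(self, mutations_str: str) -> float:
        phi = self.trait(mutations_str)
        if self.link == "linear":
            return phi
        L, U, s = self.sigmoid
        return float(L + (U - L) * expit(-s * phi))

    def to_frame(self) -> pd.DataFrame:
        rows = [{"term": k, "kind": "first_order", "value": v} for k, v in self.first_order.items()]
        rows += [
            {"term": f"{a}:{b}", "kind": "coupling", "value": v}
            for (a, b), v in self.couplings.items()
        ]
        return pd.DataFrame(rows)


@dataclass
class FitReport:
    r2_per_fold: list[float]
    r2: float
    fold_assignments: np.ndarray
    term_se: dict[str, float]
    fold_terms: pd.DataFrame  # folds x terms
    converged: bool
    n_variants: int
    seed: int
    messages: list[str] = field(default_factory=list)


def _pair_key(a: Mutation, b: Mutation) -> tuple[str, str]:
    sa, sb = sorted((a, b), key=lambda m: (m.position, m.mut))
    return (str(sa), str(sb))


def encode_variants(
    mutation_strs: list[str],
    order: int = 1,
    first_order_terms: list[str] | None = None,
    coupling_terms: list[tuple[str, str]] | None = None,
) -> tuple[np.ndarray, list[str], list[tuple[str, str]]]:
    """Binary design matrix: one indicator per substitution and (order 2) per
    substitution pair. WT encodes to the zero row.

    Term lists default to those observed in the data (sorted by position).
    Unknown mutations relative to an explicit term list are rejected.
    """
    parsed = [parse_mutation_str(s) for s in mutation_strs]
    if first_order_terms is None:
        seen = {str(m) for muts in parsed for m in muts}
        first_order_terms = sorted(seen, key=lambda s: (Mutation.parse(s).position, s))
    fo_index = {t: i for i, t in enumerate(first_order_terms)}

    if order >= 2:
        if coupling_terms is None:
            pair_seen = {
                _pair_key(a, b)
                for muts in parsed
                for a, b in itertools.combinations(muts, 2)
            }
            coupling_terms = sorted(pair_seen)
        cp_index = {p: i for i, p in enumerate(coupling_terms)}
    else:
        coupling_terms = []
        cp_index = {}

    n_terms = len(first_order_terms) + len(coupling_terms)
    X = np.zeros((len(parsed), n_terms), dtype=float)
    for row, muts in enumerate(parsed):
        for m in muts:
            key = str(m)
            if key not in fo_index:
                raise KeyError(f"mutation {key!r} outside the declared term space")
        for m in muts:
            X[row, fo_index[str(m)]] = 1.0
        if order >= 2:
            for a, b in itertools.combinations(muts, 2):
                key = _pair_key(a, b)
                if key in cp_index:
                    X[row, len(first_order_terms) + cp_index[key]] = 1.0
    return X, first_order_terms, coupling_terms


def add_reference_variant(
    table: pd.DataFrame, reference: str = "WT", gr: float = 0.0, sigma: float = 100.0
) -> pd.DataFrame:
    """Append an artificial reference genotype with GR 0 and a large error.

    Used for combinatorial libraries that do not contain the WT sequence: the
    anchor pins the trait origin while its huge error (default sigma 100, i.e.
    weight 1e-4) leaves the fit essentially uninfluenced. Idempotent.
    """
    if (table["variant"] == reference).any():
        log.warning("reference %r already present; add_reference_variant is a no-op", reference)
        return table
    row = {c: np.nan for c in table.columns}
    row.update({"variant": reference, "mutations": "", "gr": gr, "sigma": sigma})
    if "is_wt_synonym" in table.columns:
        row["is_wt_synonym"] = True
    return pd.concat([table, pd.DataFrame([row])], ignore_index=True)


def _loss_grad(params, X, y, w, lam, link, fixed_bounds):
    k = X.shape[1]
    theta = params[:k]
    phi = X @ theta
    if link == "linear":
        pred = phi
        dpred = np.ones_like(phi)
    else:
        if fixed_bounds is None:
            L, U = params[k], params[k + 1]
        else:
            L, U = fixed_bounds
        q = expit(-phi)  # 1/(1+exp(phi))
        pred = L + (U - L) * q
        dpred = -(U - L) * q * (1.0 - q)
    r = pred - y
    loss = float(np.sum(w * r * r))
    gout = 2.0 * w * r
    gtheta = X.T @ (gout * dpred)
    if lam:
        sabs = np.sqrt(theta * theta + _SMOOTH_EPS)
        loss += lam * float(np.sum(sabs) + np.sum(theta * theta))
        gtheta = gtheta + lam * (theta / sabs + 2.0 * theta)
    grad = np.empty_like(params)
    grad[:k] = gtheta
    if link != "linear" and fixed_bounds is None:
        q = expit(-phi)
        grad[k] = float(np.sum(gout * (1.0 - q)))
        grad[k + 1] = float(np.sum(gout * q))
    return loss, grad


#: iteration cap for the quasi-Newton fits. Deliberately moderate: for
#: variants saturated at the assay's growth-rate floor the loss is nearly
#: flat in their energy terms and sampling noise can reward arbitrarily
#: large values, so fully converging the objective lets unidentifiable
#: terms inflate. Capping iterations acts as early stopping — the same
#: implicit regularization the neural-network trainers used for this model
#: class rely on — and leaves well-identified terms fully converged.
MAX_ITER = 2000


def _fit_once(X, y, w, lam, link, fixed_bounds, x0, maxiter=MAX_ITER):
    res = minimize(
        _loss_grad,
        x0,
        args=(X, y, w, lam, link, fixed_bounds),
        jac=True,
        method="L-BFGS-B",
        options={"maxiter": maxiter, "ftol": 1e-12, "gtol": 1e-9},
    )
    return res


def _initial_points(k, y, link, fixed_bounds, restarts, rng):
    points = []
    base = np.zeros(k)
    if link == "linear" or fixed_bounds is not None:
        points.append(base)
        for _ in range(restarts - 1):
            points.append(rng.normal(0.0, 0.1, size=k))
        return points
    lo, hi = float(np.min(y)), float(np.max(y))
    pad = 0.1 * max(hi - lo, 1e-6)
    points.append(np.concatenate([base, [lo - pad, hi + pad]]))
    for _ in range(restarts - 1):
        points.append(
            np.concatenate(
                [rng.normal(0.0, 0.1, size=k), [lo - pad * rng.uniform(0.5, 2), hi + pad * rng.uniform(0.5, 2)]]
            )
        )
    return points


def fit_energy_model(
    table: pd.DataFrame,
    order: int = 1,
    lam: float = 1e-5,
    folds: int = 10,
    seed: int = 0,
    link: str = "sigmoid",
    fixed_bounds: tuple[float, float] | None = None,
    restarts: int = 3,
    first_order_terms: list[str] | None = None,
    coupling_terms: list[tuple[str, str]] | None = None,
) -> tuple[EnergyModel, FitReport]:
    """Fit the energy model to a merged growth-rate table.

    ``table`` needs columns ``mutations`` (comma-separated identifiers, ''
    for WT), ``gr`` and ``sigma``. The final model is fit on all data with
    ``restarts`` optimizer starts; each CV fold is refit from the full-data
    solution. Returns the model and a report with held-out R2 (per fold and
    pooled over all held-out predictions) and across-fold per-term SEs.
    """
    if link not in ("sigmoid", "linear"):
        raise ValueError(f"unknown link {link!r}")
    muts = table["mutations"].fillna("").tolist()
    y = table["gr"].to_numpy(dtype=float)
    sigma = table["sigma"].to_numpy(dtype=float)
    if not np.all(np.isfinite(sigma)) or np.any(sigma <= 0):
        raise ValueError("every variant needs a finite positive sigma")
    w = 1.0 / sigma**2

    X, fo_terms, cp_terms = encode_variants(muts, order, first_order_terms, coupling_terms)
    k = X.shape[1]
    rng = np.random.default_rng(seed)

    best = None
    for x0 in _initial_points(k, y, link, fixed_bounds, restarts, rng):
        res = _fit_once(X, y, w, lam, link, fixed_bounds, x0)
        if best is None or res.fun < best.fun:
            best = res
    assert best is not None
    if not best.success:
        if "ITERATIONS REACHED LIMIT" in str(best.message):
            # expected under the deliberate early-stopping cap (MAX_ITER)
            log.info("optimizer stopped at the iteration cap (early stopping)")
        else:
            log.warning("optimizer did not report convergence: %s", best.message)

    # cross-validation: refit from the full-data optimum on each training fold
    n = len(y)
    n_folds = min(folds, n)
    kf = KFold(n_splits=n_folds, shuffle=True, random_state=seed)
    assignments = np.empty(n, dtype=int)
    fold_thetas = np.zeros((n_folds, k))
    r2_per_fold: list[float] = []
    ss_res_total = 0.0
    y_heldout: list[np.ndarray] = []
    pred_heldout: list[np.ndarray] = []
    for fold, (tr, te) in enumerate(kf.split(X)):
        assignments[te] = fold
        res = _fit_once(X[tr], y[tr], w[tr], lam, link, fixed_bounds, best.x)
        fold_thetas[fold] = res.x[:k]
        pred = _predict_array(res.x, X[te], k, link, fixed_bounds)
        ss_res = float(np.sum((y[te] - pred) ** 2))
        ss_tot = float(np.sum((y[te] - np.mean(y[tr])) ** 2))
        r2_per_fold.append(1.0 - ss_res / ss_tot if ss_tot > 0 else np.nan)
        ss_res_total += ss_res
        y_heldout.append(y[te])
        pred_heldout.append(pred)
    yh = np.concatenate(y_heldout)
    ph = np.concatenate(pred_heldout)
    ss_tot = float(np.sum((yh - yh.mean()) ** 2))
    r2_pooled = 1.0 - float(np.sum((yh - ph) ** 2)) / ss_tot if ss_tot > 0 else np.nan

    theta = best.x[:k]
    if link == "linear":
        sig_params = (float("-inf"), float("inf"), 1.0)
    elif fixed_bounds is not None:
        sig_params = (fixed_bounds[0], fixed_bounds[1], 1.0)
    else:
        sig_params = (float(best.x[k]), float(best.x[k + 1]), 1.0)

    model = EnergyModel(
        first_order={t: float(v) for t, v in zip(fo_terms, theta[: len(fo_terms)])},
        couplings={p: float(v) for p, v in zip(cp_terms, theta[len(fo_terms):])},
        sigmoid=sig_params,
        order=order,
        lam=lam,
        link=link,
    )
    names = fo_terms + [f"{a}:{b}" for a, b in cp_terms]
    fold_df = pd.DataFrame(fold_thetas, columns=names)
    se = fold_df.std(axis=0, ddof=1)
    report = FitReport(
        r2_per_fold=r2_per_fold,
        r2=r2_pooled,
        fold_assignments=assignments,
        term_se={t: float(s) for t, s in se.items()},
        fold_terms=fold_df,
        converged=bool(best.success),
        n_variants=n,
        seed=seed,
        messages=[str(best.message)],
    )
    return model, report


def _predict_array(params, X, k, link, fixed_bounds):
    phi = X @ params[:k]
    if link == "linear":
        return phi
    if fixed_bounds is None:
        L, U = params[k], params[k + 1]
    else:
        L, U = fixed_bounds
    return L + (U - L) * expit(-phi)


def predict_growth(model: EnergyModel, mutations_str: str) -> float:
    """Predicted relative growth rate for a variant (deterministic)."""
    return model.predict(mutations_str)


def significance_terms(model: EnergyModel, report: FitReport) -> pd.DataFrame:
    """Z-test per term with Benjamini-Hochberg FDR across all tested terms.

    Z = term / SE with SE from across-fold dispersion; two-sided normal p;
    classes at q < 0.05: ``increase`` (term > 0), ``decrease`` (term < 0),
    else ``indistinguishable``. Terms with SE = 0 are flagged ``untestable``
    and excluded from the FDR correction.
    """
    values = {**model.first_order, **{f"{a}:{b}": v for (a, b), v in model.couplings.items()}}
    kinds = {t: "first_order" for t in model.first_order}
    kinds.update({f"{a}:{b}": "coupling" for a, b in model.couplings})
    rows = []
    for term, val in values.items():
        se = report.term_se.get(term, 0.0)
        rows.append({"term": term, "kind": kinds[term], "value": val, "se": se})
    df = pd.DataFrame(rows)
    testable = df["se"] > 0
    df["z"] = np.where(testable, df["value"] / df["se"].replace(0, np.nan), np.nan)
    df["p"] = np.where(testable, 2.0 * norm.sf(np.abs(df["z"])), np.nan)
    df["q"] = np.nan
    if testable.any():
        df.loc[testable, "q"] = multipletests(df.loc[testable, "p"], method="fdr_bh")[1]
    def classify(row):
        if not row["se"] > 0:
            return "untestable"
        if row["q"] < 0.05:
            return "increase" if row["value"] > 0 else "decrease"
        return "indistinguishable"
    df["class"] = df.apply(classify, axis=1)
    return df
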