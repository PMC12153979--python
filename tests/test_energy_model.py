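"""Encoding, sigmoid fitting, reference anchoring, term significance."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit

from amynuc.energy_model import (
    EnergyModel,
    FitReport,
    add_reference_variant,
    encode_variants,
    fit_energy_model,
    predict_growth,
    significance_terms,
)
from amynuc.library_design import paper_designs, count_model_parameters, enumerate_variants


def make_growth(mutations, gr, sigma=None):
    n = len(mutations)
    return pd.DataFrame(
        {
            "variant": [m or "WT" for m in mutations],
            "mutations": mutations,
            "gr": gr,
            "sigma": sigma if sigma is not None else [0.1] * n,
        }
    )


class TestEncoding:
    def test_wt_is_zero_vector(self):
        X, fo, cp = encode_variants(["", "I32M"], order=1)
        assert X[0].sum() == 0
        assert X[1].sum() == 1

    def test_double_mutant_order2_features(self):
        X, fo, cp = encode_variants(["I32M", "V40L", "I32M,V40L"], order=2)
        assert fo == ["I32M", "V40L"]
        assert cp == [("I32M", "V40L")]
        assert X[2].tolist() == [1.0, 1.0, 1.0]

    def test_joint_combinatorial_feature_counts(self, designs):
        # encoding the full declared space of the two combinatorial designs
        # yields 44 first-order and 640 coupling columns
        pc = count_model_parameters([designs["comb1"], designs["comb2"]], order=2)
        variants = []
        for name in ("comb1", "comb2"):
            d = designs[name]
            variants += [v.mutation_str for v in enumerate_variants(d, 2, include_wt=False)]
        X, fo, cp = encode_variants(variants, order=2)
        assert len(fo) == pc.first_order == 44
        assert len(cp) == pc.couplings == 640

    def test_unknown_mutation_rejected(self):
        with pytest.raises(KeyError, match="V40L"):
            encode_variants(["V40L"], order=1, first_order_terms=["I32M"])


class TestReferenceVariant:
    def test_appends_anchor_row(self):
        t = make_growth(["I32M"], [0.5])
        out = add_reference_variant(t)
        row = out[out["variant"] == "WT"].iloc[0]
        assert row["gr"] == 0.0 and row["sigma"] == 100.0
        assert 1 / row["sigma"] ** 2 == pytest.approx(1e-4)

    def test_idempotent(self):
        t = add_reference_variant(make_growth(["I32M"], [0.5]))
        assert len(add_reference_variant(t)) == len(t)


class TestLinearOracle:
    def test_lam_zero_matches_weighted_least_squares(self, rng):
        # identity link, lam=0: the optimizer must reproduce the closed-form
        # weighted normal equations
        terms = ["F19L", "I32M", "V40L"]
        muts = ["", "F19L", "I32M", "V40L", "F19L,I32M", "I32M,V40L", "F19L,V40L"]
        X, _, _ = encode_variants(muts, 1, first_order_terms=terms)
        theta_true = np.array([0.8, -0.4, 1.5])
        sigma = rng.uniform(0.05, 0.5, size=len(muts))
        y = X @ theta_true + rng.normal(0, sigma)
        table = make_growth(muts, y, sigma)
        model, _ = fit_energy_model(table, order=1, lam=0.0, folds=3, link="linear")
        W = np.diag(1 / sigma**2)
        closed = np.linalg.solve(X.T @ W @ X, X.T @ W @ y)
        est = np.array([model.first_order[t] for t in terms])
        np.testing.assert_allclose(est, closed, atol=1e-6)


class TestSigmoidFit:
    def test_noiseless_additive_recovery(self, rng):
        # effects inside the quasi-linear range of a known sigmoid
        terms = [f"A{p}V" for p in range(2, 12)]
        theta = rng.uniform(-0.5, 0.8, size=10)
        muts = [""] + terms + [
            f"{terms[i]},{terms[j]}" for i in range(10) for j in range(i + 1, 10)
        ]
        X, _, _ = encode_variants(muts, 1, first_order_terms=terms)
        L, U = -2.0, 2.0
        y = L + (U - L) * expit(-(X @ theta))
        table = make_growth(muts, y, [0.05] * len(muts))
        model, report = fit_energy_model(table, order=1, lam=1e-8, folds=5, seed=0)
        est = np.array([model.first_order[t] for t in terms])
        r = np.corrcoef(est, theta)[0, 1]
        assert r > 0.99
        np.testing.assert_allclose(est, theta, atol=0.05)

    def test_only_wt_synonyms_shrinks_to_zero(self):
        table = make_growth(["", "", ""], [0.0, 0.01, -0.01])
        table["variant"] = ["WT", "WTsyn1", "WTsyn2"]
        model, _ = fit_energy_model(table, order=1, folds=2, link="linear")
        assert model.first_order == {}  # no mutations -> no terms

    def test_fold_assignment_reproducible(self):
        muts = ["", "F19L", "I32M", "V40L", "F19L,I32M", "I32M,V40L"]
        table = make_growth(muts, [0, 0.2, 0.5, -0.1, 0.7, 0.4])
        _, r1 = fit_energy_model(table, folds=3, seed=42, link="linear")
        _, r2 = fit_energy_model(table, folds=3, seed=42, link="linear")
        assert (r1.fold_assignments == r2.fold_assignments).all()
        assert r1.fold_terms.equals(r2.fold_terms)

    def test_shuffling_rows_keeps_terms(self, rng):
        muts = ["", "F19L", "I32M", "V40L", "F19L,I32M", "I32M,V40L", "F19L,V40L"]
        table = make_growth(muts, [0, 0.2, 0.5, -0.1, 0.72, 0.38, 0.12])
        m1, _ = fit_energy_model(table, folds=3, seed=0, link="linear", lam=0.0)
        shuffled = table.sample(frac=1, random_state=7).reset_index(drop=True)
        m2, _ = fit_energy_model(shuffled, folds=3, seed=0, link="linear", lam=0.0)
        for t in m1.first_order:
            assert m1.first_order[t] == pytest.approx(m2.first_order[t], abs=1e-6)

    def test_nonfinite_sigma_rejected(self):
        table = make_growth(["I32M"], [0.5], [np.inf])
        with pytest.raises(ValueError, match="sigma"):
            fit_energy_model(table)


class TestPrediction:
    def _model(self):
        return EnergyModel(
            first_order={"F19L": 1.0, "I32M": 0.5},
            couplings={("F19L", "I32M"): -0.3},
            sigmoid=(-2.0, 2.0, 1.0),
            order=2,
            lam=0.0,
        )

    def test_wt_predicts_g_of_zero(self):
        m = self._model()
        assert predict_growth(m, "") == pytest.approx((-2 + 2) / 2)  # midpoint

    def test_monotone_decreasing_in_terms(self):
        m = self._model()
        assert predict_growth(m, "F19L") < predict_growth(m, "")
        assert predict_growth(m, "F19L,I32M") < predict_growth(m, "I32M")

    def test_order1_trait_additivity(self):
        m = EnergyModel(
            first_order={"F19L": 1.0, "I32M": 0.5}, couplings={},
            sigmoid=(-2, 2, 1), order=1, lam=0.0,
        )
        assert m.trait("F19L,I32M") == pytest.approx(m.trait("F19L") + m.trait("I32M"))

    def test_coupling_shifts_trait(self):
        m = self._model()
        assert m.trait("F19L,I32M") == pytest.approx(1.0 + 0.5 - 0.3)


def brute_force_bh(pvals):
    """Step-up BH oracle: adjusted p = min over j>=rank of m*p_(j)/j."""
    m = len(pvals)
    order = np.argsort(pvals)
    adj = np.empty(m)
    running = 1.0
    for rank_from_end, idx in enumerate(order[::-1]):
        j = m - rank_from_end
        running = min(running, m * pvals[idx] / j)
        adj[idx] = running
    return adj


class TestSignificance:
    def _fake(self, values, ses):
        model = EnergyModel(
            first_order={f"A{i+2}V": v for i, v in enumerate(values)},
            couplings={}, sigmoid=(-2, 2, 1), order=1, lam=0.0,
        )
        names = list(model.first_order)
        fold_terms = pd.DataFrame(np.zeros((3, len(names))), columns=names)
        report = FitReport(
            r2_per_fold=[], r2=0.0, fold_assignments=np.zeros(1, dtype=int),
            term_se=dict(zip(names, ses)), fold_terms=fold_terms,
            converged=True, n_variants=1, seed=0,
        )
        return model, report

    def test_zero_term_not_significant(self):
        model, report = self._fake([0.0], [1.0])
        df = significance_terms(model, report)
        assert df.loc[0, "p"] == pytest.approx(1.0)
        assert df.loc[0, "class"] == "indistinguishable"

    def test_z_of_1_96_gives_p_near_05(self):
        model, report = self._fake([1.96], [1.0])
        df = significance_terms(model, report)
        assert df.loc[0, "p"] == pytest.approx(0.05, abs=1e-3)

    def test_bh_matches_brute_force_oracle(self, rng):
        values = rng.normal(0, 2, size=25)
        ses = rng.uniform(0.3, 2.0, size=25)
        model, report = self._fake(values, ses)
        df = significance_terms(model, report)
        expected = brute_force_bh(df["p"].to_numpy())
        np.testing.assert_allclose(df["q"].to_numpy(), expected, atol=1e-12)

    def test_bh_textbook_example(self):
        # p = .01,.02,.03,.04 with m=4 all adjust to .04
        pvals = np.array([0.01, 0.02, 0.03, 0.04])
        np.testing.assert_allclose(brute_force_bh(pvals), [0.04] * 4)
        from statsmodels.stats.multitest import multipletests

        np.testing.assert_allclose(
            multipletests(pvals, method="fdr_bh")[1], [0.04] * 4
        )

    def test_zero_se_flagged_untestable(self):
        model, report = self._fake([1.0, 2.0], [0.0, 1.0])
        df = significance_terms(model, report)
        assert df.loc[0, "class"] == "untestable"
        assert np.isnan(df.loc[0, "q"])

    def test_classification_signs(self):
        model, report = self._fake([5.0, -5.0, 0.1], [0.1, 0.1, 1.0])
        df = significance_terms(model, report).set_index("term")
        assert df.loc["A2V", "class"] == "increase"
        assert df.loc["A3V", "class"] == "decrease"
        assert df.loc["A4V", "class"] == "indistinguishable"
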