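"""Design construction and per-gene robust MM regression."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from dcnet.io import GroupAssignment, PhenotypeTable
from dcnet.regression import (
    build_design,
    fit_all_genes,
    fit_robust,
)


@pytest.fixture
def design_inputs():
    g = np.random.default_rng(0)
    n = 12
    df = pd.DataFrame(
        {
            "smoking": [0] * 6 + [1] * 6,
            "age": g.normal(60, 5, n).round(1),
            "sex": list("FMFMFM" * 2),
            "race": ["a", "b", "c", "a", "b", "c"] * 2,
        },
        index=[f"s{i}" for i in range(n)],
    )
    pheno = PhenotypeTable(data=df, group_variable="smoking")
    asg = GroupAssignment(np.arange(6), np.arange(6, 12), (0, 1))
    return pheno, asg


class TestBuildDesign:
    def test_columns_and_order(self, design_inputs):
        pheno, asg = design_inputs
        X = build_design(pheno, asg)
        assert list(X.columns) == [
            "Intercept", "smoking", "age", "sex[M]", "race[b]", "race[c]",
        ]
        np.testing.assert_array_equal(X["smoking"], [0] * 6 + [1] * 6)

    def test_three_level_categorical_two_indicators(self, design_inputs):
        pheno, asg = design_inputs
        X = build_design(pheno, asg)
        # reference level "a" dropped; rows with race=a have both indicators 0
        assert X.loc["s0", ["race[b]", "race[c]"]].sum() == 0
        assert X.loc["s1", "race[b]"] == 1

    def test_duplicated_covariate_rank_deficient(self, design_inputs):
        pheno, asg = design_inputs
        pheno.data["age2"] = pheno.data["age"]
        pheno.numeric_columns.append("age2")
        with pytest.raises(ValueError, match="rank deficient.*age"):
            build_design(pheno, asg)


class TestFitRobust:
    def test_perfect_fit_flagged(self):
        g = np.random.default_rng(1)
        X = np.column_stack([np.ones(20), g.normal(size=20)])
        y = 2.0 + 3.0 * X[:, 1]
        fit = fit_robust(y, X)
        assert fit.flag == "perfect_fit"
        np.testing.assert_allclose(fit.params, [2.0, 3.0], atol=1e-8)
        np.testing.assert_array_equal(fit.pvalues, [0.0, 0.0])

    def test_clean_gaussian_close_to_ols(self):
        g = np.random.default_rng(2)
        n = 200
        X = np.column_stack([np.ones(n), g.normal(size=n), g.normal(size=n)])
        y = 1.0 + 2.0 * X[:, 1] - 0.5 * X[:, 2] + g.normal(size=n)
        fit = fit_robust(y, X)
        ols = sm.OLS(y, X).fit()
        assert fit.flag is None
        assert np.all(np.abs(fit.params - ols.params) < 2 * fit.bse)

    def test_outlier_resistance(self):
        """10% gross outliers move the LS slope but not the MM slope."""
        g = np.random.default_rng(3)
        n = 200
        x = g.normal(size=n)
        y = 1.0 + 2.0 * x + g.normal(size=n)
        X = np.column_stack([np.ones(n), x])
        clean_slope = fit_robust(y, X).params[1]
        y_out = y.copy()
        top = np.argsort(x)[-n // 10:]  # corrupt high-leverage side
        y_out[top] += 50.0
        fit = fit_robust(y_out, X)
        ols = sm.OLS(y_out, X).fit()
        assert abs(fit.params[1] - clean_slope) < 2 * fit.bse[1]
        assert abs(ols.params[1] - clean_slope) > 2 * fit.bse[1]

    def test_equal_weights_reduce_to_ols(self):
        """With all residuals of equal magnitude the IRLS fixed point is OLS."""
        x = np.array([0.0, 0.0, 1.0, 1.0, 2.0, 2.0, 3.0, 3.0])
        d = 0.5
        y = 1.0 + 2.0 * x + np.tile([d, -d], 4)
        X = np.column_stack([np.ones_like(x), x])
        fit = fit_robust(y, X)
        ols = sm.OLS(y, X).fit()
        np.testing.assert_allclose(fit.params, ols.params, atol=1e-8)

    def test_underdetermined_rejected(self):
        with pytest.raises(ValueError, match="n > design"):
            fit_robust(np.zeros(2), np.ones((2, 2)))


class TestFitAllGenes:
    def _setup(self, seed=4):
        g = np.random.default_rng(seed)
        n, p = 40, 5
        design = pd.DataFrame(
            {
                "Intercept": np.ones(n),
                "group": np.repeat([0.0, 1.0], n // 2),
                "age": g.normal(size=n),
            },
            index=[f"s{i}" for i in range(n)],
        )
        psv = pd.DataFrame(
            g.normal(size=(n, p)),
            index=design.index,
            columns=[f"g{j}" for j in range(p)],
        )
        return psv, design

    def test_shapes_and_predictors(self):
        psv, design = self._setup()
        res = fit_all_genes(psv, design, group_predictor="group")
        assert res.coefficients.shape == (5, 2)
        assert res.predictor_names == ["group", "age"]
        assert ((res.pvalues >= 0) & (res.pvalues <= 1)).all().all()

    def test_gene_permutation_equivariance(self):
        psv, design = self._setup()
        res1 = fit_all_genes(psv, design, group_predictor="group")
        perm = ["g3", "g0", "g4", "g1", "g2"]
        res2 = fit_all_genes(psv[perm], design, group_predictor="group")
        pd.testing.assert_frame_equal(res1.coefficients.loc[perm], res2.coefficients)

    def test_constant_gene_flagged_not_fatal(self):
        psv, design = self._setup()
        psv["g2"] = 7.0
        res = fit_all_genes(psv, design, group_predictor="group")
        assert res.flags.get("g2") == "perfect_fit"
        assert res.pvalues.loc["g2", "group"] == 1.0

    def test_misaligned_rows_rejected(self):
        psv, design = self._setup()
        with pytest.raises(ValueError, match="aligned"):
            fit_all_genes(psv.iloc[::-1], design, group_predictor="group")
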