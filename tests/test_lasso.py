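"""L1 regression: closed-form and direct-minimizer oracles, ranking rules."""

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import minimize

from methdrug.io import Modality, OmicsMatrix, ValidationError
from methdrug.lasso import (
    LassoFit,
    fit_drug_lasso,
    filter_drugs_by_pcc,
    select_sites,
)


def _beta_matrix(n_cells, p, seed=0, ids=None):
    rng = np.random.default_rng(seed)
    values = rng.random((p, n_cells))
    ids = ids or [f"chrS1: {1 + 3000 * i}-{2000 + 3000 * i}" for i in range(p)]
    cells = [f"c{i}" for i in range(n_cells)]
    return OmicsMatrix(Modality.METHYLATION, ids, cells, values)


class TestFitDrugLasso:
    def test_huge_penalty_full_shrinkage(self):
        beta = _beta_matrix(30, 5)
        y = np.random.default_rng(1).random(30)
        fit = fit_drug_lasso(beta, y, lambda_grid=[1e6])
        assert fit.n_nonzero == 0
        assert fit.intercept == pytest.approx(y.mean(), abs=1e-10)

    def test_zero_penalty_matches_ols_normal_equations(self):
        beta = _beta_matrix(30, 5, seed=2)
        rng = np.random.default_rng(3)
        y = rng.random(30)
        fit = fit_drug_lasso(beta, y, lambda_grid=[0.0])
        Xs = (beta.values.T - fit.feature_means) / fit.feature_scales
        A = np.hstack([Xs, np.ones((30, 1))])
        w = np.linalg.solve(A.T @ A, A.T @ y)
        np.testing.assert_allclose(fit.coef, w[:-1], atol=1e-8)
        assert fit.intercept == pytest.approx(w[-1], abs=1e-8)

    def test_objective_descent_vs_zero(self):
        beta = _beta_matrix(40, 8, seed=4)
        rng = np.random.default_rng(5)
        y = beta.values[0] * 0.5 + rng.normal(0, 0.1, 40)
        fit = fit_drug_lasso(beta, y, seed=0)
        Xs = (beta.values.T - fit.feature_means) / fit.feature_scales
        at_solution = fit.objective_value(Xs, y)
        at_zero = fit.objective_value(Xs, y, coef=np.zeros(8), intercept=y.mean())
        assert at_solution <= at_zero + 1e-12

    def test_l1_norm_monotone_along_penalty_grid(self):
        beta = _beta_matrix(40, 6, seed=6)
        rng = np.random.default_rng(7)
        y = beta.values[1] - 0.4 * beta.values[3] + rng.normal(0, 0.05, 40)
        lambdas = np.geomspace(1.0, 1e-4, 12)
        norms = [
            np.abs(fit_drug_lasso(beta, y, lambda_grid=[lam]).coef).sum() for lam in lambdas
        ]
        assert all(a <= b + 1e-10 for a, b in zip(norms, norms[1:]))

    @pytest.mark.parametrize("lam_total", [0.5, 2.0, 10.0])
    def test_matches_direct_minimizer_small_p(self, lam_total):
        """Coordinate descent vs scipy minimization of sum(y-Wx)^2 + lam*||W||_1."""
        n, p = 25, 4
        beta = _beta_matrix(n, p, seed=8)
        rng = np.random.default_rng(9)
        y = 0.8 * beta.values[0] + rng.normal(0, 0.1, n)
        alpha = lam_total / (2 * n)
        fit = fit_drug_lasso(beta, y, lambda_grid=[alpha])
        Xs = (beta.values.T - fit.feature_means) / fit.feature_scales

        def objective(z):
            w, b = z[:p], z[p]
            r = y - Xs @ w - b
            return r @ r + fit.lambda_total * np.abs(w).sum()

        best = np.inf
        for start_seed in range(5):
            z0 = np.random.default_rng(start_seed).normal(0, 0.3, p + 1)
            res = minimize(objective, z0, method="Nelder-Mead", options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 20000})
            best = min(best, res.fun)
        ours = fit.objective_value(Xs, y)
        assert ours <= best + 1e-4

    def test_constant_response_rejected(self):
        beta = _beta_matrix(20, 3)
        with pytest.raises(ValidationError, match="constant"):
            fit_drug_lasso(beta, np.full(20, 0.5))

    def test_too_few_cells_rejected(self):
        beta = _beta_matrix(5, 3)
        with pytest.raises(ValidationError, match="10 cells"):
            fit_drug_lasso(beta, np.random.default_rng(0).random(5))

    def test_negative_grid_rejected(self):
        beta = _beta_matrix(20, 3)
        with pytest.raises(ValidationError, match="grid"):
            fit_drug_lasso(beta, np.random.default_rng(0).random(20), lambda_grid=[-1.0])


def _fit_with_coef(coef, ids=None, pcc_cv=0.8, pcc_in=0.9):
    coef = np.asarray(coef, float)
    p = len(coef)
    ids = ids or [f"chrS1: {1 + 3000 * i}-{2000 + 3000 * i}" for i in range(p)]
    return LassoFit(
        drug_id="d",
        cpg_ids=ids,
        coef=coef,
        intercept=0.0,
        alpha=0.1,
        alpha_grid=np.array([0.1]),
        cv_mse=np.array([0.0]),
        pcc_insample=pcc_in,
        pcc_cv=pcc_cv,
        n_cells=50,
        feature_means=np.zeros(p),
        feature_scales=np.ones(p),
    )


class TestFilterDrugs:
    def test_strict_threshold(self):
        fits = [_fit_with_coef([1.0], pcc_cv=p) for p in (0.72, 0.70, 0.65)]
        kept, bins = filter_drugs_by_pcc(fits, threshold=0.7)
        assert len(kept) == 1 and kept[0].pcc_cv == 0.72
        assert bins[">0.7"] == 1 and bins["0.5-0.7"] == 2

    def test_empty_input(self):
        kept, bins = filter_drugs_by_pcc([])
        assert kept == [] and sum(bins.values()) == 0

    def test_bins_partition(self):
        pccs = [-0.2, 0.05, 0.15, 0.35, 0.55, 0.75, 0.95]
        _, bins = filter_drugs_by_pcc([_fit_with_coef([1.0], pcc_cv=p) for p in pccs])
        assert sum(bins.values()) == len(pccs)
        assert bins["<0.1"] == 2

    def test_insample_flavor(self):
        fits = [_fit_with_coef([1.0], pcc_cv=0.1, pcc_in=0.9)]
        kept_cv, _ = filter_drugs_by_pcc(fits, flavor="cv")
        kept_in, _ = filter_drugs_by_pcc(fits, flavor="insample")
        assert kept_cv == [] and len(kept_in) == 1


class TestSelectSites:
    def test_top_n_cap(self):
        fit = _fit_with_coef(np.linspace(1, 0.01, 150))
        sel = select_sites(fit, n=100)
        assert len(sel.records) == 100
        assert sel.records["rank"].tolist() == list(range(1, 101))

    def test_fewer_nonzero_than_n(self):
        fit = _fit_with_coef([0.5, 0.0, -0.3, 0.0, 0.1, 0.0, 0.2, 0.0, -0.9, 0.0])
        sel = select_sites(fit, n=100)
        assert len(sel.records) == 5  # only the nonzero ones
        assert (sel.records["coefficient"].abs().diff().dropna() <= 1e-12).all()

    def test_tie_broken_by_genomic_coordinate(self):
        ids = ["chrS1: 9001-9500", "chrS1: 1-500", "chrS1: 5001-5500"]
        fit = _fit_with_coef([0.5, -0.5, 0.9], ids=ids)
        sel = select_sites(fit)
        assert sel.records["cpg_id"].tolist() == [
            "chrS1: 5001-5500",  # |0.9| first
            "chrS1: 1-500",  # tie at |0.5|: earlier coordinate wins
            "chrS1: 9001-9500",
        ]

    def test_all_zero_fit_warns_empty(self):
        fit = _fit_with_coef([0.0, 0.0])
        with pytest.warns(RuntimeWarning, match="all-zero"):
            sel = select_sites(fit)
        assert len(sel.records) == 0
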