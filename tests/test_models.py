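"""Phylogenetic GLS: OLS limits, likelihood behaviour, invariances, oracles."""

import numpy as np
import pandas as pd
import pytest
from sklearn.base import clone

from hormonescan.models import PhyloGLS, SingularModelError, fit_pgls, model_ssd, qc_n50
from hormonescan.phylo import pagel_transform, phylo_vcv, tip_labels
from hormonescan.simulate import SimulationConfig, sim_tree, simulate_species_dataset
from hormonescan.traits import build_species_table

# fixed 8-species fixture; reference values computed independently with
# R nlme::gls + ape::corPagel (lambda fixed at 0.7, method="ML")
FIXTURE_X1 = np.array([0.304717, -1.039984, 0.750451, 0.940565,
                       -1.951035, -1.30218, 0.12784, -0.316243])
FIXTURE_X2 = np.array([-0.016801, -0.853044, 0.879398, 0.777792,
                       0.066031, 1.127241, 0.467509, -0.859292])
FIXTURE_Y = np.array([0.294819, -1.159458, 0.913063, 0.679711,
                      -1.035789, -0.597745, 0.418995, -0.486377])
R_GLS_COEF = np.array([0.0236354026, 0.6803862156, 0.3058035758])
R_GLS_LOGLIK = 2.31059466


def ols(design, y):
    return np.linalg.solve(design.T @ design, design.T @ y)


@pytest.fixture
def fixture_C():
    tree = sim_tree(8, 1.0, seed=11)
    C, labels = phylo_vcv(tree)
    return C


class TestOLSLimits:
    def test_lambda_zero_equals_ols_on_any_tree(self, rng):
        for _ in range(20):
            n = int(rng.integers(10, 60))
            tree = sim_tree(n, seed=int(rng.integers(0, 2**16)))
            C, _ = phylo_vcv(tree)
            X = rng.normal(size=(n, 2))
            y = rng.normal(size=n)
            est = PhyloGLS(lam=0.0).fit(X, y, C=C)
            expected = ols(np.column_stack([np.ones(n), X]), y)
            assert np.allclose(est.params_.to_numpy(), expected, atol=1e-8)

    def test_star_tree_equals_ols_for_any_lambda(self, rng):
        n = 30
        C = 2.5 * np.eye(n)  # all tips equidistant, no shared branches
        X = rng.normal(size=(n, 2))
        y = X @ [0.5, -0.2] + rng.normal(size=n)
        expected = ols(np.column_stack([np.ones(n), X]), y)
        for lam in (0.0, 0.5, 1.0, "ML"):
            est = PhyloGLS(lam=lam).fit(X, y, C=C)
            assert np.allclose(est.params_.to_numpy(), expected, atol=1e-8)

    def test_lambda_zero_r_squared_matches_ols_r_squared(self, rng):
        n = 40
        X = rng.normal(size=(n, 2))
        y = X @ [1.0, 0.5] + rng.normal(size=n)
        est = PhyloGLS(lam=0.0).fit(X, y, C=np.eye(n))
        resid = y - est.predict(X)
        r2_ols = 1 - resid @ resid / ((y - y.mean()) @ (y - y.mean()))
        assert est.r_squared_ == pytest.approx(r2_ols, abs=1e-10)


def test_matches_r_gls_corpagel_oracle(fixture_C):
    est = PhyloGLS(lam=0.7).fit(
        np.column_stack([FIXTURE_X1, FIXTURE_X2]), FIXTURE_Y, C=fixture_C
    )
    assert np.allclose(est.params_.to_numpy(), R_GLS_COEF, atol=1e-7)
    assert est.loglik_ == pytest.approx(R_GLS_LOGLIK, abs=1e-6)


def test_ml_lambda_matches_r_on_simulated_dataset():
    # frozen from R nlme::gls + ape::corPagel (unconstrained ML, which here
    # lands inside [0, 1]) on the dataset this exact configuration generates
    ds = simulate_species_dataset(SimulationConfig(seed=17, n_species=48))
    table = build_species_table(ds.traits, ds.counts, tip_labels(ds.tree))
    fit = model_ssd(table, ds.tree, "ARE", lam="ML", min_n=20)
    assert fit.lam == pytest.approx(0.463323, abs=1e-4)
    assert fit.params.to_numpy() == pytest.approx(
        [0.28993408, 0.41730726, 0.26370632], abs=1e-5
    )
    assert fit.loglik == pytest.approx(7.020852, abs=1e-4)


class TestLikelihoodAndInvariances:
    def _data(self, rng, n=40, lam=0.6):
        tree = sim_tree(n, seed=7)
        C, _ = phylo_vcv(tree)
        X = rng.normal(size=(n, 2))
        L = np.linalg.cholesky(pagel_transform(C, lam) + 1e-12 * np.eye(n))
        y = X @ [0.5, 0.3] + 0.5 * (L @ rng.standard_normal(n))
        return X, y, C

    def test_profile_optimum_beats_endpoints(self, rng):
        X, y, C = self._data(rng)
        ml = PhyloGLS(lam="ML").fit(X, y, C=C)
        for lam in (0.0, 1.0):
            fixed = PhyloGLS(lam=lam).fit(X, y, C=C)
            assert ml.loglik_ >= fixed.loglik_ - 1e-9

    def test_branch_length_rescaling_is_absorbed_by_sigma2(self, rng):
        X, y, C = self._data(rng)
        a = PhyloGLS(lam="ML").fit(X, y, C=C)
        b = PhyloGLS(lam="ML").fit(X, y, C=37.0 * C)
        assert np.allclose(a.params_, b.params_, atol=1e-6)
        assert np.allclose(a.tvalues_, b.tvalues_, atol=1e-5)
        assert a.lambda_ == pytest.approx(b.lambda_, abs=1e-5)
        assert a.r_squared_ == pytest.approx(b.r_squared_, abs=1e-8)
        assert b.sigma2_ == pytest.approx(a.sigma2_ / 37.0, rel=1e-5)

    def test_shifting_response_moves_only_the_intercept(self, rng):
        X, y, C = self._data(rng)
        a = PhyloGLS(lam=0.5).fit(X, y, C=C)
        b = PhyloGLS(lam=0.5).fit(X, y + 10.0, C=C)
        assert b.intercept_ == pytest.approx(a.intercept_ + 10.0, abs=1e-8)
        assert np.allclose(a.coef_, b.coef_, atol=1e-10)

    def test_brownian_recovery_light(self, rng):
        # mean slope estimates near truth under lambda=1 noise (small batch;
        # the full pre-registered grid runs in the acceptance suite)
        betas = []
        for rep in range(10):
            n = 128
            tree = sim_tree(n, seed=100 + rep)
            C, _ = phylo_vcv(tree)
            X = rng.normal(size=(n, 2))
            L = np.linalg.cholesky(C + 1e-12 * np.eye(n))
            y = X @ [0.5, 0.3] + 0.4 * (L @ rng.standard_normal(n))
            est = PhyloGLS(lam="ML").fit(X, y, C=C)
            betas.append(est.coef_)
        mean = np.mean(betas, axis=0)
        assert np.allclose(mean, [0.5, 0.3], atol=0.05)


class TestErrorsAndProtocol:
    def test_singular_design_rejected(self, rng):
        n = 20
        X = np.column_stack([np.ones(n), np.ones(n) * 3.0])  # collinear
        with pytest.raises((SingularModelError, np.linalg.LinAlgError)):
            PhyloGLS(lam=0.0).fit(X, rng.normal(size=n), C=np.eye(n))

    def test_too_few_species_rejected(self):
        with pytest.raises(ValueError, match="at least"):
            PhyloGLS().fit(np.ones((3, 2)), np.ones(3), C=np.eye(3))

    def test_sklearn_protocol(self, rng):
        est = PhyloGLS(lam=0.5, jitter=True)
        assert clone(est).get_params() == est.get_params()
        n = 12
        X = rng.normal(size=(n, 2))
        y = rng.normal(size=n)
        est.fit(X, y, C=np.eye(n))
        assert est.predict(X).shape == (n,)
        assert est.params_.index.tolist() == ["intercept", "x0", "x1"]

    def test_fit_pgls_wrapper_uses_design_as_given(self, rng):
        n = 15
        design = np.column_stack([np.ones(n), rng.normal(size=n)])
        y = rng.normal(size=n)
        res = fit_pgls(y, design, np.eye(n), lam=0.0, names=["const", "slope"])
        assert res.params.index.tolist() == ["const", "slope"]
        assert np.allclose(res.params.to_numpy(), ols(design, y), atol=1e-10)


class TestNamedAnalyses:
    def _dataset(self, seed=23, n=40, **kw):
        ds = simulate_species_dataset(SimulationConfig(seed=seed, n_species=n, **kw))
        table = build_species_table(ds.traits, ds.counts, tip_labels(ds.tree))
        return ds, table

    def test_model_ssd_refuses_small_samples(self):
        ds, table = self._dataset()
        with pytest.raises(ValueError, match="minimum"):
            model_ssd(table.head(10), ds.tree, min_n=20)

    def test_model_ssd_constant_counts_is_singular(self):
        ds, table = self._dataset()
        table = table.copy()
        table["ln_are"] = 1.0
        with pytest.raises((SingularModelError, np.linalg.LinAlgError)):
            model_ssd(table, ds.tree, min_n=20)

    def test_model_ssd_unknown_class_rejected(self):
        ds, table = self._dataset()
        with pytest.raises(ValueError, match="hre_class"):
            model_ssd(table, ds.tree, hre_class="XRE")

    def test_qc_n50_requires_n50_column(self):
        ds, table = self._dataset()
        with pytest.raises(ValueError, match="n50"):
            qc_n50(table.drop(columns=["ln_n50", "contig_n50"]), ds.tree)

    def test_qc_n50_recovers_planted_quality_confounding(self):
        # counts constructed to increase with N50 -> positive slope, small p
        ds, table = self._dataset(seed=31, n=64, n50_slope=0.8)
        fit = qc_n50(table, ds.tree, hre_class="ARE")
        assert fit.params["ln_n50"] > 0
        assert fit.pvalues["ln_n50"] < 1e-3

    def test_qc_n50_null_is_quiet(self):
        rejections = 0
        for seed in range(10):
            ds, table = self._dataset(seed=200 + seed, n=48, n50_slope=0.0)
            fit = qc_n50(table, ds.tree, hre_class="ARE")
            rejections += fit.pvalues["ln_n50"] < 0.05
        assert rejections <= 2
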