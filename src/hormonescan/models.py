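"""Phylogenetically controlled linear models and phylogenetic PCA.

The headline model is generalized least squares with residual covariance
``sigma^2 * V(lambda)`` where ``V(lambda)`` is the Brownian-motion
covariance of the phylogeny with its off-diagonal shrunk by Pagel's
lambda.  Lambda is estimated by maximizing the profile log-likelihood
over [0, 1]; at each candidate lambda the GLS solution is analytic:

    beta_hat = (X' V^-1 X)^-1 X' V^-1 y
    sigma2_hat = r' V^-1 r / n                      (ML)
    loglik = -(n log(2 pi sigma2_hat) + log|V| + n) / 2

Standard errors use the small-sample correction ``sigma2_hat * n/(n-p)``
on ``(X' V^-1 X)^-1`` and p-values come from a two-sided t with ``n - p``
degrees of freedom.  The phylogenetic R^2 is a deviance ratio in the
V-metric against the GLS intercept-only fit.

:class:`PhyloGLS` and :class:`PhyloPCA` follow the scikit-learn estimator
protocol (``fit``/``predict``/``transform``, ``get_params``); the
module-level functions :func:`fit_pgls`, :func:`model_ssd`,
:func:`qc_n50` and :func:`phylo_pca` are thin wrappers over them.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import dendropy
import numpy as np
import pandas as pd
from scipy import linalg, optimize, stats
from sklearn.base import BaseEstimator, RegressorMixin, TransformerMixin
from sklearn.utils.validation import check_array, check_is_fitted

from .phylo import pagel_transform, phylo_vcv, prune

logger = logging.getLogger(__name__)

_LAMBDA_XATOL = 1e-8


class SingularModelError(np.linalg.LinAlgError):
    """Design matrix or covariance is (near-)singular."""


def _chol(V: np.ndarray, jitter: bool):
    try:
        return linalg.cho_factor(V, lower=True)
    except np.linalg.LinAlgError:
        if not jitter:
            raise SingularModelError(
                "phylogenetic covariance is not positive definite; "
                "pass jitter=True to add 1e-10 * mean(diag)"
            ) from None
        V = V + 1e-10 * np.mean(np.diag(V)) * np.eye(len(V))
        return linalg.cho_factor(V, lower=True)


def _gls_core(y: np.ndarray, X: np.ndarray, V: np.ndarray, jitter: bool):
    """Analytic GLS at a fixed covariance V.  Returns a dict of pieces."""
    n, p = X.shape
    cf = _chol(V, jitter)
    logdet = 2.0 * np.sum(np.log(np.diag(cf[0])))
    Vi_X = linalg.cho_solve(cf, X)
    Vi_y = linalg.cho_solve(cf, y)
    XtViX = X.T @ Vi_X
    # reject numerically singular designs before inverting
    if np.linalg.cond(XtViX) > 1e12:
        raise SingularModelError("singular design matrix (condition number > 1e12)")
    try:
        XtViX_inv = linalg.inv(XtViX)
    except np.linalg.LinAlgError as exc:
        raise SingularModelError("singular design matrix") from exc
    beta = XtViX_inv @ (X.T @ Vi_y)
    resid = y - X @ beta
    rss = float(resid @ linalg.cho_solve(cf, resid))
    sigma2 = rss / n
    if sigma2 <= 0:
        sigma2 = np.finfo(float).tiny
    loglik = -0.5 * (n * np.log(2.0 * np.pi * sigma2) + logdet + n)
    return {
        "beta": beta, "resid": resid, "rss": rss, "sigma2": sigma2,
        "loglik": loglik, "XtViX_inv": XtViX_inv, "chol": cf,
    }


@dataclass
class PhyloGLSFit:
    """Result of one phylogenetic GLS fit."""

    params: pd.Series
    se: pd.Series
    tvalues: pd.Series
    pvalues: pd.Series
    lam: float
    sigma2: float
    loglik: float
    r_squared: float
    n: int
    df_resid: int
    names: list[str] = field(default_factory=list)

    def to_row(self, **extra) -> dict:
        """Flat dict for tabular export (one model per row)."""
        row = dict(extra)
        row.update(n=self.n, lambda_=self.lam, r_squared=self.r_squared,
                   loglik=self.loglik, sigma2=self.sigma2)
        for name in self.params.index:
            row[f"effect_{name}"] = self.params[name]
            row[f"p_{name}"] = self.pvalues[name]
        return row


class PhyloGLS(RegressorMixin, BaseEstimator):
    """Phylogenetic GLS regression with ML Pagel's lambda.

    Parameters
    ----------
    lam : "ML" or float in [0, 1]
        ``"ML"`` maximizes the profile likelihood over lambda; a float
        fixes it (0 recovers ordinary least squares on any tree).
    fit_intercept : bool
        Prepend a constant column to the design.
    jitter : bool
        Add ``1e-10 * mean(diag)`` to a non-positive-definite covariance
        instead of raising.

    Attributes (after ``fit``)
    --------------------------
    coef_, intercept_ : slopes and intercept
    params_, bse_, tvalues_, pvalues_ : full coefficient vector and tests
    lambda_, sigma2_, loglik_, r_squared_ : model-level quantities
    """

    def __init__(self, lam: float | str = "ML", fit_intercept: bool = True,
                 jitter: bool = False):
        self.lam = lam
        self.fit_intercept = fit_intercept
        self.jitter = jitter

    def fit(self, X, y, C=None, feature_names: Sequence[str] | None = None):
        X = check_array(X, ensure_2d=True, dtype=float)
        y = np.asarray(y, dtype=float).ravel()
        n = len(y)
        if X.shape[0] != n:
            raise ValueError(f"X has {X.shape[0]} rows but y has {n}")
        if C is None:
            C = np.eye(n)
        C = np.asarray(C, dtype=float)
        if C.shape != (n, n):
            raise ValueError(f"C must be ({n}, {n}), got {C.shape}")
        if not np.allclose(C, C.T):
            raise ValueError("C must be symmetric")

        if self.fit_intercept:
            design = np.column_stack([np.ones(n), X])
        else:
            design = X
        p = design.shape[1]
        if n < p + 2:
            raise ValueError(f"need at least p + 2 = {p + 2} species, got {n}")

        if self.lam == "ML":
            lam_hat, core = self._profile_ml(y, design, C)
        else:
            lam_hat = float(self.lam)
            core = _gls_core(y, design, pagel_transform(C, lam_hat), self.jitter)

        V = pagel_transform(C, lam_hat)
        # intercept-only baseline in the same metric, for phylogenetic R^2
        base = _gls_core(y, np.ones((n, 1)), V, self.jitter)
        tss = base["rss"]
        r2 = 1.0 - core["rss"] / tss if tss > 0 else 0.0
        if design.shape[1] == 1 and self.fit_intercept is False:
            r2 = max(r2, 0.0)
        r2 = float(np.clip(r2, 0.0, 1.0))

        df = n - p
        se = np.sqrt(np.diag(core["XtViX_inv"]) * core["sigma2"] * n / df)
        tvals = core["beta"] / se
        pvals = 2.0 * stats.t.sf(np.abs(tvals), df)

        if feature_names is None:
            feature_names = [f"x{i}" for i in range(X.shape[1])]
        names = (["intercept"] if self.fit_intercept else []) + list(feature_names)

        self.n_features_in_ = X.shape[1]
        self.params_ = pd.Series(core["beta"], index=names)
        self.bse_ = pd.Series(se, index=names)
        self.tvalues_ = pd.Series(tvals, index=names)
        self.pvalues_ = pd.Series(np.clip(pvals, np.finfo(float).tiny, 1.0), index=names)
        self.lambda_ = float(lam_hat)
        self.sigma2_ = float(core["sigma2"])
        self.loglik_ = float(core["loglik"])
        self.r_squared_ = r2
        self.nobs_ = n
        self.df_resid_ = df
        if self.fit_intercept:
            self.intercept_ = float(core["beta"][0])
            self.coef_ = core["beta"][1:]
        else:
            self.intercept_ = 0.0
            self.coef_ = core["beta"]
        return self

    def _profile_ml(self, y, design, C):
        def negloglik(lam):
            try:
                return -_gls_core(y, design, pagel_transform(C, lam), self.jitter)["loglik"]
            except SingularModelError:
                return np.inf

        res = optimize.minimize_scalar(
            negloglik, bounds=(0.0, 1.0), method="bounded",
            options={"xatol": _LAMBDA_XATOL},
        )
        if not res.success:
            raise RuntimeError(f"lambda optimization failed: {res}")
        # the bounded optimizer can miss a boundary optimum; check both ends
        candidates = [(negloglik(0.0), 0.0), (negloglik(1.0), 1.0), (res.fun, float(res.x))]
        best = min(candidates, key=lambda t: t[0])
        lam_hat = best[1]
        core = _gls_core(y, design, pagel_transform(C, lam_hat), self.jitter)
        return lam_hat, core

    def predict(self, X):
        check_is_fitted(self, "coef_")
        X = check_array(X, ensure_2d=True, dtype=float)
        return X @ self.coef_ + self.intercept_

    def result_(self) -> PhyloGLSFit:
        check_is_fitted(self, "coef_")
        return PhyloGLSFit(
            params=self.params_, se=self.bse_, tvalues=self.tvalues_,
            pvalues=self.pvalues_, lam=self.lambda_, sigma2=self.sigma2_,
            loglik=self.loglik_, r_squared=self.r_squared_, n=self.nobs_,
            df_resid=self.df_resid_, names=list(self.params_.index),
        )


def fit_pgls(
    y: np.ndarray,
    X: np.ndarray,
    C: np.ndarray,
    lam: float | str = "ML",
    names: Sequence[str] | None = None,
    jitter: bool = False,
) -> PhyloGLSFit:
    """GLS fit of a pre-built design matrix (no intercept added)."""
    est = PhyloGLS(lam=lam, fit_intercept=False, jitter=jitter)
    est.fit(X, y, C=C, feature_names=names)
    return est.result_()


# ---------------------------------------------------------------------------
# named analyses


def _table_fit(
    table: pd.DataFrame,
    tree: dendropy.Tree,
    y_col: str,
    x_cols: Sequence[str],
    lam: float | str,
    jitter: bool = False,
) -> PhyloGLSFit:
    species = list(table["species"])
    sub = prune(tree, species)
    C, _ = phylo_vcv(sub, order=species)
    est = PhyloGLS(lam=lam, fit_intercept=True, jitter=jitter)
    est.fit(table[list(x_cols)].to_numpy(float), table[y_col].to_numpy(float),
            C=C, feature_names=list(x_cols))
    return est.result_()


def model_ssd(
    table: pd.DataFrame,
    tree: dendropy.Tree,
    hre_class: str = "ARE",
    flank: int | None = None,
    lam: float | str = "ML",
    order: str | None = None,
    min_n: int = 20,
    jitter: bool = False,
) -> PhyloGLSFit:
    """The headline model: SSD ~ ln(HRE count) + ln(body size), PGLS.

    ``order`` restricts to one taxonomic order (per-order fits are run
    independently, never with order as a covariate).  Fewer than ``min_n``
    species is a refusal, not a fit.
    """
    sub = table
    if flank is not None and "flank" in sub.columns:
        sub = sub[sub["flank"] == flank]
    if order is not None:
        if "order" not in sub.columns:
            raise ValueError("table has no 'order' column")
        sub = sub[sub["order"] == order]
    sub = sub.reset_index(drop=True)
    if len(sub) < min_n:
        raise ValueError(
            f"only {len(sub)} species available (order={order!r}); "
            f"minimum is {min_n}"
        )
    count_col = "ln_are" if hre_class == "ARE" else "ln_ere"
    if hre_class not in ("ARE", "ERE"):
        raise ValueError(f"hre_class must be ARE or ERE, got {hre_class!r}")
    return _table_fit(sub, tree, "ssd", [count_col, "ln_body"], lam, jitter)


def qc_n50(
    table: pd.DataFrame,
    tree: dendropy.Tree,
    hre_class: str = "ARE",
    flank: int | None = None,
    lam: float | str = "ML",
) -> PhyloGLSFit:
    """Genome-quality check: ln(HRE count) ~ ln(contig N50), PGLS.

    The slope sign shows whether lower-quality assemblies carry more HREs.
    """
    if "ln_n50" not in table.columns:
        raise ValueError("table has no contig_n50 / ln_n50 column")
    sub = table
    if flank is not None and "flank" in sub.columns:
        sub = sub[sub["flank"] == flank]
    sub = sub.reset_index(drop=True)
    count_col = "ln_are" if hre_class == "ARE" else "ln_ere"
    return _table_fit(sub, tree, count_col, ["ln_n50"], lam)


# ---------------------------------------------------------------------------
# phylogenetic PCA


class PhyloPCA(TransformerMixin, BaseEstimator):
    """PCA of the evolutionary (GLS-estimated) trait covariance.

    Traits are centered on the phylogenetic (GLS) mean
    ``a = (1' C^-1 1)^-1 1' C^-1 X`` and the evolutionary covariance
    ``R = (X - 1a)' C^-1 (X - 1a) / (n - 1)`` is eigen-decomposed.
    Scores are ``(X - 1a) @ eigenvectors``.  Under Brownian motion
    ``lam = 1`` (the default); a different fixed lambda rescales C first.

    Attributes
    ----------
    components_ : (k, p) eigenvector rows, sorted by descending eigenvalue,
        sign-fixed so each row's largest-magnitude loading is positive.
    explained_variance_ : eigenvalues of R.
    mean_ : the GLS mean vector a.
    """

    def __init__(self, lam: float = 1.0, jitter: bool = False):
        self.lam = lam
        self.jitter = jitter

    def fit(self, X, y=None, C=None):
        X = check_array(X, ensure_2d=True, dtype=float)
        n, p = X.shape
        if C is None:
            C = np.eye(n)
        C = pagel_transform(np.asarray(C, dtype=float), self.lam)
        cf = _chol(C, self.jitter)
        ones = np.ones((n, 1))
        Ci1 = linalg.cho_solve(cf, ones)
        a = (Ci1.T @ X) / (ones.T @ Ci1).item()
        centered = X - a
        R = centered.T @ linalg.cho_solve(cf, centered) / (n - 1)
        evals, evecs = np.linalg.eigh(R)
        order = np.argsort(evals)[::-1]
        evals, evecs = evals[order], evecs[:, order]
        # fix sign: largest-magnitude loading positive in every component
        for j in range(p):
            k = np.argmax(np.abs(evecs[:, j]))
            if evecs[k, j] < 0:
                evecs[:, j] = -evecs[:, j]
        self.mean_ = a.ravel()
        self.components_ = evecs.T
        self.explained_variance_ = evals
        self.n_features_in_ = p
        self.nobs_ = n
        return self

    def transform(self, X):
        check_is_fitted(self, "components_")
        X = check_array(X, ensure_2d=True, dtype=float)
        return (X - self.mean_) @ self.components_.T

    def fit_transform(self, X, y=None, **fit_params):
        return self.fit(X, **fit_params).transform(X)


def phylo_pca(
    counts: pd.DataFrame,
    tree: dendropy.Tree,
    transform: str = "log10",
    lam: float = 1.0,
) -> tuple[pd.DataFrame, pd.DataFrame, np.ndarray]:
    """Phylogenetic PCA of a species x motif count matrix.

    Counts are log10-transformed first (zero counts are an error — they
    cannot be logged).  Returns (scores, loadings, eigenvalues) with
    species and motif labels preserved.
    """
    if transform not in ("log10", "none"):
        raise ValueError(f"unknown transform {transform!r}")
    X = counts.to_numpy(dtype=float)
    if transform == "log10":
        if (X <= 0).any():
            bad = counts.index[(X <= 0).any(axis=1)].tolist()
            raise ValueError(f"zero/negative counts cannot be log-transformed: {bad}")
        X = np.log10(X)
    species = list(counts.index)
    sub = prune(tree, species)
    C, _ = phylo_vcv(sub, order=species)
    est = PhyloPCA(lam=lam)
    scores = est.fit_transform(X, C=C)
    k = X.shape[1]
    pc_names = [f"PC{i + 1}" for i in range(k)]
    scores_df = pd.DataFrame(scores, index=counts.index, columns=pc_names)
    loadings_df = pd.DataFrame(est.components_.T, index=counts.columns, columns=pc_names)
    return scores_df, loadings_df, est.explained_variance_
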