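"""Phylogenetic generalized least squares with maximum-likelihood lambda.

PGLS is ordinary regression whose error covariance is the phylogenetic
covariance matrix, optionally shrunk toward a star phylogeny by Pagel's
lambda.  Lambda is estimated by profile maximum likelihood jointly with
the regression; coefficient standard errors use the GLS residual mean
square; R-squared is computed on phylogenetically whitened data against
the whitened intercept-only fit at the same lambda.

Transform conventions for this study family: temporal song variables
and body size are log-transformed, dominant frequency square-root
transformed, climate predictors left untouched.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve, cholesky
from scipy.optimize import minimize_scalar
from scipy.stats import shapiro, t as t_dist

from .tree import PhyloTree, drop_tips, lambda_transform, phylo_covariance

__all__ = ["PGLSFit", "TransformPolicy", "fit_pgls", "pgls_battery"]

ACOUSTIC_VARS = ("CD", "NE", "ER", "ED", "ID")


@dataclass
class TransformPolicy:
    """Trait -> variance-stabilising transform mapping.

    Defaults: log for the temporal song variables (CD, NE, ER, ED, ID)
    and pronotum length PL; square root for dominant frequency DF; none
    for everything else (climate and binary habitat predictors).
    """

    mapping: dict[str, str] = field(default_factory=lambda: {
        "CD": "log", "NE": "log", "ER": "log", "ED": "log", "ID": "log",
        "PL": "log", "DF": "sqrt",
    })

    def transform_name(self, var: str) -> str:
        return self.mapping.get(var, "none")

    def apply(self, var: str, values: np.ndarray) -> np.ndarray:
        how = self.transform_name(var)
        v = np.asarray(values, dtype=float)
        if how == "log":
            return np.log(v)
        if how == "sqrt":
            return np.sqrt(v)
        if how == "none":
            return v
        raise ValueError(f"unknown transform {how!r}")

    def label(self, var: str) -> str:
        how = self.transform_name(var)
        return var if how == "none" else f"{how}({var})"


@dataclass
class PGLSFit:
    lambda_: float
    coef: np.ndarray
    se: np.ndarray
    tvalues: np.ndarray
    pvalues: np.ndarray
    r2_adj: float
    n: int
    loglik: float
    residuals_whitened: np.ndarray
    terms: list[str]
    response: str = ""
    diagnostics: dict = field(default_factory=dict)


def _gls_at_lambda(V: np.ndarray, y: np.ndarray, X: np.ndarray):
    cf = cho_factor(V, lower=True)
    ViX = cho_solve(cf, X)
    XtViX = X.T @ ViX
    beta = np.linalg.solve(XtViX, ViX.T @ y)
    e = y - X @ beta
    q = float(e @ cho_solve(cf, e))
    logdet = 2.0 * np.sum(np.log(np.diag(cf[0])))
    n = len(y)
    s2_ml = q / n
    lnL = -0.5 * (n * np.log(2 * np.pi * s2_ml) + logdet + n)
    return beta, e, q, XtViX, lnL, cf


def fit_pgls(tree: PhyloTree, y: dict[str, float], X: dict[str, dict[str, float]],
             lambda_mode: str | float = "ML",
             lambda_bounds: tuple[float, float] = (0.0, 1.0),
             response_name: str = "y") -> PGLSFit:
    """Single PGLS model of ``y`` on predictors ``X`` (plus intercept).

    ``y`` maps species -> response; ``X`` maps predictor name ->
    {species: value}.  Only species present in all of tree/y/X are used
    (complete cases).  ``lambda_mode`` is "ML" or a fixed value in
    ``lambda_bounds``.
    """
    common = [s for s in tree.tip_labels
              if s in y and all(s in col for col in X.values())]
    if len(common) < len(X) + 2:
        raise ValueError("not enough complete-case species for the model")
    work = tree if len(common) == tree.n_tips else drop_tips(
        tree, set(tree.tip_labels) - set(common))
    species = work.tip_labels
    yv = np.array([float(y[s]) for s in species])
    terms = ["(Intercept)"] + list(X.keys())
    Xm = np.column_stack(
        [np.ones(len(species))] +
        [np.array([float(X[name][s]) for s in species]) for name in X]
    )
    if not np.all(np.isfinite(Xm)) or not np.all(np.isfinite(yv)):
        raise ValueError("non-finite values in model data")
    if np.linalg.matrix_rank(Xm) < Xm.shape[1]:
        raise ValueError("rank-deficient design matrix")

    C = phylo_covariance(work)

    def lnL_at(lam: float) -> float:
        V = lambda_transform(C, lam, bounds=lambda_bounds).matrix
        return _gls_at_lambda(V, yv, Xm)[4]

    if lambda_mode == "ML":
        res = minimize_scalar(lambda l: -lnL_at(l), bounds=lambda_bounds,
                              method="bounded", options={"xatol": 1e-6})
        cands = [(float(res.x), -res.fun),
                 (lambda_bounds[0], lnL_at(lambda_bounds[0])),
                 (lambda_bounds[1], lnL_at(lambda_bounds[1]))]
        lam, _ = max(cands, key=lambda c: c[1])
    else:
        lam = float(lambda_mode)

    V = lambda_transform(C, lam, bounds=lambda_bounds).matrix
    beta, e, q, XtViX, lnL, cf = _gls_at_lambda(V, yv, Xm)
    n, p = Xm.shape
    df = n - p
    s2 = q / df  # GLS residual mean square
    cov_beta = s2 * np.linalg.inv(XtViX)
    se = np.sqrt(np.diag(cov_beta))
    tvals = beta / se
    pvals = 2.0 * t_dist.sf(np.abs(tvals), df)

    # Whitened residuals and R^2 against intercept-only fit at same lambda.
    L = cholesky(V, lower=True)
    Linv_y = np.linalg.solve(L, yv)
    Linv_X = np.linalg.solve(L, Xm)
    resid_w = Linv_y - Linv_X @ beta
    rss = float(resid_w @ resid_w)
    beta0 = _gls_at_lambda(V, yv, Xm[:, :1])[0]
    resid0 = Linv_y - Linv_X[:, :1] @ beta0
    rss0 = float(resid0 @ resid0)
    r2 = 1.0 - rss / rss0
    r2_adj = 1.0 - (1.0 - r2) * (n - 1) / (n - p) if n > p else np.nan

    diags = _residual_diagnostics(resid_w, Linv_X @ beta)
    return PGLSFit(lambda_=lam, coef=beta, se=se, tvalues=tvals, pvalues=pvals,
                   r2_adj=float(r2_adj), n=n, loglik=lnL,
                   residuals_whitened=resid_w, terms=terms,
                   response=response_name, diagnostics=diags)


def _residual_diagnostics(resid_w: np.ndarray, fitted_w: np.ndarray) -> dict:
    """Shapiro-type normality of whitened residuals plus a
    residual-vs-fitted linear-trend check."""
    out: dict = {}
    if len(resid_w) >= 3:
        stat, p = shapiro(resid_w)
        out["shapiro_stat"] = float(stat)
        out["shapiro_p"] = float(p)
        out["normal_ok"] = bool(p > 0.05)
    if np.ptp(fitted_w) > 0 and len(resid_w) >= 3:
        slope = np.polyfit(fitted_w, resid_w, 1)[0]
        out["resid_fitted_slope"] = float(slope)
    return out


def pgls_battery(tree: PhyloTree, traits: pd.DataFrame, predictors: pd.DataFrame,
                 policy: TransformPolicy | None = None,
                 responses: tuple[str, ...] | None = None) -> pd.DataFrame:
    """One single-predictor PGLS per (response, predictor) pair.

    ``traits``: species-indexed DataFrame of acoustic means (CD..DF);
    ``predictors``: species-indexed DataFrame (PL, climate, 0/1 habitat
    codes).  Transforms follow ``policy``.  Per-pair failures are
    recorded in the ``error`` column and the battery continues.
    """
    policy = policy or TransformPolicy()
    responses = responses or tuple(traits.columns)
    rows = []
    for resp in responses:
        for pred in predictors.columns:
            row = {"response": policy.label(resp), "predictor": policy.label(pred)}
            try:
                yt = policy.apply(resp, traits[resp].to_numpy())
                xt = policy.apply(pred, predictors[pred].to_numpy())
                y = dict(zip(traits.index, yt))
                x = dict(zip(predictors.index, xt))
                fit = fit_pgls(tree, y, {policy.label(pred): x},
                               response_name=policy.label(resp))
                row.update({
                    "lambda": fit.lambda_, "r2_adj": fit.r2_adj,
                    "beta": fit.coef[1], "se": fit.se[1],
                    "t": fit.tvalues[1], "p": fit.pvalues[1], "n": fit.n,
                    "shapiro_p": fit.diagnostics.get("shapiro_p", np.nan),
                    "error": "",
                })
            except Exception as exc:
                row.update({"lambda": np.nan, "r2_adj": np.nan, "beta": np.nan,
                            "se": np.nan, "t": np.nan, "p": np.nan, "n": 0,
                            "shapiro_p": np.nan, "error": str(exc)})
            rows.append(row)
    out = pd.DataFrame(rows)
    # Benjamini-Hochberg column for information only (study reports raw p).
    p = out["p"].to_numpy()
    ok = np.isfinite(p)
    q = np.full_like(p, np.nan)
    if ok.sum():
        ps = p[ok]
        order = np.argsort(ps)
        m = len(ps)
        ranked = ps[order] * m / (np.arange(m) + 1)
        ranked = np.minimum.accumulate(ranked[::-1])[::-1]
        qs = np.empty(m)
        qs[order] = np.minimum(ranked, 1.0)
        q[ok] = qs
    out["p_bh"] = q
    return out
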