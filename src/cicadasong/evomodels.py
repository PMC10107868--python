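"""Macroevolutionary model fitting and AICc-based model comparison.

Seven models of continuous trait evolution are fitted by maximum
likelihood, all as multivariate normals over the species means with a
model-specific covariance plus a diagonal of squared within-species
standard errors:

* BM   — Brownian motion: V = sigma2 * C, mean z0.
* OU   — single-optimum Ornstein-Uhlenbeck with attraction alpha toward
  theta; the root sits at the optimum, so on an ultrametric tree
  V_ij = (sigma2 / 2 alpha) * exp(-2 alpha (T - t_ij)) *
  (1 - exp(-2 alpha t_ij)) with t_ij the MRCA depth and T tree height.
* EB   — early burst: Brownian motion on the exponentially
  time-rescaled tree (rate changing as exp(r t), r <= 0).
* BMS  — Brownian motion with regime-specific rates on a painted tree
  (one global mean), for each of two habitat paintings.
* OUMV — Ornstein-Uhlenbeck with a shared alpha but regime-specific
  rates and optima, for each of the two paintings.

Regimes are painted from maximum-likelihood marginal ancestral states
of a binary habitat character under an equal-rates Mk model; a branch
carries the state of its tipward node.

Model support is summarised with AICc, Delta-AICc and Akaike weights;
a Delta of 4 to the runner-up marks strong support.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve
from scipy.optimize import minimize, minimize_scalar

from .tree import PhyloTree, eb_transform, phylo_covariance

__all__ = [
    "EvoModelFit", "ModelComparison", "RegimePainting",
    "ancestral_discrete_marginal", "paint_regimes",
    "fit_single_regime", "fit_multi_regime",
    "evo_loglik", "aicc", "akaike_weights", "model_comparison",
    "SINGLE_REGIME_MODELS", "MULTI_REGIME_MODELS",
]

SINGLE_REGIME_MODELS = ("BM", "OU", "EB")
MULTI_REGIME_MODELS = ("BMS", "OUMV")

_K = {"BM": 2, "OU": 3, "EB": 3, "BMS": 3, "OUMV": 5}


@dataclass
class EvoModelFit:
    model: str
    params: dict
    loglik: float
    k: int
    aicc: float
    n: int
    se_included: bool
    boundary: list[str] = field(default_factory=list)
    converged: bool = True


@dataclass
class RegimePainting:
    """Regime per branch (indexed by the branch's tipward node; the
    root entry holds the root state) plus per-node marginal state
    probabilities."""

    branch_regime: np.ndarray
    node_probs: np.ndarray
    regime_names: tuple[str, str] = ("0", "1")

    @property
    def regimes_present(self) -> list[int]:
        return sorted(set(int(r) for r in self.branch_regime))


@dataclass
class ModelComparison:
    table: pd.DataFrame
    best_model: str
    strong_support: bool


# ---------------------------------------------------------------------------
# Discrete ancestral states (equal-rates Mk, two states)


def _mk_transition(q: float, t: np.ndarray | float) -> np.ndarray:
    """2x2 equal-rates transition matrix exp(Q t)."""
    same = 0.5 * (1.0 + np.exp(-2.0 * q * t))
    return np.array([[same, 1.0 - same], [1.0 - same, same]])


def _mk_partials(tree: PhyloTree, states: np.ndarray, q: float) -> np.ndarray:
    L = np.zeros((tree.n_nodes, 2))
    L[np.arange(tree.n_tips), states] = 1.0
    for v in tree.postorder():
        if not tree.children[v]:
            continue
        acc = np.ones(2)
        for c in tree.children[v]:
            P = _mk_transition(q, tree.length[c])
            acc *= P @ L[c]
        L[v] = acc
    return L


def _mk_loglik(tree: PhyloTree, states: np.ndarray, q: float) -> float:
    L = _mk_partials(tree, states, q)
    return float(np.log(0.5 * L[tree.root].sum()))


def ancestral_discrete_marginal(tree: PhyloTree, b: dict[str, int] | np.ndarray,
                                q_bounds: tuple[float, float] = (1e-8, 500.0)
                                ) -> tuple[np.ndarray, float]:
    """ML marginal state probabilities at every node under equal-rates Mk.

    Returns ``(node_probs, q_hat)`` where ``node_probs[v]`` is the
    marginal probability of states (0, 1) at node ``v`` (tips are their
    observed state with probability 1).  Marginals are computed by the
    standard two-pass (below/above) algorithm, which for this
    reversible model with its stationary root prior coincides with the
    re-rooting construction.
    """
    if isinstance(b, dict):
        states = np.array([int(b[s]) for s in tree.tip_labels])
    else:
        states = np.asarray(b, dtype=int)
    if not set(np.unique(states)) <= {0, 1}:
        raise ValueError("states must be coded 0/1")

    res = minimize_scalar(
        lambda lq: -_mk_loglik(tree, states, np.exp(lq)),
        bounds=(np.log(q_bounds[0]), np.log(q_bounds[1])), method="bounded",
        options={"xatol": 1e-10},
    )
    q_hat = float(np.exp(res.x))

    L = _mk_partials(tree, states, q_hat)
    above = np.zeros((tree.n_nodes, 2))
    above[tree.root] = 0.5
    for u in tree.preorder():
        kids = tree.children[u]
        for v in kids:
            sib_msg = np.ones(2)
            for w in kids:
                if w is v:
                    continue
                Pw = _mk_transition(q_hat, tree.length[w])
                sib_msg *= Pw @ L[w]
            Pv = _mk_transition(q_hat, tree.length[v])
            above[v] = Pv.T @ (above[u] * sib_msg)
    post = above * L
    total = post.sum(axis=1, keepdims=True)
    probs = post / total
    return probs, q_hat


def paint_regimes(tree: PhyloTree, node_probs: np.ndarray,
                  regime_names: tuple[str, str] = ("0", "1"),
                  tie_state: int | None = None) -> RegimePainting:
    """Assign each branch the most probable state of its tipward node.

    A node whose marginal is exactly 0.5/0.5 is a tie: an error unless
    ``tie_state`` supplies a deterministic resolution.
    """
    probs = np.asarray(node_probs, dtype=float)
    regime = np.zeros(tree.n_nodes, dtype=int)
    for v in range(tree.n_nodes):
        if probs[v, 0] == probs[v, 1]:
            if tie_state is None:
                raise ValueError(
                    f"exact 0.5/0.5 marginal at node {v}; pass tie_state to resolve")
            regime[v] = tie_state
        else:
            regime[v] = int(np.argmax(probs[v]))
    return RegimePainting(branch_regime=regime, node_probs=probs,
                          regime_names=regime_names)


# ---------------------------------------------------------------------------
# Model covariances and likelihood


def _mrca_depths(tree: PhyloTree) -> np.ndarray:
    return phylo_covariance(tree).matrix


def _branch_ages(tree: PhyloTree) -> tuple[np.ndarray, np.ndarray]:
    """(start age, end age) of the branch subtending every node."""
    depth = tree.node_depths()
    t2 = depth
    t1 = np.where(tree.parent >= 0, depth[np.clip(tree.parent, 0, None)], 0.0)
    return t1, t2


def evo_covariance(tree: PhyloTree, model: str, params: Mapping,
                   painting: RegimePainting | None = None) -> np.ndarray:
    """Model-implied covariance among the species means (without SE)."""
    model = model.upper()
    if model == "BM":
        return float(params["sigma2"]) * _mrca_depths(tree)
    if model == "EB":
        return float(params["sigma2"]) * _mrca_depths(
            eb_transform(tree, float(params["r"])))
    if model == "OU":
        a = float(params["alpha"])
        s2 = float(params["sigma2"])
        t = _mrca_depths(tree)
        T = tree.height()
        if a <= 0:
            return s2 * t
        return (s2 / (2 * a)) * np.exp(-2 * a * (T - t)) * (1 - np.exp(-2 * a * t))
    if model in MULTI_REGIME_MODELS:
        if painting is None:
            raise ValueError(f"{model} requires a regime painting")
        reg = painting.branch_regime
        M = tree.branch_tip_incidence().astype(float)
        s2 = np.asarray(params["sigma2"], dtype=float)
        if model == "BMS":
            g = s2[reg] * tree.length
            return (M * g[:, None]).T @ M
        a = float(params["alpha"])
        T = tree.height()
        t1, t2 = _branch_ages(tree)
        if a <= 0:
            g = s2[reg] * tree.length
        else:
            g = s2[reg] * (np.exp(2 * a * t2) - np.exp(2 * a * t1)) \
                / (2 * a) * np.exp(-2 * a * T)
        return (M * g[:, None]).T @ M
    raise ValueError(f"unknown model {model!r}")


def _oumv_design(tree: PhyloTree, alpha: float, painting: RegimePainting,
                 n_reg: int | None = None) -> np.ndarray:
    """Regime weight matrix W: E[x] = W @ theta under shared-alpha OU.

    Row i weights each regime by its exponentially discounted occupancy
    of the root-to-tip-i path, the root contributing exp(-alpha T) to
    the root regime.  Rows sum to 1.
    """
    reg = painting.branch_regime
    if n_reg is None:
        n_reg = int(reg.max()) + 1
    T = tree.height()
    t1, t2 = _branch_ages(tree)
    M = tree.branch_tip_incidence().astype(float)
    if alpha <= 0:
        # degenerate: only the root regime contributes
        W = np.zeros((tree.n_tips, n_reg))
        W[:, reg[tree.root]] = 1.0
        return W
    contrib = np.exp(-alpha * (T - t2)) - np.exp(-alpha * (T - t1))
    contrib[tree.root] = 0.0
    W = np.zeros((tree.n_tips, n_reg))
    for k in range(n_reg):
        W[:, k] = (M * (contrib * (reg == k))[:, None]).sum(axis=0)
    W[:, reg[tree.root]] += np.exp(-alpha * T)
    return W


def _mean_design(tree: PhyloTree, model: str, params: Mapping,
                 painting: RegimePainting | None) -> tuple[np.ndarray, np.ndarray]:
    """(design matrix W, mean parameter vector) so that E[x] = W @ m."""
    n = tree.n_tips
    model = model.upper()
    if model in ("BM", "EB"):
        return np.ones((n, 1)), np.atleast_1d(np.asarray(params["z0"], dtype=float))
    if model in ("OU", "BMS"):
        return np.ones((n, 1)), np.atleast_1d(np.asarray(params["theta"], dtype=float))
    if model == "OUMV":
        theta = np.atleast_1d(np.asarray(params["theta"], dtype=float))
        W = _oumv_design(tree, float(params["alpha"]), painting,
                         n_reg=len(theta))
        return W, theta
    raise ValueError(f"unknown model {model!r}")


def _mvn_loglik(V: np.ndarray, resid: np.ndarray) -> float:
    cf = cho_factor(V, lower=True)
    q = float(resid @ cho_solve(cf, resid))
    logdet = 2.0 * np.sum(np.log(np.diag(cf[0])))
    n = len(resid)
    return -0.5 * (n * np.log(2 * np.pi) + logdet + q)


def evo_loglik(tree: PhyloTree, x: np.ndarray, se: np.ndarray, model: str,
               params: Mapping, painting: RegimePainting | None = None) -> float:
    """Exact log-likelihood of a full parameterisation of any model."""
    V = evo_covariance(tree, model, params, painting) + np.diag(np.asarray(se) ** 2)
    W, m = _mean_design(tree, model, params, painting)
    return _mvn_loglik(V, np.asarray(x, dtype=float) - W @ m)


# ---------------------------------------------------------------------------
# Fitting


def _profiled_nll(tree, x, se, model, cov_params, painting):
    """Negative log-likelihood with the mean parameters profiled by GLS."""
    V = evo_covariance(tree, model, cov_params, painting) + np.diag(se ** 2)
    if model == "OUMV":
        W = _oumv_design(tree, float(cov_params["alpha"]), painting)
    else:
        W = np.ones((tree.n_tips, 1))
    try:
        cf = cho_factor(V, lower=True)
    except np.linalg.LinAlgError:
        return np.inf, None
    ViW = cho_solve(cf, W)
    A = W.T @ ViW
    m = np.linalg.solve(A, ViW.T @ x)
    resid = x - W @ m
    q = float(resid @ cho_solve(cf, resid))
    logdet = 2.0 * np.sum(np.log(np.diag(cf[0])))
    n = len(x)
    return 0.5 * (n * np.log(2 * np.pi) + logdet + q), m


def _prepare_xy(tree, x, se):
    if isinstance(x, dict):
        xv = np.array([float(x[s]) for s in tree.tip_labels])
    else:
        xv = np.asarray(x, dtype=float)
    if se is None:
        sv = np.zeros(tree.n_tips)
    elif isinstance(se, dict):
        sv = np.array([float(se[s]) for s in tree.tip_labels])
    else:
        sv = np.asarray(se, dtype=float)
    if np.any(sv < 0):
        raise ValueError("standard errors must be >= 0")
    return xv, sv


def _multistart(objective, x0, bounds, n_starts: int, seed: int):
    rng = np.random.default_rng(seed)
    best = None
    lo = np.array([b[0] for b in bounds])
    hi = np.array([b[1] for b in bounds])
    starts = [np.asarray(x0, dtype=float)]
    for _ in range(n_starts - 1):
        starts.append(lo + rng.random(len(bounds)) * (hi - lo))
    for s in starts:
        res = minimize(objective, s, method="L-BFGS-B", bounds=bounds)
        if best is None or res.fun < best.fun:
            best = res
    return best


def _boundary_flags(names, values, bounds, rel=1e-3):
    flags = []
    for nm, v, (lo, hi) in zip(names, values, bounds):
        span = hi - lo
        if v - lo <= rel * span:
            flags.append(f"{nm} at lower bound")
        elif hi - v <= rel * span:
            flags.append(f"{nm} at upper bound")
    return flags


_SIGMA2_BOUNDS = (np.log(1e-9), np.log(1e6))


def fit_single_regime(tree: PhyloTree, x, se=None, model: str = "BM",
                      n_starts: int = 5, seed: int = 0) -> EvoModelFit:
    """ML fit of BM, OU or EB to species means with within-species SE."""
    model = model.upper()
    if model not in SINGLE_REGIME_MODELS:
        raise ValueError(f"model must be one of {SINGLE_REGIME_MODELS}")
    xv, sv = _prepare_xy(tree, x, se)
    n = tree.n_tips
    T = tree.height()
    from .tree import check_ultrametric
    if model in ("OU", "EB") and not check_ultrametric(tree, tol=1e-6 * T):
        raise ValueError(f"{model} requires an ultrametric tree")

    s2_0 = max(float(np.var(xv)) / max(T, 1e-12), 1e-8)

    if model == "BM":
        names = ["sigma2"]
        bounds = [_SIGMA2_BOUNDS]
        to_params = lambda v: {"sigma2": float(np.exp(v[0]))}
        x0 = [np.log(s2_0)]
    elif model == "OU":
        names = ["sigma2", "alpha"]
        alpha_bounds = (np.log(1e-8), np.log(50.0 / T))
        bounds = [_SIGMA2_BOUNDS, alpha_bounds]
        to_params = lambda v: {"sigma2": float(np.exp(v[0])),
                               "alpha": float(np.exp(v[1]))}
        x0 = [np.log(s2_0), np.log(1.0 / T)]
    else:  # EB
        names = ["sigma2", "r"]
        r_bounds = (-10.0 / T, 0.0)
        bounds = [_SIGMA2_BOUNDS, r_bounds]
        to_params = lambda v: {"sigma2": float(np.exp(v[0])), "r": float(v[1])}
        x0 = [np.log(s2_0), -0.5 / T]

    def obj(v):
        return _profiled_nll(tree, xv, sv, model, to_params(v), None)[0]

    res = _multistart(obj, x0, bounds, n_starts, seed)
    params = to_params(res.x)
    nll, m = _profiled_nll(tree, xv, sv, model, params, None)
    if model in ("BM", "EB"):
        params["z0"] = float(m[0])
    else:
        params["theta"] = float(m[0])
    lnL = -nll
    k = _K[model]
    flags = _boundary_flags(names, res.x, bounds)
    return EvoModelFit(model=model, params=params, loglik=lnL, k=k,
                       aicc=_aicc_or_inf(lnL, k, n), n=n,
                       se_included=bool(np.any(sv > 0)),
                       boundary=flags, converged=bool(res.success))


def fit_multi_regime(tree: PhyloTree, x, se=None, painting: RegimePainting = None,
                     model: str = "BMS", n_starts: int = 5, seed: int = 0
                     ) -> EvoModelFit:
    """ML fit of BMS (regime rates, global mean) or OUMV (shared alpha,
    regime rates and optima) on a painted tree."""
    model = model.upper()
    if model not in MULTI_REGIME_MODELS:
        raise ValueError(f"model must be one of {MULTI_REGIME_MODELS}")
    if painting is None:
        raise ValueError("painting is required")
    xv, sv = _prepare_xy(tree, x, se)
    n = tree.n_tips
    T = tree.height()
    from .tree import check_ultrametric
    if model == "OUMV" and not check_ultrametric(tree, tol=1e-6 * T):
        raise ValueError("OUMV requires an ultrametric tree")
    n_reg = int(painting.branch_regime.max()) + 1
    present = painting.regimes_present
    degenerate = len(present) < 2

    s2_0 = max(float(np.var(xv)) / max(T, 1e-12), 1e-8)

    if model == "BMS":
        names = [f"sigma2_{k}" for k in range(n_reg)]
        bounds = [_SIGMA2_BOUNDS] * n_reg
        to_params = lambda v: {"sigma2": np.exp(v[:n_reg])}
        x0 = [np.log(s2_0)] * n_reg
    else:
        names = ["alpha"] + [f"sigma2_{k}" for k in range(n_reg)]
        alpha_bounds = (np.log(1e-8), np.log(50.0 / T))
        bounds = [alpha_bounds] + [_SIGMA2_BOUNDS] * n_reg
        to_params = lambda v: {"alpha": float(np.exp(v[0])),
                               "sigma2": np.exp(v[1:1 + n_reg])}
        x0 = [np.log(1.0 / T)] + [np.log(s2_0)] * n_reg

    def obj(v):
        return _profiled_nll(tree, xv, sv, model, to_params(v), painting)[0]

    res = _multistart(obj, x0, bounds, n_starts, seed)
    params = to_params(res.x)
    nll, m = _profiled_nll(tree, xv, sv, model, params, painting)
    if model == "BMS":
        params["theta"] = float(m[0])
    else:
        params["theta"] = np.asarray(m, dtype=float)
    lnL = -nll
    k = _K[model]
    flags = _boundary_flags(names, res.x, bounds)
    if degenerate:
        flags.append("single regime present: degenerate to the single-regime model")
    return EvoModelFit(model=model, params=params, loglik=lnL, k=k,
                       aicc=_aicc_or_inf(lnL, k, n), n=n,
                       se_included=bool(np.any(sv > 0)),
                       boundary=flags, converged=bool(res.success))


# ---------------------------------------------------------------------------
# AICc bookkeeping


def aicc(loglik: float, k: int, n: int) -> float:
    """AICc = -2 lnL + 2k + 2k(k+1)/(n-k-1)."""
    if n - k - 1 <= 0:
        raise ValueError("n too small for AICc correction")
    return -2.0 * loglik + 2.0 * k + 2.0 * k * (k + 1) / (n - k - 1)


def _aicc_or_inf(loglik: float, k: int, n: int) -> float:
    # fits on degenerate problem sizes keep their lnL but cannot be ranked
    return aicc(loglik, k, n) if n - k - 1 > 0 else np.inf


def akaike_weights(scores: Sequence[float]) -> tuple[np.ndarray, np.ndarray]:
    """Delta and Akaike weights from information-criterion scores."""
    s = np.asarray(scores, dtype=float)
    delta = s - s.min()
    w = np.exp(-0.5 * delta)
    return delta, w / w.sum()


def model_comparison(fits: Mapping[str, EvoModelFit],
                     delta_threshold: float = 4.0) -> ModelComparison:
    """Rank a complete set of model fits for one trait.

    Refuses to compare if any fit is missing (None).
    """
    for name, f in fits.items():
        if f is None:
            raise ValueError(f"missing fit for model {name!r}; comparison refused")
    names = list(fits)
    scores = [fits[m].aicc for m in names]
    delta, w = akaike_weights(scores)
    table = pd.DataFrame({
        "model": names,
        "loglik": [fits[m].loglik for m in names],
        "k": [fits[m].k for m in names],
        "aicc": scores,
        "delta_aicc": delta,
        "aic_weight": w,
    })
    order = np.argsort(delta)
    best = names[order[0]]
    runner_delta = float(delta[order[1]]) if len(names) > 1 else np.inf
    return ModelComparison(table=table, best_model=best,
                           strong_support=bool(runner_delta >= delta_threshold))
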