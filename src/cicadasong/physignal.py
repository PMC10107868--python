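"""Phylogenetic signal: Pagel's lambda and the Fritz-Purvis D statistic.

Continuous traits: lambda scales the off-diagonal entries of the
Brownian covariance, so lambda = 1 means the trait covaries exactly as
expected under Brownian motion on the tree and lambda = 0 means tip
values are phylogenetically independent.  The maximum-likelihood lambda
is found on the profile likelihood (ancestral mean and rate profiled
out analytically) and tested against lambda = 0 by a likelihood-ratio
chi-square with one degree of freedom.

Binary traits: D contrasts the observed sum of sister-clade differences
against two simulated nulls — phylogenetically random (tip-label
permutation) and Brownian (a Brownian trait rank-thresholded to the
observed prevalence).  D = 1 under phylogenetic randomness, 0 under the
Brownian expectation; values below 0 indicate extreme conservatism and
above 1 overdispersion.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import cho_factor, cho_solve
from scipy.optimize import minimize_scalar
from scipy.stats import chi2

from .tree import PhyloTree, lambda_transform, phylo_covariance

__all__ = ["LambdaSignal", "DSignal", "pagel_lambda_signal", "fritz_purvis_d",
           "sister_difference_sum"]


@dataclass
class LambdaSignal:
    lambda_: float
    loglik: float
    loglik0: float
    pvalue: float
    sigma2: float
    mu: float


@dataclass
class DSignal:
    D: float
    d_obs: float
    mean_d_random: float
    mean_d_brownian: float
    p_random: float
    p_brownian: float
    n_sim: int


def _profile_loglik(V: np.ndarray, x: np.ndarray) -> tuple[float, float, float]:
    """MVN log-likelihood with mean mu*1 and scale sigma2 profiled out (ML)."""
    n = len(x)
    cf = cho_factor(V, lower=True)
    ones = np.ones(n)
    Vi1 = cho_solve(cf, ones)
    mu = float(x @ Vi1 / (ones @ Vi1))
    e = x - mu
    q = float(e @ cho_solve(cf, e))
    sigma2 = q / n
    if sigma2 <= 0:
        raise ValueError("degenerate (constant) trait")
    logdet = 2.0 * np.sum(np.log(np.diag(cf[0])))
    lnL = -0.5 * (n * np.log(2 * np.pi * sigma2) + logdet + n)
    return lnL, mu, sigma2


def pagel_lambda_signal(tree: PhyloTree, x: dict[str, float] | np.ndarray,
                        bounds: tuple[float, float] = (0.0, 1.0),
                        tol: float = 1e-6) -> LambdaSignal:
    """ML estimate of Pagel's lambda with a likelihood-ratio test vs 0.

    ``x`` maps species to trait values (or is an array in tip order).
    Requires at least 4 species.
    """
    if isinstance(x, dict):
        missing = [s for s in tree.tip_labels if s not in x]
        if missing:
            raise KeyError(f"trait missing for species: {missing}")
        xv = np.array([float(x[s]) for s in tree.tip_labels])
    else:
        xv = np.asarray(x, dtype=float)
    if len(xv) != tree.n_tips:
        raise ValueError("trait length does not match tip count")
    if tree.n_tips < 4:
        raise ValueError("need at least 4 species")
    if np.ptp(xv) == 0:
        raise ValueError("constant trait")

    C = phylo_covariance(tree)

    def nll(lam: float) -> float:
        V = lambda_transform(C, lam, bounds=bounds).matrix
        return -_profile_loglik(V, xv)[0]

    res = minimize_scalar(nll, bounds=bounds, method="bounded",
                          options={"xatol": tol})
    candidates = [(float(res.x), -res.fun),
                  (bounds[0], -nll(bounds[0])),
                  (bounds[1], -nll(bounds[1]))]
    lam_hat, lnL = max(candidates, key=lambda c: c[1])
    V = lambda_transform(C, lam_hat, bounds=bounds).matrix
    _, mu, s2 = _profile_loglik(V, xv)
    lnL0 = -nll(0.0)
    lr = max(0.0, 2.0 * (lnL - lnL0))
    p = float(chi2.sf(lr, df=1))
    return LambdaSignal(lambda_=lam_hat, loglik=lnL, loglik0=lnL0,
                        pvalue=p, sigma2=s2, mu=mu)


# ---------------------------------------------------------------------------
# Fritz-Purvis D


def _sister_difference_operator(tree: PhyloTree) -> np.ndarray:
    """Rows express each internal node's |left - right| argument as a
    linear functional of the tip values.

    Node values are computed tips-to-root as the mean of the two
    children's values; the returned matrix has one row per internal
    node holding the weight vector of (left child value - right child
    value).
    """
    n = tree.n_tips
    weights = np.zeros((tree.n_nodes, n))
    weights[np.arange(n), np.arange(n)] = 1.0
    rows = []
    for v in tree.postorder():
        kids = tree.children[v]
        if not kids:
            continue
        if len(kids) != 2:
            raise ValueError("D statistic requires a bifurcating tree")
        c1, c2 = kids
        weights[v] = 0.5 * (weights[c1] + weights[c2])
        rows.append(weights[c1] - weights[c2])
    return np.array(rows)


def sister_difference_sum(tree: PhyloTree, b: np.ndarray) -> float:
    """Observed d: sum over internal nodes of |left - right| node values."""
    op = _sister_difference_operator(tree)
    return float(np.sum(np.abs(op @ np.asarray(b, dtype=float))))


def fritz_purvis_d(tree: PhyloTree, b: dict[str, int] | np.ndarray,
                   n_sim: int = 1000, seed: int = 0) -> DSignal:
    """Fritz-Purvis D for a binary trait, with simulated null means.

    ``p_random`` is the fraction of permutation replicates with d <=
    d_obs (small d means more clumped than random); ``p_brownian`` the
    fraction of Brownian-threshold replicates with d >= d_obs.  Both
    include the observed value in the null set (+1/+1) so p is never 0.
    """
    if isinstance(b, dict):
        bv = np.array([int(b[s]) for s in tree.tip_labels])
    else:
        bv = np.asarray(b, dtype=int)
    if set(np.unique(bv)) != {0, 1}:
        raise ValueError("binary trait must contain both states 0 and 1")
    if tree.n_tips < 4:
        raise ValueError("need at least 4 species")

    rng = np.random.default_rng(seed)
    op = _sister_difference_operator(tree)
    d_obs = float(np.sum(np.abs(op @ bv)))
    n = tree.n_tips
    k = int(bv.sum())

    # Permutation null: shuffle tip labels.
    perm = np.empty((n, n_sim))
    for j in range(n_sim):
        perm[:, j] = bv[rng.permutation(n)]
    d_r = np.sum(np.abs(op @ perm), axis=0)

    # Brownian null: BM tips rank-thresholded to the observed prevalence.
    M = tree.branch_tip_incidence().astype(float)
    S = (M * np.sqrt(tree.length)[:, None]).T  # tips x branches
    Z = rng.standard_normal((tree.n_nodes, n_sim))
    X = S @ Z
    Bb = np.zeros_like(X)
    idx = np.argsort(X, axis=0)[-k:, :]
    np.put_along_axis(Bb, idx, 1.0, axis=0)
    d_b = np.sum(np.abs(op @ Bb), axis=0)

    mean_r = float(d_r.mean())
    mean_b = float(d_b.mean())
    D = (d_obs - mean_b) / (mean_r - mean_b)
    p_random = (1 + int(np.sum(d_r <= d_obs))) / (n_sim + 1)
    p_brownian = (1 + int(np.sum(d_b >= d_obs))) / (n_sim + 1)
    return DSignal(D=float(D), d_obs=d_obs, mean_d_random=mean_r,
                   mean_d_brownian=mean_b, p_random=float(p_random),
                   p_brownian=float(p_brownian), n_sim=n_sim)
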