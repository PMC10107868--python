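"""Acoustic morphospace: PCA of temporal song variables and projection
of the phylogeny into that space with ML ancestral states.

The phylomorphospace superimposes the tree on a principal-component
scatter: tips sit at their PC scores and internal nodes at their
maximum-likelihood (Brownian) ancestral estimates, with branches drawn
between parent and child coordinates.  The PCA is computed on the
correlation matrix (z-scored input) because the temporal variables are
on incommensurate scales.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve

from .tree import PhyloTree, phylo_covariance

__all__ = ["MorphospaceProjection", "pca_species_traits",
           "ancestral_continuous", "phylomorphospace"]


@dataclass
class MorphospaceProjection:
    loadings: pd.DataFrame
    percent_variance: np.ndarray
    tip_scores: pd.DataFrame
    node_scores: np.ndarray  # internal-node coordinates per axis
    edges: list[tuple[int, int]]  # parent -> child node indices


def pca_species_traits(traits: pd.DataFrame, standardize: bool = True
                       ) -> tuple[pd.DataFrame, pd.DataFrame, np.ndarray]:
    """PCA of the species x variables table.

    Returns ``(loadings, scores, percent_variance)``.  Variables are
    z-scored (sample sd) when ``standardize``; axes are ordered by
    variance with a deterministic sign convention (the largest-
    magnitude loading of each axis is positive).
    """
    X = traits.to_numpy(dtype=float)
    if X.shape[0] < 3:
        raise ValueError("need at least 3 species")
    if np.isnan(X).any():
        raise ValueError("missing values in trait table")
    sd = X.std(axis=0, ddof=1)
    if np.any(sd == 0):
        bad = [c for c, s in zip(traits.columns, sd) if s == 0]
        raise ValueError(f"constant column(s): {bad}")
    Xc = X - X.mean(axis=0)
    if standardize:
        Xc = Xc / sd
    # SVD of the centred (scaled) matrix gives eigenvectors of the
    # correlation (covariance) matrix.
    U, S, Vt = np.linalg.svd(Xc, full_matrices=False)
    eigvals = S**2 / (X.shape[0] - 1)
    V = Vt.T
    for j in range(V.shape[1]):
        if V[np.argmax(np.abs(V[:, j])), j] < 0:
            V[:, j] = -V[:, j]
    scores = Xc @ V
    pct = 100.0 * eigvals / eigvals.sum()
    axes = [f"PC{j+1}" for j in range(V.shape[1])]
    loadings = pd.DataFrame(V, index=traits.columns, columns=axes)
    scores_df = pd.DataFrame(scores, index=traits.index, columns=axes)
    return loadings, scores_df, pct


def ancestral_continuous(tree: PhyloTree, x: dict[str, float] | np.ndarray
                         ) -> np.ndarray:
    """ML (Brownian) ancestral estimates at every internal node.

    The estimate at node k is the GLS conditional expectation
    mu + C_k,tips C^{-1} (x - mu), with mu the GLS grand mean; the root
    estimate is exactly mu.  Returned in node-index order for internal
    nodes (indices n_tips .. n_nodes-1).
    """
    if isinstance(x, dict):
        xv = np.array([float(x[s]) for s in tree.tip_labels])
    else:
        xv = np.asarray(x, dtype=float)
    C = phylo_covariance(tree).matrix
    cf = cho_factor(C, lower=True)
    ones = np.ones(tree.n_tips)
    Vi1 = cho_solve(cf, ones)
    mu = float(xv @ Vi1 / (ones @ Vi1))

    # Shared path length between internal node k and tip i: sum of branch
    # lengths ancestral to both.
    M = tree.branch_tip_incidence()
    anc = np.zeros((tree.n_nodes, tree.n_nodes), dtype=bool)
    for v in tree.preorder():
        p = tree.parent[v]
        if p >= 0:
            anc[v] = anc[p]
        anc[v, v] = True
    internals = np.arange(tree.n_tips, tree.n_nodes)
    # Ck[k, i] = sum over branches b ancestral to both of length[b]
    Ck = (anc[internals].astype(float) * tree.length[None, :]) @ M.astype(float)
    est = mu + Ck @ cho_solve(cf, xv - mu)
    return est


def phylomorphospace(tree: PhyloTree, scores: pd.DataFrame) -> MorphospaceProjection:
    """Project the tree into PC space: internal-node coordinates are the
    per-axis ML ancestral estimates; the edge list pairs parent and
    child node indices (tips 0..n-1, internals n..2n-2)."""
    missing = [s for s in tree.tip_labels if s not in scores.index]
    if missing:
        raise KeyError(f"scores missing for tips: {missing}")
    S = scores.loc[tree.tip_labels]
    node_scores = np.column_stack([
        ancestral_continuous(tree, S[c].to_dict()) for c in S.columns
    ])
    edges = [(int(tree.parent[v]), v) for v in range(tree.n_nodes)
             if tree.parent[v] >= 0]
    loadings = pd.DataFrame(index=S.columns)
    return MorphospaceProjection(
        loadings=loadings,
        percent_variance=np.array([]),
        tip_scores=S,
        node_scores=node_scores,
        edges=edges,
    )
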