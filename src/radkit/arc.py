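"""Age-range correlation (ARC) between node ages and nodal overlap.

For every internal node the *nodal mean* of a symmetric tip-pair matrix M
(range overlap, asymmetry, or niche distance) is the recursive average

    value(node) = mean over cross pairs (i in left clade, j in right clade)
                  weighted so that each daughter *clade* contributes equally
                  at every split,

implemented non-recursively with per-node tip-weight vectors: tips get
weight 1, and an internal node's weight vector is the average of its two
daughters' vectors, so value(node) = w_L^T M w_R.  Regressing nodal value
on node age tests whether younger splits show more (or less) range
overlap than older ones -- the classic signature separating sympatric
from allopatric speciation.

Because nodal values are phylogenetically non-independent, significance
comes from a Monte-Carlo null: tip identities are permuted (rows and
columns of M together), nodal values and the regression are recomputed
for every permutation in one vectorised einsum, and the two-sided p-value
is the add-one-smoothed tail proportion.  Over a posterior tree sample
the *super p* is the proportion of trees whose individual p falls below
alpha.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Sequence, Tuple

import numpy as np
import pandas as pd

from .trees import DatedTree, TreeSample
from ._treeindex import TreeIndex, index_tree

__all__ = [
    "nodal_means",
    "arc_regression",
    "mc_null",
    "ARCResult",
    "age_range_correlation",
    "super_p",
]


def _tip_weights(idx: TreeIndex) -> np.ndarray:
    """(n_nodes, n_tips) matrix of clade-balanced tip weights."""
    W = np.zeros((idx.n_nodes, idx.n_tips))
    W[np.arange(idx.n_tips), np.arange(idx.n_tips)] = 1.0
    for node in idx.internal:
        c1, c2 = idx.children[node - idx.n_tips]
        W[node] = 0.5 * (W[c1] + W[c2])
    return W


def _aligned_matrix(M: pd.DataFrame, labels: Sequence[str]) -> np.ndarray:
    missing = [l for l in labels if l not in M.index]
    if missing:
        raise ValueError(f"pair matrix missing tips {missing[:5]}")
    A = M.loc[list(labels), list(labels)].to_numpy(dtype=float)
    if not np.allclose(A, A.T, equal_nan=True):
        raise ValueError("pair matrix must be symmetric")
    return A


def nodal_means(tree: DatedTree, M: pd.DataFrame) -> pd.DataFrame:
    """Clade-balanced nodal mean of the tip-pair matrix at every internal
    node.  Returns a DataFrame with columns ``age`` and ``value`` indexed
    by internal node id (root last in postorder)."""
    idx = index_tree(tree)
    A = _aligned_matrix(M, idx.labels)
    W = _tip_weights(idx)
    rows = []
    for node in idx.internal:
        c1, c2 = idx.children[node - idx.n_tips]
        val = float(W[c1] @ A @ W[c2])
        rows.append((node, idx.age[node], val))
    return pd.DataFrame(rows, columns=["node", "age", "value"]
                        ).set_index("node")


def arc_regression(nodal: pd.DataFrame) -> Tuple[float, float]:
    """Ordinary least-squares slope and intercept of nodal value on node
    age.  Needs at least 3 internal nodes so the slope is not forced."""
    if len(nodal) < 3:
        raise ValueError("need >= 3 internal nodes (>= 4 tips) for the "
                         "age-range regression")
    x = nodal["age"].to_numpy(dtype=float)
    y = nodal["value"].to_numpy(dtype=float)
    if np.ptp(x) == 0:
        raise ValueError("all node ages identical; slope undefined")
    slope, intercept = np.polyfit(x, y, 1)
    return float(slope), float(intercept)


@dataclass
class ARCResult:
    slope: float
    intercept: float
    p_value: float
    n_iter: int
    nodal: pd.DataFrame
    null_slopes: np.ndarray = field(repr=False, default=None)


def mc_null(tree: DatedTree, M: pd.DataFrame, n_iter: int = 1000,
            seed: int = 0) -> ARCResult:
    """Monte-Carlo permutation test of the ARC slope.

    Tip identities are shuffled (simultaneous row/column permutation of
    M), keeping tree shape, node ages and the overlap distribution fixed.
    Two-sided p with add-one smoothing:
    p = (1 + #{|slope_null| >= |slope_obs|}) / (1 + n_iter).
    """
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    idx = index_tree(tree)
    A = _aligned_matrix(M, idx.labels)
    W = _tip_weights(idx)
    internal = idx.internal
    WL = np.stack([W[idx.children[n - idx.n_tips][0]] for n in internal])
    WR = np.stack([W[idx.children[n - idx.n_tips][1]] for n in internal])
    ages = np.array([idx.age[n] for n in internal], dtype=float)
    obs_vals = np.einsum("ki,ij,kj->k", WL, A, WR)
    nodal = pd.DataFrame({"age": ages, "value": obs_vals},
                         index=pd.Index(internal, name="node"))
    slope, intercept = arc_regression(nodal)

    rng = np.random.default_rng(seed)
    n = idx.n_tips
    perms = np.stack([rng.permutation(n) for _ in range(n_iter)])
    # permuted matrices A[p][:, p]; compute nodal values for all perms at
    # once: value[p, k] = WL[k] @ A[perm] @ WR[k]
    Ap = A[perms[:, :, None], perms[:, None, :]]  # (P, n, n)
    vals = np.einsum("ki,pij,kj->pk", WL, Ap, WR)
    # vectorised OLS slope per permutation
    xc = ages - ages.mean()
    sxx = float(xc @ xc)
    null_slopes = (vals - vals.mean(axis=1, keepdims=True)) @ xc / sxx
    p = (1 + int(np.sum(np.abs(null_slopes) >= abs(slope) - 1e-15))) / \
        (1 + n_iter)
    return ARCResult(slope=slope, intercept=intercept, p_value=p,
                     n_iter=n_iter, nodal=nodal, null_slopes=null_slopes)


def age_range_correlation(tree: DatedTree, M: pd.DataFrame,
                          n_iter: int = 1000, seed: int = 0) -> ARCResult:
    """Nodal means + OLS + Monte-Carlo null in one call."""
    return mc_null(tree, M, n_iter=n_iter, seed=seed)


def super_p(results: Sequence[ARCResult], alpha: float = 0.05) -> float:
    """Proportion of trees in a posterior sample whose individual
    permutation p falls below alpha."""
    if not results:
        raise ValueError("no ARC results supplied")
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    return float(np.mean([r.p_value < alpha for r in results]))
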