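"""Discrete-trait Mk models, stochastic character mapping and Pagel signal.

* Mk likelihood by Felsenstein pruning with per-branch transition
  probabilities exp(Q b); ER/SYM/ARD constraint patterns fitted by ML
  with AICc/LRT comparison.
* Marginal ancestral state probabilities by the standard two-pass
  (inside/outside) algorithm.
* Stochastic character maps: joint node states sampled from their
  conditional distribution, then endpoint-conditioned branch histories by
  rejection sampling with a uniformization fallback; shift ages binned on
  a 0.5-Myr grid anchored at the present.
* Pagel's lambda and kappa for continuous characters by profile ML under
  Brownian motion on the transformed tree, and a transform-then-fit-Mk
  analogue for discrete characters.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.linalg import expm

from .qmatrix import QMatrix
from .trees import DatedTree, TreeSample
from ._treeindex import TreeIndex, index_tree

__all__ = [
    "QMatrix",
    "StochasticMap",
    "ShiftHistogram",
    "PagelEstimate",
    "mk_loglik",
    "fit_mk",
    "ancestral_marginal",
    "simmap_sample",
    "simmap_over_sample",
    "shift_histogram",
    "pagel_continuous",
    "pagel_discrete",
    "multiaxis_signal",
]


# ---------------------------------------------------------------------------
# transition probabilities


def _transition_matrices(Q: QMatrix, lengths: np.ndarray) -> np.ndarray:
    """P(b) = exp(Q b) for every branch length, via eigendecomposition
    with an expm fallback for defective generators."""
    M = Q.matrix
    try:
        w, V = np.linalg.eig(M)
        Vinv = np.linalg.inv(V)
        if np.linalg.cond(V) > 1e8:
            raise np.linalg.LinAlgError
        P = np.einsum("ij,bj,jk->bik", V, np.exp(np.outer(lengths, w)), Vinv)
        P = np.real(P)
    except np.linalg.LinAlgError:
        P = np.stack([expm(M * b) for b in lengths])
    np.clip(P, 0.0, None, out=P)
    P /= P.sum(axis=2, keepdims=True)
    return P


def _tip_conditionals(idx: TreeIndex, trait: pd.Series, Q: QMatrix
                      ) -> np.ndarray:
    L = np.zeros((idx.n_nodes, Q.k))
    for i, lab in enumerate(idx.labels):
        if lab not in trait.index:
            raise ValueError(f"tip {lab!r} missing from trait data")
        L[i, Q.state_index(str(trait[lab]))] = 1.0
    return L


def _root_prior(Q: QMatrix, spec, L_root: np.ndarray | None = None
                ) -> np.ndarray:
    if isinstance(spec, str):
        if spec == "uniform":
            return np.full(Q.k, 1.0 / Q.k)
        if spec in ("stationary", "estimated"):
            return Q.stationary()
        if spec == "fitzjohn":
            if L_root is None:
                raise ValueError("fitzjohn prior needs root conditionals")
            s = L_root.sum()
            return L_root / s if s > 0 else np.full(Q.k, 1.0 / Q.k)
        raise ValueError(f"unknown root prior {spec!r}")
    p = np.asarray(spec, dtype=float)
    return p / p.sum()


def _pruning(idx: TreeIndex, L: np.ndarray, P: np.ndarray
             ) -> Tuple[np.ndarray, float]:
    """Postorder conditionals with per-node rescaling; returns the scaled
    conditionals and the accumulated log scale factor."""
    L = L.copy()
    log_scale = 0.0
    for node in idx.internal:
        c1, c2 = idx.children[node - idx.n_tips]
        v = (P[c1] @ L[c1]) * (P[c2] @ L[c2])
        s = v.sum()
        if s <= 0:
            return L, -math.inf
        L[node] = v / s
        log_scale += math.log(s)
    return L, log_scale


def mk_loglik(tree: DatedTree, trait: pd.Series, Q: QMatrix,
              root_prior="uniform") -> float:
    """Mk log-likelihood of tip states under generator ``Q``."""
    idx = index_tree(tree)
    P = _transition_matrices(Q, idx.branch_length)
    L = _tip_conditionals(idx, trait, Q)
    L, log_scale = _pruning(idx, L, P)
    if not math.isfinite(log_scale):
        return -math.inf
    prior = _root_prior(Q, root_prior, L[idx.root])
    val = float(prior @ L[idx.root])
    if val <= 0:
        return -math.inf
    return math.log(val) + log_scale


def fit_mk(tree: DatedTree, trait: pd.Series, pattern: str = "ER",
           root_prior="uniform") -> Tuple[QMatrix, float, float]:
    """ML fit of an Mk model under the ER/SYM/ARD constraint pattern.

    Returns (Q-hat, logL, AICc); AICc uses the tip count as sample size.
    """
    states = tuple(sorted(set(str(v) for v in trait.values)))
    if len(states) < 2:
        raise ValueError("need at least 2 observed states to fit Mk")
    k = len(states)
    n_rates = {"ER": 1, "SYM": k * (k - 1) // 2, "ARD": k * (k - 1)}[pattern]
    idx = index_tree(tree)
    span = max(tree.root_age, 1e-9)
    L_tips = None  # built once inside nll via closure caching

    def nll(logr):
        Q = QMatrix.from_pattern(states, pattern, np.exp(logr))
        ll = mk_loglik(tree, trait, Q, root_prior)
        return -ll if math.isfinite(ll) else 1e12

    x0 = np.full(n_rates, math.log(1.0 / span))
    res = optimize.minimize(nll, x0, method="L-BFGS-B",
                            bounds=[(-14.0, 8.0)] * n_rates,
                            options={"maxiter": 500})
    if not np.isfinite(res.fun):
        raise RuntimeError(f"Mk optimisation failed: {res.message}")
    Qhat = QMatrix.from_pattern(states, pattern, np.exp(res.x))
    logL = -float(res.fun)
    n_obs = tree.n_tips
    kk = n_rates
    denom = n_obs - kk - 1
    aicc = (-2 * logL + 2 * kk + (2 * kk * (kk + 1) / denom
                                  if denom > 0 else math.inf))
    return Qhat, logL, aicc


# ---------------------------------------------------------------------------
# marginal ancestral states


def ancestral_marginal(tree: DatedTree, trait: pd.Series, Q: QMatrix,
                       root_prior="uniform") -> pd.DataFrame:
    """Marginal state probabilities for every node (tips are point masses).

    Rows are node indices of the array-indexed tree (tips 0..n-1 in
    sorted-label order, internals in postorder), columns the states.
    """
    idx = index_tree(tree)
    P = _transition_matrices(Q, idx.branch_length)
    L = _tip_conditionals(idx, trait, Q)
    L, log_scale = _pruning(idx, L, P)
    if not math.isfinite(log_scale):
        raise ValueError("tip configuration has zero likelihood under Q")
    prior = _root_prior(Q, root_prior, L[idx.root])
    # outside pass: A[v] = P(data outside subtree of v | state at v)
    A = np.zeros_like(L)
    A[idx.root] = prior
    for node in reversed(idx.internal):
        c1, c2 = idx.children[node - idx.n_tips]
        down1 = P[c1] @ L[c1]
        down2 = P[c2] @ L[c2]
        for child, sib_down in ((c1, down2), (c2, down1)):
            msg = A[node] * sib_down
            A[child] = msg @ P[child]
            s = A[child].sum()
            if s > 0:
                A[child] /= s
    probs = A * L
    probs /= probs.sum(axis=1, keepdims=True)
    return pd.DataFrame(probs, columns=list(Q.states))


# ---------------------------------------------------------------------------
# stochastic character mapping


@dataclass
class StochasticMap:
    """One sampled character history: states at nodes plus, per branch,
    the ordered list of (age, from-state, to-state) changes."""

    states: Tuple[str, ...]
    node_states: np.ndarray                       # state index per node
    events: Dict[int, List[Tuple[float, str, str]]]  # node-below -> changes

    @property
    def n_changes(self) -> int:
        return sum(len(v) for v in self.events.values())

    def change_ages(self) -> List[float]:
        return [age for ev in self.events.values() for age, _, _ in ev]


def _sample_path_rejection(a: int, b: int, t: float, Q: np.ndarray,
                           rng: np.random.Generator, max_tries: int
                           ) -> List[Tuple[float, int, int]] | None:
    k = Q.shape[0]
    for _ in range(max_tries):
        s, tau, path = a, 0.0, []
        while True:
            rate = -Q[s, s]
            if rate <= 0:
                break
            tau += rng.exponential(1.0 / rate)
            if tau >= t:
                break
            p = Q[s].copy()
            p[s] = 0.0
            p /= p.sum()
            s_new = int(rng.choice(k, p=p))
            path.append((tau, s, s_new))
            s = s_new
        if s == b:
            return path
    return None


def _sample_path_uniformization(a: int, b: int, t: float, Q: np.ndarray,
                                P_ab: float, rng: np.random.Generator
                                ) -> List[Tuple[float, int, int]]:
    k = Q.shape[0]
    omega = max(-Q.diagonal().min(), 1e-12) * 1.05
    R = np.eye(k) + Q / omega
    # sample the number of uniformized jumps n | endpoints
    u = rng.random()
    pois = math.exp(-omega * t)
    Rpow = [np.eye(k)]
    cum = pois * Rpow[0][a, b] / max(P_ab, 1e-300)
    n = 0
    while cum < u and n < 500:
        n += 1
        pois *= omega * t / n
        Rpow.append(Rpow[-1] @ R)
        cum += pois * Rpow[n][a, b] / max(P_ab, 1e-300)
    # sample the jump chain conditioned on endpoints
    states = [a]
    for i in range(1, n):
        prev = states[-1]
        w = R[prev] * Rpow[n - i][:, b]
        s = w.sum()
        states.append(int(rng.choice(k, p=w / s)) if s > 0 else prev)
    if n > 0:
        states.append(b)
    times = np.sort(rng.random(n)) * t
    path = []
    for i in range(n):
        if states[i] != states[i + 1]:
            path.append((float(times[i]), states[i], states[i + 1]))
    return path


def simmap_sample(tree: DatedTree, trait: pd.Series, Q: QMatrix,
                  n_maps: int = 500, root_prior="estimated",
                  seed: int = 0, max_rejection: int = 200
                  ) -> List[StochasticMap]:
    """Draw stochastic character maps conditional on tip data and ``Q``.

    Node states are sampled jointly from their conditional distribution
    (root from prior x root conditionals, children given parents), then
    each branch history is simulated conditional on its endpoints.  The
    'estimated' root prior is the stationary distribution of ``Q``.
    """
    idx = index_tree(tree)
    P = _transition_matrices(Q, idx.branch_length)
    L0 = _tip_conditionals(idx, trait, Q)
    L, log_scale = _pruning(idx, L0, P)
    if not math.isfinite(log_scale):
        raise ValueError("tip configuration has zero likelihood under Q")
    prior = _root_prior(Q, root_prior, L[idx.root])
    rng = np.random.default_rng(seed)
    k = Q.k
    down = np.einsum("nij,nj->ni", P, L)  # P[c] @ L[c] per node
    maps: List[StochasticMap] = []
    preorder = [idx.root] + [n for n in np.argsort(-idx.age)
                             if n != idx.root]
    uses_fallback = 0
    for _ in range(n_maps):
        ns = np.empty(idx.n_nodes, dtype=int)
        w = prior * L[idx.root]
        ns[idx.root] = rng.choice(k, p=w / w.sum())
        for node in preorder:
            if node == idx.root:
                continue
            par = idx.parent[node]
            w = P[node][ns[par]] * L[node]
            s = w.sum()
            ns[node] = rng.choice(k, p=w / s)
        events: Dict[int, List[Tuple[float, str, str]]] = {}
        for node in preorder:
            if node == idx.root:
                continue
            par = idx.parent[node]
            t = idx.branch_length[node]
            a, b = int(ns[par]), int(ns[node])
            path = _sample_path_rejection(a, b, t, Q.matrix, rng,
                                          max_rejection)
            if path is None:
                uses_fallback += 1
                path = _sample_path_uniformization(
                    a, b, t, Q.matrix, float(P[node][a, b]), rng)
            if path:
                top = idx.age[par]
                events[int(node)] = [
                    (top - tau, Q.states[x], Q.states[y])
                    for tau, x, y in path
                ]
        maps.append(StochasticMap(Q.states, ns, events))
    if uses_fallback:
        warnings.warn(
            f"uniformization fallback used for {uses_fallback} branch "
            "histories after rejection-sampling cap"
        )
    return maps


def simmap_over_sample(trees: TreeSample, trait: pd.Series,
                       pattern: str = "ER", n_maps: int = 100,
                       seed: int = 0) -> Dict:
    """Fit Mk and draw maps on every tree of a sample.

    A tree whose fit or mapping fails is retried once with a fresh seed
    and then dropped with a warning; the result reports the retained
    tree count alongside the pooled maps.
    """
    pooled: List[List[StochasticMap]] = []
    retained = []
    for i, tree in enumerate(trees):
        for attempt in range(2):
            try:
                Q, _, _ = fit_mk(tree, trait, pattern)
                maps = simmap_sample(tree, trait, Q, n_maps,
                                     seed=seed + 1000 * i + attempt)
                pooled.append(maps)
                retained.append(i)
                break
            except Exception as exc:  # optimisation can fail on odd trees
                if attempt == 1:
                    warnings.warn(f"tree {i} dropped after retry: {exc}")
    return {"maps": pooled, "retained": retained,
            "n_retained": len(retained), "n_total": len(trees)}


# ---------------------------------------------------------------------------
# shift histograms


@dataclass
class ShiftHistogram:
    bin_edges: np.ndarray          # ascending ages, anchored at 0
    median: np.ndarray             # per-bin median change count across maps
    q05: np.ndarray
    q95: np.ndarray
    counts: np.ndarray             # (n_maps, n_bins)

    def total_per_map(self) -> np.ndarray:
        return self.counts.sum(axis=1)


def shift_histogram(maps: Sequence[StochasticMap], bin_width: float = 0.5,
                    max_age: float | None = None) -> ShiftHistogram:
    """Median (and 5/95% envelope) of per-bin change counts across maps.

    Bins are ``[0, w), [w, 2w), ...`` anchored at the present; maps drawn
    on different trees of a sample may be pooled directly.
    """
    all_ages = [m.change_ages() for m in maps]
    if max_age is None:
        flat = [a for ages in all_ages for a in ages]
        max_age = max(flat) if flat else bin_width
    n_bins = max(int(math.ceil(max_age / bin_width + 1e-9)), 1)
    edges = np.arange(n_bins + 1) * bin_width
    counts = np.zeros((len(maps), n_bins))
    for i, ages in enumerate(all_ages):
        if ages:
            counts[i], _ = np.histogram(ages, bins=edges)
    return ShiftHistogram(
        bin_edges=edges,
        median=np.median(counts, axis=0),
        q05=np.quantile(counts, 0.05, axis=0),
        q95=np.quantile(counts, 0.95, axis=0),
        counts=counts,
    )


# ---------------------------------------------------------------------------
# Pagel lambda / kappa


@dataclass
class PagelEstimate:
    statistic: str                 # lambda | kappa
    estimate: float
    logL: float
    per_axis: List[float] = field(default_factory=list)


LAMBDA_MAX = 1.05  # allow a small overshoot so boundary estimates show up
KAPPA_MAX = 3.0


def _bm_profile_loglik(V: np.ndarray, x: np.ndarray) -> float:
    """Brownian ML log-likelihood with the mean and rate profiled out."""
    n = len(x)
    try:
        Lc = np.linalg.cholesky(V)
    except np.linalg.LinAlgError:
        return -math.inf
    ones = np.ones(n)
    a = np.linalg.solve(Lc, x)
    b = np.linalg.solve(Lc, ones)
    mu = (b @ a) / (b @ b)
    resid = a - mu * b
    s2 = float(resid @ resid) / n
    if s2 <= 0:
        return -math.inf
    logdet = 2.0 * np.log(np.diag(Lc)).sum()
    return -0.5 * (n * math.log(2 * math.pi * s2) + logdet + n)


def pagel_continuous(tree: DatedTree, x: pd.Series,
                     statistic: str = "lambda") -> PagelEstimate:
    """Profile-ML estimate of Pagel's lambda or kappa for a continuous
    character under Brownian motion on the transformed tree."""
    labels = tree.tip_labels
    if len(labels) < 4:
        raise ValueError("signal estimation needs >= 4 tips")
    vals = np.asarray([float(x[l]) for l in labels])
    if np.allclose(vals, vals[0]):
        raise ValueError("zero-variance trait has no estimable signal")

    if statistic == "lambda":
        C = tree.brownian_cov().loc[labels, labels].values
        diag = np.diag(C).copy()

        def nll(lam):
            V = C * lam
            np.fill_diagonal(V, diag)
            return -_bm_profile_loglik(V, vals)

        res = optimize.minimize_scalar(nll, bounds=(0.0, LAMBDA_MAX),
                                       method="bounded",
                                       options={"xatol": 1e-8})
        est, logL = float(res.x), -float(res.fun)
        # the profile can be flat/boundary-maximised; check the endpoints
        for cand in (0.0, 1.0):
            if -nll(cand) > logL:
                est, logL = cand, -nll(cand)
        return PagelEstimate("lambda", est, logL)

    if statistic == "kappa":
        def nll_k(kap):
            V = tree.transform_kappa(kap).brownian_cov().loc[
                labels, labels].values
            return -_bm_profile_loglik(V, vals)

        res = optimize.minimize_scalar(nll_k, bounds=(0.0, KAPPA_MAX),
                                       method="bounded",
                                       options={"xatol": 1e-6})
        return PagelEstimate("kappa", float(res.x), -float(res.fun))

    raise ValueError(f"unknown statistic {statistic!r}")


def _lambda_transform_tree(tree: DatedTree, lam: float) -> DatedTree:
    """Pagel-lambda tree transform for discrete models: internal branches
    scaled by lam, terminal branches stretched to keep tip depths."""
    t = tree.dendropy_tree.clone(depth=1)
    depths = {}
    for node in t.preorder_node_iter():
        depths[node] = (0.0 if node.parent_node is None
                        else depths[node.parent_node]
                        + (node.edge.length or 0.0))
    for node in t.preorder_node_iter():
        if node.parent_node is None or node.edge.length is None:
            continue
        if node.is_leaf():
            parent_depth = depths[node.parent_node]
            node.edge.length = depths[node] - lam * parent_depth
        else:
            node.edge.length = lam * node.edge.length
    return DatedTree(t)


def pagel_discrete(tree: DatedTree, trait: pd.Series,
                   statistic: str = "lambda",
                   pattern: str = "ER") -> PagelEstimate:
    """Transform-then-fit-Mk analogue of Pagel's statistics for a discrete
    character; at parameter 1 it reduces to the untransformed Mk fit."""
    if statistic == "lambda":
        def nll(lam):
            work = _lambda_transform_tree(tree, lam)
            _, ll, _ = fit_mk(work, trait, pattern)
            return -ll
        hi = 1.0
    elif statistic == "kappa":
        def nll(kap):
            work = tree.transform_kappa(kap)
            _, ll, _ = fit_mk(work, trait, pattern)
            return -ll
        hi = KAPPA_MAX
    else:
        raise ValueError(f"unknown statistic {statistic!r}")
    res = optimize.minimize_scalar(nll, bounds=(0.0, hi), method="bounded",
                                   options={"xatol": 1e-4})
    return PagelEstimate(statistic, float(res.x), -float(res.fun))


def multiaxis_signal(trees: TreeSample, scores: pd.DataFrame, n_axes: int,
                     statistic: str = "lambda") -> Dict:
    """Average signal across the first ``n_axes`` ordination axes, per tree.

    The statistic is estimated per axis on each tree, averaged over axes
    within the tree, and summarised across trees by the median and the
    5%/95% quantiles.
    """
    if n_axes > scores.shape[1]:
        raise ValueError("n_axes exceeds available axes")
    tips = set(trees[0].tip_labels)
    if tips != set(scores.index):
        raise ValueError("tip labels do not match ordination scores")
    per_tree: List[float] = []
    per_tree_axes: List[List[float]] = []
    for tree in trees:
        axis_vals = []
        for a in range(n_axes):
            est = pagel_continuous(tree, scores.iloc[:, a], statistic)
            axis_vals.append(est.estimate)
        per_tree_axes.append(axis_vals)
        per_tree.append(float(np.mean(axis_vals)))
    arr = np.asarray(per_tree)
    return {
        "statistic": statistic,
        "per_tree": per_tree,
        "per_tree_axes": per_tree_axes,
        "median": float(np.median(arr)),
        "q05": float(np.quantile(arr, 0.05)),
        "q95": float(np.quantile(arr, 0.95)),
    }
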