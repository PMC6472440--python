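"""Mixed quantitative/categorical trait ordination and syndrome clustering.

Hill-Smith ordination puts quantitative and categorical variables in one
principal-components analysis.  Quantitative columns are standardised
(mean 0, variance 1 with the 1/n convention); each categorical variable
contributes one indicator column per level, centred as x/f_j - 1 where
f_j is the level frequency, and carries column weight f_j so the variable
as a whole has unit inertia.  Rows are weighted 1/n.  The weighted SVD of
this table reduces exactly to correlation-matrix PCA when all variables
are quantitative and to multiple correspondence analysis when all are
categorical -- both limits are enforced in the test suite.

Downstream helpers pick the smallest number of leading axes reaching a
cumulative-variance threshold (the published analyses keep 90%), cluster
species into syndromes with k-means on the row scores, and compute
Euclidean niche distances in the retained subspace.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Sequence, Tuple

import numpy as np
import pandas as pd

__all__ = [
    "MixedTraitTable",
    "Ordination",
    "hill_smith",
    "retained_axes",
    "SyndromeAssignment",
    "assign_syndromes",
    "habitat_distance_matrix",
]


@dataclass
class MixedTraitTable:
    """A species-by-trait table split into quantitative and categorical
    blocks.  Built from any DataFrame: numeric dtypes are treated as
    quantitative, everything else as categorical (values coerced to str).
    """

    data: pd.DataFrame
    quantitative: List[str]
    categorical: List[str]

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "MixedTraitTable":
        if df.index.has_duplicates:
            raise ValueError("duplicate species labels in trait table")
        if df.isna().any().any():
            bad = df.columns[df.isna().any()].tolist()
            raise ValueError(f"missing values in columns {bad}; "
                             "impute or drop before ordination")
        quant = [c for c in df.columns
                 if pd.api.types.is_numeric_dtype(df[c])]
        cat = [c for c in df.columns if c not in quant]
        return cls(df.copy(), quant, cat)

    @property
    def n_species(self) -> int:
        return len(self.data)


@dataclass
class Ordination:
    scores: pd.DataFrame          # species x axes (Axis1, Axis2, ...)
    eigenvalues: np.ndarray       # descending
    explained: np.ndarray         # fraction of total inertia per axis
    column_loadings: pd.DataFrame  # expanded columns x axes
    column_weights: pd.Series


def _expand(table: MixedTraitTable) -> Tuple[np.ndarray, np.ndarray,
                                             List[str]]:
    """Centred/scaled analysis table, column weights, column names."""
    df = table.data
    n = len(df)
    cols: List[np.ndarray] = []
    weights: List[float] = []
    names: List[str] = []
    for c in table.quantitative:
        x = df[c].to_numpy(dtype=float)
        sd = x.std(ddof=0)
        if sd == 0:
            raise ValueError(f"quantitative column {c!r} is constant; "
                             "drop it before ordination")
        cols.append((x - x.mean()) / sd)
        weights.append(1.0)
        names.append(c)
    for c in table.categorical:
        vals = df[c].astype(str).to_numpy()
        levels = sorted(set(vals))
        if len(levels) < 2:
            raise ValueError(f"categorical column {c!r} has a single "
                             "level; drop it before ordination")
        for lev in levels:
            ind = (vals == lev).astype(float)
            f = ind.mean()
            cols.append(ind / f - 1.0)
            weights.append(f)
            names.append(f"{c}={lev}")
    return np.column_stack(cols), np.asarray(weights), names


def hill_smith(table: MixedTraitTable | pd.DataFrame,
               n_axes: int | None = None) -> Ordination:
    """Weighted PCA of the mixed table (Hill & Smith 1976).

    Signs follow the convention that the first nonzero loading of each
    axis is positive, so results are reproducible across runs.
    """
    if isinstance(table, pd.DataFrame):
        table = MixedTraitTable.from_dataframe(table)
    X, cw, names = _expand(table)
    n = X.shape[0]
    rw = np.full(n, 1.0 / n)
    # weighted SVD: decompose diag(sqrt(rw)) X diag(sqrt(cw))
    Xt = np.sqrt(rw)[:, None] * X * np.sqrt(cw)[None, :]
    U, s, Vt = np.linalg.svd(Xt, full_matrices=False)
    eig = s ** 2
    keep = eig > max(eig[0], 1e-300) * 1e-12
    U, s, Vt, eig = U[:, keep], s[keep], Vt[keep], eig[keep]
    if n_axes is not None:
        U, s, Vt, eig = U[:, :n_axes], s[:n_axes], Vt[:n_axes], eig[:n_axes]
    # row scores in the metric of the analysis (principal coordinates)
    scores = (U * s) / np.sqrt(rw)[:, None]
    load = Vt.T / np.sqrt(cw)[:, None]
    # deterministic signs
    for a in range(scores.shape[1]):
        col = load[:, a]
        nz = np.nonzero(np.abs(col) > 1e-12)[0]
        if nz.size and col[nz[0]] < 0:
            load[:, a] *= -1.0
            scores[:, a] *= -1.0
    axes = [f"Axis{i+1}" for i in range(scores.shape[1])]
    total = float(np.sum(cw * np.average(X ** 2, axis=0, weights=rw)))
    return Ordination(
        scores=pd.DataFrame(scores, index=table.data.index, columns=axes),
        eigenvalues=eig,
        explained=eig / total,
        column_loadings=pd.DataFrame(load, index=names, columns=axes),
        column_weights=pd.Series(cw, index=names),
    )


def retained_axes(ord_: Ordination, threshold: float = 0.90) -> int:
    """Smallest axis count whose cumulative explained inertia reaches
    the threshold (the published analyses use 90%)."""
    if not 0 < threshold <= 1:
        raise ValueError("threshold must lie in (0, 1]")
    cum = np.cumsum(ord_.explained)
    hit = np.nonzero(cum >= threshold - 1e-12)[0]
    return int(hit[0]) + 1 if hit.size else len(cum)


@dataclass
class SyndromeAssignment:
    labels: pd.Series             # species -> syndrome id (str)
    k: int
    inertia: float
    silhouette: float | None      # None when k == 1 or k == n
    centers: pd.DataFrame | None  # k x axes; None for manual maps


def assign_syndromes(ord_: Ordination, k: int | None = None,
                     n_axes: int | None = None,
                     manual: Dict[str, str] | None = None,
                     seed: int = 0) -> SyndromeAssignment:
    """Cluster species into syndromes on the leading ordination axes.

    Either pass ``k`` for k-means (deterministic: fixed seed, 100
    restarts) or ``manual`` mapping species -> syndrome label, e.g. for
    published pollination syndromes.
    """
    if manual is not None:
        missing = [s for s in ord_.scores.index if s not in manual]
        if missing:
            raise ValueError(f"manual syndrome map missing species "
                             f"{missing[:5]}")
        lab = pd.Series({s: str(manual[s]) for s in ord_.scores.index})
        return SyndromeAssignment(lab, k=len(set(lab)), inertia=math.nan,
                                  silhouette=None, centers=None)
    if k is None:
        raise ValueError("pass k for k-means or a manual syndrome map")
    n = len(ord_.scores)
    if k < 1 or k > n:
        raise ValueError(f"k={k} outside [1, {n}]")
    X = ord_.scores.to_numpy()
    if n_axes is not None:
        X = X[:, :n_axes]
    from sklearn.cluster import KMeans
    km = KMeans(n_clusters=k, n_init=100, random_state=seed)
    raw = km.fit_predict(X)
    # relabel clusters in order of first appearance so output is stable
    seen: Dict[int, int] = {}
    lab = []
    for r in raw:
        if r not in seen:
            seen[r] = len(seen)
        lab.append(f"S{seen[r]+1}")
    labels = pd.Series(lab, index=ord_.scores.index)
    sil = None
    if 1 < k < n:
        from sklearn.metrics import silhouette_score
        sil = float(silhouette_score(X, raw))
    centers = pd.DataFrame(km.cluster_centers_,
                           index=[f"S{seen[r]+1}" for r in
                                  sorted(seen, key=seen.get)],
                           columns=ord_.scores.columns[:X.shape[1]])
    return SyndromeAssignment(labels, k=k, inertia=float(km.inertia_),
                              silhouette=sil, centers=centers)


def habitat_distance_matrix(ord_: Ordination,
                            n_axes: int | None = None) -> pd.DataFrame:
    """Pairwise Euclidean distances between species in the retained
    ordination subspace (all axes when ``n_axes`` is None)."""
    X = ord_.scores.to_numpy()
    if n_axes is not None:
        if n_axes < 1 or n_axes > X.shape[1]:
            raise ValueError(f"n_axes={n_axes} outside [1, {X.shape[1]}]")
        X = X[:, :n_axes]
    d2 = np.sum((X[:, None, :] - X[None, :, :]) ** 2, axis=-1)
    D = np.sqrt(np.maximum(d2, 0.0))
    return pd.DataFrame(D, index=ord_.scores.index,
                        columns=ord_.scores.index)
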