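"""Synthetic-data generators with known ground truth.

Every input class the pipeline consumes can be generated here: ultrametric
birth-death trees, perturbed tree samples standing in for a posterior
sample, discrete traits evolved under an Mk process, continuous traits
under Brownian motion with Pagel transforms, mixed quantitative/categorical
niche tables with planted syndrome structure, and planar species ranges
with controllable pairwise overlap.  Each generator is seed-deterministic
and returns a :class:`SimulationLog` recording the true parameters and the
full event history, so parameter-recovery and calibration tests can check
estimates against the truth that produced the data.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Dict, List, Sequence, Tuple

import numpy as np
import pandas as pd

from .qmatrix import QMatrix
from .ranges import SpeciesRange
from .trees import DatedTree, TreeSample
from ._treeindex import index_tree

__all__ = [
    "SimulationLog",
    "simulate_bd",
    "simulate_tree_sample",
    "simulate_mk",
    "simulate_bm",
    "simulate_ranges",
    "simulate_ranges_on_tree",
    "simulate_mixed_traits",
]


@dataclass
class SimulationLog:
    seed: int
    model: str
    params: Dict
    events: List[Dict] = field(default_factory=list)

    def to_json(self, path: str | None = None) -> str:
        blob = json.dumps(
            {"seed": self.seed, "model": self.model,
             "params": self.params, "events": self.events},
            indent=1, default=float,
        )
        if path is not None:
            with open(path, "w") as fh:
                fh.write(blob)
        return blob


# ---------------------------------------------------------------------------
# birth-death trees


class _Lineage:
    __slots__ = ("birth", "children", "end", "extinct")

    def __init__(self, birth: float):
        self.birth = birth
        self.children: List["_Lineage"] | None = None
        self.end: float | None = None
        self.extinct = False


def _forward_bd(lambda_: float, mu: float, rng: np.random.Generator,
                n_stop: int | None, t_stop: float | None, events: List[Dict]):
    """One forward pass from a crown bifurcation; returns (root pair, T)."""
    a, b = _Lineage(0.0), _Lineage(0.0)
    alive = [a, b]
    t = 0.0
    while True:
        k = len(alive)
        if k == 0:
            return None  # complete extinction
        if n_stop is not None and k >= n_stop:
            # extend to just before the next event so tips get positive
            # terminal branches (crown age adds one Exp(k(lambda+mu)) wait)
            t += rng.exponential(1.0 / (k * (lambda_ + mu)))
            break
        total = k * (lambda_ + mu)
        dt = rng.exponential(1.0 / total)
        if t_stop is not None and t + dt >= t_stop:
            t = t_stop
            break
        t += dt
        lin = alive[rng.integers(k)]
        if rng.random() < lambda_ / (lambda_ + mu):
            lin.end = t
            lin.children = [_Lineage(t), _Lineage(t)]
            alive.remove(lin)
            alive.extend(lin.children)
            events.append({"type": "speciation", "time": t})
        else:
            lin.end = t
            lin.extinct = True
            alive.remove(lin)
            events.append({"type": "extinction", "time": t})
    for lin in alive:
        lin.end = t
    return (a, b), t


def _prune_newick(lin: _Lineage, T: float, counter: List[int]) -> str | None:
    """Newick of the extant part of the subtree above ``lin``'s birth."""
    if lin.children is None:
        if lin.extinct:
            return None
        counter[0] += 1
        return f"t{counter[0]}:{T - lin.birth:.12f}"
    subs = [_prune_newick(c, T, counter) for c in lin.children]
    subs = [s for s in subs if s is not None]
    if not subs:
        return None
    if len(subs) == 1:
        # unifurcation: extend the surviving child's branch down to birth
        head = subs[0][: subs[0].rfind(":")]
        tail = float(subs[0][subs[0].rfind(":") + 1:])
        return f"{head}:{tail + (lin.end - lin.birth):.12f}"
    return f"({subs[0]},{subs[1]}):{lin.end - lin.birth:.12f}"


def simulate_bd(lambda_: float, mu: float = 0.0, *,
                n_tips: int | None = None, time: float | None = None,
                seed: int = 0, max_retries: int = 100
                ) -> Tuple[DatedTree, SimulationLog]:
    """Simulate a reconstructed (extant-only) ultrametric birth-death tree.

    Stopping is either at ``n_tips`` extant lineages (the tree is cut just
    before the first event after the n-th tip is born, so under pure birth
    the crown age is a sum of Exp(k*lambda) waits for k = 2..n) or at
    elapsed ``time`` from the crown.  Extinct lineages are pruned; the log keeps every
    speciation and extinction with forward times from the crown.
    """
    if lambda_ <= 0:
        raise ValueError("lambda must be > 0")
    if mu < 0:
        raise ValueError("mu must be >= 0")
    if (n_tips is None) == (time is None):
        raise ValueError("specify exactly one of n_tips or time")
    if n_tips is not None and n_tips < 2:
        raise ValueError("n_tips must be >= 2")
    if n_tips is not None and mu >= lambda_:
        raise ValueError("n-conditioned stopping needs mu < lambda")
    rng = np.random.default_rng(seed)
    for attempt in range(max_retries):
        events: List[Dict] = []
        res = _forward_bd(lambda_, mu, rng, n_tips, time, events)
        if res is None:
            continue
        (a, b), T = res
        counter = [0]
        left = _prune_newick(a, T, counter)
        right = _prune_newick(b, T, counter)
        if left is None and right is None:
            continue
        if left is None or right is None:
            survivor = left or right
            # only one crown lineage survived; a lone tip is no tree
            if "(" not in survivor:
                continue
            newick = survivor[: survivor.rfind(":")] + ";"
        else:
            newick = f"({left},{right});"
        tree = DatedTree.from_newick(newick)
        if tree.n_tips < 2:
            continue
        log = SimulationLog(
            seed=seed, model="birth-death",
            params={"lambda": lambda_, "mu": mu, "n_tips": n_tips,
                    "time": time, "crown_age": tree.root_age,
                    "attempt": attempt},
            events=events,
        )
        return tree, log
    raise RuntimeError(
        f"all lineages went extinct in {max_retries} attempts; "
        "lower mu or raise max_retries"
    )


# ---------------------------------------------------------------------------
# perturbed tree samples


def simulate_tree_sample(base: DatedTree, n_trees: int, jitter: float,
                         seed: int = 0, n_label_swaps: int = 0
                         ) -> Tuple[TreeSample, SimulationLog]:
    """Jittered copies of ``base`` standing in for a posterior tree sample.

    Branch lengths get i.i.d. mean-preserving lognormal noise, tips are
    re-aligned to the deepest tip, and all depths are rescaled so the
    crown age equals ``g * base crown age`` with g itself lognormal with
    sd ``jitter`` -- hence the crown-age coefficient of variation across
    the sample is ~``jitter``.  Topology is fixed by default; the optional
    ``n_label_swaps`` exchanges labels of random tip pairs to emulate
    near-tip topological uncertainty.
    """
    if jitter < 0:
        raise ValueError("jitter must be >= 0")
    base.require_ultrametric("tree-sample simulation")
    rng = np.random.default_rng(seed)
    base_crown = base.root_age
    trees: List[DatedTree] = []
    for _ in range(n_trees):
        if jitter == 0 and n_label_swaps == 0:
            trees.append(base.copy())
            continue
        t = base.dendropy_tree.clone(depth=1)
        if jitter > 0:
            sig = jitter
            for e in t.preorder_edge_iter():
                if e.head_node is t.seed_node or e.length is None:
                    continue
                e.length = float(e.length) * float(
                    rng.lognormal(-0.5 * sig * sig, sig))
            # re-ultrametrise: extend each terminal branch to the max depth
            depths = {}
            for node in t.preorder_node_iter():
                depths[node] = (0.0 if node.parent_node is None
                                else depths[node.parent_node]
                                + (node.edge.length or 0.0))
            leaves = list(t.leaf_node_iter())
            dmax = max(depths[l] for l in leaves)
            for l in leaves:
                l.edge.length = (l.edge.length or 0.0) + (dmax - depths[l])
            # rescale so the crown age is g * base crown age
            g = float(rng.lognormal(-0.5 * sig * sig, sig))
            scale = g * base_crown / dmax
            for e in t.preorder_edge_iter():
                if e.length is not None:
                    e.length *= scale
        if n_label_swaps > 0:
            leaves = sorted(t.leaf_node_iter(), key=lambda l: l.taxon.label)
            for _ in range(n_label_swaps):
                i, j = rng.choice(len(leaves), size=2, replace=False)
                leaves[i].taxon, leaves[j].taxon = (leaves[j].taxon,
                                                    leaves[i].taxon)
        trees.append(DatedTree(t))
    log = SimulationLog(seed=seed, model="tree-sample",
                        params={"n_trees": n_trees, "jitter": jitter,
                                "n_label_swaps": n_label_swaps,
                                "base_crown_age": base_crown})
    return TreeSample(trees), log


# ---------------------------------------------------------------------------
# discrete traits under Mk


def simulate_mk(tree: DatedTree, Q: QMatrix,
                root_state: str | None = None,
                root_prior: Sequence[float] | None = None,
                seed: int = 0) -> Tuple[pd.Series, SimulationLog]:
    """Evolve a discrete character along the tree under generator ``Q``.

    Every state change is logged with the node below its branch and its
    absolute age, which suffices to reconstruct the full trajectory.
    """
    idx = index_tree(tree)
    rng = np.random.default_rng(seed)
    k = Q.k
    if root_state is not None:
        s_root = Q.state_index(root_state)
    else:
        prior = (np.asarray(root_prior, dtype=float)
                 if root_prior is not None else np.full(k, 1.0 / k))
        prior = prior / prior.sum()
        s_root = int(rng.choice(k, p=prior))
    states = np.empty(idx.n_nodes, dtype=int)
    states[idx.root] = s_root
    events: List[Dict] = []
    # walk branches from the root toward the present (decreasing node age)
    for node in np.argsort(-idx.age):
        if node == idx.root:
            continue
        par = idx.parent[node]
        s = states[par]
        t_bot = idx.age[node]  # younger end of the branch
        t = idx.age[par]       # older end
        while True:
            rate = -Q.matrix[s, s]
            if rate <= 0:
                break
            t = t - rng.exponential(1.0 / rate)
            if t <= t_bot:
                break
            probs = Q.matrix[s].copy()
            probs[s] = 0.0
            probs = probs / probs.sum()
            s_new = int(rng.choice(k, p=probs))
            events.append({"type": "change", "age": float(t),
                           "node_below": int(node),
                           "from": Q.states[s], "to": Q.states[s_new]})
            s = s_new
        states[node] = s
    trait = pd.Series([Q.states[states[i]] for i in range(idx.n_tips)],
                      index=idx.labels, name="state")
    log = SimulationLog(seed=seed, model="mk",
                        params={"states": list(Q.states),
                                "Q": Q.matrix.tolist(),
                                "root_state": Q.states[s_root]},
                        events=events)
    return trait, log


# ---------------------------------------------------------------------------
# continuous traits under (transformed) Brownian motion


def simulate_bm(tree: DatedTree, sigma2: float, lambda_: float = 1.0,
                kappa: float = 1.0, root_value: float = 0.0,
                seed: int = 0) -> Tuple[pd.Series, SimulationLog]:
    """Multivariate-normal draw from the Pagel-transformed Brownian model."""
    if sigma2 < 0:
        raise ValueError("sigma2 must be >= 0")
    if not 0.0 <= lambda_ <= 1.0:
        raise ValueError("lambda must lie in [0, 1]")
    work = tree if kappa == 1.0 else tree.transform_kappa(kappa)
    C = work.brownian_cov()
    V = C.values * lambda_
    np.fill_diagonal(V, np.diag(C.values))
    rng = np.random.default_rng(seed)
    n = V.shape[0]
    if sigma2 > 0:
        L = np.linalg.cholesky(sigma2 * V + 1e-12 * np.eye(n))
        x = root_value + L @ rng.standard_normal(n)
    else:
        x = np.full(n, root_value)
    trait = pd.Series(x, index=list(C.index), name="value")
    log = SimulationLog(seed=seed, model="brownian",
                        params={"sigma2": sigma2, "lambda": lambda_,
                                "kappa": kappa, "root_value": root_value})
    return trait, log


# ---------------------------------------------------------------------------
# species ranges


def _disjoint_centres(k: int, width: float, height: float, radius: float,
                      rng: np.random.Generator) -> List[Tuple[float, float]]:
    """Grid placement of k disk centres with guaranteed separation."""
    pitch = 2.0 * radius * 1.25
    nx = int(width // pitch)
    ny = int(height // pitch)
    if nx * ny < k:
        raise ValueError(
            f"landscape {width}x{height} km too small for {k} disjoint "
            f"ranges of radius {radius} km"
        )
    cells = [(i, j) for i in range(nx) for j in range(ny)]
    picks = rng.choice(len(cells), size=k, replace=False)
    out = []
    for p in picks:
        i, j = cells[p]
        out.append((radius + i * pitch, radius + j * pitch))
    return out


def simulate_ranges(labels: Sequence[str],
                    landscape: Tuple[float, float] = (100.0, 100.0),
                    mode: str = "mixed",
                    radius_km: float = 5.0,
                    target_mean_overlap: float = 0.187,
                    points_per_species: int = 8,
                    seed: int = 0
                    ) -> Tuple[Dict[str, SpeciesRange], pd.DataFrame,
                               SimulationLog]:
    """Planar species ranges with controllable pairwise overlap.

    * ``allopatric``: disjoint disks, every pairwise overlap is 0.
    * ``sympatric``: nested concentric disks, every pairwise overlap is 1.
    * ``mixed``: a nested block of m species plus allopatric singletons,
      with m chosen so the fraction of fully-overlapping pairs is as close
      as possible to ``target_mean_overlap`` (default the empirically
      realistic 0.187).

    Returns shapely-backed ranges, an occurrence table (species, x_km,
    y_km) of points drawn inside each range, and the simulation log.
    """
    from shapely.geometry import Point

    labels = list(labels)
    k = len(labels)
    w, h = landscape
    if w <= 0 or h <= 0:
        raise ValueError("landscape must have positive area")
    if mode not in ("allopatric", "sympatric", "mixed"):
        raise ValueError(f"unknown mode {mode!r}")
    rng = np.random.default_rng(seed)

    if mode == "allopatric":
        centres = _disjoint_centres(k, w, h, radius_km, rng)
        radii = [radius_km] * k
    elif mode == "sympatric":
        cx, cy = w / 2.0, h / 2.0
        centres = [(cx, cy)] * k
        radii = [radius_km * (1.0 + 0.5 * i / max(k - 1, 1)) for i in range(k)]
    else:
        n_pairs = k * (k - 1) // 2
        best_m, best_err = 0, float("inf")
        for m in range(0, k + 1):
            frac = (m * (m - 1) / 2) / n_pairs
            err = abs(frac - target_mean_overlap)
            if err < best_err:
                best_m, best_err = m, err
        m = best_m
        n_sites = k - m + (1 if m else 0)
        sites = _disjoint_centres(n_sites, w, h, 2.0 * radius_km, rng)
        centres, radii = [], []
        if m:
            cx, cy = sites[0]
            for i in range(m):
                centres.append((cx, cy))
                radii.append(radius_km * (1.0 + 0.5 * i / max(m - 1, 1)))
        for c in sites[1 if m else 0:]:
            centres.append(c)
            radii.append(radius_km)

    ranges: Dict[str, SpeciesRange] = {}
    occ_rows = []
    for lab, (cx, cy), r in zip(labels, centres, radii):
        geom = Point(cx, cy).buffer(r, quad_segs=64)
        ranges[lab] = SpeciesRange(lab, geom, geom.area)
        for _ in range(points_per_species):
            rr = r * math.sqrt(rng.random())
            th = 2 * math.pi * rng.random()
            occ_rows.append({"species": lab, "x_km": cx + rr * math.cos(th),
                             "y_km": cy + rr * math.sin(th)})
    occurrences = pd.DataFrame(occ_rows)
    log = SimulationLog(seed=seed, model="ranges",
                        params={"mode": mode, "landscape": [w, h],
                                "radius_km": radius_km,
                                "target_mean_overlap": target_mean_overlap,
                                "centres": [list(c) for c in centres],
                                "radii": list(radii)})
    return ranges, occurrences, log


def simulate_ranges_on_tree(tree: DatedTree, radius_km: float = 5.0,
                            seed: int = 0
                            ) -> Tuple[Dict[str, SpeciesRange], SimulationLog]:
    """Ranges whose geographic distance tracks phylogenetic distance.

    Range centroids diffuse in the plane along the tree (planar Brownian
    motion), so recently diverged species sit close together and their
    fixed-radius disks overlap, while old splits lie far apart -- the
    signature of divergence in place used to exercise the power of
    age-range-correlation tests.
    """
    from shapely.geometry import Point

    sigma2 = (4.0 * radius_km ** 2) / max(tree.root_age, 1e-9)
    xs, _ = simulate_bm(tree, sigma2, seed=seed)
    ys, _ = simulate_bm(tree, sigma2, seed=seed + 1)
    ranges = {}
    for lab in xs.index:
        geom = Point(float(xs[lab]), float(ys[lab])).buffer(radius_km,
                                                            quad_segs=64)
        ranges[lab] = SpeciesRange(lab, geom, geom.area)
    log = SimulationLog(seed=seed, model="ranges-on-tree",
                        params={"radius_km": radius_km, "sigma2": sigma2})
    return ranges, log


# ---------------------------------------------------------------------------
# mixed niche tables


def simulate_mixed_traits(labels: Sequence[str], n_quant: int, n_qual: int,
                          syndrome_map: Dict[str, int],
                          separation: float = 3.0,
                          n_levels: int = 3,
                          seed: int = 0
                          ) -> Tuple[pd.DataFrame, SimulationLog]:
    """Mixed quantitative/categorical trait table with planted syndromes.

    Quantitative columns are cluster means (drawn N(0, separation^2)) plus
    unit noise; categorical columns favour a cluster-preferred level with
    probability (1+separation)/(n_levels+separation).  ``separation=0``
    yields no recoverable structure.
    """
    if separation < 0:
        raise ValueError("separation must be >= 0")
    labels = list(labels)
    clusters = sorted(set(syndrome_map.values()))
    missing = [l for l in labels if l not in syndrome_map]
    if missing:
        raise ValueError(f"syndrome_map misses labels: {missing}")
    rng = np.random.default_rng(seed)
    centres = {c: rng.normal(0.0, separation, size=n_quant) for c in clusters}
    prefs = {c: rng.integers(0, n_levels, size=n_qual) for c in clusters}
    level_names = [f"L{j}" for j in range(n_levels)]
    p_pref = (1.0 + separation) / (n_levels + separation)
    data: Dict[str, list] = {}
    for qi in range(n_quant):
        data[f"q{qi + 1}"] = [
            centres[syndrome_map[lab]][qi] + rng.normal() for lab in labels
        ]
    for ci in range(n_qual):
        col = []
        for lab in labels:
            pref = int(prefs[syndrome_map[lab]][ci])
            if rng.random() < p_pref:
                col.append(level_names[pref])
            else:
                others = [l for j, l in enumerate(level_names) if j != pref]
                col.append(others[rng.integers(len(others))])
        data[f"c{ci + 1}"] = col
    table = pd.DataFrame(data, index=labels)
    log = SimulationLog(seed=seed, model="mixed-traits",
                        params={"n_quant": n_quant, "n_qual": n_qual,
                                "separation": separation,
                                "n_levels": n_levels,
                                "syndrome_map": dict(syndrome_map)})
    return table, log
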