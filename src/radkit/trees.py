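"""Dated-tree container, Newick I/O and tree transforms.

Every downstream analysis (diversification likelihoods, Mk models,
stochastic mapping, phylogenetic signal, age-range correlation) runs on a
:class:`DatedTree`: a rooted phylogeny whose branch lengths are in Myr and
whose node ages are measured backward from the present (tips of an
ultrametric tree sit at age 0).  Parsing and serialisation are delegated to
dendropy; this module adds age bookkeeping, ultrametricity checks, the
lineage-through-time curve, Pagel-style branch-length transforms and
taxon pruning.
"""

from __future__ import annotations

import io
import math
import warnings
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Sequence, Tuple

import dendropy
import numpy as np
import pandas as pd

__all__ = [
    "DatedTree",
    "TreeSample",
    "parse_newick",
    "node_ages",
    "ltt",
    "transform_kappa",
    "transform_lambda_cov",
    "prune_to_taxa",
]

#: relative tolerance (fraction of root age) for the ultrametricity check
ULTRAMETRIC_RTOL = 1e-6


class DatedTree:
    """A rooted, dated phylogeny with branch lengths in Myr.

    Thin wrapper around a private :class:`dendropy.Tree`.  Node ages are
    computed backward from the present: ``age = max root-to-tip depth -
    root-to-node depth``, so tips of an ultrametric tree are at age 0 and
    the root is at the crown age.
    """

    def __init__(self, tree: dendropy.Tree, require_branch_lengths: bool = True):
        self._tree = tree
        self._validate(require_branch_lengths)
        self._ages: Dict[dendropy.Node, float] | None = None

    # ------------------------------------------------------------------ io

    @classmethod
    def from_newick(cls, text: str) -> "DatedTree":
        try:
            tree = dendropy.Tree.get(
                data=text,
                schema="newick",
                suppress_internal_node_taxa=True,
                preserve_underscores=True,
            )
        except Exception as exc:  # dendropy raises several DataError types
            raise ValueError(f"malformed Newick string: {exc}") from exc
        return cls(tree)

    @classmethod
    def from_file(cls, path: str) -> "DatedTree":
        with open(path) as fh:
            return cls.from_newick(fh.read())

    def to_newick(self, precision: int = 12) -> str:
        s = self._tree.as_string(
            schema="newick",
            suppress_rooting=True,
            unquoted_underscores=True,
            real_value_format_specifier=f".{precision}g",
        )
        return s.strip()

    def write(self, path: str) -> None:
        with open(path, "w") as fh:
            fh.write(self.to_newick() + "\n")

    # -------------------------------------------------------- validation

    def _validate(self, require_branch_lengths: bool) -> None:
        seen = set()
        for leaf in self._tree.leaf_node_iter():
            if leaf.taxon is None:
                raise ValueError("unlabeled tip in tree")
            label = leaf.taxon.label
            if label in seen:
                raise ValueError(f"duplicate tip label: {label!r}")
            seen.add(label)
        for edge in self._tree.preorder_edge_iter():
            if edge.head_node is self._tree.seed_node:
                continue  # root edge length is optional
            if edge.length is None:
                if require_branch_lengths:
                    raise ValueError(
                        "missing branch length on edge leading to "
                        f"{_node_repr(edge.head_node)}"
                    )
            elif edge.length < 0:
                raise ValueError(
                    f"negative branch length {edge.length} on edge to "
                    f"{_node_repr(edge.head_node)}"
                )

    # ---------------------------------------------------------- topology

    @property
    def dendropy_tree(self) -> dendropy.Tree:
        return self._tree

    @property
    def tip_labels(self) -> List[str]:
        return sorted(l.taxon.label for l in self._tree.leaf_node_iter())

    @property
    def n_tips(self) -> int:
        return sum(1 for _ in self._tree.leaf_node_iter())

    @property
    def is_binary(self) -> bool:
        for node in self._tree.preorder_node_iter():
            nc = len(node.child_nodes())
            if nc not in (0, 2):
                return False
        return True

    def require_binary(self, context: str = "this operation") -> None:
        if not self.is_binary:
            raise ValueError(f"{context} requires a fully bifurcating tree")

    def resolve_polytomies(self) -> "DatedTree":
        """Arbitrarily resolve polytomies with zero-length branches."""
        if self.is_binary:
            return self
        t = self._tree.clone(depth=1)
        t.resolve_polytomies()
        for e in t.preorder_edge_iter():
            if e.length is None and e.head_node is not t.seed_node:
                e.length = 0.0
        warnings.warn("polytomies resolved arbitrarily with zero-length branches")
        return DatedTree(t)

    # -------------------------------------------------------------- ages

    def node_ages(self) -> Dict[dendropy.Node, float]:
        """Map every node to its age in Myr before present."""
        if self._ages is None:
            depths: Dict[dendropy.Node, float] = {}
            for node in self._tree.preorder_node_iter():
                if node.parent_node is None:
                    depths[node] = 0.0
                else:
                    bl = node.edge.length or 0.0
                    depths[node] = depths[node.parent_node] + bl
            max_depth = max(depths[l] for l in self._tree.leaf_node_iter())
            self._ages = {n: max_depth - d for n, d in depths.items()}
        return self._ages

    @property
    def root_age(self) -> float:
        return self.node_ages()[self._tree.seed_node]

    def internal_node_ages(self, include_root: bool = True) -> np.ndarray:
        ages = self.node_ages()
        out = [
            ages[n]
            for n in self._tree.preorder_node_iter()
            if not n.is_leaf() and (include_root or n.parent_node is not None)
        ]
        return np.sort(np.asarray(out))[::-1]

    def is_ultrametric(self, rtol: float = ULTRAMETRIC_RTOL) -> bool:
        ages = self.node_ages()
        tip_ages = [ages[l] for l in self._tree.leaf_node_iter()]
        tol = max(rtol * max(self.root_age, 1e-12), 1e-12)
        return max(abs(a) for a in tip_ages) <= tol

    def require_ultrametric(self, context: str = "this operation") -> None:
        if not self.is_ultrametric():
            raise ValueError(f"{context} requires an ultrametric tree")

    # ----------------------------------------------------------- curves

    def ltt(self) -> Dict[float, int]:
        """Lineage-through-time step function {node age -> lineage count}.

        The count at the root age is 2 (or the root's child count for a
        basal polytomy) and reaches the tip count at the youngest internal
        node; counts are non-decreasing toward the present.
        """
        self.require_ultrametric("lineage-through-time computation")
        ages = self.node_ages()
        events = sorted(
            (
                (ages[n], len(n.child_nodes()) - 1)
                for n in self._tree.preorder_node_iter()
                if not n.is_leaf()
            ),
            key=lambda t: -t[0],
        )
        steps: Dict[float, int] = {}
        count = 1
        for age, incr in events:
            count += incr
            steps[age] = count
        return steps

    # -------------------------------------------------------- transforms

    def transform_kappa(self, kappa: float) -> "DatedTree":
        """Raise every branch length to the power ``kappa`` (Pagel's κ).

        κ=1 is the identity; κ→0 approaches the punctual-evolution limit
        in which every branch has unit length.
        """
        if kappa < 0:
            raise ValueError("kappa must be >= 0")
        t = self._tree.clone(depth=1)
        for e in t.preorder_edge_iter():
            if e.head_node is t.seed_node:
                continue
            if e.length is not None:
                e.length = float(e.length) ** kappa
        return DatedTree(t)

    def brownian_cov(self) -> pd.DataFrame:
        """Brownian-motion covariance: shared root-to-MRCA path length."""
        labels = self.tip_labels
        idx = {lab: i for i, lab in enumerate(labels)}
        n = len(labels)
        C = np.zeros((n, n))
        depths: Dict[dendropy.Node, float] = {}
        for node in self._tree.preorder_node_iter():
            if node.parent_node is None:
                depths[node] = 0.0
            else:
                depths[node] = depths[node.parent_node] + (node.edge.length or 0.0)
        # postorder accumulation of tip sets
        tipsets: Dict[dendropy.Node, List[int]] = {}
        for node in self._tree.postorder_node_iter():
            if node.is_leaf():
                i = idx[node.taxon.label]
                tipsets[node] = [i]
                C[i, i] = depths[node]
            else:
                children = node.child_nodes()
                merged: List[int] = []
                for a in range(len(children)):
                    for b in range(a + 1, len(children)):
                        for i in tipsets[children[a]]:
                            for j in tipsets[children[b]]:
                                C[i, j] = C[j, i] = depths[node]
                for c in children:
                    merged.extend(tipsets[c])
                tipsets[node] = merged
        return pd.DataFrame(C, index=labels, columns=labels)

    def transform_lambda_cov(self, lam: float) -> pd.DataFrame:
        """Pagel's λ covariance: off-diagonals scaled by ``lam``.

        λ=1 is the plain Brownian covariance, λ=0 a diagonal matrix
        (phylogenetic independence).
        """
        if not 0.0 <= lam <= 1.0:
            raise ValueError("lambda must lie in [0, 1]")
        self.require_ultrametric("lambda covariance transform")
        C = self.brownian_cov()
        V = C.values * lam
        np.fill_diagonal(V, np.diag(C.values))
        return pd.DataFrame(V, index=C.index, columns=C.columns)

    # ----------------------------------------------------------- pruning

    def prune_to_taxa(self, keep: Iterable[str]) -> "DatedTree":
        """Induced subtree on ``keep``; path lengths between kept tips are
        preserved and degree-2 nodes merged."""
        keep = set(keep)
        have = set(self.tip_labels)
        unknown = keep - have
        if unknown:
            raise ValueError(f"unknown tip labels: {sorted(unknown)}")
        if len(keep) < 2:
            raise ValueError("need at least two taxa to keep")
        sub = self._tree.extract_tree_with_taxa_labels(
            labels=keep, suppress_unifurcations=True
        )
        return DatedTree(sub)

    # ------------------------------------------------------------- misc

    def tip_distance_matrix(self) -> pd.DataFrame:
        labels = self.tip_labels
        pdm = self._tree.phylogenetic_distance_matrix()
        n = len(labels)
        D = np.zeros((n, n))
        taxa = {t.label: t for t in self._tree.taxon_namespace}
        for i in range(n):
            for j in range(i + 1, n):
                d = pdm.patristic_distance(taxa[labels[i]], taxa[labels[j]])
                D[i, j] = D[j, i] = d
        return pd.DataFrame(D, index=labels, columns=labels)

    def copy(self) -> "DatedTree":
        return DatedTree(self._tree.clone(depth=1))

    def __repr__(self) -> str:  # pragma: no cover
        return f"<DatedTree n_tips={self.n_tips} root_age={self.root_age:.4g}>"


def _node_repr(node: dendropy.Node) -> str:
    if node.taxon is not None:
        return f"tip {node.taxon.label!r}"
    return "internal node"


@dataclass
class TreeSample:
    """An ordered collection of dated trees sharing one tip set.

    Stands in for a posterior sample of dated trees used to propagate
    phylogenetic (and dating) uncertainty through downstream analyses.
    """

    trees: List[DatedTree]

    def __post_init__(self) -> None:
        if not self.trees:
            raise ValueError("TreeSample must contain at least one tree")
        ref = set(self.trees[0].tip_labels)
        for k, t in enumerate(self.trees[1:], start=1):
            if set(t.tip_labels) != ref:
                raise ValueError(f"tree {k} has a different tip set")

    def __len__(self) -> int:
        return len(self.trees)

    def __iter__(self):
        return iter(self.trees)

    def __getitem__(self, i):
        return self.trees[i]

    @classmethod
    def from_file(cls, path: str, schema: str = "newick") -> "TreeSample":
        """Read a multi-tree file: one Newick per line, or a NEXUS TREES
        block (read-only)."""
        trees: List[DatedTree] = []
        if schema == "newick":
            with open(path) as fh:
                for line in fh:
                    line = line.strip()
                    if line:
                        trees.append(DatedTree.from_newick(line))
        elif schema == "nexus":
            tl = dendropy.TreeList.get(path=path, schema="nexus")
            for t in tl:
                trees.append(DatedTree(t))
        else:
            raise ValueError(f"unsupported schema: {schema}")
        return cls(trees)

    def write(self, path: str) -> None:
        with open(path, "w") as fh:
            for t in self.trees:
                fh.write(t.to_newick() + "\n")


# --------------------------------------------------------------------------
# module-level functional interface

def parse_newick(text: str) -> DatedTree:
    return DatedTree.from_newick(text)


def node_ages(tree: DatedTree) -> Dict[dendropy.Node, float]:
    return tree.node_ages()


def ltt(tree: DatedTree) -> Dict[float, int]:
    return tree.ltt()


def transform_kappa(tree: DatedTree, kappa: float) -> DatedTree:
    return tree.transform_kappa(kappa)


def transform_lambda_cov(tree: DatedTree, lam: float) -> pd.DataFrame:
    return tree.transform_lambda_cov(lam)


def prune_to_taxa(tree: DatedTree, keep: Iterable[str]) -> DatedTree:
    return tree.prune_to_taxa(keep)
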