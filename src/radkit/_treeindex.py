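"""Array-indexed view of a binary dated tree for likelihood kernels.

Tips are indexed 0..n-1 in sorted-label order, internal nodes n..2n-2 in
postorder.  Kernels (Mk pruning, birth-death and SSE likelihoods,
stochastic mapping) iterate over ``postorder`` and index flat arrays rather
than walking dendropy nodes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List

import numpy as np

from .trees import DatedTree


@dataclass(frozen=True)
class TreeIndex:
    labels: List[str]              # tip labels, sorted; tip i has index i
    n_tips: int
    parent: np.ndarray             # parent index per node (-1 at root)
    children: np.ndarray           # (n_internal, 2) child indices
    internal: np.ndarray           # internal node indices in postorder
    branch_length: np.ndarray      # edge length above each node (0 at root)
    age: np.ndarray                # node ages, Myr before present
    root: int

    @property
    def n_nodes(self) -> int:
        return 2 * self.n_tips - 1


def index_tree(tree: DatedTree) -> TreeIndex:
    tree.require_binary("array indexing")
    labels = tree.tip_labels
    tip_idx = {lab: i for i, lab in enumerate(labels)}
    n = len(labels)
    ages_map = tree.node_ages()

    n_nodes = 2 * n - 1
    parent = np.full(n_nodes, -1, dtype=int)
    children = np.zeros((n - 1, 2), dtype=int)
    blen = np.zeros(n_nodes)
    age = np.zeros(n_nodes)
    internal_order: List[int] = []

    node_id: Dict[object, int] = {}
    next_internal = n
    dtree = tree.dendropy_tree
    for node in dtree.postorder_node_iter():
        if node.is_leaf():
            i = tip_idx[node.taxon.label]
        else:
            i = next_internal
            next_internal += 1
            internal_order.append(i)
            ch = node.child_nodes()
            children[i - n] = [node_id[ch[0]], node_id[ch[1]]]
        node_id[node] = i
        age[i] = ages_map[node]
        blen[i] = node.edge.length or 0.0
    for node in dtree.postorder_node_iter():
        i = node_id[node]
        if node.parent_node is not None:
            parent[i] = node_id[node.parent_node]

    return TreeIndex(
        labels=labels,
        n_tips=n,
        parent=parent,
        children=children,
        internal=np.array(internal_order, dtype=int),
        branch_length=blen,
        age=age,
        root=node_id[dtree.seed_node],
    )
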