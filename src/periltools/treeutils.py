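"""Time-scaled family tree: wrapper, array form, Brownian simulation, VCV.

:class:`FamilyTree` wraps a rooted dendropy tree with family-labelled tips
and branch lengths in Myr. :class:`TreeArrays` flattens it into postorder
index arrays so that nodal downpasses, Brownian simulation and the
phylogenetic covariance matrix can be computed with numpy over many trait
vectors at once.
"""

from __future__ import annotations

import warnings

import dendropy
import numpy as np

__all__ = ["FamilyTree", "TreeArrays"]

#: floor on branch lengths when inverting them as weights
_MIN_BL = 1e-8


class FamilyTree:
    """Rooted, time-scaled tree with uniquely labelled tips."""

    def __init__(self, tree: dendropy.Tree, ultrametric_tol: float = 1e-6):
        self.tree = tree
        labels = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
        if any(lbl is None for lbl in labels):
            raise ValueError("every tip must be labelled")
        if len(set(labels)) != len(labels):
            dupes = sorted({l for l in labels if labels.count(l) > 1})
            raise ValueError(f"duplicate tip labels: {dupes}")
        for node in tree.preorder_node_iter():
            if node.parent_node is not None and node.edge.length is None:
                name = node.taxon.label if node.taxon else "<internal>"
                raise ValueError(f"missing branch length on edge above {name}")
        self._depths: dict[int, float] = {}
        for node in tree.preorder_node_iter():
            parent = node.parent_node
            d = 0.0 if parent is None else self._depths[id(parent)] + node.edge.length
            self._depths[id(node)] = d
        tip_depths = [self._depths[id(l)] for l in tree.leaf_node_iter()]
        self.height = max(tip_depths)
        spread = max(tip_depths) - min(tip_depths)
        self.is_ultrametric = spread <= ultrametric_tol * max(self.height, 1.0)
        if not self.is_ultrametric:
            warnings.warn(
                f"tree is not ultrametric: tip-depth spread {spread:.6g} "
                f"exceeds tolerance",
                stacklevel=2,
            )

    @classmethod
    def from_newick(cls, source: str, *, path: bool = False, **kw) -> "FamilyTree":
        try:
            if path:
                tree = dendropy.Tree.get(path=source, schema="newick")
            else:
                tree = dendropy.Tree.get(data=source, schema="newick")
        except dendropy.utility.error.DataParseError as exc:
            raise ValueError(f"invalid newick: {exc}") from exc
        return cls(tree, **kw)

    @property
    def tip_labels(self) -> list[str]:
        return [leaf.taxon.label for leaf in self.tree.leaf_node_iter()]

    def __len__(self) -> int:
        return len(self.tree.leaf_nodes())

    def as_newick(self) -> str:
        return self.tree.as_string(schema="newick", suppress_rooting=True).strip()

    def write_newick(self, path: str) -> None:
        with open(path, "w") as fh:
            fh.write(self.as_newick() + "\n")

    def arrays(self) -> "TreeArrays":
        return TreeArrays(self)


class TreeArrays:
    """Flattened postorder form of a :class:`FamilyTree`.

    Node indices: tips are ``0 .. n_tips-1`` in ``tip_labels`` order; internal
    nodes follow in postorder, the root last. ``children[j]`` lists the child
    node indices of internal node ``j`` and ``child_bl[j]`` the matching edge
    lengths.
    """

    def __init__(self, ftree: FamilyTree):
        tree = ftree.tree
        leaves = list(tree.leaf_node_iter())
        self.tip_labels = [l.taxon.label for l in leaves]
        index = {id(l): i for i, l in enumerate(leaves)}
        internals = [n for n in tree.postorder_internal_node_iter()]
        for j, node in enumerate(internals):
            index[id(node)] = len(leaves) + j
        self.n_tips = len(leaves)
        self.n_nodes = len(leaves) + len(internals)
        self.children: list[np.ndarray] = []
        self.child_bl: list[np.ndarray] = []
        for node in internals:
            kids = node.child_nodes()
            self.children.append(np.array([index[id(k)] for k in kids], dtype=int))
            self.child_bl.append(
                np.array([max(k.edge.length, _MIN_BL) for k in kids], dtype=float)
            )
        # parent/edge arrays in preorder for Brownian simulation
        preorder = list(tree.preorder_node_iter())
        self.preorder_idx = np.array([index[id(n)] for n in preorder], dtype=int)
        self.parent_idx = np.array(
            [
                -1 if n.parent_node is None else index[id(n.parent_node)]
                for n in preorder
            ],
            dtype=int,
        )
        self.edge_len = np.array(
            [0.0 if n.parent_node is None else n.edge.length for n in preorder],
            dtype=float,
        )
        self.node_depth = np.zeros(self.n_nodes)
        for k, n in enumerate(preorder):
            i = self.preorder_idx[k]
            p = self.parent_idx[k]
            self.node_depth[i] = 0.0 if p < 0 else self.node_depth[p] + self.edge_len[k]
        self.root_index = self.preorder_idx[0]

    # ------------------------------------------------------------------
    def nodal_downpass(self, tip_values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Estimate nodal values of a tip trait and tally sister differences.

        ``tip_values`` has shape ``(n_tips,)`` or ``(n_tips, m)``. Each
        internal node takes the 1/branch-length-weighted average of its
        daughters' nodal values; its contribution to the difference sum is
        ``|v1 - v2|`` for a bifurcation and ``sum_c |v_c - mean_c(v)|`` at a
        polytomy. Returns ``(node_values, d_sum)`` where ``d_sum`` has shape
        ``(m,)`` (or a scalar array for 1-D input).
        """
        tv = np.atleast_2d(np.asarray(tip_values, dtype=float).T).T  # (n_tips, m)
        if tv.shape[0] != self.n_tips:
            raise ValueError("tip_values length does not match tree")
        m = tv.shape[1]
        values = np.zeros((self.n_nodes, m))
        values[: self.n_tips] = tv
        d_sum = np.zeros(m)
        for j in range(len(self.children)):
            kids = self.children[j]
            w = 1.0 / self.child_bl[j]
            kv = values[kids]  # (k, m)
            values[self.n_tips + j] = (w[:, None] * kv).sum(axis=0) / w.sum()
            if len(kids) == 2:
                d_sum += np.abs(kv[0] - kv[1])
            else:
                d_sum += np.abs(kv - kv.mean(axis=0)).sum(axis=0)
        return values, d_sum

    def simulate_brownian(self, m: int, rng: np.random.Generator) -> np.ndarray:
        """Simulate ``m`` independent Brownian traits; returns ``(n_tips, m)``."""
        values = np.zeros((self.n_nodes, m))
        z = rng.standard_normal((len(self.preorder_idx), m))
        for k in range(len(self.preorder_idx)):
            i = self.preorder_idx[k]
            p = self.parent_idx[k]
            if p >= 0:
                values[i] = values[p] + np.sqrt(self.edge_len[k]) * z[k]
        return values[: self.n_tips]

    def vcv(self) -> np.ndarray:
        """Phylogenetic covariance: C[i, j] = depth of the MRCA of tips i, j."""
        n = self.n_tips
        C = np.zeros((n, n))
        tipsets: dict[int, np.ndarray] = {
            i: np.array([i]) for i in range(self.n_tips)
        }
        for j in range(len(self.children)):
            node = self.n_tips + j
            kids = self.children[j]
            groups = [tipsets[int(k)] for k in kids]
            depth = self.node_depth[node]
            for a in range(len(groups)):
                for b in range(a + 1, len(groups)):
                    C[np.ix_(groups[a], groups[b])] = depth
                    C[np.ix_(groups[b], groups[a])] = depth
            tipsets[node] = np.concatenate(groups)
            for k in kids:
                del tipsets[int(k)]
        np.fill_diagonal(C, self.node_depth[: self.n_tips])
        return C
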