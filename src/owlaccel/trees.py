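"""Rooted phylogenies with designated foreground branches.

The tree is stored in flat arrays (parent pointers, branch lengths,
postorder) so that likelihood recursions can run without object traversal.
Newick reading/writing is delegated to dendropy; foreground branches are
marked by tip name through the run configuration, never by in-file tags.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import dendropy
import numpy as np

from .errors import DataError, InvalidParameterError

__all__ = ["Phylogeny"]


@dataclass
class Phylogeny:
    """A rooted tree with branch lengths in expected substitutions per site.

    Attributes
    ----------
    parent:
        Integer array, one entry per node; ``-1`` marks the single root.
    lengths:
        Branch length of the edge above each node (0 for the root).
    names:
        Node labels; every tip must carry a unique name, internal labels
        are optional (``None``).
    foreground:
        Indices of the branches (nodes) under test for acceleration; in the
        owl design these are the three diurnal tip branches.
    outgroup:
        Name of the outgroup tip, if designated.
    """

    parent: np.ndarray
    lengths: np.ndarray
    names: list
    foreground: frozenset = field(default_factory=frozenset)
    outgroup: str | None = None

    def __post_init__(self) -> None:
        self.parent = np.asarray(self.parent, dtype=np.int64)
        self.lengths = np.asarray(self.lengths, dtype=float)
        n = self.parent.size
        roots = np.flatnonzero(self.parent < 0)
        if roots.size != 1:
            raise DataError(f"tree must have exactly one root, found {roots.size}")
        if not np.all(np.isfinite(self.lengths)) or np.any(self.lengths < 0):
            raise InvalidParameterError("branch lengths must be finite and non-negative")
        self._children: list[list[int]] = [[] for _ in range(n)]
        for i in range(n):
            p = int(self.parent[i])
            if p >= 0:
                self._children[p].append(i)
        tip_names = [self.names[i] for i in range(n) if not self._children[i]]
        if any(name is None for name in tip_names):
            raise DataError("every tip must be named")
        if len(set(tip_names)) != len(tip_names):
            raise DataError("tip names must be unique")
        self.foreground = frozenset(int(b) for b in self.foreground)
        for b in self.foreground:
            if not (0 <= b < n) or b == self.root:
                raise DataError(f"foreground branch {b} not a non-root node")
        if self.outgroup is not None and self.outgroup not in tip_names:
            raise DataError(f"outgroup {self.outgroup!r} is not a tip")

    # -- basic structure ---------------------------------------------------

    @property
    def n_nodes(self) -> int:
        return self.parent.size

    @property
    def root(self) -> int:
        return int(np.flatnonzero(self.parent < 0)[0])

    def children(self, node: int) -> list[int]:
        return self._children[node]

    @property
    def tips(self) -> np.ndarray:
        return np.array([i for i in range(self.n_nodes) if not self._children[i]])

    @property
    def tip_names(self) -> list[str]:
        return [self.names[int(i)] for i in self.tips]

    def tip_index(self, name: str) -> int:
        for i in self.tips:
            if self.names[int(i)] == name:
                return int(i)
        raise KeyError(name)

    @property
    def postorder(self) -> np.ndarray:
        """Node indices, children always before parents."""
        order: list[int] = []
        stack = [self.root]
        while stack:
            node = stack.pop()
            order.append(node)
            stack.extend(self._children[node])
        return np.array(order[::-1], dtype=np.int64)

    @property
    def branches(self) -> np.ndarray:
        """All non-root node indices (each indexes the edge above it)."""
        return np.array([i for i in range(self.n_nodes) if i != self.root])

    @property
    def total_length(self) -> float:
        return float(self.lengths.sum())

    @property
    def foreground_names(self) -> list[str]:
        return sorted(self.names[b] for b in self.foreground if self.names[b])

    def with_lengths(self, lengths: np.ndarray) -> "Phylogeny":
        return Phylogeny(self.parent.copy(), np.asarray(lengths, dtype=float),
                         list(self.names), self.foreground, self.outgroup)

    def scaled(self, factor: float) -> "Phylogeny":
        return self.with_lengths(self.lengths * factor)

    def set_foreground(self, tip_names) -> "Phylogeny":
        fg = frozenset(self.tip_index(n) for n in tip_names)
        return Phylogeny(self.parent.copy(), self.lengths.copy(), list(self.names),
                         fg, self.outgroup)

    # -- newick ------------------------------------------------------------

    @classmethod
    def from_newick(cls, newick: str, foreground=(), outgroup: str | None = None
                    ) -> "Phylogeny":
        dtree = dendropy.Tree.get(data=newick, schema="newick")
        dnodes = list(dtree.preorder_node_iter())
        index = {id(nd): i for i, nd in enumerate(dnodes)}
        n = len(dnodes)
        parent = np.full(n, -1, dtype=np.int64)
        lengths = np.zeros(n)
        names: list[str | None] = [None] * n
        for i, nd in enumerate(dnodes):
            if nd.parent_node is not None:
                parent[i] = index[id(nd.parent_node)]
                lengths[i] = nd.edge.length if nd.edge.length is not None else 0.0
            if nd.taxon is not None:
                names[i] = nd.taxon.label.replace(" ", "_")
            elif nd.label:
                names[i] = nd.label
        tree = cls(parent, lengths, names, outgroup=outgroup)
        if foreground:
            tree = tree.set_foreground(foreground)
        return tree

    def to_newick(self) -> str:
        def fmt(node: int) -> str:
            kids = self._children[node]
            label = self.names[node] or ""
            if kids:
                inner = ",".join(fmt(k) for k in kids)
                body = f"({inner}){label}"
            else:
                body = label
            if node == self.root:
                return body
            return f"{body}:{self.lengths[node]:.10g}"

        return fmt(self.root) + ";"

    @classmethod
    def read(cls, path, foreground=(), outgroup=None) -> "Phylogeny":
        with open(path) as fh:
            return cls.from_newick(fh.read(), foreground, outgroup)

    def write(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(self.to_newick() + "\n")

    # -- taxon subsetting --------------------------------------------------

    def subtree(self, keep_tips) -> "Phylogeny":
        """Restrict to a tip subset, suppressing unary internal nodes.

        Used to fit separate neutral models on taxon subsets (e.g. the four
        nocturnal owls for element discovery vs all eight species).
        """
        keep = set(keep_tips)
        missing = keep - set(self.tip_names)
        if missing:
            raise DataError(f"tips not in tree: {sorted(missing)}")
        dtree = dendropy.Tree.get(data=self.to_newick(), schema="newick")
        dtree.retain_taxa_with_labels([n.replace("_", " ") for n in keep]
                                      if False else list(keep))
        fg_names = [self.names[b] for b in self.foreground
                    if self.names[b] in keep]
        out = self.outgroup if self.outgroup in keep else None
        return Phylogeny.from_newick(dtree.as_string(schema="newick"),
                                     foreground=fg_names, outgroup=out)
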