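"""Time-calibrated phylogenies: parsing, patristic distances, time slices.

Trees are stored as flat parent-pointer arrays with branch lengths in
millions of years (Myr).  Node ages are measured backward from the present
(tips of an ultrametric tree sit at age 0).  Every downstream stage -- the
gain/loss model, ancestral-network reconstruction, the distance modifier on
gain rates -- queries trees through this module.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import dendropy
import numpy as np

__all__ = [
    "Phylogeny",
    "DistanceMatrix",
    "NewickParseError",
    "parse_newick",
    "patristic_distances",
    "lineages_at_time",
]

#: tolerance (Myr) for declaring root-to-tip path lengths equal
ULTRAMETRIC_TOL = 1e-9


class NewickParseError(ValueError):
    """Raised for malformed Newick input; carries position info when known."""


@dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric patristic-distance matrix with ordered labels."""

    labels: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.labels), len(self.labels)):
            raise ValueError("distance matrix shape does not match labels")
        object.__setattr__(self, "values", v)

    def __getitem__(self, pair: tuple[str, str]) -> float:
        a, b = pair
        return float(self.values[self.labels.index(a), self.labels.index(b)])

    @property
    def mean_offdiagonal(self) -> float:
        n = len(self.labels)
        if n < 2:
            return 0.0
        mask = ~np.eye(n, dtype=bool)
        return float(self.values[mask].mean())


@dataclass
class Phylogeny:
    """Rooted tree over ``n_nodes`` nodes indexed 0..n_nodes-1.

    ``parent[i]`` is -1 for the root; ``branch_length[i]`` is the length of
    the edge above node ``i`` (0 for the root).  ``labels[i]`` is the tip
    label for tips and "" for unlabeled internal nodes.  Ages are derived:
    age(node) = max root-to-tip depth - depth(node), so for an ultrametric
    tree all tips have age 0 and the root age equals the tree height.
    """

    parent: np.ndarray
    branch_length: np.ndarray
    labels: list[str]
    _children: list[list[int]] = field(init=False, repr=False)

    def __post_init__(self):
        self.parent = np.asarray(self.parent, dtype=int)
        self.branch_length = np.asarray(self.branch_length, dtype=float)
        n = self.parent.size
        if self.branch_length.size != n or len(self.labels) != n:
            raise ValueError("field lengths disagree")
        roots = np.flatnonzero(self.parent < 0)
        if roots.size != 1:
            raise ValueError(f"tree must have exactly one root, found {roots.size}")
        if np.any(self.branch_length < 0):
            raise ValueError("negative branch length")
        self._children = [[] for _ in range(n)]
        for i in range(n):
            if self.parent[i] >= 0:
                self._children[self.parent[i]].append(i)
        tips = [self.labels[i] for i in self.tip_indices]
        if len(set(tips)) != len(tips):
            raise ValueError("tip labels are not unique")

    # -- basic structure ---------------------------------------------------
    @property
    def n_nodes(self) -> int:
        return int(self.parent.size)

    @property
    def root(self) -> int:
        return int(np.flatnonzero(self.parent < 0)[0])

    def children(self, node: int) -> list[int]:
        return self._children[node]

    @property
    def tip_indices(self) -> list[int]:
        return [i for i in range(self.n_nodes) if not self._children[i]]

    @property
    def tip_labels(self) -> list[str]:
        return [self.labels[i] for i in self.tip_indices]

    @property
    def n_tips(self) -> int:
        return len(self.tip_indices)

    # -- depths and ages ---------------------------------------------------
    @property
    def depths(self) -> np.ndarray:
        """Root-to-node path lengths (Myr)."""
        d = np.zeros(self.n_nodes)
        for i in self._preorder():
            if self.parent[i] >= 0:
                d[i] = d[self.parent[i]] + self.branch_length[i]
        return d

    @property
    def ages(self) -> np.ndarray:
        """Node ages, Myr before present; tips of an ultrametric tree = 0."""
        d = self.depths
        return d.max() - d

    @property
    def root_age(self) -> float:
        return float(self.depths.max())

    @property
    def is_ultrametric(self) -> bool:
        tip_d = self.depths[self.tip_indices]
        return bool(np.ptp(tip_d) <= ULTRAMETRIC_TOL) if len(tip_d) else True

    @property
    def total_branch_length(self) -> float:
        return float(self.branch_length.sum())

    def _preorder(self) -> list[int]:
        order, stack = [], [self.root]
        while stack:
            node = stack.pop()
            order.append(node)
            stack.extend(reversed(self._children[node]))
        return order

    def postorder(self) -> list[int]:
        return self._preorder()[::-1]

    def tip_set(self, node: int) -> frozenset[str]:
        """Labels of the extant tips descending from ``node``."""
        if not self._children[node]:
            return frozenset([self.labels[node]])
        out: set[str] = set()
        for c in self._children[node]:
            out |= self.tip_set(c)
        return frozenset(out)

    def mrca(self, a: int, b: int) -> int:
        anc = set()
        x = a
        while x >= 0:
            anc.add(x)
            x = self.parent[x]
        x = b
        while x not in anc:
            x = self.parent[x]
        return int(x)

    # -- serialization -----------------------------------------------------
    def to_newick(self) -> str:
        def rec(node: int) -> str:
            if not self._children[node]:
                core = self.labels[node]
            else:
                core = "(" + ",".join(rec(c) for c in self._children[node]) + ")"
                core += self.labels[node]
            if self.parent[node] >= 0:
                core += f":{self.branch_length[node]:.10g}"
            return core

        return rec(self.root) + ";"


def parse_newick(text: str) -> Phylogeny:
    """Parse a single rooted Newick tree with branch lengths.

    Raises :class:`NewickParseError` for malformed input (with position
    information where the underlying reader provides it) and for any edge
    missing an explicit branch length -- lengths are never defaulted.
    """
    if not isinstance(text, str) or not text.strip():
        raise NewickParseError("empty Newick input")
    if not text.strip().endswith(";"):
        raise NewickParseError(
            f"missing terminating ';' at character {len(text.rstrip())}"
        )
    try:
        dtree = dendropy.Tree.get(
            data=text, schema="newick", suppress_internal_node_taxa=False,
            preserve_underscores=True,
        )
    except Exception as exc:  # dendropy raises several error classes
        raise NewickParseError(f"malformed Newick: {exc}") from exc

    dnodes = list(dtree.preorder_node_iter())
    index = {id(nd): i for i, nd in enumerate(dnodes)}
    parent = np.full(len(dnodes), -1, dtype=int)
    blen = np.zeros(len(dnodes))
    labels: list[str] = []
    for i, nd in enumerate(dnodes):
        if nd.parent_node is not None:
            parent[i] = index[id(nd.parent_node)]
            if nd.edge.length is None:
                name = nd.taxon.label if nd.taxon else "(internal)"
                raise NewickParseError(f"missing branch length on edge above {name}")
            blen[i] = float(nd.edge.length)
        label = nd.taxon.label if nd.taxon is not None else (nd.label or "")
        labels.append(label)
    return Phylogeny(parent=parent, branch_length=blen, labels=labels)


def read_newick(path) -> Phylogeny:
    with io.open(path, "r", encoding="utf-8") as fh:
        return parse_newick(fh.read())


def patristic_distances(tree: Phylogeny, tips_only: bool = True) -> DistanceMatrix:
    """Pairwise path-length (patristic) distances between tips.

    d(x, y) is the sum of branch lengths on the unique path x -> y; the
    diagonal is zero.  Works for non-ultrametric trees (distances only need
    depths, not ages).
    """
    idx = tree.tip_indices if tips_only else list(range(tree.n_nodes))
    depths = tree.depths
    n = len(idx)
    out = np.zeros((n, n))
    for a in range(n):
        for b in range(a + 1, n):
            m = tree.mrca(idx[a], idx[b])
            d = depths[idx[a]] + depths[idx[b]] - 2.0 * depths[m]
            out[a, b] = out[b, a] = d
    labels = tuple(tree.labels[i] if tree.labels[i] else f"node{i}" for i in idx)
    return DistanceMatrix(labels=labels, values=out)


def lineages_at_time(tree: Phylogeny, t: float) -> dict[int, frozenset[str]]:
    """Branches crossing age ``t``, mapped to their extant descendant tips.

    A branch (edge above child c) crosses t iff age(c) < t <= age(parent(c)),
    with t = 0 returning the tip branches: the interval is half-open on the
    tipward side, so a split node sitting exactly at t belongs to its child
    branches (a split dated exactly t has already happened at t) and
    lineages are never double-counted.  Only defined on dated (ultrametric)
    trees.
    """
    if not tree.is_ultrametric:
        raise ValueError("time slices require an ultrametric (dated) tree")
    if t < 0 or t > tree.root_age:
        raise ValueError(f"slice age {t} outside [0, root age {tree.root_age}]")
    ages = tree.ages
    out: dict[int, frozenset[str]] = {}
    for c in range(tree.n_nodes):
        p = tree.parent[c]
        if p < 0:
            continue
        if ages[c] < t <= ages[p] or (t == 0 and ages[c] <= ULTRAMETRIC_TOL):
            out[c] = tree.tip_set(c)
    return out


def lineage_name(tips: frozenset[str]) -> str:
    """Stable lineage identity: '+'-joined sorted descendant tips."""
    return "+".join(sorted(tips))
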