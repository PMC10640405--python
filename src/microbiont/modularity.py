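"""Weighted bipartite modularity: Barber's Q and its maximization.

Q compares the within-module interaction weight against a degree-based
expectation:

    Q = (1/m) sum_ij (A_ij - k_i d_j / m) delta(g_i, h_j)

with A the host x ASV weight matrix, m its total weight, k_i / d_j the row
and column sums, and delta = 1 when row i and column j share a module.
Maximization follows the weighted label-propagation scheme (LPAwb+): rows
and columns alternately adopt the module label that maximizes their own Q
contribution, which increases Q monotonically until a local maximum; the
multiple-restart wrapper (DIRT-style) reruns from seeded random
initializations and forced module counts and keeps the best partition.
An exhaustive oracle (exact on small networks) backs the tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
from scipy.optimize import linear_sum_assignment

__all__ = [
    "ModulePartition",
    "barber_modularity",
    "lpawb_plus",
    "dirt_lpawb_plus",
    "exhaustive_best_partition",
    "match_modules",
]


@dataclass
class ModulePartition:
    """Module assignment for rows and columns of a bipartite network."""

    row_modules: np.ndarray
    col_modules: np.ndarray
    modularity: float
    row_labels: list[str] | None = None
    col_labels: list[str] | None = None

    def __post_init__(self):
        self.row_modules = np.asarray(self.row_modules, dtype=int)
        self.col_modules = np.asarray(self.col_modules, dtype=int)
        if not -1.0 - 1e-12 <= self.modularity <= 1.0 + 1e-12:
            raise ValueError(f"Q = {self.modularity} outside [-1, 1]")

    @property
    def n_modules(self) -> int:
        return len(set(self.row_modules) | set(self.col_modules))

    def renumber_by_weight(self, weights: np.ndarray) -> "ModulePartition":
        """Relabel modules 1..K in descending total interaction weight."""
        w = np.asarray(weights, dtype=float)
        totals: dict[int, float] = {}
        for lab in set(self.row_modules) | set(self.col_modules):
            rows = self.row_modules == lab
            cols = self.col_modules == lab
            totals[lab] = float(w[np.ix_(rows, cols)].sum())
        order = sorted(totals, key=lambda lab: (-totals[lab], lab))
        remap = {lab: i + 1 for i, lab in enumerate(order)}
        return ModulePartition(
            row_modules=np.array([remap[x] for x in self.row_modules]),
            col_modules=np.array([remap[x] for x in self.col_modules]),
            modularity=self.modularity,
            row_labels=self.row_labels, col_labels=self.col_labels,
        )

    def module_members(self) -> dict[int, dict[str, list]]:
        out: dict[int, dict[str, list]] = {}
        rl = self.row_labels or [str(i) for i in range(len(self.row_modules))]
        cl = self.col_labels or [str(j) for j in range(len(self.col_modules))]
        for lab in sorted(set(self.row_modules) | set(self.col_modules)):
            out[int(lab)] = {
                "rows": [rl[i] for i in np.flatnonzero(self.row_modules == lab)],
                "cols": [cl[j] for j in np.flatnonzero(self.col_modules == lab)],
            }
        return out


def _check_weights(weights) -> np.ndarray:
    w = np.asarray(weights, dtype=float)
    if w.ndim != 2:
        raise ValueError("weight matrix must be 2-D")
    if (w < 0).any():
        raise ValueError("negative weights")
    if w.sum() == 0:
        raise ValueError("network has no interactions (total weight 0)")
    return w


def barber_modularity(weights, row_modules, col_modules) -> float:
    """Barber's bipartite modularity Q of a given partition."""
    w = _check_weights(weights)
    g = np.asarray(row_modules)
    h = np.asarray(col_modules)
    if g.size != w.shape[0] or h.size != w.shape[1]:
        raise ValueError("partition does not cover all nodes")
    m = w.sum()
    k = w.sum(axis=1)
    d = w.sum(axis=0)
    delta = g[:, None] == h[None, :]
    return float(((w - np.outer(k, d) / m) * delta).sum() / m)


def _greedy_pass(btilde, fixed_labels, free_labels):
    """One label-propagation half-step.

    Each free node (rows or columns, via ``btilde`` orientation: free x
    fixed contribution matrix) adopts the existing fixed-side label with the
    highest positive contribution, or keeps a fresh singleton label (zero
    contribution) when every contribution is negative.  Ties break to the
    lowest label id.
    """
    labels = free_labels.copy()
    uniq = np.unique(fixed_labels)
    # contribution of free node i to module c: sum of btilde[i, fixed in c]
    contrib = np.zeros((btilde.shape[0], uniq.size))
    for ci, c in enumerate(uniq):
        contrib[:, ci] = btilde[:, fixed_labels == c].sum(axis=1)
    fresh = max(int(fixed_labels.max()), int(free_labels.max())) + 1
    for i in range(btilde.shape[0]):
        best = contrib[i].max()
        if best >= 0:
            # ties at zero join the lowest existing label
            labels[i] = uniq[int(np.argmax(contrib[i]))]
        else:
            labels[i] = fresh + i  # own singleton module, contribution 0
    return labels


def lpawb_plus(weights, seed=None, init_row_modules=None,
               max_iter: int = 200) -> ModulePartition:
    """Weighted bipartite label propagation to a local maximum of Q.

    Rows start with unique labels (or ``init_row_modules``); columns and
    rows then alternately adopt the label maximizing their Q contribution
    until Q stops increasing.  Deterministic given the initialization.
    """
    w = _check_weights(weights)
    nr, nc = w.shape
    m = w.sum()
    btilde = w - np.outer(w.sum(axis=1), w.sum(axis=0)) / m
    if init_row_modules is None:
        row_lab = np.arange(nr)
    else:
        row_lab = np.asarray(init_row_modules, dtype=int).copy()
    col_lab = _greedy_pass(btilde.T, row_lab, np.arange(nr, nr + nc))
    q = barber_modularity(w, row_lab, col_lab)
    for _ in range(max_iter):
        row_lab = _greedy_pass(btilde, col_lab, row_lab)
        col_lab = _greedy_pass(btilde.T, row_lab, col_lab)
        q_new = barber_modularity(w, row_lab, col_lab)
        if q_new <= q + 1e-14:
            q = max(q, q_new)
            break
        q = q_new
    return ModulePartition(row_modules=row_lab, col_modules=col_lab,
                           modularity=q)


def dirt_lpawb_plus(weights, restarts: int = 20, seed=None,
                    row_labels=None, col_labels=None) -> ModulePartition:
    """Best-of-restarts LPAwb+ (DIRT-style search).

    Runs label propagation from the unique-labels start, from forced module
    counts 2..min(rows, cols), and from ``restarts`` seeded random
    initializations; returns the highest-Q partition (first found wins
    ties), with modules renumbered 1..K by descending total weight.
    """
    if restarts < 1:
        raise ValueError("restarts must be >= 1")
    w = _check_weights(weights)
    nr, nc = w.shape
    rng = np.random.default_rng(seed)
    best = lpawb_plus(w)
    for kmod in range(2, min(nr, nc) + 1):
        part = lpawb_plus(w, init_row_modules=rng.integers(0, kmod, size=nr))
        if part.modularity > best.modularity + 1e-14:
            best = part
    for _ in range(restarts - 1):
        kmod = int(rng.integers(1, nr + 1))
        part = lpawb_plus(w, init_row_modules=rng.integers(0, kmod, size=nr))
        if part.modularity > best.modularity + 1e-14:
            best = part
    best = ModulePartition(best.row_modules, best.col_modules,
                           best.modularity, row_labels, col_labels)
    return best.renumber_by_weight(w)


def _set_partitions(items):
    """All set partitions of ``items`` (Bell-number many; small inputs)."""
    items = list(items)
    if not items:
        yield []
        return
    first, rest = items[0], items[1:]
    for part in _set_partitions(rest):
        for i in range(len(part)):
            yield part[:i] + [[first] + part[i]] + part[i + 1:]
        yield [[first]] + part


def exhaustive_best_partition(weights) -> ModulePartition:
    """Exact maximum-Q partition by enumerating row set-partitions.

    For a fixed row partition each column independently joins the module
    with the highest contribution (or stays alone at contribution 0), so
    enumerating row partitions suffices for the global optimum.  Intended
    for test oracles on small networks.
    """
    w = _check_weights(weights)
    nr, nc = w.shape
    if nr > 8:
        raise ValueError("exhaustive search limited to 8 rows")
    m = w.sum()
    btilde = w - np.outer(w.sum(axis=1), w.sum(axis=0)) / m
    best_q = -np.inf
    best = None
    for part in _set_partitions(range(nr)):
        row_lab = np.empty(nr, dtype=int)
        for lab, block in enumerate(part):
            for i in block:
                row_lab[i] = lab
        col_lab = np.empty(nc, dtype=int)
        total = 0.0
        for j in range(nc):
            contribs = [btilde[block, j].sum() for block in
                        [np.flatnonzero(row_lab == lab)
                         for lab in range(len(part))]]
            cbest = max(contribs)
            if cbest > 0:
                col_lab[j] = int(np.argmax(contribs))
                total += cbest
            else:
                col_lab[j] = len(part) + j
        q = total / m
        if q > best_q + 1e-14:
            best_q = q
            best = (row_lab.copy(), col_lab.copy())
    return ModulePartition(row_modules=best[0], col_modules=best[1],
                           modularity=float(best_q))


def match_modules(old: ModulePartition, new: ModulePartition,
                  descent_map: dict[str, set] | None = None) -> ModulePartition:
    """Relabel ``old`` modules to the best-matching ``new`` modules.

    Ancestral lineages are expanded to their extant descendants through
    ``descent_map`` (old row label -> set of extant species); matching
    maximizes total Jaccard similarity of the expanded row-membership sets
    (ties to the lower new-module id); unmatched old modules get fresh
    labels above the new partition's range.
    """
    if old.row_modules.size == 0 or new.row_modules.size == 0:
        raise ValueError("empty partitions cannot be matched")
    if old.row_labels is None or new.row_labels is None:
        raise ValueError("both partitions need row_labels for matching")
    if descent_map is None:
        descent_map = {lab: {lab} for lab in old.row_labels}
    missing = set(old.row_labels) - set(descent_map)
    if missing:
        raise ValueError(f"descent map misses lineages: {sorted(missing)}")

    old_ids = sorted(set(old.row_modules) | set(old.col_modules))
    new_ids = sorted(set(new.row_modules))
    old_members = {
        o: set().union(*(descent_map[old.row_labels[i]]
                         for i in np.flatnonzero(old.row_modules == o)))
        if (old.row_modules == o).any() else set()
        for o in old_ids
    }
    new_members = {
        n: {new.row_labels[i] for i in np.flatnonzero(new.row_modules == n)}
        for n in new_ids
    }
    # maximize total Jaccard; epsilon on the new-id rank breaks ties low
    jac = np.zeros((len(old_ids), len(new_ids)))
    for a, o in enumerate(old_ids):
        for b, n in enumerate(new_ids):
            u = old_members[o] | new_members[n]
            jac[a, b] = (len(old_members[o] & new_members[n]) / len(u)) if u else 0.0
    tie = 1e-9 * (len(new_ids) - np.arange(len(new_ids))) / max(len(new_ids), 1)
    rows, cols = linear_sum_assignment(-(jac + tie[None, :]))
    remap: dict[int, int] = {}
    fresh = max(new_ids, default=0)
    for a, b in zip(rows, cols):
        if jac[a, b] > 0:
            remap[old_ids[a]] = new_ids[b]
    for o in old_ids:
        if o not in remap:
            fresh += 1
            remap[o] = fresh
    return ModulePartition(
        row_modules=np.array([remap[x] for x in old.row_modules]),
        col_modules=np.array([remap[x] for x in old.col_modules]),
        modularity=old.modularity,
        row_labels=old.row_labels, col_labels=old.col_labels,
    )
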